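"""Mapped-read count tables shared by the simulator, read mapper, and all
normalization stages.

A :class:`CountTable` holds one count per (sample, molecule, feature) cell
together with per-feature metadata (marker, lineage/family, gene length in
bp) and the per-(sample, molecule) total of mapped reads that serves as the
RPKM denominator.  The on-disk form is a plain TSV with ``#``-prefixed
metadata lines so a table produced by an external aligner can be dropped in.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._exceptions import InputDataError

DNA = "DNA"
RNA = "RNA"

#: Required columns of the tabular form, in on-disk order.
COLUMNS = ("feature_id", "lineage", "marker", "length_bp",
           "sample_id", "molecule", "count")


@dataclass
class CountTable:
    """Sample x feature mapped-read counts for one or more molecules.

    Parameters
    ----------
    data:
        Long-form frame with columns :data:`COLUMNS`.  ``lineage`` carries
        the ground-truth lineage (synthetic data) or the assigned family
        (mapped data); ``length_bp`` is the feature's gene length in bp.
    totals:
        ``(sample_id, molecule) -> total mapped reads`` used as the RPKM
        denominator.  May exceed the column sum when the table is a subset
        of a larger mapping run.
    """

    data: pd.DataFrame
    totals: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise InputDataError(f"count table missing columns: {missing}")
        self.data = self.data.loc[:, list(COLUMNS)].reset_index(drop=True)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`InputDataError` on negative counts, non-positive
        lengths, or counts exceeding the recorded totals."""
        d = self.data
        if (d["count"] < 0).any():
            raise InputDataError("negative counts present")
        if (d["length_bp"] <= 0).any():
            raise InputDataError("non-positive feature lengths present")
        sums = d.groupby(["sample_id", "molecule"])["count"].sum()
        for (sample, mol), s in sums.items():
            total = self.totals.get((sample, mol))
            if total is None:
                raise InputDataError(
                    f"no total recorded for sample={sample} molecule={mol}")
            # small float slack: expected-mode counts are real-valued
            if s > total * (1 + 1e-9) + 1e-9:
                raise InputDataError(
                    f"counts exceed total for sample={sample} molecule={mol}:"
                    f" {s} > {total}")

    # ------------------------------------------------------------------
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def molecules(self) -> list[str]:
        return sorted(self.data["molecule"].unique())

    def subset(self, *, sample: str | None = None,
               molecule: str | None = None,
               marker: str | None = None) -> pd.DataFrame:
        d = self.data
        if sample is not None:
            d = d[d["sample_id"] == sample]
        if molecule is not None:
            d = d[d["molecule"] == molecule]
        if marker is not None:
            d = d[d["marker"] == marker]
        return d

    def total(self, sample: str, molecule: str) -> float:
        try:
            return self.totals[(sample, molecule)]
        except KeyError as exc:
            raise InputDataError(
                f"no total for sample={sample} molecule={molecule}") from exc

    def feature_meta(self) -> pd.DataFrame:
        """One row per feature: lineage, marker, length_bp."""
        return (self.data[["feature_id", "lineage", "marker", "length_bp"]]
                .drop_duplicates("feature_id")
                .set_index("feature_id"))

    # ------------------------------------------------------------------
    def write_tsv(self, path: str | Path,
                  extra_header: Iterable[str] = ()) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("# nitriquant count table\n")
            for line in extra_header:
                fh.write(f"# {line}\n")
            for (sample, mol) in sorted(self.totals):
                fh.write(f"# total\tsample={sample}\tmolecule={mol}\t"
                         f"count={self.totals[(sample, mol)]!r}\n")
            self.data.to_csv(fh, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        path = Path(path)
        totals: dict[tuple[str, str], float] = {}
        body: list[str] = []
        for lineno, line in enumerate(path.read_text(encoding="utf-8")
                                      .splitlines(), start=1):
            if line.startswith("#"):
                if line.startswith("# total\t"):
                    try:
                        fields = dict(tok.split("=", 1)
                                      for tok in line[2:].split("\t")[1:])
                        totals[(fields["sample"], fields["molecule"])] = \
                            float(fields["count"])
                    except (ValueError, KeyError) as exc:
                        raise InputDataError(
                            f"{path}:{lineno}: malformed total line") from exc
            else:
                body.append(line)
        if not body:
            raise InputDataError(f"{path}: no table body")
        try:
            data = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t")
        except Exception as exc:  # parse errors -> uniform error type
            raise InputDataError(f"{path}: cannot parse TSV: {exc}") from exc
        return cls(data=data, totals=totals)


def concat_tables(tables: Iterable[CountTable]) -> CountTable:
    """Concatenate tables; totals for duplicate (sample, molecule) keys must
    agree."""
    tables = list(tables)
    totals: dict[tuple[str, str], float] = {}
    for t in tables:
        for key, val in t.totals.items():
            if key in totals and totals[key] != val:
                raise InputDataError(f"conflicting totals for {key}")
            totals[key] = val
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return CountTable(data=data, totals=totals)


def guild_map_from_meta(table: CountTable,
                        lineage_guilds: Mapping[str, str | None]) -> dict[str, str | None]:
    """Map each feature's lineage to a guild label via ``lineage_guilds``."""
    meta = table.feature_meta()
    return {lin: lineage_guilds.get(lin) for lin in meta["lineage"].unique()}
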