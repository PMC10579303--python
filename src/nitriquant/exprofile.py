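"""Per-lineage rpoB-normalized expression profiles and comparison against
pure-culture reference profiles.

For each lineage, phylotype transcript counts are summed per marker, turned
into RPKM with a member-weighted representative length, and divided by the
lineage's rpoB transcript RPKM; the log2 of that ratio is the profile
entry.  rpoB is constitutively expressed, so its own entry is exactly 0 and
other entries read as expression relative to the housekeeping baseline.
Two non-numeric states follow the heatmap vocabulary of such analyses: a
gene absent from the lineage's inventory is ABSENT ("X"); a gene present
but without detected transcripts is ND ("nd").  No pseudocounts are used.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._exceptions import FeatureLookupError, InputDataError
from .counts import RNA, CountTable
from .markers import MARKER_ORDER, marker_sort_key
from .abundance import rpkm

logger = logging.getLogger(__name__)


class ProfileState(enum.Enum):
    """Non-numeric heatmap states."""

    ABSENT = "X"   # gene absent from the lineage's inventory
    ND = "nd"      # gene present, no transcripts detected


ABSENT = ProfileState.ABSENT
ND = ProfileState.ND


@dataclass
class ExpressionProfile:
    """One lineage's (or strain's) log2 rpoB-normalized transcript profile."""

    lineage: str
    values: dict[str, "float | ProfileState"]
    inventory: dict[str, bool] = field(default_factory=dict)
    available: bool = True  # False when the lineage had no rpoB transcripts

    def numeric_markers(self) -> list[str]:
        return [m for m, v in self.values.items()
                if not isinstance(v, ProfileState)]


#: Reference profiles share the structure; the strain name sits in
#: ``lineage``.
ReferenceProfile = ExpressionProfile


@dataclass(frozen=True)
class FoldComparison:
    marker: str
    fold: float | None = None
    log2_delta: float | None = None
    incomparable: str | None = None


# ---------------------------------------------------------------------------
def lineage_aggregate(counts: CountTable,
                      family_map: Mapping[str, str],
                      members: Mapping[str, int] | None = None,
                      sample: str | None = None,
                      molecule: str = RNA) -> dict[tuple[str, str], float]:
    """Sum phylotype counts within (lineage, marker), then convert to RPKM.

    ``family_map`` maps feature (phylotype) id to lineage; every counted
    feature must be mapped.  The RPKM length of an aggregate is the
    member-count-weighted mean of its phylotype lengths, rounded
    (``members`` defaults to one member per phylotype).
    """
    if sample is None:
        samples = counts.samples()
        if len(samples) != 1:
            raise InputDataError("sample must be given for multi-sample "
                                 "tables")
        sample = samples[0]
    d = counts.subset(sample=sample, molecule=molecule)
    offenders = sorted(set(d["feature_id"]) - set(family_map))
    if offenders:
        raise InputDataError(
            f"features without a lineage mapping: {offenders}")
    total = counts.total(sample, molecule)
    groups: dict[tuple[str, str], dict[str, float]] = {}
    for row in d.itertuples():
        key = (family_map[row.feature_id], row.marker)
        g = groups.setdefault(key, {"count": 0.0, "wlen": 0.0, "w": 0.0})
        n = (members or {}).get(row.feature_id, 1)
        g["count"] += row.count
        g["wlen"] += n * row.length_bp
        g["w"] += n
    out: dict[tuple[str, str], float] = {}
    for key, g in groups.items():
        length = int(round(g["wlen"] / g["w"]))
        out[key] = rpkm(g["count"], length, total)
    return out


def rpob_profile(lineage: str, lineage_rpkm: Mapping[str, float],
                 rpob_rpkm: float,
                 inventory: Mapping[str, bool]) -> ExpressionProfile:
    """Build one lineage's profile from its per-marker transcript RPKMs.

    Markers absent from the inventory are ABSENT regardless of counts
    (counts on absent markers log an inconsistency); present markers with
    zero RPKM are ND.  ``rpob_rpkm`` must be positive — a lineage without
    rpoB transcripts has no baseline (see :func:`profiles_from_aggregate`).
    """
    if rpob_rpkm <= 0:
        raise InputDataError(
            f"{lineage}: zero rpoB transcript RPKM, profile unavailable")
    values: dict[str, float | ProfileState] = {}
    markers = set(lineage_rpkm) | set(inventory)
    for m in sorted(markers, key=marker_sort_key):
        present = inventory.get(m, m in lineage_rpkm)
        r = lineage_rpkm.get(m, 0.0)
        if not present:
            if r > 0:
                logger.warning(
                    "%s: transcripts for %s though inventory marks it "
                    "absent", lineage, m)
            values[m] = ABSENT
        elif r == 0:
            values[m] = ND
        else:
            values[m] = math.log2(r / rpob_rpkm)
    return ExpressionProfile(lineage=lineage, values=values,
                             inventory={m: inventory.get(m, m in lineage_rpkm)
                                        for m in markers})


def profiles_from_aggregate(agg: Mapping[tuple[str, str], float],
                            inventories: Mapping[str, Mapping[str, bool]]
                            ) -> dict[str, ExpressionProfile]:
    """Profiles for every lineage in an aggregate; lineages without rpoB
    transcripts come back with ``available=False`` and empty values."""
    lineages = sorted({lin for lin, _ in agg})
    out: dict[str, ExpressionProfile] = {}
    for lin in lineages:
        per_marker = {m: v for (l, m), v in agg.items() if l == lin}
        inv = dict(inventories.get(lin, {}))
        rpob = per_marker.get("rpoB", 0.0)
        if rpob <= 0:
            logger.warning("%s: no rpoB transcripts; profile unavailable",
                           lin)
            out[lin] = ExpressionProfile(lineage=lin, values={},
                                         inventory={m: bool(p) for m, p
                                                    in inv.items()},
                                         available=False)
        else:
            out[lin] = rpob_profile(lin, per_marker, rpob, inv)
    return out


def average_profiles(profiles: Sequence[ExpressionProfile],
                     lineage: str | None = None) -> ExpressionProfile:
    """Average one lineage's profiles over samples (plots/seasons).

    Numeric entries are arithmetic means of log2 ratios over the samples
    where the marker was numeric; ND propagates only when every sample is
    ND; ABSENT propagates as ABSENT.
    """
    profiles = [p for p in profiles if p.available]
    if not profiles:
        raise InputDataError("no available profiles to average")
    name = lineage or profiles[0].lineage
    markers = sorted({m for p in profiles for m in p.values},
                     key=marker_sort_key)
    values: dict[str, float | ProfileState] = {}
    inventory: dict[str, bool] = {}
    for m in markers:
        states = [p.values[m] for p in profiles if m in p.values]
        inventory[m] = any(p.inventory.get(m, False) for p in profiles)
        if any(v is ABSENT for v in states):
            values[m] = ABSENT
        else:
            numeric = [v for v in states if not isinstance(v, ProfileState)]
            values[m] = (sum(numeric) / len(numeric)) if numeric else ND
    return ExpressionProfile(lineage=name, values=values,
                             inventory=inventory)


# ---------------------------------------------------------------------------
def fold_difference(soil: ExpressionProfile, ref: ReferenceProfile,
                    marker: str) -> FoldComparison:
    """Fold change of a marker between a soil lineage and a culture strain.

    Both entries numeric: fold = 2**(soil - ref).  Any ABSENT/ND state on
    either side makes the marker incomparable, with the state as reason.
    """
    for prof, side in ((soil, "soil"), (ref, "reference")):
        if marker not in prof.values:
            raise FeatureLookupError(
                f"marker {marker} not in {side} profile {prof.lineage}")
    sv, rv = soil.values[marker], ref.values[marker]
    for v, side in ((sv, "soil"), (rv, "reference")):
        if isinstance(v, ProfileState):
            return FoldComparison(
                marker=marker,
                incomparable=f"{side}_{'absent' if v is ABSENT else 'nd'}")
    delta = sv - rv
    return FoldComparison(marker=marker, fold=2.0 ** delta,
                          log2_delta=delta)


def flag_divergent(soil: ExpressionProfile, ref: ReferenceProfile,
                   fold_cutoff: float = 10.0
                   ) -> tuple[list[tuple[str, float, str]], list[tuple[str, str]]]:
    """Markers whose soil-vs-culture fold change exceeds ``fold_cutoff``.

    Returns (divergent, incomparable): divergent entries are
    (marker, fold, direction) with direction ``higher_in_soil`` or
    ``lower_in_soil``; incomparable entries are (marker, reason).
    """
    if fold_cutoff <= 1:
        raise InputDataError("fold_cutoff must exceed 1")
    shared = sorted(set(soil.values) & set(ref.values),
                    key=marker_sort_key)
    divergent: list[tuple[str, float, str]] = []
    incomparable: list[tuple[str, str]] = []
    for m in shared:
        cmp_ = fold_difference(soil, ref, m)
        if cmp_.incomparable is not None:
            incomparable.append((m, cmp_.incomparable))
        elif cmp_.fold > fold_cutoff:
            divergent.append((m, cmp_.fold, "higher_in_soil"))
        elif cmp_.fold < 1.0 / fold_cutoff:
            divergent.append((m, cmp_.fold, "lower_in_soil"))
    return divergent, incomparable


# ---------------------------------------------------------------------------
# heatmap matrix IO
# ---------------------------------------------------------------------------
def _cell(v: "float | ProfileState") -> str:
    return v.value if isinstance(v, ProfileState) else f"{v:.6f}"


def heatmap_frame(profiles: Sequence[ExpressionProfile],
                  marker_order: Iterable[str] = MARKER_ORDER
                  ) -> pd.DataFrame:
    """Markers x lineages matrix with 'X'/'nd' cells, heatmap-ready."""
    cols = [p for p in profiles if p.available]
    markers = [m for m in marker_order
               if any(m in p.values for p in cols)]
    extra = sorted({m for p in cols for m in p.values} - set(markers),
                   key=marker_sort_key)
    data = {p.lineage: [(_cell(p.values[m]) if m in p.values else "X")
                        for m in markers + extra]
            for p in cols}
    return pd.DataFrame(data, index=markers + extra).rename_axis("marker")


def write_heatmap_tsv(profiles: Sequence[ExpressionProfile],
                      path: str | Path,
                      extra_header: Iterable[str] = ()) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# nitriquant expression heatmap "
                 "(log2 rpoB-normalized RPKM; X=absent, nd=no transcripts)\n")
        for line in extra_header:
            fh.write(f"# {line}\n")
        heatmap_frame(profiles).to_csv(fh, sep="\t", lineterminator="\n")


def read_reference_profiles(path: str | Path) -> dict[str, ReferenceProfile]:
    """Read strain reference profiles from a heatmap-style TSV
    (rows=markers, columns=strains, cells numeric / 'X' / 'nd')."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    out: dict[str, ReferenceProfile] = {}
    for strain in df.columns:
        values: dict[str, float | ProfileState] = {}
        inventory: dict[str, bool] = {}
        for marker, cell in df[strain].items():
            cell = str(cell).strip()
            if cell == "X":
                values[marker] = ABSENT
                inventory[marker] = False
            elif cell == "nd":
                values[marker] = ND
                inventory[marker] = True
            else:
                try:
                    values[marker] = float(cell)
                except ValueError as exc:
                    raise InputDataError(
                        f"{path}: bad cell {cell!r} for {strain}/{marker}"
                    ) from exc
                inventory[marker] = True
        out[strain] = ExpressionProfile(lineage=strain, values=values,
                                        inventory=inventory)
    return out
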