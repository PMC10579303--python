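"""End-to-end orchestration of the synthetic quantification workflow.

``run_quantify`` wires the stages in dependency order — community
simulation, marker FASTA emission, phylotype dereplication and family
assignment, guild proportions, phylotype activity, and per-lineage
expression profiles — writing each result as a self-describing TSV stamped
with the configuration hash and seed.  Re-running an identical
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import abundance, activity, exprofile, phylodb, synthcomm
from ._exceptions import InputDataError
from .config import RunConfig
from .counts import CountTable

logger = logging.getLogger(__name__)


def _header(config: RunConfig) -> list[str]:
    return [f"config_sha256={config.config_hash()}", f"seed={config.seed}"]


def run_quantify(config: RunConfig) -> Path:
    """Run the full synthetic pipeline; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = _header(config)

    # 1. community truth and simulated counts
    truth = synthcomm.generate_community(config.n_lineages, config.seed,
                                         config.profile)
    truth.write_tsv(outdir / "truth.tsv")
    sim = synthcomm.SimulationConfig(depth_dna=config.depth_dna,
                                     depth_rna=config.depth_rna,
                                     seed=config.seed, mode=config.mode)
    table_dna, table_rna = synthcomm.simulate_counts(truth, sim)
    table_dna.write_tsv(outdir / "counts_dna.tsv", hdr)
    table_rna.write_tsv(outdir / "counts_rna.tsv", hdr)

    # 2. marker proteins -> phylotype database with family assignment;
    #    the first variant of each lineage doubles as its reference entry
    records = synthcomm.emit_marker_fasta(
        truth, config.phylotypes_per_lineage, config.divergence,
        config.seed, path=outdir / "markers.faa")
    by_marker: dict[str, list[phylodb.ProteinRecord]] = {}
    refs_by_marker: dict[str, list[phylodb.ProteinRecord]] = {}
    for rec in records:
        tokens = dict(t.split("=", 1) for t in rec.description.split()
                      if "=" in t)
        pr = phylodb.ProteinRecord(id=rec.id, marker=tokens["marker"],
                                   sequence=str(rec.seq))
        by_marker.setdefault(pr.marker, []).append(pr)
        if rec.id.endswith("|pt1"):
            refs_by_marker.setdefault(pr.marker, []).append(
                phylodb.ProteinRecord(
                    id=f"ref_{rec.id}", marker=pr.marker,
                    sequence=pr.sequence, source=phylodb.REFERENCE,
                    family=tokens["family"]))
    phylotypes: list[phylodb.Phylotype] = []
    for marker in sorted(by_marker):
        phylotypes.extend(phylodb.build_phylodb(
            by_marker[marker], refs_by_marker[marker],
            threshold=config.thresholds.derep_threshold(marker),
            min_identity=config.thresholds.assign_min_identity))
    phylodb.write_phylotype_table(phylotypes, outdir / "phylotypes.tsv",
                                  hdr)

    # 3. guild proportions from the DNA table
    model = config.copy_model()
    estimates = abundance.estimate_guild_proportions(
        table_dna, truth.guild_map(), model)
    frame = abundance.proportions_frame(estimates, sim.sample_id)
    _write_frame(frame, outdir / "proportions.tsv",
                 ["nitriquant guild proportions (cell share of all "
                  "prokaryotes)"] + hdr)

    # 4. phylotype activity on the archaeal amoA group
    aoa_lineages = [l.name for l in truth.lineages if l.guild == "AOA"]
    fam_of = {f"{l.name}|{m}": l.family for l in truth.lineages
              for m in l.markers()}
    act_records = activity.compute_activity(
        table_dna, table_rna, "amoA", family_map=fam_of,
        threshold=config.thresholds.activity_threshold,
        guild_lineages=aoa_lineages)
    _write_frame(activity.activity_frame(act_records),
                 outdir / "activity.tsv",
                 ["nitriquant amoA transcript:gene activity"] + hdr)
    fam_summary = activity.classify_activity(
        act_records, config.thresholds.activity_threshold)
    _write_frame(
        _frame_from_pairs(fam_summary, "family", "fraction_active"),
        outdir / "activity_family_summary.tsv", hdr)

    # 5. per-lineage expression profiles from the RNA table
    feature_lineage = {f"{l.name}|{m}": l.name for l in truth.lineages
                       for m in l.markers()}
    feature_lineage[f"{synthcomm.BACKGROUND}|rpoB"] = synthcomm.BACKGROUND
    agg = exprofile.lineage_aggregate(table_rna, feature_lineage)
    inventories = {l.name: {m: True for m in l.markers()}
                   for l in truth.lineages}
    profiles = exprofile.profiles_from_aggregate(
        {k: v for k, v in agg.items() if k[0] != synthcomm.BACKGROUND},
        inventories)
    exprofile.write_heatmap_tsv(list(profiles.values()),
                                outdir / "expression_profiles.tsv", hdr)
    logger.info("run complete: %s", outdir)
    return outdir


def _write_frame(frame, path: Path, header: Iterable[str]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _frame_from_pairs(mapping, key, value):
    import pandas as pd
    return pd.DataFrame([{key: k, value: v}
                         for k, v in sorted(mapping.items())])


def output_digests(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every file in a run directory (determinism checks)."""
    outdir = Path(outdir)
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.iterdir()) if p.is_file()}


# ---------------------------------------------------------------------------
# table validation
# ---------------------------------------------------------------------------
@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_tables(count_tables: Iterable[str | Path],
                    phylotype_table: str | Path | None = None
                    ) -> ValidationReport:
    """Check count-table schema and invariants, and cross-reference feature
    ids against a phylotype table when given."""
    report = ValidationReport()
    known_features: set[str] | None = None
    if phylotype_table is not None:
        import pandas as pd
        pt = pd.read_csv(phylotype_table, sep="\t", comment="#")
        known_features = set(pt["phylotype_id"].astype(str))
    for path in count_tables:
        path = Path(path)
        try:
            table = CountTable.read_tsv(path)
            table.validate()
        except InputDataError as exc:
            report.violations.append(f"{path}: {exc}")
            continue
        if known_features is not None:
            unknown = sorted(set(table.data["feature_id"].astype(str))
                             - known_features)
            if unknown:
                report.violations.append(
                    f"{path}: features absent from phylotype table: "
                    f"{unknown[:5]}")
    return report
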