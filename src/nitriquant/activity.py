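"""Transcript-to-gene recovery-ratio activity classification of phylotypes.

Within a marker's group (e.g. all archaeal amoA phylotypes) each phylotype
gets a *recovery frequency*: its share of the group's mapped reads,
separately in the DNA and RNA pools.  The ratio RNA-frequency over
DNA-frequency exceeds 1 for phylotypes transcribing the gene
disproportionately to their abundance; a phylotype detected only in RNA is
active by definition (infinite ratio sentinel), one detected in neither
pool is undetected and excluded from family summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._exceptions import InputDataError
from .counts import DNA, RNA, CountTable

logger = logging.getLogger(__name__)

ACTIVE = "active"
LOW = "low"
RNA_ONLY = "rna_only"
UNDETECTED = "undetected"


@dataclass(frozen=True)
class ActivityRecord:
    phylotype: str
    family: str
    sample: str
    freq_dna: float
    freq_rna: float
    ratio: float  # math.inf when detected in RNA only; nan when undetected
    status: str


def recovery_frequency(counts: Mapping[str, float],
                       group_total: float | None = None
                       ) -> dict[str, float]:
    """Each phylotype's share of the group's reads; shares sum to 1."""
    total = sum(counts.values()) if group_total is None else group_total
    if total <= 0:
        raise InputDataError("zero group total: no reads to apportion")
    return {pt: c / total for pt, c in counts.items()}


def transcript_gene_ratio(freq_rna: float, freq_dna: float) -> float:
    """RNA over DNA recovery frequency; inf if RNA-only, nan if undetected."""
    if not (0 <= freq_rna <= 1 and 0 <= freq_dna <= 1):
        raise InputDataError("frequencies must be in [0, 1]")
    if freq_dna > 0:
        return freq_rna / freq_dna
    return math.inf if freq_rna > 0 else math.nan


def activity_status(freq_dna: float, freq_rna: float,
                    threshold: float = 1.0) -> str:
    if freq_dna == 0 and freq_rna == 0:
        return UNDETECTED
    if freq_dna == 0:
        return RNA_ONLY
    return ACTIVE if (freq_rna / freq_dna) > threshold else LOW


def compute_activity(table_dna: CountTable, table_rna: CountTable,
                     marker: str,
                     family_map: Mapping[str, str] | None = None,
                     threshold: float = 1.0,
                     guild_lineages: Iterable[str] | None = None
                     ) -> list[ActivityRecord]:
    """Build per-(phylotype, sample) activity records for one marker group.

    The group is all features of ``marker`` (optionally restricted to
    ``guild_lineages``); frequencies are computed within the group per
    sample and molecule.  ``family_map`` maps feature id to family,
    defaulting to the table's lineage column.
    """
    records: list[ActivityRecord] = []
    for sample in table_dna.samples():
        d_dna = table_dna.subset(sample=sample, molecule=DNA, marker=marker)
        d_rna = table_rna.subset(sample=sample, molecule=RNA, marker=marker)
        if guild_lineages is not None:
            keep = set(guild_lineages)
            d_dna = d_dna[d_dna["lineage"].isin(keep)]
            d_rna = d_rna[d_rna["lineage"].isin(keep)]
        fams = {r.feature_id: (family_map[r.feature_id] if family_map
                               else r.lineage)
                for r in pd.concat([d_dna, d_rna]).itertuples()}
        cd = {r.feature_id: r.count for r in d_dna.itertuples()}
        cr = {r.feature_id: r.count for r in d_rna.itertuples()}
        feats = sorted(set(cd) | set(cr))
        fd = recovery_frequency({f: cd.get(f, 0.0) for f in feats}) \
            if sum(cd.values()) > 0 else {f: 0.0 for f in feats}
        fr = recovery_frequency({f: cr.get(f, 0.0) for f in feats}) \
            if sum(cr.values()) > 0 else {f: 0.0 for f in feats}
        for f in feats:
            records.append(ActivityRecord(
                phylotype=f, family=fams[f], sample=sample,
                freq_dna=fd[f], freq_rna=fr[f],
                ratio=transcript_gene_ratio(fr[f], fd[f]),
                status=activity_status(fd[f], fr[f], threshold)))
    return records


def classify_activity(records: Sequence[ActivityRecord],
                      threshold: float = 1.0) -> dict[str, float]:
    """Fraction of each family's phylotypes active in at least one sample.

    A phylotype is active if its ratio strictly exceeds ``threshold`` or it
    is RNA-only in any sample; phylotypes undetected in every sample are
    excluded from the denominator.  Families with no detected phylotype are
    excluded with a warning.
    """
    by_pt: dict[tuple[str, str], list[ActivityRecord]] = {}
    for r in records:
        by_pt.setdefault((r.family, r.phylotype), []).append(r)
    active: dict[str, int] = {}
    detected: dict[str, int] = {}
    families = {fam for fam, _ in by_pt}
    for (fam, _pt), recs in by_pt.items():
        if all(r.status == UNDETECTED for r in recs):
            continue
        detected[fam] = detected.get(fam, 0) + 1
        is_active = any(
            r.status == RNA_ONLY
            or (not math.isnan(r.ratio) and not math.isinf(r.ratio)
                and r.ratio > threshold)
            for r in recs)
        if is_active:
            active[fam] = active.get(fam, 0) + 1
    out: dict[str, float] = {}
    for fam in sorted(families):
        if detected.get(fam, 0) == 0:
            logger.warning("family %s has no detected phylotypes; excluded",
                           fam)
            continue
        out[fam] = active.get(fam, 0) / detected[fam]
    return out


def activity_frame(records: Sequence[ActivityRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "phylotype": r.phylotype, "family": r.family, "sample": r.sample,
        "freq_dna": r.freq_dna, "freq_rna": r.freq_rna,
        "ratio": ("inf" if math.isinf(r.ratio)
                  else "nan" if math.isnan(r.ratio) else r.ratio),
        "status": r.status} for r in records])
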