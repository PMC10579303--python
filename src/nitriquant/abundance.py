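"""RPKM normalization and copy-number-corrected community proportions of
nitrifier guilds.

The model: every prokaryotic genome carries exactly one rpoB copy, so total
rpoB RPKM is proportional to total cells.  A guild's cell share is its
marker-gene RPKM divided by the guild's per-cell gene copy number, relative
to total rpoB RPKM.  Default copy numbers: AOA 1 amoA, AOB 2.5 amoA,
comammox Nitrospira 1.5 amoA, Nitrospira 4 nxrB copies per cell.  Canonical
(strictly nitrite-oxidizing) Nitrospira is the difference between total
Nitrospira (nxrB-based) and comammox (amoA-based) proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ._exceptions import ConfigurationError, InputDataError
from .counts import DNA, CountTable

logger = logging.getLogger(__name__)

SINGLE = "single"
MULTI = "multi"
FACULTATIVE = "facultative"

DEFAULT_COPIES: dict[tuple[str, str], float] = {
    ("prokaryote", "rpoB"): 1.0,
    ("AOA", "amoA"): 1.0,
    ("AOB", "amoA"): 2.5,
    ("comammox", "amoA"): 1.5,
    ("Nitrospira", "nxrB"): 4.0,
}


@dataclass(frozen=True)
class CopyModel:
    """Per-(guild, marker) gene copy numbers used for cell-share correction."""

    copies: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COPIES))

    def __post_init__(self) -> None:
        for (g, m), c in self.copies.items():
            if c <= 0:
                raise ConfigurationError(
                    f"copy number for ({g}, {m}) must be positive")

    def get(self, guild: str, marker: str) -> float:
        try:
            return self.copies[(guild, marker)]
        except KeyError as exc:
            raise ConfigurationError(
                f"no copy number configured for guild={guild} "
                f"marker={marker}") from exc

    @classmethod
    def from_mapping(cls, flat: Mapping[str, float]) -> "CopyModel":
        """Build from flat ``"guild.marker" -> copies`` keys (config files)."""
        copies = dict(DEFAULT_COPIES)
        for key, val in flat.items():
            guild, _, marker = key.partition(".")
            if not marker:
                raise ConfigurationError(f"bad copy-model key {key!r}")
            copies[(guild, marker)] = float(val)
        return cls(copies=copies)


# ---------------------------------------------------------------------------
def rpkm(count: float, length_bp: int, total_reads: float) -> float:
    """Reads per kilobase of gene per million mapped reads.

    Computed as ``(count / total) * (1e9 / length)`` so that a common
    integer scaling of count and total cancels exactly in the division.
    """
    if length_bp <= 0:
        raise InputDataError("length_bp must be positive")
    if total_reads <= 0:
        raise InputDataError("total_reads must be positive")
    if count < 0:
        raise InputDataError("count must be non-negative")
    return (count / total_reads) * (1e9 / length_bp)


def guild_proportion(guild_marker_rpkm: float, guild: str, marker: str,
                     model: CopyModel, rpob_total_rpkm: float) -> float:
    """Guild cell share: copy-corrected marker RPKM over total rpoB RPKM."""
    if rpob_total_rpkm <= 0:
        raise InputDataError("rpob_total_rpkm must be positive")
    if guild_marker_rpkm < 0:
        raise InputDataError("negative RPKM")
    return (guild_marker_rpkm / model.get(guild, marker)) / rpob_total_rpkm


def canonical_nitrospira(nxrb_rpkm: float, comammox_amoa_rpkm: float,
                         model: CopyModel, rpob_total_rpkm: float) -> float:
    """Canonical (non-comammox) Nitrospira cell share.

    Total Nitrospira (nxrB-based) minus comammox (amoA-based); a negative
    difference — possible since nxrB copy numbers vary between cells — is
    clamped to zero and logged.  The difference is taken on the proportion
    scale so that comammox + canonical equals the total share exactly.
    """
    total = guild_proportion(nxrb_rpkm, "Nitrospira", "nxrB", model,
                             rpob_total_rpkm)
    comammox = guild_proportion(comammox_amoa_rpkm, "comammox", "amoA",
                                model, rpob_total_rpkm)
    diff = total - comammox
    if diff < 0:
        logger.warning(
            "canonical Nitrospira clamp: comammox share %.3g exceeds total "
            "Nitrospira share %.3g", comammox, total)
        return 0.0
    # The partition identity comammox + canonical == total is part of the
    # contract; the rounded difference can miss it by one ulp, so nudge to
    # the neighbouring float that restores exactness when needed.
    if comammox + diff != total:
        for cand in (math.nextafter(diff, 0.0),
                     math.nextafter(diff, math.inf)):
            if cand >= 0 and comammox + cand == total:
                diff = cand
                break
    return diff


def comammox_fraction_of_nitrospira(comammox_amoa_rpkm: float,
                                    nxrb_rpkm: float,
                                    model: CopyModel) -> float:
    """Comammox cells as a fraction of all Nitrospira cells (clamped to 1)."""
    if nxrb_rpkm <= 0:
        raise InputDataError("nxrb_rpkm must be positive")
    frac = ((comammox_amoa_rpkm / model.get("comammox", "amoA"))
            / (nxrb_rpkm / model.get("Nitrospira", "nxrB")))
    if frac > 1:
        logger.warning("comammox fraction %.3g > 1 clamped", frac)
        return 1.0
    return frac


def copy_ratio(gene_rpkm: float, rpob_rpkm: float, expected_class: str,
               band: tuple[float, float] = (0.5, 2.0)) -> tuple[float, str]:
    """Gene:rpoB RPKM ratio with a consistency flag for its copy class.

    Single-copy genes should sit near 1 (within ``band``); habitually
    multi-copy genes above 1; facultative genes (not carried by every cell)
    below 1.
    """
    if rpob_rpkm <= 0:
        raise InputDataError("rpob_rpkm must be positive")
    ratio = gene_rpkm / rpob_rpkm
    if expected_class == SINGLE:
        ok = band[0] <= ratio <= band[1]
    elif expected_class == MULTI:
        ok = ratio > 1
    elif expected_class == FACULTATIVE:
        ok = ratio < 1
    else:
        raise ConfigurationError(
            f"unknown copy class {expected_class!r}")
    return ratio, ("consistent" if ok else "inconsistent")


def gene_prevalence(gene_rpkm: float, rpob_rpkm: float) -> float:
    """Percent of a guild's cells carrying a (single-copy) gene.

    The rpoB RPKM of the same guild anchors the denominator; ratios above
    one violate the single-copy prevalence reading and clamp to 100%.
    """
    if rpob_rpkm <= 0:
        raise InputDataError("rpob_rpkm must be positive")
    ratio = gene_rpkm / rpob_rpkm
    if ratio > 1:
        logger.warning("gene prevalence %.3g > 1 clamped to 100%%", ratio)
        return 100.0
    return 100.0 * ratio


# ---------------------------------------------------------------------------
# table-level estimation
# ---------------------------------------------------------------------------
def marker_rpkm_sum(table: CountTable, *, sample: str, molecule: str,
                    marker: str,
                    guild_map: Mapping[str, str | None] | None = None,
                    guild: str | None = None) -> float:
    """Summed RPKM of a marker, optionally restricted to one guild's
    lineages."""
    d = table.subset(sample=sample, molecule=molecule, marker=marker)
    if guild is not None:
        if guild_map is None:
            raise ConfigurationError("guild filter requires a guild_map")
        d = d[d["lineage"].map(lambda l: guild_map.get(l)) == guild]
    total = table.total(sample, molecule)
    return float(sum(rpkm(row.count, row.length_bp, total)
                     for row in d.itertuples()))


def estimate_guild_proportions(table: CountTable,
                               guild_map: Mapping[str, str | None],
                               model: CopyModel | None = None,
                               sample: str | None = None,
                               molecule: str = DNA) -> dict[str, float]:
    """Estimate nitrifier guild cell shares from a DNA count table.

    Returns AOA, AOB, and comammox shares (amoA-based), the total- and
    canonical-Nitrospira shares (nxrB-based with comammox differencing),
    and, when nxrB signal is present, the comammox fraction of Nitrospira.
    """
    model = model or CopyModel()
    if sample is None:
        samples = table.samples()
        if len(samples) != 1:
            raise InputDataError("sample must be given for multi-sample "
                                 "tables")
        sample = samples[0]
    rpob_total = marker_rpkm_sum(table, sample=sample, molecule=molecule,
                                 marker="rpoB")
    if rpob_total <= 0:
        raise InputDataError("no rpoB signal: cannot normalize")
    out: dict[str, float] = {}
    for guild in ("AOA", "AOB", "comammox"):
        g_rpkm = marker_rpkm_sum(table, sample=sample, molecule=molecule,
                                 marker="amoA", guild_map=guild_map,
                                 guild=guild)
        out[guild] = guild_proportion(g_rpkm, guild, "amoA", model,
                                      rpob_total)
    nxrb = marker_rpkm_sum(table, sample=sample, molecule=molecule,
                           marker="nxrB")
    cmx_amoa = marker_rpkm_sum(table, sample=sample, molecule=molecule,
                               marker="amoA", guild_map=guild_map,
                               guild="comammox")
    out["total_Nitrospira"] = guild_proportion(
        nxrb, "Nitrospira", "nxrB", model, rpob_total)
    out["canonical_Nitrospira"] = canonical_nitrospira(
        nxrb, cmx_amoa, model, rpob_total)
    if nxrb > 0:
        out["comammox_fraction_of_Nitrospira"] = \
            comammox_fraction_of_nitrospira(cmx_amoa, nxrb, model)
    return out


def proportions_frame(estimates: Mapping[str, float],
                      sample: str) -> pd.DataFrame:
    markers = {"AOA": "amoA", "AOB": "amoA", "comammox": "amoA",
               "total_Nitrospira": "nxrB", "canonical_Nitrospira": "nxrB",
               "comammox_fraction_of_Nitrospira": "amoA/nxrB"}
    rows = [{"sample": sample, "guild": g, "marker": markers.get(g, ""),
             "proportion": v, "percent": 100.0 * v}
            for g, v in estimates.items()]
    return pd.DataFrame(rows)


def _isclose(a: float, b: float, rel: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=rel, abs_tol=1e-12)
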