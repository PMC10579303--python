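"""Synthetic nitrifier communities with known ground truth.

The generator emulates the quantities the quantification pipeline estimates
from real metagenomes: a set of lineages with relative cell abundances,
per-marker gene copy numbers (rpoB fixed at one copy per genome, the
single-copy normalization anchor), per-gene transcription rates relative to
rpoB, a dominant pool of non-nitrifier prokaryotes contributing only rpoB
signal, and DNA/RNA read counts drawn either as exact expectations
("expected" mode) or as one multinomial draw at a fixed sequencing depth
("sampled" mode).  Conditioning on total depth mirrors the per-million-reads
normalization of RPKM.

Closed-form guild proportions and delta-method standard errors are exposed
so downstream estimates can be checked against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from ._exceptions import ConfigurationError, FeatureLookupError, InputDataError
from .counts import DNA, RNA, CountTable
from .markers import DEFAULT_MARKER_LENGTHS, marker_sort_key

BACKGROUND = "background"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# guild labels used by the soil-like preset
AOA = "AOA"
AOB = "AOB"
COMAMMOX = "comammox"

_AOA_FAMILIES = (
    "NS-delta", "Nitrososphaeraceae", "NS-beta", "NS-epsilon",
    "NS-beta-associated", "NS-gamma", "NS-zeta", "NP-delta",
    "Nitrosotenuaceae", "Nitrosotaleaceae",
)


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class LineageSpec:
    """One lineage of the synthetic community.

    ``gene_copies`` are population-average copies per genome (real-valued so
    guild averages such as 2.5 amoA copies in ammonia-oxidizing bacteria can
    be represented); ``expression_rate`` is transcripts per gene copy
    relative to rpoB, whose rate is 1 by definition.
    """

    name: str
    family: str
    order: str
    cell_abundance: float
    gene_copies: Mapping[str, float]
    expression_rate: Mapping[str, float]
    guild: str | None = None

    def __post_init__(self) -> None:
        if self.cell_abundance < 0:
            raise InputDataError(f"{self.name}: negative cell abundance")
        if self.gene_copies.get("rpoB") != 1:
            raise InputDataError(
                f"{self.name}: rpoB must be single-copy (got "
                f"{self.gene_copies.get('rpoB')})")
        for m, c in self.gene_copies.items():
            if c < 0:
                raise InputDataError(f"{self.name}: negative copies for {m}")
            if c > 0 and m not in self.expression_rate:
                raise InputDataError(
                    f"{self.name}: no expression rate for carried gene {m}")

    def markers(self) -> list[str]:
        return sorted((m for m, c in self.gene_copies.items() if c > 0),
                      key=marker_sort_key)


@dataclass(frozen=True)
class CommunityTruth:
    """Ground truth of a synthetic community.

    ``background_rpob`` is the rpoB signal (in cell units) of all non-target
    prokaryotes; it enters the rpoB denominator only.
    """

    lineages: tuple[LineageSpec, ...]
    background_rpob: float
    marker_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_LENGTHS))

    def __post_init__(self) -> None:
        if not any(l.cell_abundance > 0 for l in self.lineages):
            raise InputDataError("all lineage abundances are zero")
        if self.background_rpob < 0:
            raise InputDataError("negative background rpoB pool")
        for m, L in self.marker_lengths.items():
            if L <= 0:
                raise InputDataError(f"non-positive length for marker {m}")
        names = [l.name for l in self.lineages]
        if len(set(names)) != len(names):
            raise InputDataError("duplicate lineage names")
        for lin in self.lineages:
            for m in lin.gene_copies:
                if m not in self.marker_lengths:
                    raise InputDataError(
                        f"{lin.name}: no length for marker {m}")

    # -- lookups -----------------------------------------------------------
    def lineage(self, name: str) -> LineageSpec:
        for lin in self.lineages:
            if lin.name == name:
                return lin
        raise FeatureLookupError(name)

    def guild_map(self) -> dict[str, str | None]:
        gm: dict[str, str | None] = {l.name: l.guild for l in self.lineages}
        gm[BACKGROUND] = None
        return gm

    def total_cells(self) -> float:
        return sum(l.cell_abundance for l in self.lineages) + self.background_rpob

    # -- closed-form truth -------------------------------------------------
    def weights(self, molecule: str) -> dict[tuple[str, str], float]:
        """Un-normalized expected read mass per (lineage, marker) feature.

        DNA mass is abundance x copies x length; RNA mass additionally
        carries the expression rate.  The background pool contributes a
        single rpoB feature (expression rate 1: housekeeping).
        """
        if molecule not in (DNA, RNA):
            raise ConfigurationError(f"unknown molecule {molecule!r}")
        w: dict[tuple[str, str], float] = {}
        for lin in self.lineages:
            for m in lin.markers():
                mass = (lin.cell_abundance * lin.gene_copies[m]
                        * self.marker_lengths[m])
                if molecule == RNA:
                    mass *= lin.expression_rate[m]
                w[(lin.name, m)] = mass
        if self.background_rpob > 0:
            w[(BACKGROUND, "rpoB")] = (self.background_rpob
                                       * self.marker_lengths["rpoB"])
        return w

    def true_guild_proportion(self, guild: str) -> float:
        """Cell share of a guild among all rpoB-carrying prokaryotes."""
        num = sum(l.cell_abundance for l in self.lineages if l.guild == guild)
        return num / self.total_cells()

    def true_guild_proportions(self) -> dict[str, float]:
        guilds = sorted({l.guild for l in self.lineages if l.guild})
        return {g: self.true_guild_proportion(g) for g in guilds}

    def proportion_standard_error(self, guild: str, marker: str,
                                  depth: int) -> float:
        """Delta-method SE of the estimated guild proportion at ``depth``.

        The estimate is a ratio of two read counts, each a binomial draw at
        its expected multinomial cell probability; the SE propagates both
        count variances (their covariance is O(1/depth), negligible).
        """
        w = self.weights(DNA)
        W = sum(w.values())
        q_num = sum(v for (lin, m), v in w.items() if m == marker
                    and self.guild_map().get(lin) == guild) / W
        q_den = sum(v for (_, m), v in w.items() if m == "rpoB") / W
        if q_num == 0:
            return 0.0
        rel_var = ((1 - q_num) / (depth * q_num)
                   + (1 - q_den) / (depth * q_den))
        return self.true_guild_proportion(guild) * math.sqrt(rel_var)

    def scaled(self, factor: float) -> "CommunityTruth":
        """Multiply every cell abundance (and the background pool) by
        ``factor``; all downstream proportions are invariant."""
        if factor <= 0:
            raise ConfigurationError("scale factor must be positive")
        lineages = tuple(replace(l, cell_abundance=l.cell_abundance * factor)
                         for l in self.lineages)
        return replace(self, lineages=lineages,
                       background_rpob=self.background_rpob * factor)

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lin in self.lineages:
            for m in lin.markers():
                rows.append({
                    "lineage": lin.name, "family": lin.family,
                    "order": lin.order, "guild": lin.guild or "",
                    "cell_abundance": lin.cell_abundance, "marker": m,
                    "gene_copies": lin.gene_copies[m],
                    "expression_rate": lin.expression_rate[m],
                    "length_bp": self.marker_lengths[m],
                })
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("# truth\n")
            fh.write(f"# background_rpob={self.background_rpob!r}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False,
                                   lineterminator="\n")


@dataclass(frozen=True)
class SimulationConfig:
    """Sequencing-depth and noise configuration for one simulation call."""

    depth_dna: int
    depth_rna: int
    seed: int
    mode: Literal["sampled", "expected"] = "sampled"
    sample_id: str = "S1"

    def __post_init__(self) -> None:
        if self.depth_dna <= 0 or self.depth_rna <= 0:
            raise ConfigurationError("sequencing depth must be positive")
        if self.mode not in ("sampled", "expected"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


# ---------------------------------------------------------------------------
def _quantize45(x: np.ndarray) -> np.ndarray:
    """Round to 45 significand bits; exact under small integer scaling."""
    mant, exp = np.frexp(x)
    return np.ldexp(np.round(np.ldexp(mant, 45)), exp - 45)


def expected_count(truth: CommunityTruth, lineage: str, marker: str,
                   molecule: str, depth: int) -> float:
    """Expected mapped-read count of one (lineage, marker) feature.

    Expectations over all features (including the background rpoB pool) sum
    to ``depth``: the simulator conditions on total mapped reads.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    if lineage != BACKGROUND:
        lin = truth.lineage(lineage)  # raises FeatureLookupError
        if marker not in truth.marker_lengths:
            raise FeatureLookupError(marker)
        if marker not in lin.gene_copies:
            return 0.0
    w = truth.weights(molecule)
    W = sum(w.values())
    return depth * w.get((lineage, marker), 0.0) / W


def simulate_counts(truth: CommunityTruth,
                    config: SimulationConfig) -> tuple[CountTable, CountTable]:
    """Simulate one DNA and one RNA count table.

    ``expected`` mode returns exact (real-valued) expectations; ``sampled``
    mode draws a single multinomial of size ``depth`` over the features.
    DNA and RNA use independent RNG streams derived from the seed.
    """
    tables = []
    for stream, (molecule, depth) in enumerate(
            [(DNA, config.depth_dna), (RNA, config.depth_rna)]):
        w = truth.weights(molecule)
        feats = sorted(w, key=lambda k: (k[0], marker_sort_key(k[1])))
        mass = np.array([w[f] for f in feats], dtype=float)
        p = mass / mass.sum()
        if config.mode == "expected":
            # Expectations are reported at 45 significant bits (relative
            # rounding 2^-45 ~ 3e-14) so that multiplying counts and totals
            # by a small integer stays exact in IEEE arithmetic, making
            # depth invariance of RPKM exact rather than approximate.
            counts = _quantize45(depth * p)
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, stream]))
            counts = rng.multinomial(depth, p).astype(float)
        rows = []
        for (lin, m), c in zip(feats, counts):
            rows.append({
                "feature_id": f"{lin}|{m}", "lineage": lin, "marker": m,
                "length_bp": truth.marker_lengths[m],
                "sample_id": config.sample_id, "molecule": molecule,
                "count": c,
            })
        tables.append(CountTable(
            data=pd.DataFrame(rows),
            totals={(config.sample_id, molecule): float(depth)}))
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
def _uniform_community(n_lineages: int) -> CommunityTruth:
    lineages = []
    copies = {"rpoB": 1.0, "amoA": 1.0, "accB": 1.0}
    rates = {"rpoB": 1.0, "amoA": 1.0, "accB": 1.0}
    for i in range(n_lineages):
        lineages.append(LineageSpec(
            name=f"L{i + 1:02d}", family=f"family-{i + 1:02d}",
            order="OrderA", cell_abundance=1.0,
            gene_copies=dict(copies), expression_rate=dict(rates),
            guild=AOA))
    return CommunityTruth(lineages=tuple(lineages), background_rpob=0.0)


#: Guild cell shares of the soil-like preset (cells per total prokaryote
#: cells).  Ammonia-oxidizing archaea dominate nitrifiers by orders of
#: magnitude over comammox and AOB, with a large non-nitrifier background.
SOIL_LIKE_SHARES = {AOA: 0.05, COMAMMOX: 0.002, AOB: 0.0002}
SOIL_LIKE_BACKGROUND = 0.9478

_AOA_COPIES = {"rpoB": 1.0, "amoA": 1.0, "amoB": 1.0, "nirK": 1.0,
               "accB": 1.0, "4hbd": 1.0, "coxA": 1.0, "atpA": 1.0,
               "amt1": 2.0, "glnB": 2.0}
_AOA_RATES = {"rpoB": 1.0, "amoA": 4.0, "amoB": 4.0, "nirK": 2.0,
              "accB": 1.0, "4hbd": 1.0, "coxA": 1.0, "atpA": 1.0,
              "amt1": 1.5, "glnB": 1.0}


def _soil_like_community(n_lineages: int,
                         rng: np.random.Generator) -> CommunityTruth:
    lineages: list[LineageSpec] = []
    n_aoa = max(1, n_lineages - 2)
    shares = np.sort(rng.dirichlet(np.full(n_aoa, 2.0)))[::-1]
    shares = shares * SOIL_LIKE_SHARES[AOA]
    for i, share in enumerate(shares):
        fam = _AOA_FAMILIES[i % len(_AOA_FAMILIES)]
        copies = dict(_AOA_COPIES)
        # urease / urea-transport inventory varies across lineages: most but
        # not all soil AOA lineages encode ureC, fewer carry ut
        if n_aoa >= 2 and i == n_aoa - 1:
            pass  # smallest lineage lacks urea genes entirely
        else:
            copies["ureC"] = 1.0
            if not (n_aoa >= 3 and i == n_aoa - 2):
                copies["ut"] = 1.0
        rates = {m: _AOA_RATES.get(m, 1.5) for m in copies}
        rates["ureC"] = 1.5
        rates["ut"] = 1.0
        # per-lineage jitter differentiates transcriptional activity
        rates = {m: (r if m == "rpoB"
                     else r * float(rng.lognormal(0.0, 0.3)))
                 for m, r in rates.items()}
        rates = {m: r for m, r in rates.items() if m in copies}
        lineages.append(LineageSpec(
            name=f"AOA-{fam}", family=fam, order="Nitrososphaerales",
            cell_abundance=float(share), gene_copies=copies,
            expression_rate=rates, guild=AOA))
    if n_lineages >= 2:
        lineages.append(LineageSpec(
            name="comammox-Nitrospira", family="Nitrospiraceae",
            order="Nitrospirales",
            cell_abundance=SOIL_LIKE_SHARES[COMAMMOX],
            gene_copies={"rpoB": 1.0, "amoA": 1.5, "nxrB": 4.0, "hao": 1.0},
            expression_rate={"rpoB": 1.0, "amoA": 0.5, "nxrB": 2.0,
                             "hao": 0.3},
            guild=COMAMMOX))
    if n_lineages >= 3:
        lineages.append(LineageSpec(
            name="AOB-Nitrosomonadaceae", family="Nitrosomonadaceae",
            order="Nitrosomonadales",
            cell_abundance=SOIL_LIKE_SHARES[AOB],
            gene_copies={"rpoB": 1.0, "amoA": 2.5, "hao": 1.0},
            expression_rate={"rpoB": 1.0, "amoA": 0.3, "hao": 0.3},
            guild=AOB))
    return CommunityTruth(lineages=tuple(lineages),
                          background_rpob=SOIL_LIKE_BACKGROUND)


def generate_community(n_lineages: int, seed: int,
                       profile: str = "soil-like") -> CommunityTruth:
    """Generate a synthetic community under a named preset.

    ``uniform`` gives ``n_lineages`` equal-abundance archaeal lineages with a
    minimal single-copy inventory and no background pool.  ``soil-like``
    reproduces the guild structure of nitrifiers in soil: AOA >> comammox >
    AOB in cell share, plus a dominant non-nitrifier rpoB background; the
    AOA share is split over up to ``n_lineages - 2`` family-level lineages.
    """
    if n_lineages < 1:
        raise ConfigurationError("n_lineages must be >= 1")
    if profile == "uniform":
        return _uniform_community(n_lineages)
    if profile == "soil-like":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        return _soil_like_community(n_lineages, rng)
    raise ConfigurationError(f"unknown community profile {profile!r}")


# ---------------------------------------------------------------------------
def emit_marker_fasta(truth: CommunityTruth, phylotypes_per_lineage: int,
                      divergence: float, seed: int,
                      path: str | Path | None = None) -> list[SeqRecord]:
    """Emit protein sequences for every (lineage, marker) with copies > 0.

    Within a lineage the ``phylotypes_per_lineage`` variants of a marker are
    substitution-mutated from a lineage consensus at no more than
    ``divergence * length / 2`` positions each, so every within-lineage pair
    is at least ``1 - divergence`` identical.  Lineage consensus sequences
    for the same marker differ at ``min(0.8, 2 * divergence + 0.2)`` of
    positions, keeping between-lineage identity strictly lower.  Headers
    carry ``lineage= family= marker=`` ground-truth tokens.
    """
    if not 0 <= divergence < 1:
        raise ConfigurationError("divergence must be in [0, 1)")
    if phylotypes_per_lineage < 1:
        raise ConfigurationError("phylotypes_per_lineage must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    aas = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    between = min(0.8, 2.0 * divergence + 0.2)
    records: list[SeqRecord] = []
    for marker in sorted(truth.marker_lengths, key=marker_sort_key):
        carriers = [l for l in truth.lineages
                    if l.gene_copies.get(marker, 0) > 0]
        if not carriers:
            continue
        la = max(20, truth.marker_lengths[marker] // 3)
        base = rng.choice(aas, size=la)
        for lin in carriers:
            consensus = _mutate(base, round(between * la), rng, aas)
            k = int(divergence * la / 2)
            for i in range(phylotypes_per_lineage):
                seq = _mutate(consensus, k, rng, aas)
                records.append(SeqRecord(
                    Seq(seq.tobytes().decode()),
                    id=f"{lin.name}|{marker}|pt{i + 1}",
                    description=(f"lineage={lin.name} family={lin.family} "
                                 f"marker={marker}")))
    if path is not None:
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            seqio_write(records, fh, "fasta")
    return records


def _mutate(seq: np.ndarray, n_sites: int, rng: np.random.Generator,
            aas: np.ndarray) -> np.ndarray:
    """Substitute ``n_sites`` uniformly chosen positions with a different
    residue (no indels, so identity arithmetic stays exact)."""
    out = seq.copy()
    if n_sites == 0:
        return out
    pos = rng.choice(len(seq), size=n_sites, replace=False)
    for p in pos:
        choices = aas[aas != out[p]]
        out[p] = rng.choice(choices)
    return out
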