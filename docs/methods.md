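# Methods

## Quantification model

The package treats a shotgun library as a multinomial draw over marker-gene
features. A feature's expected read mass is proportional to
`cell_abundance x copies_per_cell x gene_length_bp` for DNA, with an extra
`expression_rate` factor (transcripts per gene copy, relative to *rpoB*)
for RNA. Normalizing a count by gene length and total mapped reads (RPKM)
removes the length and depth factors; dividing a marker's RPKM by the
per-cell copy number and by the community-wide *rpoB* RPKM — one copy per
prokaryotic genome — converts it to a cell share. All higher-level
quantities (guild proportions, gene:*rpoB* copy ratios, gene prevalence,
transcript:gene activity ratios, log2 expression profiles) are ratios of
RPKMs and therefore cancel depth exactly.

Default per-cell copy numbers, configurable per (guild, marker):
*rpoB* 1 for every prokaryote, *amoA* 1 (AOA), 2.5 (AOB), 1.5 (comammox),
*nxrB* 4 (*Nitrospira*). Canonical *Nitrospira* is the *nxrB*-based total
share minus the comammox *amoA*-based share; a negative difference (real
communities have variable *nxrB* copy numbers) clamps to zero and is
logged.

## Synthetic communities

The generator emulates the structure such estimates face in soil:

- a handful of AOA family-level lineages splitting a 5% total cell share
  (Dirichlet split, seeded), each with a realistic marker inventory
  (ammonia oxidation, nitrite reduction, carbon fixation, respiration,
  transporters; urea genes present in most but not all lineages);
- one comammox lineage at 0.2% and one AOB lineage at 0.02% of cells,
  carrying the guild-average *amoA* copy numbers the correction model
  assumes (copy numbers are real-valued population means for this reason);
- a dominant non-nitrifier background (94.78% of cells) contributing only
  *rpoB* signal — the denominator of every cell-share estimate;
- per-gene expression rates relative to *rpoB*, jittered across lineages
  so transcript:gene ratios differ.

Sequencing is simulated either as exact expectations (`expected` mode) or
as a single multinomial draw at fixed depth (`sampled` mode), conditioning
on total mapped reads exactly as per-million normalization does. DNA and
RNA use independent RNG streams derived from the explicit seed; no global
RNG state is touched. Marker protein sequences are emitted per lineage by
substitution-only mutation (no indels, keeping identity arithmetic exact):
within-lineage variants differ from a lineage consensus at no more than
`divergence x length / 2` sites, lineage consensuses differ at
`min(0.8, 2 x divergence + 0.2)` of sites, so within-lineage identity is
at least `1 - divergence` and between-lineage identity strictly lower.

What the simulator deliberately omits: nucleotide-level reads, sequencing
error and quality profiles, chimeras, alignment ambiguity between related
references, compositional correlations between samples, and copy-number
variation *within* a guild. Passing tests therefore demonstrate that the
estimators are correct for the stated sampling model, not that real
alignments are error-free.

## Phylotypes, read mapping

Dereplication follows the greedy incremental convention of CD-HIT:
records sorted by length descending (ties by id), each joining the first
cluster whose representative it matches at or above the threshold.
Identity is computed from a global alignment (match +1, mismatch 0,
linear gap −1) as identical residues over the shorter length, so
substrings collapse at 100%. Among score-optimal alignments the one with
the most identical residues is chosen (a lexicographic (score, matches)
dynamic program), making the identity value well defined. Family
assignment takes the best-identity labelled reference, requiring 85%
identity by default — a configurable artifact default, since family
assignment by "high sequence similarity" admits no universal cutoff.

The bundled read classifier places peptide reads ungapped at every offset
of each representative and requires 90% identity over the aligned read
residues and 60% read coverage, the conventional thresholds for
short-read protein mapping; the highest identity wins, ties by smallest
phylotype id (logged). It exists so the pipeline is testable without an
external aligner — count tables from a real aligner can be substituted at
the TSV interface.

## Activity and expression profiles

Within a marker group (e.g. all archaeal *amoA* phylotypes) each
phylotype's recovery frequency is its share of the group's reads,
separately for DNA and RNA. The activity ratio RNA/DNA exceeds 1 for
phylotypes transcribing disproportionately to their abundance; the
threshold is strict (a ratio of exactly 1 is not "active"), RNA-only
detection counts as active, and a phylotype undetected in both pools is
excluded from family denominators. A family's activity fraction counts
phylotypes active in at least one sample.

Expression profiles sum phylotype transcript counts within (lineage,
marker), convert with a member-count-weighted representative length, and
take log2 relative to the lineage's *rpoB* transcript RPKM, so *rpoB*'s
own entry is exactly 0. No pseudocounts: a present gene without
transcripts is `nd`, a gene absent from the inventory is `X` regardless
of counts (counts on absent genes are logged as inconsistencies), and a
lineage without *rpoB* transcripts has no baseline and is marked
unavailable. Averaging over samples is the arithmetic mean of numeric
log2 ratios; `nd` propagates only if every sample is `nd`. Culture
comparisons report fold = 2^(soil − reference) per marker and flag folds
beyond a 10-fold cutoff in either direction; any non-numeric state makes
a marker incomparable rather than silently zero.

## Pan/core classification

From a binary cluster x genome matrix with (order, family) taxonomy: a
cluster is core when every order in the panel has at least one carrier
genome; family-specific when all carriers belong to one family and number
at least the family minimum (default 2, set to 1 for families represented
by a single genome). Copy numbers within a genome are ignored — presence
is the unit of evidence. With a single order in the panel the two
categories can overlap; the summary flags this degenerate case.

## Numerical choices

- **RPKM ordering.** Computed as `(count / total) * (1e9 / length)` so an
  integer rescaling of counts and totals cancels exactly in the division.
- **Expected-mode precision.** Expected counts are emitted at 45
  significand bits (relative rounding 2^-45 ≈ 3e-14). This makes
  `k x count` exact for any integer k < 256, so scaling counts and totals
  together leaves every RPKM, proportion, ratio, and log2 profile
  bit-identical — depth invariance holds exactly, not approximately —
  while the rounding is orders of magnitude below every tolerance used.
- **Partition exactness.** The canonical-*Nitrospira* share is the total
  minus comammox difference computed on the proportion scale, nudged by
  at most one ulp to the neighbouring float that makes
  `comammox + canonical == total` bitwise when such a float exists (for
  a small fraction of inputs the sum grid makes the total unreachable by
  any addend; the identity then holds to 1 ulp, the double-precision
  limit).
- **Uncertainty.** The standard error of a guild-share estimate is
  propagated by the delta method from the binomial variances of the
  numerator (marker) and denominator (*rpoB*) read counts; their
  multinomial covariance is O(1/depth) and neglected.
- **Determinism.** Every stochastic operation takes an explicit seed and
  derives a private RNG stream; identical configuration reproduces
  byte-identical output files (headers carry the configuration hash and
  seed, never timestamps).
- **Validation scale.** Tests and the acceptance script use depths of
  10^4–10^6 reads and panels of tens of genomes / hundreds of clusters —
  sizes at which closed-form truth, brute-force oracles, and exhaustive
  alignment enumeration are all feasible, chosen as the package's own
  verification conditions.

## Known limitations

- The read classifier is ungapped and single-best-hit; it is a testing
  default, not a replacement for a real protein aligner on real data.
- Guild proportions are only as good as the copy-number model; the
  defaults are literature averages and real communities deviate
  (especially *nxrB* in *Nitrospira*).
- Reference expression profiles are user-supplied data; the package ships
  none.
- Ortholog clustering, assembly, binning, phylogenetics, and amplicon
  processing are out of scope: the cluster matrix and marker sequences
  are inputs.
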