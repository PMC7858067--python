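# Methods

This note documents the models, conventions and design choices behind
`ltspop`, in the order the pipeline runs them.

## Coordinates and mutation identity

All coordinates are 1-based with inclusive interval ends (the GenomeDiff
convention); BED input on the CLI is converted on read. A mutation's
identity is the triple (position, category, detail), where `detail` is a
canonical string (`"C>T"`, `"+ACG"`, `"-3"`, `"IS2:+"`, `"x2:50000"`).
Identity deliberately ignores which clone or day an event was seen in, so
the same event in many clones is one catalog column. Insertion-sequence
events are identical only when family, position and strand all match:
independent insertions at different locations in one gene are distinct
alleles. Small indels are 1–16 bp; deletions of ≥ 100 bp are a separate
`large_deletion` category.

## Quality control

Three filters, in order: (1) clones with mean read depth below
`min_mean_depth` (default 20×, inclusive at the boundary) are dropped;
(2) mutations at parental-variant positions are masked from every clone —
the default list is the 11 positions by which the parental strains differ
from the reference assembly (281996, 1398837, 1576168, 1810671, 2166923,
2246663, 2499451, 2894668, 2959436, 3457470, 4175949); (3) mutations
inside configured exclusion intervals (e.g. an unreliable prophage region)
are removed. The prophage coordinates are not built in because no
authoritative coordinates ship with the package; the exclusion list is
config-supplied and empty by default. Filters may remove everything; the
filter report records each removal class.

## Effect classification

The bacterial genetic code (translation table 11) drives SNP effect calls:
nonsense iff the alternate codon is a stop, synonymous iff the amino acid
is preserved, nonsynonymous otherwise; the reference codon must be a sense
codon. Coding indels are frameshift when length mod 3 ≠ 0, otherwise
in-frame disruptions; IS insertions in coding sequence are disruptions;
anything between genes is intergenic with a `"left/right"` flank-pair
context. Codon lookup needs the genome sequence; without one,
pre-annotated effects from a flat TSV (or GD `effect=` extras) are
accepted verbatim, and with one, recomputed effects that contradict stated
ones are logged rather than silently overwritten.

## Genotypes, MST, lineages

Clones collapse to genotypes by exact mutation-set equality; the parental
(empty-set) genotype is always inserted as the root even when never
sampled, so lineages are subtrees. The distance between genotypes is the
symmetric-difference size |a Δ b| — the natural metric on binary mutation
profiles. The tree is built with Prim's algorithm; any minimum-weight
frontier edge yields a minimum spanning tree, so total weight is always
optimal and the tie-break only shapes topology among co-optimal trees. The
tie-break is goeBURST-flavoured, reduced to three deterministic levels:
candidate parent with more sampled clones, then earlier first-detection
day, then lexicographic genotype id (a deterministic child-side tie-break
is applied last). The full goeBURST hierarchy ranks nodes by single- and
double-locus-variant counts, which presumes an MLST-style allele encoding
this data does not have; clone count is its dominant criterion and is kept.
Genotype ids are functions of content (first day, clone count, sorted
mutation set), so results are independent of input order.

Each root-child subtree is a candidate lineage. Candidates with at least
`min_total_clones` (default 2) sampled clones get labels L1, L2, ...
ordered by descending clone count; a lineage is flagged *major* when its
first-to-last sampled-day span reaches `min_persistence_days` (default
150) — detection gaps do not break persistence, since lineages fluctuate
and occasionally drop below the limit of detection. Sub-threshold subtrees
are "unassigned".

A genotype is **core** when every mutation separating it from its lineage
founder is a fixed mutation of that lineage (so founders are core by
construction). Maximal non-core branches count their clones cumulatively
over time; branches with at least `sublineage_min_clones` (default 10,
inclusive — "10 or more") are **sublineages**, the rest **collateral**.
Reversions are MST edges whose child lacks a parental mutation; they are
reported as edge annotations rather than new "reversion mutation" columns,
keeping matrix columns monotone in meaning.

## Trajectories, fixation, sweeps

Frequencies are always among *sampled* clones, with explicit denominators;
for lineage scope the denominator is that lineage's clone count that day.
Fixation requires frequency exactly 1.0 (a configurable threshold below
1.0 exists but is off by default): the fixation day is the earliest
sampled day with f = 1.0 and denominator ≥ `min_n` (default 5, guarding
against under-sampled days such as a 15-clone time point) such that every
later adequately-sampled day also has f = 1.0. When a reversion is
confined to a sublineage or collateral branch, the sweep stands: the
branch's clones (descendants of the MST edge that lost the mutation) are
excluded and fixation is re-tested; events rescued this way carry a flag.
A lineage-wide loss after fixation is *not* rescued — the trajectory then
simply never satisfies the rule. Mutations sharing a fixation day form a
cofixation group; the sweep count is the number of distinct fixation days,
which can undercount if biologically separate sweeps complete within one
sampling interval.

## Selection statistics

**Ka/Ks.** Expected site counts follow the NG86 convention: each codon
position contributes syn/3 synonymous sites, where syn counts synonymous
changes among its three alternatives; changes to stop codons count as
nonsynonymous, so N + S = 3 per codon exactly. The default estimator is
the *uncorrected* proportion ratio (Nd/N)/(Sd/S): clone-panel SNP sets are
sparse, multiple hits per codon are negligible, and distance corrections
diverge when pS is large. The Li (1993) estimator is provided for
comparability with seqinR's `kaks`: sites are classed 0-, 2- or 4-fold
degenerate by counting synonymous alternatives, transitions/transversions
are tallied per class (split 50/50 when the two codons disagree on a
site's class), Kimura two-parameter distances A_i (transitional) and B_i
(transversional) are computed per class, and
Ks = B₄ + (L₂A₂ + L₄A₄)/(L₂ + L₄),
Ka = A₀ + (L₀B₀ + L₂B₂)/(L₀ + L₂).
Known limitation: Li's original special-case degeneracy tables for
arginine and isoleucine codons are not reproduced, so agreement with
seqinR is exact on many codon sets and within ~10% on others. A
calibration property holds by construction: uniformly random
single-base, stop-rejecting mutations of random sense codons give a mean
NG86 ratio within 0.1 of 1.0 (the small downward bias comes from
stop-creating changes counting as nonsynonymous sites but never appearing
as differences).

**Insertion-site enrichment.** Under uniform insertion the expected coding
count is total × coding_fraction; the departure is Pearson's χ² goodness
of fit with df 1 and no continuity correction. The per-gene hit
probability under the null is 1 − (1 − 1/G)^n with n the expected coding
hits; the simpler n/G is reported alongside (both round to 7% for n ≈ 298,
G = 4295).

**Hotspot test.** The default statistic is the exact binomial upper tail
P(X ≥ hits | n = total, p = target_bp/genome_bp) — transparent and
reproducible. A Fisher variant uses the base-pair-weighted 2 × 2 table
[[hits, total − hits], [target_bp − hits, (genome_bp − target_bp) −
(total − hits)]]; since any such 2 × 2 construction is a convention, it
sits behind a flag. No multiple-testing correction is applied anywhere by
default (single planned tests); a Bonferroni-style adjustment is left to
the caller.

**Spectra.** SNPs collapse onto six strand-symmetric classes (C→T and G→A
are both G:C>A:T, etc.); two spectra are compared with a 2 × 6 χ²
contingency test, dropping classes absent from both.

## Sampling saturation

Linkage is average (UPGMA) by default — the linkage behind such dendrogram
figures is rarely stated, so it is a parameter (complete/single
selectable). Trees are cut with `fcluster(..., criterion="maxclust")` and
labels renumbered by lowest member index for determinism. Subsampling is
without replacement ("subsampling sequenced clones"); the analytic
expectation Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)) is reported beside the seeded
Monte-Carlo mean, is non-decreasing in m, and equals k at m = N.

## The simulator

The generator plants structure directly instead of running a fitness-based
forward model: the analysis consumes only sampled clones, and planting
gives exact, testable truth. Defaults emulate a 1,200-day, single-culture
batch experiment:

* **Sampling**: 24 days — 10, 20, 30, then every 30 days through 600, then
  900 and 1200. (A literal "every 30 days to 1200" schedule would have 42
  points; real panels sequence a subset, so the default keeps the dense
  early schedule and thins late.) 48 clones/day, 15 on day 240 (a
  poorly-growing time point), giving 1,119 clones per run.
* **Lineages**: two persistent (≈ 60% and ≈ 35% of all clones, trading
  dominance: L1 ≈ 92% on day 20, L2 ≈ 85% on day 60) and two transient
  lineages prominent on day 10 and extinct by days 150/120 — so the
  persistent pair spans ≥ 150 days (major) and the transient pair does
  not. Per-day sampling weights are step functions, config-exposed.
* **Sweeps**: first sweep at founding (the larger persistent lineage's
  founder carries 3 mutations), then intervals ~ Normal(90, 25) days,
  min 30. Cofixation group sizes 1–8 with mean ≈ 1.37 (80% singletons).
  Transient lineages are founder-sweep-only: they dwindle rather than
  adapt, and sweeps in a lineage sampled at 1–4 clones/day would be
  unobservable under the fixation rule anyway. This puts the day-1200
  mutation burden near 19 per clone.
* **Mutation categories**: drawn from the fixed catalog mixture
  227 SNP : 48 indel : 376 IS : 14 deletion : 14 amplification (of 679),
  positions collision-free (rejection sampling) over a synthetic
  4,541,111 bp genome tiled by 4,295 equal genes at 90% coding fraction.
  Coding SNP effects are drawn 65/25/10 nonsyn/syn/nonsense.
* **IS2 burst**: confined to the second persistent lineage between days
  270 and 600 — Poisson(1) extra private IS2 insertions per burst-lineage
  clone in the window, and core sweeps there are IS2 with probability 0.8.
  Outside the burst only 2% of background IS draws are family IS2, so
  ≥ 95% of IS2 events land in the burst lineage.
* **Reversions**: with probability 0.05 per sweep, a branch carrying a
  marker mutation but lacking one earlier core mutation appears for 60
  days at 12% of the lineage's sampled clones. Branch clones otherwise
  track the core genotype, so other sweeps stay exactly datable.
* **Collaterals**: Poisson(0.35) private mutations per clone — mostly
  singleton genotypes, yielding ≈ 440 genotypes per run.

All randomness flows from one `numpy` generator seeded once; identical
(config, seed) produce byte-identical output files. Ground truth records
per-clone lineage labels, the sweep schedule, collateral and IS2 mutation
ids, and reversions.

What the simulator does **not** emulate: population-size dynamics (CFU
trajectories), fitness and clonal interference (frequencies move by
sampling weights, not selection coefficients), gradual allele-frequency
rises before fixation (planted sweeps are instantaneous, so trajectories
jump 0 → 1), sequencing error/false calls, and within-gene codon
structure. Passing recovery tests therefore shows the *inference* is
correct under the stated sampling model, not that the statistics are
robust to call errors or to slow sweeps spanning several sampling
intervals.

## Recovery scoring

Lineage recovery is pair-counting (Rand) agreement between planted and
inferred clone partitions — label-permutation invariant, 1.0 iff
identical. Sweep recovery matches planted (mutation, day) events to
inferred fixation events on the sampled-day grid: a planted sweep is only
observable from the first sampled day at or after its true day, so
matching tolerates a configurable number of sampled-day steps (default 1).
With no inferred events, precision is reported as 1.0 with an explicit
flag (no false positives) while recall reflects the misses.

## Problem sizes in the tests and acceptance script

The test suite runs one shared default simulation plus 20 smaller-seeded
replicates for the recovery property (mean pair agreement and sweep recall
≥ 0.9); the MST oracle check uses 200 random instances of ≤ 12 genotypes
against networkx Kruskal; the neutral Ka/Ks calibration uses 200
replicates of 500 codon pairs; subsampling Monte-Carlo uses 10,000
replicates per size. `scripts/acceptance.py` repeats the analytic blocks
and 10 end-to-end recovery replicates, all seeded from `--seed`. These
sizes keep the whole suite to a couple of minutes on one CPU while leaving
the statistical bounds comfortably non-trivial.
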