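# ltspop

Clone-resolved population structure for long-term stationary-phase (LTSP)
evolution experiments.

When a bacterial batch culture is left unfed for months to years, the
population survives on nutrients scavenged from dead cells and keeps
evolving. Sequencing ~48 individual clones at each of many time points
turns that process into data: each clone is a genome, each genome a set of
mutations, and the structure of those sets over time reveals coexisting
lineages, selective sweeps, mobile-element bursts, and evolutionary dead
ends. `ltspop` is the analysis toolkit for such clone panels, plus a fully
seeded simulator that generates panels with known ground truth so every
stage of the analysis can be validated.

## What it computes

Starting from per-clone mutation calls (a minimal GenomeDiff dialect as
produced by Breseq, or a flat TSV) and clone metadata:

1. **Mutation catalog** (`ltspop.catalog`) — QC filters (mean-depth cutoff,
   parental-variant masking, region exclusion), category and coding-effect
   classification, deduplication into unique mutations keyed by
   (position, category, detail), and the boolean clones × mutations
   presence/absence matrix. Also: strand-collapsed substitution spectra and
   a coverage-based amplification caller.
2. **Genotypes and lineages** (`ltspop.lineage`) — clones with identical
   mutation sets collapse into genotypes ("sequence types"); a minimum
   spanning tree under the symmetric-difference distance
   d(a, b) = |a Δ b| is rooted at the parental (empty-set) genotype with
   goeBURST-style tie-breaking (higher clone count wins, then earlier first
   detection, then lexicographic id). Root-child subtrees become lineages
   L1, L2, ... ordered by clone count; genotypes are tagged core (built
   purely from fixed mutations), sublineage (non-core branches with ≥ 10
   clones), or collateral; edges that lose a parental mutation are reported
   as reversions.
3. **Trajectories and sweeps** (`ltspop.trajectories`) — per-day allele
   frequencies within the population or a lineage; fixation = frequency
   exactly 1.0 among sampled lineage clones from some day onward (days with
   fewer than `min_n` lineage clones are skipped); mutations fixing on the
   same day form cofixation groups; sweeps = distinct fixation days.
4. **Selection statistics** (`ltspop.selection`) — Ka/Ks from observed
   codon pairs (uncorrected Nei–Gojobori-style proportions by default, the
   Li 1993 degeneracy-class estimator for comparability with seqinR);
   coding/noncoding insertion-site enrichment against the uniform null
   (Pearson χ², df 1); exact binomial insertion-hotspot tests; 2 × 6
   spectrum contingency comparisons; cross-culture parallelism and
   multiallelic gene tables.
5. **Sampling saturation** (`ltspop.saturation`) — pairwise distances among
   one day's clones, UPGMA clustering cut at k groups, and subsampling
   detection curves with the closed-form expectation
   E[detected] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)).
6. **Simulator** (`ltspop.simulate`) — plants lineages, sweep schedules
   (~every 90 days), an IS2 mobilization burst confined to one lineage in a
   day window, collateral singletons, and rare reversions; emits the
   pipeline's own input formats plus a truth JSON, and scores recovery
   (pair-counting lineage agreement, sweep precision/recall).

## Worked example

```python
import ltspop as lp
from ltspop.pipeline import analyze_clones
from ltspop.trajectories import sweep_summary

res = lp.simulate_ltsp(seed=7)          # 1,119 clones over 24 sampling days
ana = analyze_clones(res.clones)        # catalog -> MST -> lineages -> sweeps

print(len(ana.catalog.records))         # 632   unique mutations
print(sum(1 for g in ana.genotypes if g.clone_count > 0))   # 434 genotypes
print(ana.assignment.major)             # {'L1': True, 'L2': True,
                                        #  'L3': False, 'L4': False}
s1 = sweep_summary(ana.fixations, lineage="L1")
print(s1.n_sweeps, round(s1.mean_interval, 1))              # 10 132.2
print(lp.evaluate_lineage_recovery(res.truth.clone_labels,
                                   ana.clone_labels))       # 1.0
```

Two persistent lineages (L1, L2, flagged major because they span ≥ 150
days) and two transient ones are recovered; the inferred clone partition
agrees with the planted truth for every clone pair (pair agreement 1.0),
and L1 shows 10 distinct fixation days a mean of 132 days apart.

The statistics module reproduces classic insertion-enrichment arithmetic:
331 insertion-sequence hits on a genome that is 90% coding should put
~297.9 in coding sequence, so observing only 268 (with 63 noncoding) is a
strong departure:

```python
e = lp.insertion_site_enrichment(n_coding=268, n_noncoding=63,
                                 coding_fraction=0.90, n_genes=4295)
print(round(e.expected_coding, 1))      # 297.9
print(round(e.chi2, 2), e.p_value)      # 30.01 4.30e-08
print(round(e.per_gene_probability, 3)) # 0.067  (~7% per gene)
```

## Command line

`ltspop simulate | catalog | lineages | trajectories | stats | saturation |
evaluate` — each a thin wrapper over the library; see `ltspop COMMAND
--help`. A full round trip:

```bash
ltspop simulate --seed 7 --out sim --gd
ltspop catalog --gd-dir sim/gd --clones sim/clone_table.tsv --out cat
ltspop lineages --matrix cat/matrix.tsv --clones sim/clone_table.tsv --out lin
ltspop evaluate --truth sim/truth.json --mutations sim/mutations.tsv \
                --clones sim/clone_table.tsv
```

## Input formats

* **GenomeDiff dialect**: `#=GENOME_DIFF` header, tab-separated SNP / INS /
  DEL / MOB / AMP records (evidence lines are skipped). Coordinates are
  1-based with inclusive interval ends throughout.
* **Clone metadata TSV**: `clone_id  culture  day  mean_depth`.
* **Flat mutation TSV**: `clone_id  position  category  detail
  [gene_context  effect]` — pre-annotated effects are accepted verbatim;
  with a reference FASTA + GFF3 they are recomputed from the genetic code.
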