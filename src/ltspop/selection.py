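"""Selection and enrichment statistics for clone-resolved mutation catalogs.

* Ka/Ks from observed (ref codon, alt codon) pairs, either as uncorrected
  NG86 proportions (default) or with the Li (1993) degeneracy-class
  estimator for comparability with seqinR's ``kaks``.
* Coding/noncoding insertion-site enrichment against the uniform null
  (expected coding hits = total x coding fraction; Pearson chi-square
  goodness of fit, df 1).
* Per-gene insertion hotspot test: exact binomial upper tail on hits in a
  base-pair-weighted target, with a Fisher 2x2 variant behind a flag.
* Mutation-spectrum contingency comparison (2 x 6 chi-square).
* Cross-culture parallelism and multiallelic gene tables.
"""
from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (MutationCatalog, MutationRecord, SPECTRUM_CLASSES,
                      SpectrumCounts)
from .codons import (GENETIC_CODE, codon_neighbors, is_transition,
                     site_degeneracy, validate_codon)


# ---------------------------------------------------------------------------
# Ka/Ks

@dataclass
class KaKsResult:
    """Nonsynonymous/synonymous rate ratio and its ingredients.

    ``n_sites``/``s_sites`` are NG86 expected-site counts (single-neighbour
    enumeration per reference codon, changes to stops counted as
    nonsynonymous); ``nd``/``sd`` are observed differences.  ``defined`` is
    False when the ratio cannot be formed (no synonymous sites or
    differences).
    """
    nd: float
    sd: float
    n_sites: float
    s_sites: float
    method: str
    ka: Optional[float] = None
    ks: Optional[float] = None
    ratio: Optional[float] = None
    defined: bool = False


def _validate_pair(ref: str, alt: str) -> tuple[str, str, int]:
    ref = validate_codon(ref)
    alt = validate_codon(alt)
    if GENETIC_CODE[ref] == "*":
        raise ValueError(f"reference codon {ref} is a stop codon")
    diffs = [i for i in range(3) if ref[i] != alt[i]]
    if len(diffs) > 1:
        raise ValueError(f"codon pair {ref}->{alt} differs at "
                         f"{len(diffs)} positions (max 1)")
    return ref, alt, (diffs[0] if diffs else -1)


@functools.lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon.

    Each position contributes ``syn/3`` synonymous sites where ``syn`` is
    the number of synonymous changes among its three alternatives; stops
    count as nonsynonymous targets, so N + S = 3 exactly.
    """
    codon = validate_codon(codon)
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"{codon} is a stop codon")
    syn = sum(1 for nb in codon_neighbors(codon) if GENETIC_CODE[nb] == aa)
    s = syn / 3.0
    return 3.0 - s, s


def kaks_estimate(codon_pairs: Sequence[tuple[str, str]],
                  method: str = "NG86") -> KaKsResult:
    """Ka/Ks over observed codon substitutions.

    ``method="NG86"`` (default): uncorrected proportion ratio
    (Nd/N)/(Sd/S) with NG86 site counts — appropriate for the sparse SNP
    sets of a clone panel, where multiple hits per codon are negligible and
    distance corrections diverge.  ``method="Li93"`` applies the Li (1993)
    degeneracy-class estimator to the concatenated ref/alt pseudo-sequences.
    """
    if not codon_pairs:
        raise ValueError("no codon pairs")
    if method not in {"NG86", "Li93"}:
        raise ValueError(f"unknown method {method!r}")
    pairs = [_validate_pair(r, a) for r, a in codon_pairs]
    if method == "Li93":
        return _kaks_li93(pairs)
    nd = sd = 0.0
    n_sites = s_sites = 0.0
    for ref, alt, pos in pairs:
        n, s = ng86_sites(ref)
        n_sites += n
        s_sites += s
        if pos >= 0:
            if GENETIC_CODE[alt] == GENETIC_CODE[ref]:
                sd += 1
            else:  # includes nonsense changes, NG86 convention
                nd += 1
    result = KaKsResult(nd=nd, sd=sd, n_sites=n_sites, s_sites=s_sites,
                        method="NG86")
    if s_sites > 0 and n_sites > 0 and sd > 0:
        result.ka = nd / n_sites
        result.ks = sd / s_sites
        result.ratio = result.ka / result.ks
        result.defined = True
    return result


def _kimura_distances(p: float, q: float) -> tuple[float, float]:
    """Kimura two-parameter transitional (A) and transversional (B) distances."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("substitution proportions too large for Li93 "
                         "log corrections")
    a = 0.5 * math.log(1.0 / w1) - 0.25 * math.log(1.0 / w2)
    b = 0.5 * math.log(1.0 / w2)
    return a, b


def _kaks_li93(pairs) -> KaKsResult:
    # site counts per degeneracy class, averaged over ref and alt codons
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    ts = {0: 0.0, 2: 0.0, 4: 0.0}  # transitions per class
    tv = {0: 0.0, 2: 0.0, 4: 0.0}  # transversions per class
    nd = sd = 0.0
    for ref, alt, pos in pairs:
        for codon in (ref, alt):
            if GENETIC_CODE[codon] == "*":
                continue
            for i in range(3):
                L[site_degeneracy(codon, i)] += 0.5
        if pos < 0:
            continue
        if GENETIC_CODE[alt] == GENETIC_CODE[ref]:
            sd += 1
        else:
            nd += 1
        classes = [site_degeneracy(ref, pos)]
        if GENETIC_CODE[alt] != "*":
            classes.append(site_degeneracy(alt, pos))
        else:
            classes.append(classes[0])
        share = 1.0 / len(classes)
        for cls in classes:
            if is_transition(ref[pos], alt[pos]):
                ts[cls] += share
            else:
                tv[cls] += share
    result = KaKsResult(nd=nd, sd=sd, n_sites=L[0] + 2 * L[2] / 3,
                        s_sites=L[4] + L[2] / 3, method="Li93")
    try:
        a = {}
        b = {}
        for cls in (0, 2, 4):
            p = ts[cls] / L[cls] if L[cls] > 0 else 0.0
            q = tv[cls] / L[cls] if L[cls] > 0 else 0.0
            a[cls], b[cls] = _kimura_distances(p, q)
        if L[2] + L[4] == 0 or L[0] + L[2] == 0:
            return result
        # synonymous: transitions at 2-/4-fold sites plus transversions at
        # 4-fold sites; nonsynonymous: the complement
        ks = b[4] + (L[2] * a[2] + L[4] * a[4]) / (L[2] + L[4])
        ka = a[0] + (L[0] * b[0] + L[2] * b[2]) / (L[0] + L[2])
        if ks > 0:
            result.ka, result.ks = ka, ks
            result.ratio = ka / ks
            result.defined = True
    except ValueError:
        pass
    return result


def catalog_codon_pairs(catalog: MutationCatalog,
                        reference) -> list[tuple[str, str]]:
    """(ref, alt) codon pairs for the catalog's coding SNPs (needs sequence)."""
    pairs = []
    for r in catalog.records:
        if r.category != "SNP":
            continue
        _, alt = r.snp_bases
        codons = reference.codon_for_snp(r.position, alt)
        if codons is not None:
            pairs.append(codons)
    return pairs


# ---------------------------------------------------------------------------
# insertion-site enrichment

@dataclass
class EnrichmentResult:
    observed_coding: int
    observed_noncoding: int
    expected_coding: float
    expected_noncoding: float
    chi2: float
    p_value: float
    #: P(a given gene receives >= 1 insertion) = 1 - (1 - 1/G)^n
    per_gene_probability: float
    #: the simpler n/G rate, reported alongside
    per_gene_probability_naive: float


def insertion_site_enrichment(n_coding: int, n_noncoding: int,
                              coding_fraction: float,
                              n_genes: int) -> EnrichmentResult:
    """Test observed coding/noncoding insertion counts against the uniform null.

    Under uniform insertion the expected coding count is
    ``total x coding_fraction``; the Pearson chi-square goodness-of-fit
    statistic (df 1, no continuity correction) measures the departure.
    Also reports the per-gene hit probability under the null.
    """
    if n_coding < 0 or n_noncoding < 0:
        raise ValueError("counts must be >= 0")
    total = n_coding + n_noncoding
    if total < 1:
        raise ValueError("no insertions")
    if not 0 < coding_fraction < 1:
        raise ValueError("coding_fraction must be in (0, 1)")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    exp_c = total * coding_fraction
    exp_n = total - exp_c
    chi2, p = stats.chisquare([n_coding, n_noncoding], [exp_c, exp_n])
    return EnrichmentResult(
        observed_coding=n_coding, observed_noncoding=n_noncoding,
        expected_coding=exp_c, expected_noncoding=exp_n,
        chi2=float(chi2), p_value=float(p),
        per_gene_probability=1.0 - (1.0 - 1.0 / n_genes) ** exp_c,
        per_gene_probability_naive=exp_c / n_genes)


# ---------------------------------------------------------------------------
# hotspot test

@dataclass
class HotspotResult:
    p_value: float
    expected_hits: float
    method: str


def gene_hotspot_test(hits_in_targets: int, total_insertions: int,
                      target_bp: int, genome_bp: int,
                      method: str = "binomial") -> HotspotResult:
    """Are ``hits_in_targets`` insertions in ``target_bp`` of sequence excess?

    Default: exact binomial upper tail
    ``P(X >= hits | n=total, p=target_bp/genome_bp)``.  The ``"fisher"``
    variant builds the base-pair-weighted 2x2 table
    ``[[hits, total-hits], [target_bp-hits, (genome_bp-target_bp)-(total-hits)]]``
    (insertions vs. unhit base pairs, in-target vs. elsewhere) and reports
    the one-sided exact test; its construction is a convention, which is why
    the binomial tail is the default.
    """
    if target_bp <= 0:
        raise ValueError("zero-length target")
    if target_bp > genome_bp:
        raise ValueError("target larger than genome")
    if hits_in_targets > total_insertions:
        raise ValueError("hits exceed total insertions")
    rate = target_bp / genome_bp
    expected = total_insertions * rate
    if method == "binomial":
        p = float(stats.binom.sf(hits_in_targets - 1, total_insertions, rate))
        return HotspotResult(p_value=min(p, 1.0), expected_hits=expected,
                             method="binomial")
    if method == "fisher":
        table = [[hits_in_targets, total_insertions - hits_in_targets],
                 [target_bp - hits_in_targets,
                  (genome_bp - target_bp) - (total_insertions - hits_in_targets)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        return HotspotResult(p_value=float(p), expected_hits=expected,
                             method="fisher")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# spectrum comparison

def spectrum_comparison_test(counts_a, counts_b) -> tuple[float, float]:
    """Chi-square contingency test between two substitution spectra.

    Accepts :class:`SpectrumCounts` or 6-vectors; classes absent from both
    spectra are dropped (df adjusts with the table shape).  Returns
    (statistic, p).
    """
    a = counts_a.as_vector() if isinstance(counts_a, SpectrumCounts) \
        else np.asarray(counts_a)
    b = counts_b.as_vector() if isinstance(counts_b, SpectrumCounts) \
        else np.asarray(counts_b)
    if a.sum() < 1 or b.sum() < 1:
        raise ValueError("each spectrum needs at least one substitution")
    table = np.vstack([a, b])
    table = table[:, table.sum(axis=0) > 0]
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# parallelism / multiallelic tables

def _gene_of(record: MutationRecord) -> str:
    return record.gene_context or f"pos{record.position}"


def parallelism_summary(catalogs_by_culture: Mapping[int, MutationCatalog],
                        min_cultures: int = 2) -> pd.DataFrame:
    """Genes (or intergenic regions) mutated in at least ``min_cultures``.

    Per gene: allele counts per culture (distinct mutation identities),
    the total over cultures, the number of unique identities pooled across
    cultures, and whether any identical allele recurs in several cultures
    (``shared_alleles`` flag — e.g. the same promoter SNP arising in
    independent populations).
    """
    if len(catalogs_by_culture) < 2:
        raise ValueError("need catalogs from at least two cultures")
    cultures = sorted(catalogs_by_culture)
    per_gene: dict[str, dict[int, set]] = {}
    for cult in cultures:
        for r in catalogs_by_culture[cult].records:
            per_gene.setdefault(_gene_of(r), {}).setdefault(cult, set()).add(r.key)
    rows = []
    for gene in sorted(per_gene):
        hits = per_gene[gene]
        if len(hits) < min_cultures:
            continue
        per_culture = [len(hits.get(c, ())) for c in cultures]
        total = sum(per_culture)
        unique = len(set().union(*hits.values()))
        rows.append([gene, *per_culture, total, unique, total > unique])
    cols = (["gene"] + [f"culture_{c}" for c in cultures]
            + ["total_alleles", "unique_alleles", "shared_alleles"])
    return pd.DataFrame(rows, columns=cols)


_CLASS_COLUMNS = ("synonymous", "nonsynonymous", "nonsense", "indel", "IS",
                  "IS2", "deletion", "amplification")


def _allele_class(record: MutationRecord) -> str:
    if record.category == "SNP":
        return record.effect if record.effect in {"synonymous",
                                                  "nonsynonymous",
                                                  "nonsense"} else "synonymous"
    if record.category == "small_indel":
        return "indel"
    if record.category == "IS_insertion":
        return "IS"
    if record.category == "large_deletion":
        return "deletion"
    return "amplification"


def multiallelic_gene_table(catalog: MutationCatalog,
                            min_alleles: int = 3) -> pd.DataFrame:
    """Genes carrying at least ``min_alleles`` distinct alleles, by class.

    The IS column counts all insertion-sequence alleles with the IS2 family
    sub-count alongside (insertions at different positions in one gene are
    distinct alleles).
    """
    per_gene: dict[str, list[MutationRecord]] = {}
    for r in catalog.records:
        per_gene.setdefault(_gene_of(r), []).append(r)
    rows = []
    for gene in sorted(per_gene):
        recs = per_gene[gene]
        if len(recs) < min_alleles:
            continue
        counts = {c: 0 for c in _CLASS_COLUMNS}
        for r in recs:
            counts[_allele_class(r)] += 1
            if r.category == "IS_insertion" and r.is_family == "IS2":
                counts["IS2"] += 1
        rows.append([gene, len(recs)] + [counts[c] for c in _CLASS_COLUMNS])
    return pd.DataFrame(rows, columns=["gene", "n_alleles", *_CLASS_COLUMNS]
                        ).sort_values("n_alleles", ascending=False,
                                      kind="stable").reset_index(drop=True)
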