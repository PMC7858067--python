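import io

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

import ltspop as lp
from ltspop.catalog import (CoverageTrack, classify_substitution_class,
                            write_clone_table)
from ltspop.codons import SENSE_CODONS, codon_neighbors
from ltspop.genomediff import RawEntry


# ---------------------------------------------------------------------------
# effect classification

@pytest.mark.parametrize("ref,alt,expected", [
    ("ATG", "ATA", "nonsynonymous"),  # M107I-style change
    ("TCT", "TCC", "synonymous"),     # S210S-style change
    ("TTG", "TAG", "nonsense"),       # L116*-style change
])
def test_codon_substitution_effects(ref, alt, expected):
    assert lp.classify_substitution_effect(ref, alt) == expected


@pytest.mark.parametrize("bad", ["AT", "ATGA", "AXG", 42])
def test_effect_classifier_rejects_non_codons(bad):
    with pytest.raises(ValueError):
        lp.classify_substitution_effect(bad, "ATG")


def test_effect_classifier_rejects_stop_reference():
    with pytest.raises(ValueError):
        lp.classify_substitution_effect("TAA", "TAC")


def test_effect_classifier_agrees_with_translation_oracle():
    """All 9 single-nucleotide neighbours of all 61 sense codons."""
    for codon in SENSE_CODONS:
        ref_aa = str(Seq(codon).translate(table=11))
        for nb in codon_neighbors(codon):
            alt_aa = str(Seq(nb).translate(table=11))
            expected = ("nonsense" if alt_aa == "*" else
                        "synonymous" if alt_aa == ref_aa else "nonsynonymous")
            assert lp.classify_substitution_effect(codon, nb) == expected


# ---------------------------------------------------------------------------
# reference model and annotation

def test_coding_fraction_is_union_length_over_genome():
    genes = [lp.Gene("a", 1, 40), lp.Gene("b", 31, 60), lp.Gene("c", 81, 90)]
    ref = lp.ReferenceModel(100, genes)
    assert ref.coding_fraction == pytest.approx((60 + 10) / 100, abs=1e-9)


def test_codon_lookup_on_both_strands(tiny_reference):
    # plus gene starts ATG at 10..12; first-base SNP 10 A->T gives TTG,
    # middle-base SNP 11 T->C gives ACG
    assert tiny_reference.codon_for_snp(10, "T") == ("ATG", "TTG")
    assert tiny_reference.codon_for_snp(11, "C") == ("ATG", "ACG")
    # minus gene: first codon ATG maps to plus positions 48(A'),47,46; a
    # plus-strand C at 48 is a G on the gene strand
    ref_codon, alt_codon = tiny_reference.codon_for_snp(48, "C")
    assert ref_codon == "ATG" and alt_codon == "GTG"


def test_annotate_snp_inside_gene_uses_gene_name(tiny_reference):
    e = RawEntry("SNP", "chrom", 13, {"new_seq": "T"})
    rec = lp.annotate_mutation(e, tiny_reference)
    assert rec.gene_context == "plusA"
    assert rec.category == "SNP"


def test_annotate_intergenic_is_insertion_gets_flank_pair(tiny_reference):
    e = RawEntry("MOB", "chrom", 30,
                 {"repeat_name": "IS2", "strand": 1, "duplication_size": 5})
    rec = lp.annotate_mutation(e, tiny_reference)
    assert rec.gene_context == "plusA/minusB"
    assert rec.effect == "intergenic"
    assert rec.detail == "IS2:+"


@pytest.mark.parametrize("length", range(1, 17))
def test_coding_indel_frameshift_follows_length_mod_three(tiny_reference, length):
    e = RawEntry("INS", "chrom", 13, {"new_seq": "A" * length})
    rec = lp.annotate_mutation(e, tiny_reference)
    assert rec.effect == ("frameshift" if length % 3 else "disruption")


def test_annotate_position_outside_genome_raises(tiny_reference):
    with pytest.raises(ValueError):
        lp.annotate_mutation(RawEntry("SNP", "chrom", 61, {"new_seq": "A"}),
                             tiny_reference)


def test_deletion_size_splits_small_vs_large(tiny_reference):
    small = lp.annotate_mutation(
        RawEntry("DEL", "chrom", 5, {"size": 3}), tiny_reference)
    large = lp.annotate_mutation(
        RawEntry("DEL", "chrom", 5, {"size": 150}), tiny_reference)
    assert small.category == "small_indel"
    assert large.category == "large_deletion"
    assert large.effect == "disruption"  # overlaps plusA


# ---------------------------------------------------------------------------
# clone table

def test_clone_table_round_trip_and_errors(tmp_path):
    clones = [lp.CloneRecord(f"c{i}", 2, 10 * (i + 1), 40.0 + i)
              for i in range(3)]
    path = tmp_path / "clones.tsv"
    write_clone_table(clones, path)
    back = lp.read_clone_table(path)
    assert [(c.clone_id, c.culture, c.day, c.mean_depth) for c in back] == \
        [(c.clone_id, c.culture, c.day, c.mean_depth) for c in clones]

    assert lp.read_clone_table(
        io.StringIO("clone_id\tculture\tday\tmean_depth\n")) == []
    with pytest.raises(ValueError, match="duplicate"):
        lp.read_clone_table(io.StringIO(
            "clone_id\tculture\tday\tmean_depth\nx\t1\t10\t40\nx\t1\t20\t40\n"))
    with pytest.raises(ValueError):
        lp.read_clone_table(io.StringIO(
            "clone_id\tculture\tday\tmean_depth\nx\t1\tten\t40\n"))


# ---------------------------------------------------------------------------
# QC filters

def _clone(cid, depth, positions):
    muts = [lp.MutationRecord(p, "SNP", "A>G") for p in positions]
    return lp.CloneRecord(cid, 2, 10, depth, muts)


def test_depth_cutoff_is_inclusive_at_twenty():
    clones = [_clone("low", 19.9, [500]), _clone("ok", 20.0, [500])]
    kept, report = lp.apply_qc_filters(clones, lp.QCConfig())
    assert [c.clone_id for c in kept] == ["ok"]
    assert report.clones_removed_low_depth == 1


def test_parental_variant_positions_are_masked_by_default():
    clones = [_clone("c", 40.0, [2246663, 500])]  # gyrA parental position
    kept, report = lp.apply_qc_filters(clones, lp.QCConfig())
    assert [m.position for m in kept[0].mutations] == [500]
    assert report.calls_removed_parental == 1


def test_exclusion_interval_ends_are_inclusive():
    clones = [_clone("c", 40.0, [999, 1000, 2000, 2001])]
    cfg = lp.QCConfig(exclusion_intervals=((1000, 2000),),
                      parental_positions=())
    kept, report = lp.apply_qc_filters(clones, cfg)
    assert [m.position for m in kept[0].mutations] == [999, 2001]
    assert report.calls_removed_excluded_region == 2


@given(st.lists(st.floats(0, 60), min_size=1, max_size=30),
       st.floats(0, 50), st.floats(0, 15))
def test_raising_depth_cutoff_never_retains_more_clones(depths, lo, delta):
    clones = [_clone(f"c{i}", d, [100 + i]) for i, d in enumerate(depths)]
    n_lo = len(lp.apply_qc_filters(clones, lp.QCConfig(min_mean_depth=lo))[0])
    n_hi = len(lp.apply_qc_filters(
        clones, lp.QCConfig(min_mean_depth=lo + delta))[0])
    assert n_hi <= n_lo


# ---------------------------------------------------------------------------
# catalog construction

def test_shared_mutation_deduplicates_to_one_column():
    shared = lp.MutationRecord(100, "SNP", "C>T")
    clones = [lp.CloneRecord("a", 2, 10, 40, [shared]),
              lp.CloneRecord("b", 2, 10, 40, [shared])]
    cat = lp.build_catalog(clones)
    assert len(cat.records) == 1
    assert cat.matrix[shared.mutation_id].all()


def test_five_clone_fixture_column_sums():
    shared = [lp.MutationRecord(100 + i, "SNP", "C>T") for i in range(3)]
    private = [lp.MutationRecord(900 + i, "SNP", "A>G") for i in range(2)]
    clones = [
        lp.CloneRecord("a", 2, 10, 40, shared + [private[0]]),
        lp.CloneRecord("b", 2, 10, 40, shared + [private[1]]),
        lp.CloneRecord("c", 2, 10, 40, shared[:2]),
        lp.CloneRecord("d", 2, 10, 40, [shared[0]]),
        lp.CloneRecord("e", 2, 10, 40, [shared[2]]),
    ]
    cat = lp.build_catalog(clones)
    assert len(cat.records) == 5
    sums = cat.matrix.sum().to_dict()
    assert sums[shared[0].mutation_id] == 4
    assert sums[shared[1].mutation_id] == 3
    assert sums[shared[2].mutation_id] == 3
    assert sums[private[0].mutation_id] == 1
    assert sums[private[1].mutation_id] == 1


def test_matrix_reconstructs_each_clone_mutation_set(sim_default):
    cat = lp.build_catalog(sim_default.clones)
    sets = cat.mutation_sets()
    for clone in sim_default.clones:
        assert sets[clone.clone_id] == clone.mutation_ids


def test_catalog_build_is_idempotent(sim_default):
    clones = sim_default.clones[:100]
    first = lp.build_catalog(clones)
    again = lp.build_catalog(clones)
    assert [r.key for r in first.records] == [r.key for r in again.records]
    assert first.matrix.equals(again.matrix)


# ---------------------------------------------------------------------------
# substitution spectrum

def test_single_snp_spectrum_class():
    s = lp.substitution_spectrum([lp.MutationRecord(1, "SNP", "A>G")])
    assert s.counts["A:T>G:C"] == 1 and s.total == 1


def test_strand_collapse_merges_complementary_changes():
    recs = [lp.MutationRecord(1, "SNP", "C>T"),
            lp.MutationRecord(2, "SNP", "G>A")]
    s = lp.substitution_spectrum(recs)
    assert s.counts["G:C>A:T"] == 2


def test_identical_ref_alt_is_rejected():
    with pytest.raises(ValueError):
        classify_substitution_class("A", "A")


def test_spectrum_matches_exhaustive_pair_oracle():
    # independent oracle: explicit 12-entry lookup built from complements
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    oracle = {}
    for ref in "ACGT":
        for alt in "ACGT":
            if ref == alt:
                continue
            r, a = (ref, alt) if ref in "AG" else (comp[ref], comp[alt])
            oracle[(ref, alt)] = f"{r}:{comp[r]}>{a}:{comp[a]}"
    rng = np.random.default_rng(7)
    pairs = []
    for _ in range(1000):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        pairs.append((str(ref), str(alt)))
    recs = [lp.MutationRecord(i + 1, "SNP", f"{r}>{a}")
            for i, (r, a) in enumerate(pairs)]
    spectrum = lp.substitution_spectrum(recs)
    expected = {c: 0 for c in spectrum.counts}
    for pair in pairs:
        expected[oracle[pair]] += 1
    assert spectrum.counts == expected
    assert spectrum.total == 1000  # conservation


# ---------------------------------------------------------------------------
# amplification calls

def _track(depths, window=1000):
    return CoverageTrack(np.asarray(depths, dtype=float), window,
                         genome_length=window * len(depths))


def test_flat_coverage_yields_no_amplification_calls():
    assert lp.detect_amplifications(_track([40.0] * 500)) == []


def test_hundred_kb_threefold_segment_is_called_once():
    depths = [40.0] * 500
    depths[200:300] = [120.0] * 100  # 100 kb at 3x background
    calls = lp.detect_amplifications(_track(depths))
    assert len(calls) == 1
    call = calls[0]
    assert (call.start, call.end) == (200 * 1000 + 1, 300 * 1000)
    assert call.fold_change == pytest.approx(3.0, rel=1e-6)


def test_short_segment_below_span_threshold_is_not_called():
    depths = [40.0] * 500
    depths[200:210] = [120.0] * 10  # only 10 kb
    assert lp.detect_amplifications(_track(depths), min_span_bp=45_000) == []


def test_all_zero_track_is_an_error():
    with pytest.raises(ValueError):
        lp.detect_amplifications(_track([0.0] * 100))
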