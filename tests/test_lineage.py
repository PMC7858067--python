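import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ltspop as lp
from ltspop.lineage import (GenotypeNode, PARENTAL_ID, lineage_founders,
                            mst_edge_table)


def _matrix(sets, all_muts=None):
    all_muts = sorted(all_muts or set().union(*sets.values()))
    df = pd.DataFrame(
        [[m in sets[c] for m in all_muts] for c in sets],
        index=list(sets), columns=all_muts)
    df.index.name = "clone_id"
    return df


def _clones(sets, day=10):
    return [lp.CloneRecord(cid, 2, day, 40.0, []) for cid in sets]


def _node(gid, muts, count=1, day=10):
    return GenotypeNode(gid, frozenset(muts), count, {(2, day): count},
                        day if count else None)


# ---------------------------------------------------------------------------
# genotype collapse

def test_identical_clones_collapse_to_single_genotype():
    sets = {f"c{i}": {"m1", "m2"} for i in range(48)}
    nodes = lp.collapse_genotypes(_matrix(sets), _clones(sets))
    sampled = [n for n in nodes if n.clone_count > 0]
    assert len(sampled) == 1 and sampled[0].clone_count == 48
    root = next(n for n in nodes if n.genotype_id == PARENTAL_ID)
    assert root.clone_count == 0 and root.mutations == frozenset()


def test_six_clone_fixture_counts():
    sets = {"a": {"m1"}, "b": {"m1"}, "c": {"m2"}, "d": {"m2"},
            "e": {"m1", "m2"}, "f": {"m3"}}
    nodes = lp.collapse_genotypes(_matrix(sets), _clones(sets))
    counts = sorted(n.clone_count for n in nodes if n.clone_count > 0)
    assert counts == [1, 1, 2, 2]


def test_genotype_ids_are_content_deterministic():
    sets = {"a": {"m1"}, "b": {"m2"}, "c": {"m1", "m2"}}
    nodes1 = lp.collapse_genotypes(_matrix(sets), _clones(sets))
    shuffled = dict(reversed(list(sets.items())))
    nodes2 = lp.collapse_genotypes(_matrix(shuffled), _clones(shuffled))
    assert {n.genotype_id: n.mutations for n in nodes1} == \
        {n.genotype_id: n.mutations for n in nodes2}


# ---------------------------------------------------------------------------
# distance

def test_distance_identity_and_hand_example():
    a = frozenset({"m1", "m2"})
    assert lp.genotype_distance(a, a) == 0
    assert lp.genotype_distance(a, frozenset({"m2", "m3", "m4"})) == 3


@given(st.lists(st.frozensets(st.integers(0, 12), max_size=8),
                min_size=3, max_size=3))
def test_distance_triangle_inequality(sets):
    a, b, c = sets
    assert lp.genotype_distance(a, c) <= \
        lp.genotype_distance(a, b) + lp.genotype_distance(b, c)


# ---------------------------------------------------------------------------
# minimum spanning tree

def test_single_genotype_attaches_to_root_with_weight_one():
    mst = lp.build_mst([_node(PARENTAL_ID, (), 0), _node("g1", {"m1"}, 5)])
    assert mst.total_weight == 1
    assert list(mst.graph.edges) == [(PARENTAL_ID, "g1")]


def _random_instance(rng, n):
    universe = list(range(12))
    sets = {frozenset()}
    while len(sets) < n:
        sets.add(frozenset(rng.choice(universe,
                                      size=rng.integers(1, 7),
                                      replace=False).tolist()))
    sets = sorted(sets, key=sorted)
    nodes = [_node(PARENTAL_ID if s == frozenset() else f"g{i:02d}", s,
                   0 if s == frozenset() else int(rng.integers(1, 20)))
             for i, s in enumerate(sets)]
    return nodes


def _kruskal_weight(nodes):
    g = nx.Graph()
    for a, b in itertools.combinations(nodes, 2):
        g.add_edge(a.genotype_id, b.genotype_id,
                   weight=lp.genotype_distance(a.mutations, b.mutations))
    if len(nodes) == 1:
        return 0
    return sum(d["weight"] for _, _, d in
               nx.minimum_spanning_tree(g, algorithm="kruskal").edges(data=True))


def test_mst_weight_matches_kruskal_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(200):
        nodes = _random_instance(rng, int(rng.integers(2, 13)))
        assert lp.build_mst(nodes).total_weight == _kruskal_weight(nodes)


def test_tie_break_prefers_higher_clone_count_parent():
    nodes = [_node(PARENTAL_ID, (), 0), _node("gA", {"m1"}, 5),
             _node("gB", {"m2"}, 2), _node("gC", {"m1", "m2"}, 1)]
    mst = lp.build_mst(nodes)
    assert mst.parent("gC") == "gA"  # equidistant from gA and gB


def test_mst_edges_invariant_under_node_order_shuffle():
    rng = np.random.default_rng(3)
    nodes = _random_instance(rng, 10)
    ref_edges = set(lp.build_mst(nodes).graph.edges)
    for _ in range(5):
        perm = list(nodes)
        rng.shuffle(perm)
        assert set(lp.build_mst(perm).graph.edges) == ref_edges


# ---------------------------------------------------------------------------
# lineage assignment

def test_single_chain_is_one_lineage():
    nodes = [_node(PARENTAL_ID, (), 0), _node("g1", {"m1"}, 5, day=10),
             _node("g2", {"m1", "m2"}, 3, day=20)]
    mst = lp.build_mst(nodes)
    a = lp.assign_lineages(mst)
    assert a.labels["g1"] == a.labels["g2"] == "L1"
    assert a.labels[PARENTAL_ID] == PARENTAL_ID


def test_labels_ordered_by_descending_clone_count():
    nodes = [_node(PARENTAL_ID, (), 0), _node("small", {"m1"}, 3),
             _node("big", {"m2"}, 30)]
    a = lp.assign_lineages(lp.build_mst(nodes))
    assert a.labels["big"] == "L1" and a.labels["small"] == "L2"


def test_simulated_lineages_recover_major_and_minor_flags(sim_analysis):
    a = sim_analysis.assignment
    majors = sorted(lab for lab, m in a.major.items() if m)
    minors = sorted(lab for lab, m in a.major.items() if not m)
    assert len(majors) == 2 and len(minors) >= 2


def test_lineage_labels_partition_sampled_genotypes(sim_analysis):
    mst, a = sim_analysis.mst, sim_analysis.assignment
    for gid, node in mst.nodes.items():
        if node.clone_count > 0 and gid != PARENTAL_ID:
            assert gid in a.labels
            assert a.labels[gid] != PARENTAL_ID


# ---------------------------------------------------------------------------
# core / sublineage / collateral

def _chain_mst(counts):
    muts = [f"m{i}" for i in range(len(counts))]
    nodes = [_node(PARENTAL_ID, (), 0)]
    acc = []
    for i, c in enumerate(counts):
        acc.append(muts[i])
        nodes.append(_node(f"g{i}", set(acc), c, day=10 * (i + 1)))
    return lp.build_mst(nodes), muts


def test_fully_fixing_chain_is_all_core():
    mst, muts = _chain_mst([5, 5, 5])
    a = lp.assign_lineages(mst)
    tags = lp.classify_core_collateral(mst, a, {"L1": set(muts)})
    assert all(tags[g] == "core" for g in tags)


@pytest.mark.parametrize("branch_clones,expected",
                         [(10, "sublineage"), (9, "collateral")])
def test_sublineage_threshold_is_inclusive_at_ten(branch_clones, expected):
    nodes = [_node(PARENTAL_ID, (), 0),
             _node("core1", {"m1"}, 20, day=10),
             _node("branch", {"m1", "x1"}, branch_clones, day=20)]
    mst = lp.build_mst(nodes)
    a = lp.assign_lineages(mst)
    tags = lp.classify_core_collateral(mst, a, {"L1": {"m1"}})
    assert tags["branch"] == expected
    assert tags["core1"] == "core"


def test_tags_partition_non_parental_genotypes(sim_analysis):
    tags = sim_analysis.assignment.tags
    mst = sim_analysis.mst
    sampled = {g for g, n in mst.nodes.items()
               if n.clone_count > 0 and g != PARENTAL_ID}
    assert sampled <= set(tags)
    assert set(tags.values()) <= {"core", "sublineage", "collateral"}


def test_planted_collateral_singletons_are_tagged_collateral(sim_default,
                                                             sim_analysis):
    tags = sim_analysis.assignment.tags
    mst = sim_analysis.mst
    collateral_ids = set(sim_default.truth.collateral_ids)
    mislabeled = 0
    total = 0
    for gid, node in mst.nodes.items():
        if node.mutations & collateral_ids:
            total += 1
            if tags.get(gid) == "core":
                mislabeled += 1
    assert total > 50
    assert mislabeled == 0


# ---------------------------------------------------------------------------
# reversions

def test_strictly_accumulating_chain_has_no_reversions():
    mst, _ = _chain_mst([5, 5, 5])
    assert lp.detect_reversions(mst) == []


def test_lost_parent_mutation_is_reported():
    nodes = [_node(PARENTAL_ID, (), 0),
             _node("p", {"m1", "m2"}, 10, day=10),
             _node("c", {"m1", "m3"}, 1, day=20)]
    mst = lp.build_mst(nodes)
    events = lp.detect_reversions(mst)
    assert len(events) == 1
    ev = events[0]
    assert (ev.mutation_id, ev.parent_genotype, ev.child_genotype,
            ev.day_first_seen) == ("m2", "p", "c", 20)


def test_all_planted_reversions_on_sampled_edges_are_reported(sim_default,
                                                              sim_analysis):
    planted = {r.mutation_id for r in sim_default.truth.reversions}
    markers = {r.marker_id for r in sim_default.truth.reversions}
    detected = {e.mutation_id
                for e in lp.detect_reversions(sim_analysis.mst)}
    # every planted reversion whose branch was actually sampled shows up as
    # an MST edge loss (branch genotypes carry the marker mutation)
    sampled_planted = {
        r.mutation_id for r in sim_default.truth.reversions
        if any(r.marker_id in c.mutation_ids for c in sim_default.clones)}
    assert sampled_planted <= detected
    # no spurious reversions of never-planted mutations beyond edge noise
    spurious = detected - planted
    assert all(mid not in markers for mid in spurious)


def test_mst_edge_table_has_loss_and_gain_columns():
    nodes = [_node(PARENTAL_ID, (), 0), _node("g", {"m1"}, 2)]
    table = mst_edge_table(lp.build_mst(nodes))
    assert list(table.columns) == ["parent_id", "child_id", "weight",
                                   "lost_mutations", "gained_mutations"]
    assert table.loc[0, "gained_mutations"] == "m1"
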