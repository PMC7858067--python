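"""Genotypes, minimum spanning tree, lineages, core/collateral tags.

Clones with identical mutation sets collapse into one genotype ("sequence
type").  Genotypes are connected into a minimum spanning tree under the
symmetric-difference distance, rooted at the parental (empty-set) genotype,
with goeBURST-flavoured deterministic tie-breaking: among equal-weight
candidate links the parent with more sampled clones wins, then the earlier
first-detection day, then the lexicographically smaller genotype id.

Each child subtree of the parental root is a candidate lineage; candidates
meeting clone-count thresholds are labelled L1, L2, ... by descending clone
count, and flagged "major" when they persist (first to last detection) for
at least the configured number of days.  Within a lineage, genotypes built
purely from fixed ("core") mutations are core genotypes; non-core branches
with enough sampled clones are sublineages; everything else is collateral.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .catalog import CloneRecord

logger = logging.getLogger(__name__)

PARENTAL_ID = "parental"


# ---------------------------------------------------------------------------
# domain types

@dataclass
class GenotypeNode:
    """A unique mutation set with clone counts per (culture, day)."""
    genotype_id: str
    mutations: frozenset[str]
    clone_count: int
    counts_by_culture_day: dict[tuple[int, int], int]
    first_day: Optional[int]  # None when never sampled (parental root)
    clone_ids: tuple[str, ...] = ()

    @property
    def last_day(self) -> Optional[int]:
        days = [d for (_, d) in self.counts_by_culture_day]
        return max(days) if days else None


@dataclass
class GenotypeMst:
    """Parental-rooted MST over genotypes, edges oriented away from the root."""
    graph: nx.DiGraph  # edge attrs: weight, gained (set), lost (set)
    nodes: dict[str, GenotypeNode]
    root: str = PARENTAL_ID

    @property
    def total_weight(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def children(self, node_id: str) -> list[str]:
        return sorted(self.graph.successors(node_id))

    def subtree(self, node_id: str) -> list[str]:
        return sorted(nx.descendants(self.graph, node_id) | {node_id})

    def parent(self, node_id: str) -> Optional[str]:
        preds = list(self.graph.predecessors(node_id))
        return preds[0] if preds else None


@dataclass(frozen=True)
class ReversionEvent:
    """A mutation present in an MST parent but absent from its child."""
    lineage: str
    mutation_id: str
    parent_genotype: str
    child_genotype: str
    day_first_seen: Optional[int]


@dataclass
class LineageAssignment:
    """Genotype -> lineage label, major flags, and core/collateral tags."""
    labels: dict[str, str]             # genotype_id -> L1.../parental/unassigned
    major: dict[str, bool] = field(default_factory=dict)  # label -> persists?
    tags: dict[str, str] = field(default_factory=dict)    # core/sublineage/collateral
    reversions: list[ReversionEvent] = field(default_factory=list)

    def genotypes_of(self, label: str) -> list[str]:
        return sorted(g for g, lab in self.labels.items() if lab == label)


# ---------------------------------------------------------------------------
# genotype collapse and distance

def genotype_distance(a: frozenset, b: frozenset) -> int:
    """Symmetric-difference distance between two mutation sets."""
    return len(a ^ b)


def collapse_genotypes(matrix: pd.DataFrame,
                       clones: Sequence[CloneRecord]) -> list[GenotypeNode]:
    """Collapse matrix rows into unique genotypes; add the parental root.

    Genotype ids are deterministic functions of content, assigned g0001,
    g0002, ... in order of (first detection day, descending clone count,
    sorted mutation tuple); the empty set is always "parental" even when it
    was never sampled (clone_count 0).
    """
    meta = {c.clone_id: c for c in clones}
    missing = [cid for cid in matrix.index if cid not in meta]
    if missing:
        raise ValueError(f"clones absent from metadata: {missing[:5]}")
    groups: dict[frozenset, dict] = {}
    sets = _matrix_row_sets(matrix)
    for clone_id, mset in sets.items():
        g = groups.setdefault(mset, {"count": 0, "by_cd": {}, "clones": []})
        c = meta[clone_id]
        g["count"] += 1
        g["by_cd"][(c.culture, c.day)] = g["by_cd"].get((c.culture, c.day), 0) + 1
        g["clones"].append(clone_id)
    nodes = []
    order = sorted(
        (g for g in groups if g != frozenset()),
        key=lambda s: (min(d for (_, d) in groups[s]["by_cd"]),
                       -groups[s]["count"], tuple(sorted(s))))
    for i, mset in enumerate(order, start=1):
        g = groups[mset]
        nodes.append(GenotypeNode(
            genotype_id=f"g{i:04d}", mutations=mset, clone_count=g["count"],
            counts_by_culture_day=dict(sorted(g["by_cd"].items())),
            first_day=min(d for (_, d) in g["by_cd"]),
            clone_ids=tuple(sorted(g["clones"]))))
    root_info = groups.get(frozenset(), {"count": 0, "by_cd": {}, "clones": []})
    root = GenotypeNode(
        genotype_id=PARENTAL_ID, mutations=frozenset(),
        clone_count=root_info["count"],
        counts_by_culture_day=dict(sorted(root_info["by_cd"].items())),
        first_day=(min(d for (_, d) in root_info["by_cd"])
                   if root_info["by_cd"] else None),
        clone_ids=tuple(sorted(root_info["clones"])))
    return [root] + nodes


def _matrix_row_sets(matrix: pd.DataFrame) -> dict[str, frozenset[str]]:
    import numpy as np
    cols = np.asarray(matrix.columns)
    values = matrix.to_numpy(dtype=bool)
    return {cid: frozenset(cols[values[i]])
            for i, cid in enumerate(matrix.index)}


def clone_genotype_map(matrix: pd.DataFrame,
                       genotypes: Sequence[GenotypeNode]) -> dict[str, str]:
    """clone_id -> genotype_id."""
    by_set = {g.mutations: g.genotype_id for g in genotypes}
    return {cid: by_set[mset] for cid, mset in _matrix_row_sets(matrix).items()}


# ---------------------------------------------------------------------------
# minimum spanning tree

def _parent_rank(node: GenotypeNode) -> tuple:
    # goeBURST-flavoured: more clones first, then earlier first detection,
    # then lexicographic id.  Unsampled parental root sorts after sampled
    # nodes on the day criterion only when counts tie.
    day = node.first_day if node.first_day is not None else -1
    return (-node.clone_count, day, node.genotype_id)


def build_mst(genotypes: Sequence[GenotypeNode]) -> GenotypeMst:
    """Prim's algorithm over symmetric-difference distances with the
    deterministic 3-level tie-break described in the module docstring.

    Any minimum-weight frontier edge yields a minimum spanning tree, so the
    tie-break affects topology only where several trees share the optimal
    total weight.  The result is independent of input order.
    """
    if not genotypes:
        raise ValueError("no genotypes")
    nodes = {g.genotype_id: g for g in genotypes}
    if PARENTAL_ID not in nodes:
        raise ValueError("genotype list must include the parental root")
    graph = nx.DiGraph()
    for g in genotypes:
        graph.add_node(g.genotype_id)
    in_tree = {PARENTAL_ID}
    # best known connection for each out-of-tree node: (weight, parent_rank, parent_id)
    best: dict[str, tuple] = {}
    for gid, g in nodes.items():
        if gid == PARENTAL_ID:
            continue
        w = genotype_distance(g.mutations, nodes[PARENTAL_ID].mutations)
        best[gid] = (w, _parent_rank(nodes[PARENTAL_ID]), PARENTAL_ID)
    while best:
        child = min(best,
                    key=lambda v: (best[v][0], best[v][1],
                                   _parent_rank(nodes[v]), v))
        weight, _, parent = best.pop(child)
        pset, cset = nodes[parent].mutations, nodes[child].mutations
        graph.add_edge(parent, child, weight=weight,
                       gained=frozenset(cset - pset),
                       lost=frozenset(pset - cset))
        in_tree.add(child)
        for other in best:
            w = genotype_distance(nodes[child].mutations,
                                  nodes[other].mutations)
            cand = (w, _parent_rank(nodes[child]), child)
            if cand[:2] < best[other][:2]:
                best[other] = cand
    return GenotypeMst(graph=graph, nodes=nodes)


# ---------------------------------------------------------------------------
# lineage assignment

def assign_lineages(mst: GenotypeMst, min_persistence_days: int = 150,
                    min_total_clones: int = 2) -> LineageAssignment:
    """Label each root-child subtree as a lineage.

    Subtrees with at least ``min_total_clones`` sampled clones get labels
    L1, L2, ... ordered by descending total clone count; a lineage is
    flagged *major* when its first-to-last sampled-day span is at least
    ``min_persistence_days`` (detection gaps do not break persistence).
    Smaller subtrees are "unassigned"; the root is "parental".
    """
    if mst.graph.number_of_nodes() == 0:
        raise ValueError("empty MST")
    candidates = []
    for child in mst.children(mst.root):
        subtree = mst.subtree(child)
        total = sum(mst.nodes[g].clone_count for g in subtree)
        days = [d for g in subtree
                for (_, d) in mst.nodes[g].counts_by_culture_day]
        candidates.append((child, subtree, total,
                           min(days) if days else None,
                           max(days) if days else None))
    candidates.sort(key=lambda t: (-t[2], t[0]))
    labels = {mst.root: PARENTAL_ID}
    major: dict[str, bool] = {}
    k = 0
    for child, subtree, total, first, last in candidates:
        if total >= min_total_clones:
            k += 1
            label = f"L{k}"
            major[label] = (first is not None
                            and last - first >= min_persistence_days)
        else:
            label = "unassigned"
        for g in subtree:
            labels[g] = label
    return LineageAssignment(labels=labels, major=major)


def lineage_founders(mst: GenotypeMst,
                     assignment: LineageAssignment) -> dict[str, str]:
    """Lineage label -> founding genotype id (the root-child of its subtree)."""
    founders = {}
    for child in mst.children(mst.root):
        label = assignment.labels.get(child)
        if label and label.startswith("L"):
            founders[label] = child
    return founders


def classify_core_collateral(mst: GenotypeMst, assignment: LineageAssignment,
                             core_mutations: Mapping[str, Iterable[str]],
                             sublineage_min_clones: int = 10
                             ) -> dict[str, str]:
    """Tag every sampled non-parental genotype core / sublineage / collateral.

    A genotype is *core* when every mutation distinguishing it from its
    lineage founder is a fixed (core) mutation of that lineage
    (``core_mutations``: label -> fixed mutation ids, from the trajectories
    module).  Maximal non-core branches with at least
    ``sublineage_min_clones`` sampled clones (cumulatively over time) are
    *sublineages*; the rest are *collateral*.  Unassigned genotypes are
    collateral, with a warning.
    """
    founders = lineage_founders(mst, assignment)
    tags: dict[str, str] = {}
    is_core: dict[str, bool] = {mst.root: True}
    for gid in mst.subtree(mst.root):
        if gid == mst.root:
            continue
        label = assignment.labels.get(gid, "unassigned")
        if not label.startswith("L"):
            if label == "unassigned":
                logger.warning("genotype %s unassigned; tagged collateral", gid)
            is_core[gid] = False
            tags[gid] = "collateral"
            continue
        founder = founders[label]
        core_set = frozenset(core_mutations.get(label, ()))
        diff = mst.nodes[gid].mutations ^ mst.nodes[founder].mutations
        is_core[gid] = diff <= core_set
        tags[gid] = "core" if is_core[gid] else "collateral"
    # group non-core genotypes into maximal branches hanging off core nodes
    seen: set[str] = set()
    for gid in sorted(tags):
        if tags[gid] != "collateral" or gid in seen:
            continue
        parent = mst.parent(gid)
        if parent is not None and not is_core.get(parent, True):
            continue  # not a branch root
        branch = [g for g in mst.subtree(gid) if not is_core.get(g, False)]
        seen.update(branch)
        total = sum(mst.nodes[g].clone_count for g in branch)
        if total >= sublineage_min_clones:
            for g in branch:
                tags[g] = "sublineage"
    assignment.tags = tags
    return tags


def detect_reversions(mst: GenotypeMst,
                      assignment: Optional[LineageAssignment] = None
                      ) -> list[ReversionEvent]:
    """Report every MST edge where the child lost a parental mutation."""
    labels = assignment.labels if assignment is not None else {}
    events = []
    for parent, child, data in sorted(mst.graph.edges(data=True)):
        for mid in sorted(data["lost"]):
            events.append(ReversionEvent(
                lineage=labels.get(child, "unassigned"), mutation_id=mid,
                parent_genotype=parent, child_genotype=child,
                day_first_seen=mst.nodes[child].first_day))
    if assignment is not None:
        assignment.reversions = events
    return events


# ---------------------------------------------------------------------------
# exports

def mst_edge_table(mst: GenotypeMst) -> pd.DataFrame:
    rows = [(p, c, d["weight"], ",".join(sorted(d["lost"])),
             ",".join(sorted(d["gained"])))
            for p, c, d in sorted(mst.graph.edges(data=True))]
    return pd.DataFrame(rows, columns=["parent_id", "child_id", "weight",
                                       "lost_mutations", "gained_mutations"])


def genotype_table(mst: GenotypeMst,
                   assignment: Optional[LineageAssignment] = None
                   ) -> pd.DataFrame:
    rows = []
    for gid in sorted(mst.nodes):
        node = mst.nodes[gid]
        rows.append((gid, node.clone_count, node.first_day, node.last_day,
                     len(node.mutations),
                     assignment.labels.get(gid, "") if assignment else "",
                     assignment.tags.get(gid, "") if assignment else ""))
    return pd.DataFrame(rows, columns=["genotype_id", "clone_count",
                                       "first_day", "last_day", "n_mutations",
                                       "lineage", "tag"])


def mst_to_dot(mst: GenotypeMst,
               assignment: Optional[LineageAssignment] = None) -> str:
    lines = ["digraph mst {", '  node [shape=circle];']
    for gid in sorted(mst.nodes):
        node = mst.nodes[gid]
        label = gid
        if assignment is not None and gid in assignment.labels:
            label += f"\\n{assignment.labels[gid]}"
        lines.append(f'  "{gid}" [label="{label}", '
                     f'width={0.3 + 0.05 * node.clone_count ** 0.5:.2f}];')
    for p, c, d in sorted(mst.graph.edges(data=True)):
        lines.append(f'  "{p}" -> "{c}" [label="{d["weight"]}"];')
    lines.append("}")
    return "\n".join(lines)
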