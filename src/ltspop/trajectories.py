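"""Allele- and lineage-frequency time series, fixation and sweeps.

Frequencies are computed among *sampled* clones: for lineage scope the
denominator on a given day is the number of that lineage's clones sampled
that day.  A mutation fixes in a lineage on the earliest sampled day where
its within-lineage frequency is exactly 1.0 with an adequate denominator
and stays 1.0 at every later adequately-sampled day; days where the lineage
falls below ``min_n`` sampled clones are skipped rather than counted
against fixation (lineages fluctuate and occasionally drop below the limit
of detection).  Mutations fixing on the same day form one cofixation group;
a sweep is a distinct fixation day.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import CloneRecord
from .lineage import (GenotypeMst, LineageAssignment, clone_genotype_map,
                      GenotypeNode)


@dataclass(frozen=True)
class FixationEvent:
    mutation_id: str
    lineage: str
    first_detected_day: int
    fixation_day: int
    cofixation_group: Optional[str] = None
    #: True when fixation holds only after excluding a reversion branch
    via_reversion_exclusion: bool = False


@dataclass
class SweepSummary:
    lineage: str
    n_sweeps: int
    cofixation_groups: dict[int, list[str]]  # fixation day -> mutation ids
    intervals: list[int] = field(default_factory=list)

    @property
    def mean_interval(self) -> Optional[float]:
        return float(np.mean(self.intervals)) if self.intervals else None


def clone_lineage_labels(matrix: pd.DataFrame,
                         genotypes: Sequence[GenotypeNode],
                         assignment: LineageAssignment) -> dict[str, str]:
    """clone_id -> lineage label, via each clone's genotype."""
    gmap = clone_genotype_map(matrix, genotypes)
    return {cid: assignment.labels.get(gid, "unassigned")
            for cid, gid in gmap.items()}


def _scope_clones(clones: Sequence[CloneRecord], scope: str,
                  clone_labels: Optional[Mapping[str, str]]) -> list[CloneRecord]:
    if scope == "population":
        return list(clones)
    if clone_labels is None:
        raise ValueError("lineage scope requires clone_labels")
    return [c for c in clones if clone_labels.get(c.clone_id) == scope]


def allele_frequency_series(mutation_id: str, matrix: pd.DataFrame,
                            clones: Sequence[CloneRecord],
                            scope: str = "population",
                            clone_labels: Optional[Mapping[str, str]] = None
                            ) -> pd.DataFrame:
    """Per-day frequency of one mutation within a scope.

    ``scope`` is "population" or a lineage label.  Returns a DataFrame with
    columns day, numerator, denominator, frequency; days where the scope
    has no sampled clones are omitted.
    """
    if mutation_id not in matrix.columns:
        raise KeyError(f"unknown mutation {mutation_id!r}")
    in_scope = _scope_clones(clones, scope, clone_labels)
    col = matrix[mutation_id]
    rows = []
    days = sorted({c.day for c in in_scope})
    by_day: dict[int, list[str]] = {}
    for c in in_scope:
        by_day.setdefault(c.day, []).append(c.clone_id)
    for day in days:
        ids = by_day[day]
        num = int(col.loc[ids].sum())
        rows.append((day, num, len(ids), num / len(ids)))
    return pd.DataFrame(rows, columns=["day", "numerator", "denominator",
                                       "frequency"])


def lineage_frequency_series(clone_labels: Mapping[str, str],
                             clones: Sequence[CloneRecord]) -> pd.DataFrame:
    """Per-day fraction of sampled clones per lineage label (tidy frame).

    Fractions over all labels (including parental/unassigned) sum to 1 for
    each day; lineages undetected on a day appear with fraction 0 and that
    day's denominator.
    """
    labels = sorted(set(clone_labels.values()))
    days = sorted({c.day for c in clones})
    counts = {(d, lab): 0 for d in days for lab in labels}
    denom = {d: 0 for d in days}
    for c in clones:
        lab = clone_labels[c.clone_id]
        counts[(c.day, lab)] += 1
        denom[c.day] += 1
    rows = [(d, lab, counts[(d, lab)], denom[d],
             counts[(d, lab)] / denom[d] if denom[d] else np.nan)
            for d in days for lab in labels]
    return pd.DataFrame(rows, columns=["day", "lineage", "n", "denominator",
                                       "fraction"])


def detect_fixation(trajectory: pd.DataFrame, min_n: int = 5,
                    allow_gaps: bool = True) -> Optional[int]:
    """Earliest day from which the trajectory holds frequency 1.0.

    Only days with ``denominator >= min_n`` qualify (and, with
    ``allow_gaps``, under-sampled days are ignored entirely; with
    ``allow_gaps=False`` any later sampled day with frequency < 1 vetoes
    fixation regardless of its denominator).  Returns None when frequency
    never settles at 1.0.
    """
    if trajectory.empty:
        raise ValueError("empty trajectory")
    t = trajectory.sort_values("day")
    qualifying = t[t["denominator"] >= min_n]
    if qualifying.empty:
        return None
    vet = qualifying if allow_gaps else t
    candidate = None
    for _, row in qualifying.iterrows():
        if row["frequency"] == 1.0:
            later = vet[vet["day"] >= row["day"]]
            if (later["frequency"] == 1.0).all():
                candidate = int(row["day"])
                break
    return candidate


def _reversion_excluded_clones(mst: GenotypeMst) -> dict[str, set[str]]:
    """mutation_id -> clone ids descending from an edge that lost it."""
    out: dict[str, set[str]] = {}
    for _, child, data in mst.graph.edges(data=True):
        for mid in data["lost"]:
            clones = out.setdefault(mid, set())
            for gid in mst.subtree(child):
                clones.update(mst.nodes[gid].clone_ids)
    return out


def fixation_events(matrix: pd.DataFrame, clones: Sequence[CloneRecord],
                    clone_labels: Mapping[str, str], min_n: int = 5,
                    mst: Optional[GenotypeMst] = None,
                    fixation_threshold: float = 1.0) -> list[FixationEvent]:
    """Fixation calls for every mutation within every lineage.

    When an MST is supplied, a mutation lost on some MST edge (a reversion)
    is re-tested after excluding the clones of the reverted branch: a
    fixation that stands once the branch is excluded is kept and flagged,
    so a reversion confined to a sublineage or collateral branch does not
    retroactively cancel a sweep.  ``fixation_threshold`` below 1.0 relaxes
    the all-sampled-clones requirement (off by default).
    """
    excluded = _reversion_excluded_clones(mst) if mst is not None else {}
    events: list[FixationEvent] = []
    lineages = sorted({lab for lab in clone_labels.values()
                       if lab.startswith("L")})
    for lineage in lineages:
        members = [c for c in clones if clone_labels.get(c.clone_id) == lineage]
        if not members:
            continue
        ids = [c.clone_id for c in members]
        sub = matrix.loc[ids]
        present = sub.columns[sub.any(axis=0)]
        day_of = {c.clone_id: c.day for c in members}
        for mid in present:
            traj = _traj_from_submatrix(sub[mid], day_of)
            first = int(traj.loc[traj["numerator"] > 0, "day"].min())
            day = _detect_with_threshold(traj, min_n, fixation_threshold)
            via_reversion = False
            if mid in excluded:
                # a reversion confined to a branch must not cancel (or
                # postpone) the sweep: retry without the reverted branch
                keep = [cid for cid in ids if cid not in excluded[mid]]
                if keep:
                    traj2 = _traj_from_submatrix(sub[mid].loc[keep],
                                                 {k: day_of[k] for k in keep})
                    day2 = _detect_with_threshold(traj2, min_n,
                                                  fixation_threshold)
                    if day2 is not None and (day is None or day2 < day):
                        day = day2
                        via_reversion = True
            if day is not None:
                events.append(FixationEvent(mid, lineage, first, day,
                                            via_reversion_exclusion=via_reversion))
    return events


def _traj_from_submatrix(col: pd.Series, day_of: Mapping[str, int]) -> pd.DataFrame:
    frame = pd.DataFrame({"present": col.astype(bool),
                          "day": [day_of[c] for c in col.index]})
    g = frame.groupby("day")["present"].agg(["sum", "count"]).reset_index()
    g.columns = ["day", "numerator", "denominator"]
    g["frequency"] = g["numerator"] / g["denominator"]
    return g


def _detect_with_threshold(traj: pd.DataFrame, min_n: int,
                           threshold: float) -> Optional[int]:
    if threshold >= 1.0:
        return detect_fixation(traj, min_n=min_n)
    q = traj[traj["denominator"] >= min_n]
    for _, row in q.iterrows():
        if row["frequency"] >= threshold:
            later = q[q["day"] >= row["day"]]
            if (later["frequency"] >= threshold).all():
                return int(row["day"])
    return None


def sweep_summary(events: Sequence[FixationEvent],
                  lineage: Optional[str] = None) -> SweepSummary:
    """Group fixation events into cofixation groups and count sweeps.

    Mutations sharing a fixation day form one group; the sweep count is the
    number of distinct fixation days; inter-sweep intervals are differences
    between consecutive fixation days.
    """
    if lineage is not None:
        events = [e for e in events if e.lineage == lineage]
    else:
        labs = {e.lineage for e in events}
        if len(labs) > 1:
            raise ValueError("events span multiple lineages; pass lineage=")
        lineage = labs.pop() if labs else "none"
    groups: dict[int, list[str]] = {}
    for e in sorted(events, key=lambda e: (e.fixation_day, e.mutation_id)):
        groups.setdefault(e.fixation_day, []).append(e.mutation_id)
    days = sorted(groups)
    return SweepSummary(lineage=lineage, n_sweeps=len(days),
                        cofixation_groups=groups,
                        intervals=[b - a for a, b in zip(days, days[1:])])


def annotate_cofixation_groups(events: Sequence[FixationEvent]
                               ) -> list[FixationEvent]:
    """Return events with cofixation group ids like ``"L1.s03"`` filled in."""
    out = []
    for lineage in sorted({e.lineage for e in events}):
        evs = sorted((e for e in events if e.lineage == lineage),
                     key=lambda e: (e.fixation_day, e.mutation_id))
        day_rank = {d: i + 1 for i, d in
                    enumerate(sorted({e.fixation_day for e in evs}))}
        for e in evs:
            out.append(FixationEvent(
                e.mutation_id, e.lineage, e.first_detected_day, e.fixation_day,
                cofixation_group=f"{lineage}.s{day_rank[e.fixation_day]:02d}",
                via_reversion_exclusion=e.via_reversion_exclusion))
    return out


def trajectory_table(matrix: pd.DataFrame, clones: Sequence[CloneRecord],
                     clone_labels: Optional[Mapping[str, str]] = None,
                     scopes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Long-format trajectory table for export (mutation, scope, day, ...)."""
    scopes = list(scopes) if scopes is not None else ["population"]
    frames = []
    for scope in scopes:
        for mid in matrix.columns:
            t = allele_frequency_series(mid, matrix, clones, scope=scope,
                                        clone_labels=clone_labels)
            t.insert(0, "scope", scope)
            t.insert(0, "mutation_id", mid)
            frames.append(t)
    return pd.concat(frames, ignore_index=True)


def muller_plot(lineage_series: pd.DataFrame, path) -> None:
    """Stacked-area (Muller-style) plot of lineage fractions, saved as SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = lineage_series.pivot(index="day", columns="lineage",
                                values="fraction").fillna(0.0)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.stackplot(wide.index, wide.T.to_numpy(), labels=list(wide.columns))
    ax.set_xlabel("day")
    ax.set_ylabel("fraction of sampled clones")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
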