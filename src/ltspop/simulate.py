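"""Synthetic clone-resolved LTSP datasets with known ground truth.

The generator plants population structure directly rather than running an
explicit fitness model: each lineage carries an ordered sweep schedule
(core mutations fixing roughly every ``sweep_interval_mean`` days, in
cofixation groups of configurable size), clones are drawn per sampling day
by per-lineage sampling weights, and every clone's mutation set is its
lineage's core set at that day plus Poisson-distributed private collateral
mutations — plus a burst of IS2 insertions confined to one lineage within a
day window, and rare reversion branches that lose a core mutation.  Because
the analysis consumes only sampled clones, direct planting yields exact,
testable truth.

Outputs use the pipeline's own input formats (per-clone GenomeDiff files or
a flat mutation TSV, plus a clone metadata TSV) and a truth JSON.  All
randomness flows from one seeded generator; identical (config, seed) give
byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog import CloneRecord, MutationRecord, write_clone_table, \
    write_mutation_table
from .genomediff import RawEntry, write_genomediff
from .reference import ReferenceModel

# 24 sampling days: dense through day 600, sparse afterwards, ending at 1200
DEFAULT_SAMPLING_DAYS: tuple[int, ...] = (
    10, 20, 30, *range(60, 601, 30), 900, 1200)

_IS_OTHER_FAMILIES = ("IS1", "IS3", "IS5", "IS30", "IS186")


@dataclass(frozen=True)
class LineageSpec:
    """One planted lineage: lifespan plus per-day sampling weights.

    ``weights`` are (from_day, weight) breakpoints; the weight in force on a
    day is the last breakpoint at or before it (zero before founding and
    after extinction).
    """
    name: str
    founding_day: int
    extinction_day: Optional[int]
    weights: tuple[tuple[int, float], ...]
    founder_group_size: int = 1
    #: plant only the founding mutation group, no later sweeps — the natural
    #: setting for transient lineages that dwindle rather than adapt
    founder_sweep_only: bool = False

    def weight_at(self, day: int) -> float:
        if day < self.founding_day:
            return 0.0
        if self.extinction_day is not None and day > self.extinction_day:
            return 0.0
        w = 0.0
        for from_day, weight in self.weights:
            if from_day <= day:
                w = weight
        return w


def _default_lineages() -> tuple[LineageSpec, ...]:
    # Two persistent lineages trading dominance (the larger one ~60% of all
    # clones, the other ~35%) and two transient lineages prominent on day 10
    # and gone within ~5 months.
    return (
        LineageSpec("L1", 10, None, ((10, 0.30), (20, 0.92), (30, 0.30),
                                     (60, 0.10), (90, 0.60)),
                    founder_group_size=3),
        LineageSpec("L2", 10, None, ((10, 0.15), (20, 0.02), (30, 0.50),
                                     (60, 0.85), (90, 0.36))),
        LineageSpec("L3", 10, 150, ((10, 0.25), (20, 0.02), (30, 0.05)),
                    founder_sweep_only=True),
        LineageSpec("L4", 10, 120, ((10, 0.20), (20, 0.02), (30, 0.03)),
                    founder_sweep_only=True),
    )


def _default_mixture() -> dict[str, float]:
    # proportions of a 679-mutation clone-panel catalog:
    # 227 SNPs, 48 small indels, 376 IS insertions, 14 deletions, 14 amps
    total = 679.0
    return {"SNP": 227 / total, "small_indel": 48 / total,
            "IS_insertion": 376 / total, "large_deletion": 14 / total,
            "amplification": 14 / total}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate a 1,200-day batch culture
    sampled at 24 time points, ~48 clones per day (15 on the poorly-growing
    day 240), with sweeps roughly every 90 days and an IS2 mobilisation
    burst confined to the second persistent lineage between days 270 and
    600."""
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    clones_per_day: int = 48
    clones_per_day_overrides: dict[int, int] = field(
        default_factory=lambda: {240: 15})
    lineages: tuple[LineageSpec, ...] = field(
        default_factory=_default_lineages)
    parental_weights: tuple[tuple[int, float], ...] = (
        (0, 1.0), (10, 0.10), (20, 0.04), (30, 0.05), (60, 0.03), (90, 0.0))
    sweep_interval_mean: float = 90.0
    sweep_interval_sd: float = 25.0
    min_sweep_interval: float = 30.0
    #: P(cofixation group size = 1..8)
    cofixation_size_probs: tuple[float, ...] = (
        0.80, 0.12, 0.04, 0.015, 0.01, 0.006, 0.005, 0.004)
    #: Poisson mean of private (collateral) mutations per sampled clone
    collateral_rate: float = 0.35
    category_mixture: dict[str, float] = field(default_factory=_default_mixture)
    #: P(an IS insertion outside the burst is family IS2)
    is2_background_prob: float = 0.02
    burst_lineage: str = "L2"
    burst_window: tuple[int, int] = (270, 600)
    #: Poisson mean of extra private IS2 insertions per burst-lineage clone
    #: sampled inside the window
    burst_rate: float = 1.0
    #: P(a core sweep mutation in the burst lineage/window is an IS2)
    burst_core_is2_prob: float = 0.8
    reversion_probability: float = 0.05
    reversion_branch_fraction: float = 0.12
    reversion_branch_duration: int = 60
    genome_length: int = 4_541_111
    n_genes: int = 4_295
    coding_fraction: float = 0.90
    #: if set, P(a mutation lands in coding sequence); None = uniform
    coding_bias: Optional[float] = None
    mean_depth: float = 40.0
    depth_sd: float = 5.0

    def validate(self) -> None:
        days = self.sampling_days
        if not days or list(days) != sorted(set(days)) or days[0] < 1:
            raise ValueError("sampling_days must be strictly increasing, >= 1")
        if self.clones_per_day < 1:
            raise ValueError("clones_per_day must be >= 1")
        horizon = days[-1]
        lo, hi = self.burst_window
        if not (0 <= lo <= hi <= horizon):
            raise ValueError(f"burst window {self.burst_window} outside "
                             f"sampling horizon [0, {horizon}]")
        for rate_name in ("collateral_rate", "burst_rate",
                          "reversion_probability", "sweep_interval_mean"):
            if getattr(self, rate_name) < 0:
                raise ValueError(f"{rate_name} must be >= 0")
        mix_total = sum(self.category_mixture.values())
        if not math.isclose(mix_total, 1.0, abs_tol=1e-9):
            raise ValueError(f"category mixture sums to {mix_total}, not 1")
        if not math.isclose(sum(self.cofixation_size_probs), 1.0,
                            abs_tol=1e-9):
            raise ValueError("cofixation size probabilities must sum to 1")
        names = [l.name for l in self.lineages]
        if len(set(names)) != len(names):
            raise ValueError("duplicate lineage names")
        for l in self.lineages:
            if any(w < 0 for _, w in l.weights):
                raise ValueError(f"negative sampling weight in {l.name}")


def default_config() -> SimulationConfig:
    return SimulationConfig()


# ---------------------------------------------------------------------------
# ground truth bookkeeping

@dataclass(frozen=True)
class SweepTruth:
    lineage: str
    day: int
    mutation_ids: tuple[str, ...]


@dataclass(frozen=True)
class ReversionTruth:
    lineage: str
    mutation_id: str
    day: int
    marker_id: str


@dataclass
class GroundTruth:
    clone_labels: dict[str, str]
    sweeps: list[SweepTruth]
    collateral_ids: list[str]
    reversions: list[ReversionTruth]
    is2_insertions: dict[str, int]  # mutation_id -> position

    def to_json(self, path=None) -> str:
        payload = {
            "clone_labels": self.clone_labels,
            "sweeps": [dataclasses.asdict(s) for s in self.sweeps],
            "collateral_ids": self.collateral_ids,
            "reversions": [dataclasses.asdict(r) for r in self.reversions],
            "is2_insertions": self.is2_insertions,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if isinstance(source, (str, Path)) and Path(source).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        return cls(
            clone_labels=payload["clone_labels"],
            sweeps=[SweepTruth(s["lineage"], s["day"],
                               tuple(s["mutation_ids"]))
                    for s in payload["sweeps"]],
            collateral_ids=payload["collateral_ids"],
            reversions=[ReversionTruth(**r) for r in payload["reversions"]],
            is2_insertions=payload["is2_insertions"])


@dataclass
class SimulationResult:
    clones: list[CloneRecord]
    truth: GroundTruth
    reference: ReferenceModel
    config: SimulationConfig
    seed: int

    def calls_by_clone(self) -> dict[str, list[MutationRecord]]:
        return {c.clone_id: list(c.mutations) for c in self.clones}

    def write(self, outdir, gd_files: bool = False) -> None:
        """clone_table.tsv + mutations.tsv + truth.json (+ per-clone GD)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        clones = [CloneRecord(c.clone_id, c.culture, c.day,
                              round(c.mean_depth, 2), c.mutations)
                  for c in self.clones]
        write_clone_table(clones, outdir / "clone_table.tsv")
        write_mutation_table(self.calls_by_clone(), outdir / "mutations.tsv")
        self.truth.to_json(outdir / "truth.json")
        if gd_files:
            gd_dir = outdir / "gd"
            gd_dir.mkdir(exist_ok=True)
            for clone in clones:
                entries = [record_to_gd_entry(m) for m in
                           sorted(clone.mutations, key=lambda m: m.key)]
                write_genomediff(entries, gd_dir / f"{clone.clone_id}.gd")


def record_to_gd_entry(record: MutationRecord) -> RawEntry:
    """Serialise a catalog record back into the GenomeDiff dialect."""
    extra = {}
    if record.category == "SNP":
        ref, alt = record.snp_bases
        extra = {"ref_seq": ref, "effect": record.effect}
        return RawEntry("SNP", "chrom", record.position,
                        {"new_seq": alt}, extra)
    if record.category == "small_indel":
        if record.detail.startswith("+"):
            return RawEntry("INS", "chrom", record.position,
                            {"new_seq": record.detail[1:]})
        return RawEntry("DEL", "chrom", record.position,
                        {"size": record.indel_length})
    if record.category == "large_deletion":
        return RawEntry("DEL", "chrom", record.position,
                        {"size": record.indel_length})
    if record.category == "IS_insertion":
        family, strand = record.detail.split(":")
        return RawEntry("MOB", "chrom", record.position,
                        {"repeat_name": family,
                         "strand": 1 if strand == "+" else -1,
                         "duplication_size": 5})
    copy, size = record.detail[1:].split(":")
    return RawEntry("AMP", "chrom", record.position,
                    {"size": int(size), "new_copy_number": int(copy)})


# ---------------------------------------------------------------------------
# mutation factory

class MutationFactory:
    """Draws annotated mutations with collision-free positions."""

    def __init__(self, config: SimulationConfig, reference: ReferenceModel,
                 rng: np.random.Generator):
        self.config = config
        self.reference = reference
        self.rng = rng
        self._used_positions: set[int] = set()
        self._categories = sorted(config.category_mixture)
        self._cat_probs = np.array([config.category_mixture[c]
                                    for c in self._categories])

    def draw_category(self) -> str:
        return self._categories[self.rng.choice(len(self._categories),
                                                p=self._cat_probs)]

    def _draw_position(self) -> tuple[int, object]:
        bias = self.config.coding_bias
        want_coding = None
        if bias is not None:
            want_coding = bool(self.rng.random() < bias)
        for _ in range(10_000):
            pos = int(self.rng.integers(1, self.reference.genome_length + 1))
            if pos in self._used_positions:
                continue
            gene = self.reference.gene_at(pos)
            if want_coding is not None and (gene is not None) != want_coding:
                continue
            self._used_positions.add(pos)
            return pos, gene
        raise RuntimeError("could not place mutation without collision")

    def new_mutation(self, category: Optional[str] = None,
                     is_family: Optional[str] = None) -> MutationRecord:
        rng = self.rng
        if category is None:
            category = self.draw_category()
        pos, gene = self._draw_position()
        context = (gene.name if gene is not None
                   else self.reference.intergenic_context(pos))
        coding = gene is not None
        if category == "SNP":
            ref = "ACGT"[rng.integers(4)]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            if not coding:
                effect = "intergenic"
            else:
                effect = ["nonsynonymous", "synonymous", "nonsense"][
                    rng.choice(3, p=[0.65, 0.25, 0.10])]
            return MutationRecord(pos, "SNP", f"{ref}>{alt}", context, effect)
        if category == "small_indel":
            length = int(rng.integers(1, 17))
            if rng.random() < 0.5:
                seq = "".join(rng.choice(list("ACGT"), size=length))
                detail = f"+{seq}"
            else:
                detail = f"-{length}"
            effect = ("intergenic" if not coding
                      else ("frameshift" if length % 3 else "disruption"))
            return MutationRecord(pos, "small_indel", detail, context, effect)
        if category == "IS_insertion":
            if is_family is None:
                if rng.random() < self.config.is2_background_prob:
                    is_family = "IS2"
                else:
                    is_family = _IS_OTHER_FAMILIES[
                        rng.integers(len(_IS_OTHER_FAMILIES))]
            strand = "+" if rng.random() < 0.5 else "-"
            effect = "disruption" if coding else "intergenic"
            return MutationRecord(pos, "IS_insertion",
                                  f"{is_family}:{strand}", context, effect)
        if category == "large_deletion":
            length = int(round(10 ** rng.uniform(2.0, math.log10(64_000))))
            effect = "disruption" if coding else "intergenic"
            return MutationRecord(pos, "large_deletion", f"-{length}",
                                  context, effect)
        if category == "amplification":
            size = int(rng.integers(50_000, 500_001))
            copy = int(rng.integers(2, 6))
            return MutationRecord(pos, "amplification", f"x{copy}:{size}",
                                  context, "not_applicable")
        raise ValueError(f"unknown category {category!r}")


# ---------------------------------------------------------------------------
# simulation

def _parental_weight_at(config: SimulationConfig, day: int) -> float:
    w = 0.0
    for from_day, weight in config.parental_weights:
        if from_day <= day:
            w = weight
    return w


@dataclass
class _Reversion:
    lineage: str
    mutation_id: str
    start_day: int
    end_day: int
    marker: MutationRecord


def _plan_sweeps(config: SimulationConfig, factory: MutationFactory,
                 rng: np.random.Generator
                 ) -> tuple[dict[str, list[SweepTruth]], list[_Reversion],
                            dict[str, MutationRecord]]:
    horizon = config.sampling_days[-1]
    group_sizes = np.arange(1, len(config.cofixation_size_probs) + 1)
    sweeps: dict[str, list[SweepTruth]] = {}
    reversions: list[_Reversion] = []
    registry: dict[str, MutationRecord] = {}
    for spec in config.lineages:
        last = spec.extinction_day if spec.extinction_day is not None else horizon
        day = spec.founding_day
        lineage_sweeps: list[SweepTruth] = []
        first = True
        while day <= last:
            size = (spec.founder_group_size if first else
                    int(rng.choice(group_sizes,
                                   p=config.cofixation_size_probs)))
            in_burst = (spec.name == config.burst_lineage
                        and config.burst_window[0] <= day
                        <= config.burst_window[1])
            muts = []
            for _ in range(size):
                if in_burst and rng.random() < config.burst_core_is2_prob:
                    m = factory.new_mutation("IS_insertion", is_family="IS2")
                else:
                    m = factory.new_mutation()
                registry[m.mutation_id] = m
                muts.append(m.mutation_id)
            lineage_sweeps.append(SweepTruth(spec.name, int(day), tuple(muts)))
            if (not first and config.reversion_probability > 0
                    and rng.random() < config.reversion_probability):
                earlier = [mid for s in lineage_sweeps[:-1]
                           for mid in s.mutation_ids]
                target = earlier[rng.integers(len(earlier))]
                marker = factory.new_mutation()
                registry[marker.mutation_id] = marker
                reversions.append(_Reversion(
                    spec.name, target, int(day),
                    int(day) + config.reversion_branch_duration, marker))
            if spec.founder_sweep_only:
                break
            interval = max(config.min_sweep_interval,
                           rng.normal(config.sweep_interval_mean,
                                      config.sweep_interval_sd))
            day = day + int(round(interval))
            first = False
        sweeps[spec.name] = lineage_sweeps
    return sweeps, reversions, registry


def simulate_ltsp(config: Optional[SimulationConfig] = None,
                  seed: int = 0) -> SimulationResult:
    """Generate a full synthetic clone panel with ground truth.

    Reproducible: identical (config, seed) produce identical results (and
    byte-identical files through :meth:`SimulationResult.write`).
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(seed)
    reference = ReferenceModel.synthetic(config.genome_length, config.n_genes,
                                         config.coding_fraction)
    factory = MutationFactory(config, reference, rng)
    sweeps, reversions, registry = _plan_sweeps(config, factory, rng)

    truth = GroundTruth(clone_labels={}, sweeps=[s for spec in config.lineages
                                                 for s in sweeps[spec.name]],
                        collateral_ids=[], reversions=[], is2_insertions={})
    for rev in reversions:
        truth.reversions.append(ReversionTruth(
            rev.lineage, rev.mutation_id, rev.start_day,
            rev.marker.mutation_id))

    core_at: dict[str, dict[int, frozenset[str]]] = {}
    for spec in config.lineages:
        acc: set[str] = set()
        by_day = {}
        schedule = sweeps[spec.name]
        for day in config.sampling_days:
            for s in schedule:
                if s.day <= day:
                    acc.update(s.mutation_ids)
            by_day[day] = frozenset(acc)
            acc = set(by_day[day])
        core_at[spec.name] = by_day

    clones: list[CloneRecord] = []
    lineage_names = [spec.name for spec in config.lineages]
    for day in config.sampling_days:
        n = config.clones_per_day_overrides.get(day, config.clones_per_day)
        weights = np.array([spec.weight_at(day) for spec in config.lineages]
                           + [_parental_weight_at(config, day)])
        if weights.sum() <= 0:
            weights[-1] = 1.0
        probs = weights / weights.sum()
        choices = rng.choice(len(probs), size=n, p=probs)
        for i, choice in enumerate(choices):
            clone_id = f"d{day:04d}c{i + 1:02d}"
            label = (lineage_names[choice] if choice < len(lineage_names)
                     else "parental")
            mut_ids: set[str] = set()
            if label != "parental":
                mut_ids = set(core_at[label][day])
                for rev in reversions:
                    if (rev.lineage == label
                            and rev.start_day <= day <= rev.end_day
                            and rev.mutation_id in mut_ids
                            and rng.random() < config.reversion_branch_fraction):
                        mut_ids.discard(rev.mutation_id)
                        mut_ids.add(rev.marker.mutation_id)
                if (label == config.burst_lineage
                        and config.burst_window[0] <= day
                        <= config.burst_window[1]):
                    for _ in range(rng.poisson(config.burst_rate)):
                        m = factory.new_mutation("IS_insertion",
                                                 is_family="IS2")
                        registry[m.mutation_id] = m
                        mut_ids.add(m.mutation_id)
            for _ in range(rng.poisson(config.collateral_rate)):
                m = factory.new_mutation()
                registry[m.mutation_id] = m
                truth.collateral_ids.append(m.mutation_id)
                mut_ids.add(m.mutation_id)
            depth = max(0.0, float(rng.normal(config.mean_depth,
                                              config.depth_sd)))
            records = sorted((registry[mid] for mid in mut_ids),
                             key=lambda m: m.key)
            clones.append(CloneRecord(clone_id, culture=2, day=day,
                                      mean_depth=depth, mutations=records))
            truth.clone_labels[clone_id] = label

    truth.is2_insertions = {
        mid: rec.position for mid, rec in sorted(registry.items())
        if rec.category == "IS_insertion" and rec.is_family == "IS2"}
    return SimulationResult(clones=clones, truth=truth, reference=reference,
                            config=config, seed=seed)


# ---------------------------------------------------------------------------
# recovery scoring

def evaluate_lineage_recovery(truth_labels: Mapping[str, str],
                              inferred_labels: Mapping[str, str]) -> float:
    """Pair-counting (Rand) agreement between planted and inferred partitions.

    Label names are irrelevant; 1.0 iff the partitions are identical.
    """
    if set(truth_labels) != set(inferred_labels):
        raise ValueError("clone sets differ between truth and inference")
    from sklearn.metrics import rand_score
    keys = sorted(truth_labels)
    return float(rand_score([truth_labels[k] for k in keys],
                            [inferred_labels[k] for k in keys]))


@dataclass
class SweepRecovery:
    precision: float
    recall: float
    n_truth: int
    n_inferred: int
    #: True when precision defaults to 1.0 because nothing was inferred
    no_inferred_events: bool = False


def evaluate_sweep_recovery(truth_sweeps: Sequence[SweepTruth],
                            inferred_events, sampling_days: Sequence[int],
                            day_tolerance: int = 1) -> SweepRecovery:
    """Match planted sweeps against inferred fixation events by mutation.

    A planted sweep is only observable from the first sampled day at or
    after its true day, so matching is done on sampled-day indices with a
    tolerance (default 1 step).  Truth sweeps of mutations are matched
    irrespective of lineage labels (mutation ids are global).
    """
    days = sorted(sampling_days)

    def day_index(day: int, ceil: bool) -> Optional[int]:
        for i, d in enumerate(days):
            if (ceil and d >= day) or (not ceil and d == day):
                return i
        return None

    truth_items = [(mid, day_index(s.day, ceil=True))
                   for s in truth_sweeps for mid in s.mutation_ids]
    truth_items = [(m, i) for m, i in truth_items if i is not None]
    inferred_items = [(e.mutation_id, day_index(e.fixation_day, ceil=False))
                      for e in inferred_events]
    matched_truth = 0
    used: set[int] = set()
    for mid, idx in truth_items:
        for j, (imid, iidx) in enumerate(inferred_items):
            if j in used or imid != mid or iidx is None:
                continue
            if abs(iidx - idx) <= day_tolerance:
                used.add(j)
                matched_truth += 1
                break
    n_truth = len(truth_items)
    n_inferred = len(inferred_items)
    recall = matched_truth / n_truth if n_truth else 1.0
    if n_inferred == 0:
        return SweepRecovery(precision=1.0, recall=recall, n_truth=n_truth,
                             n_inferred=0, no_inferred_events=True)
    return SweepRecovery(precision=len(used) / n_inferred, recall=recall,
                         n_truth=n_truth, n_inferred=n_inferred)
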