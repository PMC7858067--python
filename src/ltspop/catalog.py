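"""Unique-mutation catalog and clone x mutation presence/absence matrix.

Takes per-clone mutation calls (GenomeDiff dialect or a flat TSV), applies
the quality-control and masking rules of a clone-resolved resequencing
study (read-depth cutoff, parental-variant masking, prophage-region
exclusion), classifies mutation categories and coding effects, and collapses
identical events across clones into one catalog record each.

Mutation identity is the triple (position, category, detail): the same event
observed in two clones maps to a single catalog column.  IS insertions are
identical only when family, position and strand all match, so independent
insertions at different locations in one gene stay distinct alleles.
"""
from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .codons import classify_substitution_effect
from .genomediff import RawEntry, read_genomediff
from .reference import ReferenceModel

logger = logging.getLogger(__name__)

CATEGORIES = ("SNP", "small_indel", "IS_insertion", "large_deletion",
              "amplification")
EFFECTS = ("synonymous", "nonsynonymous", "nonsense", "frameshift",
           "intergenic", "disruption", "not_applicable")

#: Positions of the 11 variants the parental strains carry relative to the
#: reference assembly; masked from every clone by default.
PARENTAL_VARIANT_POSITIONS: tuple[int, ...] = (
    2894668, 2499451, 1810671, 1398837, 1576168, 2166923, 281996, 2246663,
    2959436, 3457470, 4175949,
)

#: strand-collapsed substitution classes (ref purine representative)
SPECTRUM_CLASSES = ("A:T>G:C", "G:C>A:T", "A:T>T:A", "A:T>C:G", "G:C>T:A",
                    "G:C>C:G")

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True, eq=False)
class MutationRecord:
    """One unique mutation; the unit of the presence/absence matrix columns.

    ``detail`` is a canonical string:

    =============== =========================================
    SNP             ``"C>T"`` (ref>alt, plus strand)
    small_indel     ``"+ACG"`` insertion / ``"-3"`` deletion
    IS_insertion    ``"IS2:+"`` (family:strand)
    large_deletion  ``"-1500"`` (deleted length)
    amplification   ``"x2:50000"`` (copy number, size)
    =============== =========================================
    """
    position: int
    category: str
    detail: str
    gene_context: str = ""
    effect: str = "not_applicable"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown mutation category {self.category!r}")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.category == "small_indel" and not 1 <= self.indel_length <= 16:
            raise ValueError(
                f"small indel length {self.indel_length} outside [1, 16]")
        if self.category == "large_deletion" and self.indel_length < 100:
            raise ValueError(
                f"large deletion length {self.indel_length} < 100 bp")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.category, self.detail)

    @property
    def mutation_id(self) -> str:
        return f"{self.category}:{self.position}:{self.detail}"

    @property
    def indel_length(self) -> int:
        if self.detail.startswith("+"):
            return len(self.detail) - 1
        if self.detail.startswith("-"):
            return int(self.detail[1:])
        raise ValueError(f"{self.detail!r} is not an indel detail")

    @property
    def is_family(self) -> Optional[str]:
        if self.category != "IS_insertion":
            return None
        return self.detail.split(":", 1)[0]

    @property
    def snp_bases(self) -> Optional[tuple[str, str]]:
        if self.category != "SNP":
            return None
        ref, alt = self.detail.split(">", 1)
        return ref, alt

    def __eq__(self, other):
        if not isinstance(other, MutationRecord):
            return NotImplemented
        return self.key == other.key

    def __hash__(self):
        return hash(self.key)


@dataclass
class CloneRecord:
    """One sequenced isolate; a row of the presence/absence matrix."""
    clone_id: str
    culture: int
    day: int
    mean_depth: float
    mutations: list[MutationRecord] = dc_field(default_factory=list)

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError(f"{self.clone_id}: mean_depth < 0")

    @property
    def mutation_ids(self) -> frozenset[str]:
        return frozenset(m.mutation_id for m in self.mutations)


@dataclass
class FilterReport:
    """Counts for each removal class applied by :func:`apply_qc_filters`."""
    clones_in: int = 0
    clones_removed_low_depth: int = 0
    clones_out: int = 0
    calls_in: int = 0
    calls_removed_parental: int = 0
    calls_removed_excluded_region: int = 0
    calls_out: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class QCConfig:
    min_mean_depth: float = 20.0
    #: 1-based inclusive intervals to mask (e.g. an unreliable prophage region)
    exclusion_intervals: tuple[tuple[int, int], ...] = ()
    parental_positions: tuple[int, ...] = PARENTAL_VARIANT_POSITIONS


@dataclass
class MutationCatalog:
    """Unique mutations, the boolean matrix, and per-category tallies."""
    records: list[MutationRecord]
    matrix: pd.DataFrame  # bool; index clone_id, columns mutation_id
    category_counts: dict

    @property
    def by_id(self) -> dict[str, MutationRecord]:
        return {r.mutation_id: r for r in self.records}

    def mutation_sets(self) -> dict[str, frozenset[str]]:
        """clone_id -> set of mutation ids, reconstructed from the matrix."""
        out = {}
        cols = np.asarray(self.matrix.columns)
        values = self.matrix.to_numpy(dtype=bool)
        for i, clone_id in enumerate(self.matrix.index):
            out[clone_id] = frozenset(cols[values[i]])
        return out


@dataclass
class SpectrumCounts:
    """Counts for the six strand-collapsed substitution classes."""
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in SPECTRUM_CLASSES])


# ---------------------------------------------------------------------------
# readers

def read_clone_table(source) -> list[CloneRecord]:
    """Read clone metadata TSV (clone_id, culture, day, mean_depth)."""
    df = pd.read_csv(source, sep="\t", dtype={"clone_id": str})
    required = {"clone_id", "culture", "day", "mean_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clone table missing columns: {sorted(missing)}")
    if df["clone_id"].duplicated().any():
        dups = df.loc[df["clone_id"].duplicated(), "clone_id"].tolist()
        raise ValueError(f"duplicate clone_id(s): {dups}")
    try:
        days = df["day"].astype(int)
        cultures = df["culture"].astype(int)
        depths = df["mean_depth"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric clone table field: {exc}") from exc
    return [CloneRecord(clone_id=row.clone_id, culture=c, day=d, mean_depth=md)
            for row, c, d, md in zip(df.itertuples(), cultures, days, depths)]


def write_clone_table(clones: Sequence[CloneRecord], target) -> None:
    df = pd.DataFrame(
        {"clone_id": [c.clone_id for c in clones],
         "culture": [c.culture for c in clones],
         "day": [c.day for c in clones],
         "mean_depth": [c.mean_depth for c in clones]})
    df.to_csv(target, sep="\t", index=False)


_MUTATION_TSV_COLS = ("clone_id", "position", "category", "detail",
                      "gene_context", "effect")


def read_mutation_table(source) -> dict[str, list[MutationRecord]]:
    """Read a flat per-clone mutation TSV (pre-annotated path).

    Columns: clone_id, position, category, detail and optionally
    gene_context, effect.  Effects given in the table are accepted verbatim.
    """
    df = pd.read_csv(source, sep="\t", dtype={"clone_id": str},
                     keep_default_na=False)
    missing = {"clone_id", "position", "category", "detail"} - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    out: dict[str, list[MutationRecord]] = {}
    for row in df.itertuples():
        rec = MutationRecord(
            position=int(row.position), category=row.category,
            detail=row.detail,
            gene_context=getattr(row, "gene_context", ""),
            effect=getattr(row, "effect", "not_applicable") or "not_applicable")
        out.setdefault(row.clone_id, []).append(rec)
    return out


def write_mutation_table(calls: dict[str, list[MutationRecord]], target) -> None:
    rows = []
    for clone_id in calls:
        for m in calls[clone_id]:
            rows.append((clone_id, m.position, m.category, m.detail,
                         m.gene_context, m.effect))
    pd.DataFrame(rows, columns=_MUTATION_TSV_COLS).to_csv(
        target, sep="\t", index=False)


def load_gd_directory(directory, clones: Sequence[CloneRecord],
                      reference: ReferenceModel) -> list[CloneRecord]:
    """Attach annotated mutations from ``<clone_id>.gd`` files to clones."""
    directory = Path(directory)
    out = []
    for clone in clones:
        path = directory / f"{clone.clone_id}.gd"
        entries = read_genomediff(path)
        muts = [annotate_mutation(e, reference) for e in entries]
        out.append(CloneRecord(clone.clone_id, clone.culture, clone.day,
                               clone.mean_depth, muts))
    return out


# ---------------------------------------------------------------------------
# annotation

def _coding_effect_for_indel(length: int) -> str:
    return "frameshift" if length % 3 != 0 else "disruption"


def annotate_mutation(entry: RawEntry, reference: ReferenceModel) -> MutationRecord:
    """Turn a raw GenomeDiff entry into an annotated catalog record.

    Gene context is the containing coding gene's name, or the
    ``"left/right"`` flank pair for intergenic positions.  SNP effects are
    computed from the genetic code when the reference carries a sequence
    (``ref_seq=`` extras provide the reference base otherwise).
    """
    pos = entry.position
    reference._check_position(pos)
    gene = reference.gene_at(pos)
    context = gene.name if gene is not None else reference.intergenic_context(pos)

    if entry.type == "SNP":
        alt = entry.fields["new_seq"].upper()
        if reference.sequence is not None:
            ref_base = reference.sequence[pos - 1]
        else:
            ref_base = entry.extra.get("ref_seq", "N").upper()
        detail = f"{ref_base}>{alt}"
        if gene is None:
            effect = "intergenic"
        else:
            codons = reference.codon_for_snp(pos, alt)
            if codons is None:
                effect = entry.extra.get("effect", "not_applicable")
            else:
                effect = classify_substitution_effect(*codons)
                stated = entry.extra.get("effect")
                if stated and stated != effect:
                    logger.warning(
                        "effect conflict at %d: stated %s, computed %s",
                        pos, stated, effect)
        return MutationRecord(pos, "SNP", detail, context, effect)

    if entry.type == "INS":
        seq = entry.fields["new_seq"].upper()
        effect = ("intergenic" if gene is None
                  else _coding_effect_for_indel(len(seq)))
        return MutationRecord(pos, "small_indel", f"+{seq}", context, effect)

    if entry.type == "DEL":
        size = int(entry.fields["size"])
        if size < 100:
            effect = ("intergenic" if gene is None
                      else _coding_effect_for_indel(size))
            return MutationRecord(pos, "small_indel", f"-{size}", context,
                                  effect)
        overlaps = bool(reference._tree.overlap(pos, pos + size))
        return MutationRecord(pos, "large_deletion", f"-{size}", context,
                              "disruption" if overlaps else "intergenic")

    if entry.type == "MOB":
        strand = "+" if int(entry.fields["strand"]) >= 0 else "-"
        detail = f"{entry.fields['repeat_name']}:{strand}"
        effect = "disruption" if gene is not None else "intergenic"
        return MutationRecord(pos, "IS_insertion", detail, context, effect)

    if entry.type == "AMP":
        detail = f"x{entry.fields['new_copy_number']}:{entry.fields['size']}"
        return MutationRecord(pos, "amplification", detail, context,
                              "not_applicable")

    raise ValueError(f"cannot annotate GD entry type {entry.type!r}")


# ---------------------------------------------------------------------------
# QC filters

def _in_intervals(pos: int, intervals) -> bool:
    return any(lo <= pos <= hi for lo, hi in intervals)


def apply_qc_filters(clones: Sequence[CloneRecord],
                     config: Optional[QCConfig] = None
                     ) -> tuple[list[CloneRecord], FilterReport]:
    """Depth cutoff, parental-variant masking and region exclusion.

    Clones whose mean read depth is below ``min_mean_depth`` are dropped
    entirely; mutations at parental-variant positions or inside exclusion
    intervals (1-based, inclusive ends) are removed from every clone.
    Filters may legitimately remove everything; the report says what went.
    """
    config = config or QCConfig()
    report = FilterReport(clones_in=len(clones),
                          calls_in=sum(len(c.mutations) for c in clones))
    parental = set(config.parental_positions)
    kept: list[CloneRecord] = []
    for clone in clones:
        if clone.mean_depth < config.min_mean_depth:
            report.clones_removed_low_depth += 1
            continue
        retained = []
        for m in clone.mutations:
            if m.position in parental:
                report.calls_removed_parental += 1
            elif _in_intervals(m.position, config.exclusion_intervals):
                report.calls_removed_excluded_region += 1
            else:
                retained.append(m)
        kept.append(CloneRecord(clone.clone_id, clone.culture, clone.day,
                                clone.mean_depth, retained))
    report.clones_out = len(kept)
    report.calls_out = sum(len(c.mutations) for c in kept)
    return kept, report


# ---------------------------------------------------------------------------
# catalog construction

def build_catalog(clones: Sequence[CloneRecord]) -> MutationCatalog:
    """Deduplicate mutations across clones and build the boolean matrix.

    Identity is (position, category, detail); annotation fields are taken
    from the first occurrence (conflicting annotations are logged).
    """
    unique: dict[tuple, MutationRecord] = {}
    for clone in clones:
        for m in clone.mutations:
            prev = unique.get(m.key)
            if prev is None:
                unique[m.key] = m
            elif (prev.gene_context, prev.effect) != (m.gene_context, m.effect) \
                    and m.gene_context:
                logger.warning("conflicting annotation for %s: %r vs %r",
                               m.mutation_id, (prev.gene_context, prev.effect),
                               (m.gene_context, m.effect))
    records = sorted(unique.values(), key=lambda r: r.key)
    ids = [r.mutation_id for r in records]
    col_index = {mid: j for j, mid in enumerate(ids)}
    data = np.zeros((len(clones), len(ids)), dtype=bool)
    for i, clone in enumerate(clones):
        for m in clone.mutations:
            data[i, col_index[m.mutation_id]] = True
    matrix = pd.DataFrame(data, index=[c.clone_id for c in clones], columns=ids)
    matrix.index.name = "clone_id"
    return MutationCatalog(records=records, matrix=matrix,
                           category_counts=_category_counts(records))


def _category_counts(records: Iterable[MutationRecord]) -> dict:
    counts = {"total": 0, "by_category": {c: 0 for c in CATEGORIES},
              "snp_effects": {}, "is_families": {}}
    for r in records:
        counts["total"] += 1
        counts["by_category"][r.category] += 1
        if r.category == "SNP":
            counts["snp_effects"][r.effect] = \
                counts["snp_effects"].get(r.effect, 0) + 1
        elif r.category == "IS_insertion":
            fam = r.is_family
            counts["is_families"][fam] = counts["is_families"].get(fam, 0) + 1
    return counts


def write_catalog_tsv(catalog: MutationCatalog, target) -> None:
    rows = [(r.mutation_id, r.position, r.category, r.detail, r.gene_context,
             r.effect, int(catalog.matrix[r.mutation_id].sum()))
            for r in catalog.records]
    pd.DataFrame(rows, columns=["mutation_id", "position", "category",
                                "detail", "gene_context", "effect",
                                "n_clones"]).to_csv(target, sep="\t",
                                                    index=False)


def write_matrix_tsv(matrix: pd.DataFrame, target) -> None:
    matrix.astype(int).to_csv(target, sep="\t")


def read_matrix_tsv(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", index_col=0)
    return df.astype(bool)


# ---------------------------------------------------------------------------
# substitution spectrum

def classify_substitution_class(ref: str, alt: str) -> str:
    """Map a base substitution to its strand-collapsed class.

    C>T and G>A both collapse to G:C>A:T, and so on; the representative is
    chosen by complementing pyrimidine reference bases to purines.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMP or alt not in _COMP:
        raise ValueError(f"invalid substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref}); not a substitution")
    if ref in "CT":
        ref, alt = _COMP[ref], _COMP[alt]
    return {"G": {"A": "G:C>A:T", "T": "G:C>T:A", "C": "G:C>C:G"},
            "A": {"G": "A:T>G:C", "T": "A:T>T:A", "C": "A:T>C:G"}}[ref][alt]


def substitution_spectrum(catalog: Union[MutationCatalog,
                                         Iterable[MutationRecord]]
                          ) -> SpectrumCounts:
    """Count SNPs in the catalog by strand-collapsed substitution class."""
    records = catalog.records if isinstance(catalog, MutationCatalog) else catalog
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for r in records:
        if r.category != "SNP":
            continue
        ref, alt = r.snp_bases
        counts[classify_substitution_class(ref, alt)] += 1
    return SpectrumCounts(counts)


# ---------------------------------------------------------------------------
# coverage-based amplification calls

@dataclass
class CoverageTrack:
    """Windowed read depth tiling [1, genome_length]."""
    depths: np.ndarray  # one value per window
    window_bp: int
    genome_length: int

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise ValueError("coverage depths must be >= 0")
        expect = -(-self.genome_length // self.window_bp)  # ceil division
        if len(self.depths) != expect:
            raise ValueError(
                f"{len(self.depths)} windows of {self.window_bp} bp do not "
                f"tile a {self.genome_length} bp genome (need {expect})")

    @classmethod
    def from_tsv(cls, source, genome_length: int) -> "CoverageTrack":
        df = pd.read_csv(source, sep="\t")
        if not {"window_start", "depth"} <= set(df.columns):
            raise ValueError("coverage TSV needs columns window_start, depth")
        starts = df["window_start"].to_numpy()
        window_bp = int(starts[1] - starts[0]) if len(starts) > 1 else genome_length
        return cls(df["depth"].to_numpy(), window_bp, genome_length)


@dataclass(frozen=True)
class AmplificationCall:
    start: int
    end: int
    fold_change: float


def detect_amplifications(track: CoverageTrack, min_ratio: float = 2.0,
                          min_span_bp: int = 45_000) -> list[AmplificationCall]:
    """Call amplified regions from median-normalised windowed depth.

    A call is a maximal run of consecutive windows whose depth divided by
    the genome-median window depth is at least ``min_ratio`` and whose
    spanned length is at least ``min_span_bp``; the reported fold change is
    the mean windowed ratio over the run.  This formalises the visual
    "elevated coverage" procedure used for clone resequencing panels.
    """
    median = float(np.median(track.depths))
    if median <= 0:
        raise ValueError("median window depth is zero; ratios undefined")
    ratio = track.depths / median
    above = ratio >= min_ratio
    calls = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        start = i * track.window_bp + 1
        end = min((j + 1) * track.window_bp, track.genome_length)
        if end - start + 1 >= min_span_bp:
            calls.append(AmplificationCall(start, end,
                                           float(ratio[i : j + 1].mean())))
        i = j + 1
    return calls
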