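"""Reference genome model: gene intervals, coding fraction, codon lookup.

Coordinates are 1-based with inclusive interval ends throughout the package
(the GenomeDiff convention).
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .codons import reverse_complement


@dataclass(frozen=True)
class Gene:
    name: str
    start: int  # 1-based, inclusive
    end: int    # inclusive
    strand: str = "+"
    is_coding: bool = True

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad gene interval {self.name}: [{self.start}, {self.end}]")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for gene {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ReferenceModel:
    """Gene annotation plus (optionally) the genome sequence.

    Parameters
    ----------
    genome_length : int
        Total genome size in bp.
    genes : iterable of Gene
        Gene intervals; may overlap.
    sequence : str, optional
        The genome sequence; enables codon extraction for SNP effect calls.
    """

    def __init__(self, genome_length: int, genes: Iterable[Gene],
                 sequence: Optional[str] = None):
        self.genome_length = int(genome_length)
        self.genes = sorted(genes, key=lambda g: (g.start, g.end, g.name))
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        for g in self.genes:
            if g.end > self.genome_length:
                raise ValueError(
                    f"gene {g.name} [{g.start}, {g.end}] exceeds genome length "
                    f"{self.genome_length}")
        if sequence is not None:
            sequence = sequence.upper()
            if len(sequence) != self.genome_length:
                raise ValueError(
                    f"sequence length {len(sequence)} != genome_length {self.genome_length}")
        self.sequence = sequence
        # interval tree over coding genes; +1 on end because IntervalTree is half-open
        self._tree = IntervalTree()
        for g in self.genes:
            if g.is_coding:
                self._tree[g.start : g.end + 1] = g
        self._starts = [g.start for g in self.genes]
        self.coding_fraction = self._union_coding_length() / self.genome_length

    def _union_coding_length(self) -> int:
        merged = IntervalTree(self._tree)
        merged.merge_overlaps(strict=False)
        return sum(iv.end - iv.begin for iv in merged)

    # -- queries ---------------------------------------------------------

    def gene_at(self, position: int) -> Optional[Gene]:
        """The coding gene containing *position*, or None (leftmost wins on overlap)."""
        self._check_position(position)
        hits = sorted(self._tree[position], key=lambda iv: (iv.begin, iv.data.name))
        return hits[0].data if hits else None

    def flanking_genes(self, position: int) -> tuple[str, str]:
        """Names of the nearest genes left/right of an intergenic position.

        "." stands in when the position lies before the first or after the
        last annotated gene.
        """
        self._check_position(position)
        left = "."
        right = "."
        idx = bisect.bisect_right(self._starts, position)
        for g in reversed(self.genes[:idx]):
            if g.end < position:
                left = g.name
                break
        for g in self.genes[idx:]:
            if g.start > position:
                right = g.name
                break
        return left, right

    def intergenic_context(self, position: int) -> str:
        left, right = self.flanking_genes(position)
        return f"{left}/{right}"

    def codon_for_snp(self, position: int, alt_base: str) -> Optional[tuple[str, str]]:
        """(ref_codon, alt_codon) for a SNP inside a coding gene.

        Returns None when no sequence is loaded, the position is intergenic,
        or it falls in a trailing partial codon of a gene whose length is not
        a multiple of three.  Codons are given in the gene's reading frame
        (reverse-complemented for minus-strand genes); *alt_base* is on the
        reference (plus) strand.
        """
        if self.sequence is None:
            return None
        gene = self.gene_at(position)
        if gene is None:
            return None
        alt_base = alt_base.upper()
        if gene.strand == "+":
            offset = position - gene.start
            codon_start = gene.start + 3 * (offset // 3)
            if codon_start + 2 > gene.end:
                return None
            codon = self.sequence[codon_start - 1 : codon_start + 2]
            within = offset % 3
            alt = codon[:within] + alt_base + codon[within + 1 :]
            return codon, alt
        offset = gene.end - position
        codon_end = gene.end - 3 * (offset // 3)
        if codon_end - 2 < gene.start:
            return None
        fwd = self.sequence[codon_end - 3 : codon_end]
        codon = reverse_complement(fwd)
        within = offset % 3
        alt_rc = reverse_complement(alt_base)
        alt = codon[:within] + alt_rc + codon[within + 1 :]
        return codon, alt

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.genome_length:
            raise ValueError(
                f"position {position} outside genome [1, {self.genome_length}]")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_gff3(cls, path, genome_length: Optional[int] = None,
                  fasta: Optional[str] = None) -> "ReferenceModel":
        """Load gene/CDS features from a GFF3 file (subset: columns only).

        Feature name resolution order: Name=, gene=, locus_tag=, ID=.
        *fasta*, if given, is a path to the genome FASTA; its sequence also
        fixes the genome length.
        """
        sequence = None
        if fasta is not None:
            from Bio import SeqIO
            record = next(SeqIO.parse(str(fasta), "fasta"))
            sequence = str(record.seq).upper()
            genome_length = len(sequence)
        genes = []
        declared_length = None
        for line in Path(path).read_text().splitlines():
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    declared_length = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                continue
            ftype = cols[2]
            if ftype not in {"gene", "CDS"}:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            name = (attrs.get("Name") or attrs.get("gene")
                    or attrs.get("locus_tag") or attrs.get("ID") or "unnamed")
            genes.append(Gene(name=name, start=int(cols[3]), end=int(cols[4]),
                              strand=cols[6] if cols[6] in "+-" else "+",
                              is_coding=True))
        # gene + CDS for the same locus: keep one interval per (name, start, end)
        genes = sorted(set(genes), key=lambda g: (g.start, g.end, g.name))
        if genome_length is None:
            genome_length = declared_length or (max(g.end for g in genes) if genes else 1)
        return cls(genome_length, genes, sequence=sequence)

    @classmethod
    def synthetic(cls, genome_length: int = 4_541_111, n_genes: int = 4_295,
                  coding_fraction: float = 0.90) -> "ReferenceModel":
        """Evenly spaced synthetic annotation with a target coding fraction.

        Used by the simulator: *n_genes* equal-length genes tile the genome
        so that the realised coding fraction is within ~0.1% of the target.
        """
        period = genome_length / n_genes
        gene_len = max(3, round(coding_fraction * period))
        genes = []
        for i in range(n_genes):
            start = int(i * period) + 1
            end = min(start + gene_len - 1, genome_length)
            strand = "+" if i % 2 == 0 else "-"
            genes.append(Gene(name=f"gene{i + 1:04d}", start=start, end=end,
                              strand=strand))
        return cls(genome_length, genes)
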