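"""Genetic-code utilities shared by the mutation annotator and the selection
statistics.

The bacterial/archaeal code (NCBI translation table 11) is used throughout;
for the codons handled here it is identical to the standard code.
"""
from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _build_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[11]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


#: codon -> one-letter amino acid, stops as "*"
GENETIC_CODE: dict[str, str] = _build_code()

#: the 61 sense codons
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_codon(codon: str) -> str:
    """Return the codon upper-cased, or raise ``ValueError``."""
    if not isinstance(codon, str):
        raise ValueError(f"codon must be a string, got {type(codon).__name__}")
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not a valid DNA codon: {codon!r}")
    return codon


def translate(codon: str) -> str:
    return GENETIC_CODE[validate_codon(codon)]


def is_stop(codon: str) -> bool:
    return translate(codon) == "*"


def is_transition(a: str, b: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine changes."""
    return (a in PURINES) == (b in PURINES) and a != b


def classify_substitution_effect(ref_codon: str, alt_codon: str) -> str:
    """Classify a codon substitution as synonymous / nonsynonymous / nonsense.

    The reference codon must be a sense codon.  A change to a stop codon is
    "nonsense"; an amino-acid-preserving change is "synonymous"; every other
    change (including no change at all) falls back to the amino-acid
    comparison.
    """
    ref_codon = validate_codon(ref_codon)
    alt_codon = validate_codon(alt_codon)
    ref_aa = GENETIC_CODE[ref_codon]
    if ref_aa == "*":
        raise ValueError(f"reference codon {ref_codon} is a stop codon")
    alt_aa = GENETIC_CODE[alt_codon]
    if alt_aa == "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def codon_neighbors(codon: str):
    """Yield the nine single-nucleotide neighbours of a codon."""
    codon = validate_codon(codon)
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                yield codon[:pos] + base + codon[pos + 1 :]


def site_degeneracy(codon: str, pos: int) -> int:
    """Degeneracy class (0, 2 or 4) of one codon position.

    Counted from the number of synonymous changes among the three possible
    substitutions at that site: none -> 0-fold, all three -> 4-fold,
    otherwise 2-fold.  Changes to stop codons count as nonsynonymous.
    """
    codon = validate_codon(codon)
    aa = GENETIC_CODE[codon]
    syn = 0
    for base in BASES:
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if GENETIC_CODE[alt] == aa:
            syn += 1
    if syn == 0:
        return 0
    if syn == 3:
        return 4
    return 2
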