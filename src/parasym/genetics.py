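"""Standard genetic code tables shared by the counting, likelihood and
simulation machinery.

Codons are indexed 0..60 over the 61 sense codons of the standard code,
in lexicographic (A<C<G<T) order. Index -1 marks a masked codon column
(gap, ambiguity or stop).
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_standard.stop_codons)

#: the 61 sense codons, lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)
N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid (one-letter) per sense codon index
CODON_AA: tuple[str, ...] = tuple(_standard.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a->b is a transition (A<->G, C<->T)."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _build_pair_structure():
    """For every ordered sense-codon pair differing at exactly one position:
    which position, whether the change is a transition, and whether it is
    synonymous."""
    single = np.full((N_CODONS, N_CODONS), False)
    transition = np.full((N_CODONS, N_CODONS), False)
    synonymous = np.full((N_CODONS, N_CODONS), False)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            single[i, j] = True
            transition[i, j] = is_transition(ci[k], cj[k])
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return single, transition, synonymous


SINGLE_STEP, IS_TRANSITION, IS_SYNONYMOUS = _build_pair_structure()


def codon_to_index(codon: str) -> int:
    """Sense-codon index, or -1 for gap/ambiguous/stop codons."""
    return CODON_INDEX.get(codon.upper(), -1)


def encode_codon_sequence(seq: str) -> np.ndarray:
    """Encode an aligned nucleotide string into per-column codon indices
    (-1 where the codon is not a clean sense codon)."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    return np.array(
        [codon_to_index(seq[i : i + 3]) for i in range(0, len(seq), 3)],
        dtype=np.int64,
    )
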