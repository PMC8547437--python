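"""Codon-table and amino-acid chemistry constants shared across modules.

Everything here derives from the standard bacterial genetic code
(NCBI translation table 11) and textbook amino-acid molecular formulas.
Side-chain atom counts are the residue formula minus the glycine backbone
(2 C, 1 N): e.g. arginine C6H14N4O2 has a C4N3 side chain.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

NUCLEOTIDES = "ACGT"

#: transition partner of each nucleotide (A<->G, C<->T)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

STOP_CODONS = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in fixed lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in (a + b + d for a in NUCLEOTIDES for b in NUCLEOTIDES for d in NUCLEOTIDES)
           if c not in STOP_CODONS)
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: side-chain nitrogen atoms per residue
N_SIDECHAIN = {
    "A": 0, "C": 0, "D": 0, "E": 0, "F": 0, "G": 0, "H": 2, "I": 0, "K": 1,
    "L": 0, "M": 0, "N": 1, "P": 0, "Q": 1, "R": 3, "S": 0, "T": 0, "V": 0,
    "W": 1, "Y": 0,
}

#: side-chain carbon atoms per residue
C_SIDECHAIN = {
    "A": 1, "C": 1, "D": 2, "E": 3, "F": 7, "G": 0, "H": 4, "I": 4, "K": 4,
    "L": 4, "M": 3, "N": 2, "P": 3, "Q": 3, "R": 4, "S": 1, "T": 2, "V": 3,
    "W": 9, "Y": 7,
}

#: per-codon GC base count, side-chain N and C of the encoded residue
CODON_GC = np.array([sum(ch in "GC" for ch in c) for c in SENSE_CODONS], dtype=float)
CODON_N = np.array([N_SIDECHAIN[a] for a in CODON_AA], dtype=float)
CODON_C = np.array([C_SIDECHAIN[a] for a in CODON_AA], dtype=float)


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (no internal stops); a terminal stop is stripped."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa = []
    n = len(cds) // 3
    for i in range(n):
        codon = cds[3 * i: 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon {i}")
        aa.append(_TABLE.forward_table[codon])
    return "".join(aa)


def _neighbor_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per sense codon, its 9 single-nucleotide neighbours.

    Returns (dest, weight_is_ts, is_syn) arrays of shape (61, 9); dest is the
    sense-codon index or -1 for a stop.  Neighbour j = position j//3,
    alternative nucleotide j%3 (alternatives in NUCLEOTIDES order, skipping
    the current base).
    """
    dest = np.full((61, 9), -1, dtype=np.int64)
    is_ts = np.zeros((61, 9), dtype=bool)
    is_syn = np.zeros((61, 9), dtype=bool)
    for ci, codon in enumerate(SENSE_CODONS):
        j = 0
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                is_ts[ci, j] = TRANSITION[codon[pos]] == nt
                if alt not in STOP_CODONS:
                    dest[ci, j] = CODON_INDEX[alt]
                    is_syn[ci, j] = _TABLE.forward_table[alt] == CODON_AA[ci]
                j += 1
    return dest, is_ts, is_syn


NEIGHBOR_DEST, NEIGHBOR_IS_TS, NEIGHBOR_IS_SYN = _neighbor_tables()
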