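"""Internal alignment primitives shared by features, divergence, recruitment.

Proteins are aligned globally with Bio.Align.PairwiseAligner: BLOSUM62 with
BLAST-style gap costs for homology search (RBH), or the simple +1/-1/-2
scheme used by the CD-HIT-style clusterer.  DNA fragments and reads are
located by exact k-mer seeding and refined with edlib's banded bit-vector
alignment — adequate at desk scale and exact on the substitution-only
synthetic data; production-scale read recruitment enters the pipeline as
pre-computed BLAST tabular files instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices


def _blosum_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    return al


def _simple_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -2.0
    al.extend_gap_score = -2.0
    al.mode = "global"
    return al


_BLOSUM = _blosum_aligner()
_SIMPLE = _simple_aligner()


@dataclass(frozen=True)
class PairwiseResult:
    score: float
    identity_percent: float   # matches / alignment columns * 100
    n_matches: int
    n_columns: int
    aligned_a: str
    aligned_b: str
    coverage_shorter: float   # aligned (non-gap-pair) columns / len(shorter)


def _result_from(alignment, a: str, b: str) -> PairwiseResult:
    sa, sb = alignment[0], alignment[1]
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    aligned_cols = sum(1 for x, y in zip(sa, sb) if x != "-" and y != "-")
    n_cols = len(sa)
    return PairwiseResult(
        score=float(alignment.score),
        identity_percent=100.0 * matches / n_cols if n_cols else 0.0,
        n_matches=matches,
        n_columns=n_cols,
        aligned_a=str(sa),
        aligned_b=str(sb),
        coverage_shorter=aligned_cols / min(len(a), len(b)) if a and b else 0.0,
    )


def align_proteins(a: str, b: str, scoring: str = "blosum62") -> PairwiseResult:
    """Global protein alignment; scoring 'blosum62' (gap -11/-1) or 'simple' (+1/-1/-2)."""
    if not a or not b:
        raise ValueError("empty protein sequence")
    aligner = _BLOSUM if scoring == "blosum62" else _SIMPLE
    aln = aligner.align(a.replace("*", ""), b.replace("*", ""))[0]
    return _result_from(aln, a, b)


# ---------------------------------------------------------------------------
# k-mer candidate search over a set of protein sequences

class KmerCandidateIndex:
    """Shared-k-mer prefilter: BLAST-like word seeding over a proteome."""

    def __init__(self, sequences: dict[str, str], k: int = 5):
        self.k = k
        self.sequences = sequences
        self._index: dict[str, set[str]] = {}
        for sid, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i:i + k], set()).add(sid)

    def candidates(self, query: str, max_candidates: int = 20) -> list[str]:
        """Subject ids sharing >=1 k-mer, ordered by shared-k-mer count."""
        counts: Counter[str] = Counter()
        k = self.k
        for i in range(len(query) - k + 1):
            for sid in self._index.get(query[i:i + k], ()):
                counts[sid] += 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [sid for sid, _ in ranked[:max_candidates]]


# ---------------------------------------------------------------------------
# DNA seeding + edlib refinement

class DnaSeedIndex:
    """Exact k-mer index over one DNA sequence (forward strand)."""

    def __init__(self, sequence: str, k: int = 15):
        self.k = k
        self.sequence = sequence
        self._index: dict[str, list[int]] = {}
        for i in range(len(sequence) - k + 1):
            self._index.setdefault(sequence[i:i + k], []).append(i)

    def seed_diagonal(self, query: str, stride: int | None = None) -> int | None:
        """Most-supported diagonal (target_pos - query_pos), or None."""
        k = self.k
        stride = stride or max(1, k // 2)
        diags: Counter[int] = Counter()
        positions = list(range(0, max(1, len(query) - k + 1), stride))
        for qp in positions:
            for tp in self._index.get(query[qp:qp + k], ()):
                diags[tp - qp] += 1
        if not diags:
            # fall back to every query k-mer before giving up
            for qp in range(len(query) - k + 1):
                for tp in self._index.get(query[qp:qp + k], ()):
                    diags[tp - qp] += 1
        if not diags:
            return None
        return max(diags.items(), key=lambda kv: (kv[1], -abs(kv[0])))[0]


@dataclass(frozen=True)
class DnaHit:
    identity_percent: float
    n_matches: int
    alignment_length: int
    target_start: int   # 1-based inclusive
    target_end: int
    score: float


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, alignment_columns) from an edlib extended cigar."""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return matches, cols


def align_dna_to_window(query: str, index: DnaSeedIndex, pad: int = 30) -> DnaHit | None:
    """Locate ``query`` in the indexed sequence and align it within a window.

    Seeding finds the best diagonal; edlib then aligns the query in infix
    mode against target[diag-pad : diag+len(query)+pad].  Returns None when
    no seed exists (treated as "no alignment", not identity 0).
    """
    diag = index.seed_diagonal(query)
    if diag is None:
        return None
    target = index.sequence
    lo = max(0, diag - pad)
    hi = min(len(target), diag + len(query) + pad)
    res = edlib.align(query, target[lo:hi], mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    matches, cols = _cigar_stats(res["cigar"])
    t0, t1 = res["locations"][0]
    score = 2.0 * matches - 3.0 * (cols - matches)
    return DnaHit(
        identity_percent=100.0 * matches / cols if cols else 0.0,
        n_matches=matches,
        alignment_length=cols,
        target_start=lo + t0 + 1,
        target_end=lo + t1 + 1,
        score=score,
    )
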