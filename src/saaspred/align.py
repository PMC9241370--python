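"""Global pairwise alignment (Needleman–Wunsch with affine gaps).

Used by the pseudoneutral simulator's homolog filtering / deduplication and
by the annotation-transfer best-hit step.  The traceback tie-break is fixed
(diagonal > up > left) so alignments are deterministic; a length-k gap costs
``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from Bio.Align import substitution_matrices

from .records import GAP, SaasError

_NEG_INF = float("-inf")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus affine gap penalties.

    Either a named substitution matrix (default BLOSUM62) or a simple
    match/mismatch pair may be used.
    """

    matrix_name: Optional[str] = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def substitution(self, a: str, b: str) -> float:
        if self.matrix_name is None:
            return self.match if a == b else self.mismatch
        mat = (_BLOSUM62 if self.matrix_name == "BLOSUM62"
               else substitution_matrices.load(self.matrix_name))
        return float(mat[a, b])


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise SaasError("aligned strings differ in length")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace(GAP, "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace(GAP, "")

    def map_a_to_b(self, pos_a: int) -> Optional[int]:
        """Map a 1-based position in seq_a to the corresponding 1-based
        position in seq_b; ``None`` if it sits opposite a gap."""
        ia = ib = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != GAP:
                ia += 1
            if cb != GAP:
                ib += 1
            if ia == pos_a and ca != GAP:
                return ib if cb != GAP else None
        raise SaasError(f"position {pos_a} beyond sequence length {ia}")


def needleman_wunsch(seq_a: str, seq_b: str,
                     scoring: ScoringScheme = DEFAULT_SCORING) -> Alignment:
    """Optimal global alignment of two protein sequences.

    Three-state affine-gap dynamic programme (match, gap-in-b, gap-in-a);
    ties resolved diagonal-first, then up (gap in b), then left.
    """
    if not seq_a or not seq_b:
        raise SaasError("cannot align an empty sequence")
    n, m = len(seq_a), len(seq_b)
    go, ge = scoring.gap_open, scoring.gap_extend

    sub: Dict[Tuple[str, str], float] = {}
    for ca in set(seq_a):
        for cb in set(seq_b):
            sub[(ca, cb)] = scoring.substitution(ca, cb)

    # state matrices: 0 = M (diagonal), 1 = Ix (up, gap in b), 2 = Iy (left)
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Iy = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    ptr: Dict[Tuple[int, int, int], int] = {}  # (i, j, state) -> prev state

    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = go + (i - 1) * ge
        ptr[(i, 0, 1)] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0][j] = go + (j - 1) * ge
        ptr[(0, j, 2)] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        row_m, row_x, row_y = M[i], Ix[i], Iy[i]
        pm, px, py = M[i - 1], Ix[i - 1], Iy[i - 1]
        ca = seq_a[i - 1]
        for j in range(1, m + 1):
            s = sub[(ca, seq_b[j - 1])]
            # M: consume both
            cands = (pm[j - 1], px[j - 1], py[j - 1])
            best = max(cands)
            if best > _NEG_INF:
                row_m[j] = best + s
                ptr[(i, j, 0)] = cands.index(best)
            # Ix: consume a (gap in b)
            cands = (pm[j] + go, px[j] + ge, py[j] + go)
            best = max(cands)
            if best > _NEG_INF:
                row_x[j] = best
                ptr[(i, j, 1)] = cands.index(best)
            # Iy: consume b (gap in a)
            cands = (row_m[j - 1] + go, row_x[j - 1] + go, row_y[j - 1] + ge)
            best = max(cands)
            if best > _NEG_INF:
                row_y[j] = best
                ptr[(i, j, 2)] = cands.index(best)

    finals = (M[n][m], Ix[n][m], Iy[n][m])
    score = max(finals)
    state = finals.index(score)

    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[(i, j, state)]
        if state == 0:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(seq_a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(seq_b[j - 1])
            j -= 1
        state = prev

    return Alignment(aligned_a="".join(reversed(out_a)),
                     aligned_b="".join(reversed(out_b)),
                     score=score)


def percent_identity(alignment: Alignment) -> float:
    """Fraction of identical columns over the full alignment length.

    Gapped columns count in the denominator, so the reproducible meaning of
    an identity threshold (e.g. >= 0.95) includes coverage.
    """
    total = len(alignment.aligned_a)
    if total == 0:
        raise SaasError("zero-length alignment")
    same = sum(ca == cb and ca != GAP
               for ca, cb in zip(alignment.aligned_a, alignment.aligned_b))
    return same / total


def global_identity(seq_a: str, seq_b: str,
                    scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Convenience: align then compute percent identity."""
    return percent_identity(needleman_wunsch(seq_a, seq_b, scoring))
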