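"""Sequence-evolutionary features: PSSM_FROM, PSSM_TO, PSSM_CHANGE, SFM,
CON_SCORE.

PSSM scores come either from a PSI-BLAST ASCII matrix or from an internal
profile built from an alignment.  SFM is the frequency of the mutant residue
among aligned residues at the substitution's column.  CON_SCORE is the
Shannon entropy (bits) of the column's residue frequencies: despite the
name, larger values mean a *more variable* column — the formula is kept as
the field uses it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Optional

from ..records import AMINO_ACIDS, AA_SET, Msa, Pssm, SaasError, SaasRecord

EVO_FEATURE_NAMES = ("PSSM_FROM", "PSSM_TO", "PSSM_CHANGE", "SFM", "CON_SCORE")

#: floor applied to log-odds of residues unseen at a column (pseudocount 0)
SCORE_FLOOR = -10.0


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts at one alignment column (gaps and X excluded)."""

    counts: Dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise SaasError("negative residue count")
        bad = set(self.counts) - AA_SET
        if bad:
            raise SaasError(f"non-standard residues in profile: {sorted(bad)}")

    @property
    def n_effective(self) -> int:
        return sum(self.counts.values())

    def frequency(self, residue: str) -> float:
        n = self.n_effective
        return self.counts.get(residue, 0) / n if n else 0.0


def pssm_features(pssm: Pssm, saas: SaasRecord) -> Dict[str, float]:
    """PSSM_FROM / PSSM_TO / PSSM_CHANGE for one substitution."""
    from_score = pssm.score(saas.position, saas.wt)
    to_score = pssm.score(saas.position, saas.mut)
    return {
        "PSSM_FROM": from_score,
        "PSSM_TO": to_score,
        "PSSM_CHANGE": abs(from_score - to_score),
    }


def msa_to_pssm(msa: Msa, pseudocount: float = 1.0,
                background: Optional[Dict[str, float]] = None,
                floor: float = SCORE_FLOOR) -> Pssm:
    """Build a log-odds profile from an alignment.

    ``score[i][a] = log2(((count_i(a) + c) / (n_i + 20 c)) / q(a))`` with a
    Laplace-style pseudocount ``c`` and background ``q`` (default uniform
    1/20).  Positions are indexed by de-gapped query position.  A zero
    estimated frequency (pseudocount 0) is floored at ``floor``.
    """
    if background is None:
        background = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}
    if abs(sum(background.values()) - 1.0) > 1e-9:
        raise SaasError("background frequencies must sum to 1")
    if pseudocount < 0:
        raise SaasError("pseudocount must be nonnegative")
    scores: Dict[int, Dict[str, float]] = {}
    for col in range(1, msa.width + 1):
        pos = msa.query_position_of_column(col)
        if pos is None:
            continue
        counts = msa.column_counts(col)
        n = sum(counts.values())
        row: Dict[str, float] = {}
        for aa in AMINO_ACIDS:
            p = (counts.get(aa, 0) + pseudocount) / (n + 20.0 * pseudocount) \
                if (n + 20.0 * pseudocount) > 0 else 0.0
            row[aa] = max(floor, math.log2(p / background[aa])) if p > 0 else floor
        scores[pos] = row
    return Pssm(scores=scores)


def substitution_frequency(msa: Msa, saas: SaasRecord,
                           count_all_nonwild: bool = False) -> float:
    """SFM: frequency of the mutant residue at the substitution's column.

    The denominator excludes gaps and ``X``.  With ``count_all_nonwild``
    every residue other than the wildtype is counted instead of the mutant
    alone.  An all-gap column yields 0 with a warning.
    """
    col = msa.column_of_query_position(saas.position)
    counts = msa.column_counts(col)
    n = sum(counts.values())
    if n == 0:
        warnings.warn(f"all-gap column {col} for {saas.substitution}; SFM = 0")
        return 0.0
    if count_all_nonwild:
        return sum(v for aa, v in counts.items() if aa != saas.wt) / n
    return counts.get(saas.mut, 0) / n


def conservation_score(profile: ColumnProfile) -> float:
    """CON_SCORE: Shannon entropy (bits) of the column residue frequencies,
    with 0 * log2(0) taken as 0."""
    n = profile.n_effective
    if n == 0:
        raise SaasError("empty column profile")
    h = 0.0
    for count in profile.counts.values():
        if count:
            p = count / n
            h -= p * math.log2(p)
    return max(h, 0.0)


def evo_feature_vector(msa: Msa, saas: SaasRecord,
                       pssm: Optional[Pssm] = None,
                       pseudocount: float = 1.0) -> Dict[str, float]:
    """All five sequence-evolutionary features for one substitution.

    ``pssm`` may be a PSI-BLAST matrix read from disk; otherwise an internal
    profile is computed from the alignment.
    """
    if pssm is None:
        pssm = msa_to_pssm(msa, pseudocount=pseudocount)
    out = pssm_features(pssm, saas)
    out["SFM"] = substitution_frequency(msa, saas)
    col = msa.column_of_query_position(saas.position)
    out["CON_SCORE"] = conservation_score(ColumnProfile(msa.column_counts(col)))
    return out
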