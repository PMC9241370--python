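"""Database-annotation distance features (SRD).

A query protein is matched to its best-scoring annotated reference protein
by global alignment; the substitution position is mapped through that
alignment; and for each of the 25 annotation types a shortest relative
distance is computed:

``RD = |pos - annotation| / length`` (0 when the position lies inside an
annotated span, distance to the nearest span endpoint otherwise), ``SRD =
min`` over that type's annotations, and ``SRD = 1`` when the type is absent
from the hit.  Six merged features take the SRD over each category's pooled
annotations; EC is a presence indicator (0 when any EC annotation exists)
and is excluded from the Function merge.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from ..align import Alignment, ScoringScheme, DEFAULT_SCORING, needleman_wunsch
from ..records import (
    ANNOTATION_CATEGORIES,
    ANNOTATION_TYPES,
    Annotation,
    ProteinRecord,
    SaasError,
)

MERGE_MEMBERS: Dict[str, Tuple[str, ...]] = {
    "FUNCTION_MERGE": tuple(k for k in ANNOTATION_CATEGORIES["Function"]
                            if k != "EC"),
    "PTM_MERGE": ANNOTATION_CATEGORIES["PTM"],
    "SUBLOC_MERGE": ANNOTATION_CATEGORIES["Subloc"],
    "FAMILY_MERGE": ANNOTATION_CATEGORIES["Family"],
    "STRUCTURE1_MERGE": ("HELIX", "STRAND"),
    "STRUCTURE2_MERGE": ("HELIX", "STRAND", "TURN"),
}

ANNOT_FEATURE_NAMES: Tuple[str, ...] = ANNOTATION_TYPES + tuple(MERGE_MEMBERS)


def best_hit(query: ProteinRecord,
             annotated_library: Sequence[ProteinRecord],
             scoring: ScoringScheme = DEFAULT_SCORING,
             ) -> Tuple[ProteinRecord, Alignment]:
    """Highest global-alignment-score library protein (ties by id sort)."""
    if not annotated_library:
        raise SaasError("empty annotated library")
    best: Optional[Tuple[float, str, ProteinRecord, Alignment]] = None
    for prot in sorted(annotated_library, key=lambda p: p.protein_id):
        aln = needleman_wunsch(query.sequence, prot.sequence, scoring)
        if best is None or aln.score > best[0]:
            best = (aln.score, prot.protein_id, prot, aln)
    assert best is not None
    return best[2], best[3]


def map_position(alignment: Alignment, query_pos: int) -> Optional[int]:
    """Hit-protein position in the column holding ``query_pos``; ``None``
    when the hit has a gap there."""
    return alignment.map_a_to_b(query_pos)


def _relative_distance(pos: int, ann: Annotation, length: int) -> float:
    if ann.end > length:
        raise SaasError(
            f"annotation {ann.type} {ann.start}..{ann.end} outside protein "
            f"of length {length}"
        )
    if ann.start <= pos <= ann.end:
        return 0.0
    return min(abs(pos - ann.start), abs(pos - ann.end)) / length


def srd_features(hit: ProteinRecord,
                 hit_pos: Optional[int]) -> Dict[str, float]:
    """All 31 annotation features against the mapped hit position.

    A missing ``hit_pos`` (substitution opposite a gap in the hit) defaults
    every feature to 1 — no reliable transfer.
    """
    if hit_pos is None:
        return {name: 1.0 for name in ANNOT_FEATURE_NAMES}
    length = len(hit)
    by_type: Dict[str, List[Annotation]] = {}
    for a in hit.annotations:
        by_type.setdefault(a.type, []).append(a)

    def srd_over(types: Sequence[str]) -> float:
        rds = [_relative_distance(hit_pos, a, length)
               for t in types for a in by_type.get(t, [])]
        return min(rds) if rds else 1.0

    out: Dict[str, float] = {}
    for t in ANNOTATION_TYPES:
        if t == "EC":
            out["EC"] = 0.0 if by_type.get("EC") else 1.0
        else:
            out[t] = srd_over([t])
    for name, members in MERGE_MEMBERS.items():
        out[name] = srd_over(members)
    return out


def annotation_feature_vector(query: ProteinRecord, position: int,
                              annotated_library: Sequence[ProteinRecord],
                              min_identity: float = 0.3,
                              scoring: ScoringScheme = DEFAULT_SCORING,
                              ) -> Dict[str, float]:
    """Best-hit search, position correction, then the 31 SRD features.

    When the best hit's identity falls below ``min_identity`` every feature
    defaults to 1 (annotation transfer judged unreliable).
    """
    from ..align import percent_identity

    hit, aln = best_hit(query, annotated_library, scoring)
    if percent_identity(aln) < min_identity:
        return {name: 1.0 for name in ANNOT_FEATURE_NAMES}
    return srd_features(hit, map_position(aln, position))
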