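"""Pseudoneutral substitution simulation from multiple sequence alignments.

Neutral-labelled substitutions are inferred from near-identical homologs: if
a residue differs between a query protein and a >= 95%-identical hit, and
the difference is isolated (the four rules below), the substitution is taken
to be tolerated in nature and labelled neutral.

Rules applied per (alignment column, hit row):

* R1 — the alignment holds at least three sequences;
* R2 — the candidate column contains exactly two distinct non-gap residues;
* R3 — within a five-column window centred on the candidate column
  (truncated at the alignment ends), exactly one column shows any
  query/hit disagreement;
* R4 — the hit differs from the query in exactly one column over their
  mutual non-gap span, with no internal gaps between them (terminal
  overhangs tolerated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .align import Alignment, ScoringScheme, DEFAULT_SCORING, needleman_wunsch, percent_identity
from .records import GAP, AA_SET, Msa, NEUTRAL, ProteinRecord, SaasRecord


@dataclass(frozen=True)
class SimulatorConfig:
    min_identity: float = 0.95
    min_rows: int = 3          # R1
    window: int = 5            # R3 window width (odd, centred)
    dedup: bool = True
    scoring: ScoringScheme = DEFAULT_SCORING


@dataclass(frozen=True)
class CandidateSaas:
    """A substitution candidate: the query/hit disagreement at one column."""

    record: SaasRecord
    msa_column: int  # 1-based alignment column
    hit_id: str


@dataclass
class SimulationLog:
    """Per-rule rejection counts accumulated over a run."""

    counts: Dict[str, int] = field(default_factory=dict)

    def bump(self, key: str, n: int = 1) -> None:
        self.counts[key] = self.counts.get(key, 0) + n


def filter_hits(query: str, hits: Sequence[str], min_identity: float = 0.95,
                scoring: ScoringScheme = DEFAULT_SCORING) -> List[str]:
    """Retain hit sequences whose global-alignment identity to the query is
    at least ``min_identity``."""
    kept = []
    for hit in hits:
        aln = needleman_wunsch(query, hit, scoring)
        if percent_identity(aln) >= min_identity:
            kept.append(hit)
    return kept


def _row_identity(msa: Msa, row_index: int) -> float:
    """Identity between the query row and another row, projected from the
    MSA: identical columns over columns where either row is non-gap."""
    q, h = msa.query_row, msa.rows[row_index]
    total = same = 0
    for cq, ch in zip(q, h):
        if cq == GAP and ch == GAP:
            continue
        total += 1
        if cq == ch:
            same += 1
    return same / total if total else 0.0


def _hit_mismatch_profile(msa: Msa, row_index: int) -> Optional[int]:
    """R4 check for one hit row.

    Returns the single mismatching 1-based column if the hit differs from
    the query in exactly one column over their mutual non-gap span and has
    no internal gap columns against the query; ``None`` otherwise.
    """
    q, h = msa.query_row, msa.rows[row_index]
    both = [i for i, (cq, ch) in enumerate(zip(q, h))
            if cq != GAP and ch != GAP]
    if not both:
        return None
    lo, hi = both[0], both[-1]
    mismatches = []
    for i in range(lo, hi + 1):
        cq, ch = q[i], h[i]
        if cq == GAP or ch == GAP:
            if cq != ch:
                return None  # internal gap inside the overlap
            continue
        if cq != ch:
            mismatches.append(i)
    if len(mismatches) != 1:
        return None
    return mismatches[0] + 1


def _window_disagreements(msa: Msa, row_index: int, col: int,
                          window: int) -> int:
    """Count query/hit disagreeing columns in the window centred on ``col``
    (R3); gap-vs-residue columns count as disagreement."""
    half = window // 2
    lo = max(1, col - half)
    hi = min(msa.width, col + half)
    q, h = msa.query_row, msa.rows[row_index]
    return sum(q[i - 1] != h[i - 1] for i in range(lo, hi + 1))


def extract_candidates(msa: Msa, protein_id: Optional[str] = None,
                       config: SimulatorConfig = SimulatorConfig(),
                       log: Optional[SimulationLog] = None) -> List[CandidateSaas]:
    """Apply rules R1–R4 to one alignment and emit substitution candidates.

    ``protein_id`` defaults to the query row's id.  An alignment with fewer
    than ``config.min_rows`` rows yields an empty list (R1), not an error.
    """
    log = log if log is not None else SimulationLog()
    pid = protein_id or msa.ids[msa.query_index]
    if msa.n_rows < config.min_rows:
        log.bump("R1_too_few_rows")
        return []
    out: List[CandidateSaas] = []
    for r in range(msa.n_rows):
        if r == msa.query_index:
            continue
        col = _hit_mismatch_profile(msa, r)
        if col is None:
            log.bump("R4_not_single_substitution")
            continue
        counts = msa.column_counts(col)
        if len(counts) != 2:
            log.bump("R2_column_not_biallelic")
            continue
        if _window_disagreements(msa, r, col, config.window) != 1:
            log.bump("R3_window_not_isolated")
            continue
        wt = msa.query_row[col - 1]
        mut = msa.rows[r][col - 1]
        if wt not in AA_SET or mut not in AA_SET:
            log.bump("nonstandard_residue")
            continue
        pos = msa.query_position_of_column(col)
        assert pos is not None
        out.append(CandidateSaas(
            record=SaasRecord(protein_id=pid, wt=wt, position=pos, mut=mut,
                              label=NEUTRAL, source="simulated"),
            msa_column=col,
            hit_id=msa.ids[r],
        ))
    return out


def dedup_candidates(candidates: Sequence[CandidateSaas],
                     proteins: Dict[str, str],
                     min_identity: float = 0.95,
                     scoring: ScoringScheme = DEFAULT_SCORING,
                     log: Optional[SimulationLog] = None) -> List[CandidateSaas]:
    """Drop repeatedly-recorded substitutions.

    Two candidates are duplicates when their host proteins align at
    ``>= min_identity`` identity and the (wt, mut) pair matches at
    alignment-corresponding positions.  Candidates are processed in
    deterministic order (protein_id, position, mut); the first is kept.
    ``proteins`` maps protein_id to sequence.
    """
    log = log if log is not None else SimulationLog()
    ordered = sorted(
        candidates,
        key=lambda c: (c.record.protein_id, c.record.position, c.record.mut,
                       c.hit_id),
    )
    kept: List[CandidateSaas] = []
    aln_cache: Dict[Tuple[str, str], Tuple[Alignment, float]] = {}

    def pair_alignment(pa: str, pb: str) -> Tuple[Alignment, float]:
        key = (pa, pb)
        if key not in aln_cache:
            aln = needleman_wunsch(proteins[pa], proteins[pb], scoring)
            aln_cache[key] = (aln, percent_identity(aln))
        return aln_cache[key]

    for cand in ordered:
        dup = False
        for prev in kept:
            ra, rb = prev.record, cand.record
            if (ra.wt, ra.mut) != (rb.wt, rb.mut):
                continue
            if ra.protein_id == rb.protein_id:
                if ra.position == rb.position:
                    dup = True
                    break
                continue
            if rb.protein_id not in proteins or ra.protein_id not in proteins:
                continue
            aln, ident = pair_alignment(ra.protein_id, rb.protein_id)
            if ident < min_identity:
                continue
            if aln.map_a_to_b(ra.position) == rb.position:
                dup = True
                break
        if dup:
            log.bump("dedup_duplicate")
        else:
            kept.append(cand)
    return kept


def simulate_neutral(msas: Iterable[Msa],
                     config: SimulatorConfig = SimulatorConfig(),
                     protein_ids: Optional[Sequence[str]] = None,
                     ) -> Tuple[List[SaasRecord], SimulationLog]:
    """Full pseudoneutral simulation: per-alignment homolog filtering, rule
    extraction, then cross-alignment deduplication.

    Returns the neutral-labelled records plus a run log of per-rule
    rejection counts.
    """
    log = SimulationLog()
    candidates: List[CandidateSaas] = []
    proteins: Dict[str, str] = {}
    for k, msa in enumerate(msas):
        pid = protein_ids[k] if protein_ids else msa.ids[msa.query_index]
        proteins[pid] = msa.query_sequence
        keep = [msa.query_index] + [
            r for r in range(msa.n_rows)
            if r != msa.query_index
            and _row_identity(msa, r) >= config.min_identity
        ]
        n_dropped = msa.n_rows - len(keep)
        if n_dropped:
            log.bump("identity_below_threshold", n_dropped)
        sub = Msa(ids=[msa.ids[r] for r in keep],
                  rows=[msa.rows[r] for r in keep],
                  query_index=0)
        candidates.extend(extract_candidates(sub, protein_id=pid,
                                             config=config, log=log))
    if config.dedup:
        candidates = dedup_candidates(candidates, proteins,
                                      config.min_identity, config.scoring,
                                      log=log)
    log.bump("emitted", len(candidates))
    return [c.record for c in candidates], log
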