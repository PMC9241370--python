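"""Physicochemical features from AAindex entries, one per retained accession.

Per-residue indices (AAindex1) contribute the mutant-minus-wildtype
difference; symmetric residue-pair matrices (AAindex2/3) contribute the
matrix value at (wt, mut).  Entries with missing values, and asymmetric
matrices, are excluded before feature construction; a residue absent from an
entry yields a missing value that downstream imputation fills.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

from ..records import AaindexEntry, SaasError, SaasRecord

MISSING = float("nan")


def retained_entries(db: Sequence[AaindexEntry]) -> List[AaindexEntry]:
    """Entries usable as features: complete and symmetric, accession-sorted."""
    return sorted((e for e in db if not e.has_missing),
                  key=lambda e: e.accession)


def physchem_feature(entry: AaindexEntry, saas: SaasRecord) -> float:
    """One physicochemical feature value, NaN when a residue is not covered."""
    if entry.kind == "index1":
        wt_v = entry.index_value(saas.wt)
        mut_v = entry.index_value(saas.mut)
        if wt_v is None or mut_v is None:
            return MISSING
        return mut_v - wt_v
    v = entry.pair_value(saas.wt, saas.mut)
    return MISSING if v is None else v


def build_physchem_vector(db: Sequence[AaindexEntry],
                          saas: SaasRecord) -> Dict[str, float]:
    """One feature per retained accession, named by accession, in
    deterministic (sorted) order."""
    if not db:
        raise SaasError("empty AAindex database")
    return {e.accession: physchem_feature(e, saas)
            for e in retained_entries(db)}


def is_missing(value: float) -> bool:
    return isinstance(value, float) and math.isnan(value)
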