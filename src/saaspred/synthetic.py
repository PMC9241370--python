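"""Deterministic synthetic-data generators for the whole pipeline.

These generators emulate the statistical structure the feature extractors
assume — conserved alignment columns, jointly varying (coevolving) column
pairs, near-identical homolog sets, annotated reference proteins — and a
labelled feature table with planted logistic signal for selection-recovery
and model tests.  Every generator is a pure function of its seed.

They deliberately do not model phylogeny (rows are i.i.d. derivatives of
the query, not a tree) or realistic annotation density.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .records import (
    AMINO_ACIDS,
    ANNOTATION_TYPES,
    Annotation,
    Msa,
    ProteinRecord,
    SaasError,
)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_protein_family(length: int = 60, n_seqs: int = 10,
                        conserved_cols: Sequence[int] = (),
                        coupled_col_pairs: Sequence[Tuple[int, int]] = (),
                        substitution_rate: float = 0.05,
                        coupled_rate: float = 0.5,
                        seed: int = 0) -> Msa:
    """A gapless alignment: a random query plus derived homolog rows.

    Columns are 1-based.  Conserved columns never mutate; each coupled
    column pair switches both members jointly (to a fixed alternative
    residue pair) in the same random rows at ``coupled_rate``; every other
    column mutates independently at ``substitution_rate`` to one fixed
    alternative residue, so columns hold at most two residue kinds.
    """
    if not (0.0 <= substitution_rate <= 1.0 and 0.0 <= coupled_rate <= 1.0):
        raise SaasError("rates must lie in [0, 1]")
    conserved = set(conserved_cols)
    coupled = {c for pair in coupled_col_pairs for c in pair}
    if conserved & coupled:
        raise SaasError("conserved and coupled column sets overlap")
    for c in conserved | coupled:
        if not (1 <= c <= length):
            raise SaasError(f"column {c} outside 1..{length}")
    rng = _rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    query = aa[rng.integers(0, 20, size=length)]
    # a fixed alternative residue per column, distinct from the query's
    alt = aa[(np.searchsorted(aa, query) + 1 + rng.integers(0, 19, size=length)) % 20]
    alt = np.where(alt == query, aa[(np.searchsorted(aa, query) + 1) % 20], alt)

    rows = [query.copy()]
    n_hits = n_seqs - 1
    mutate = np.zeros((n_hits, length), dtype=bool)
    for col in range(1, length + 1):
        if col in conserved or col in coupled:
            continue
        mutate[:, col - 1] = rng.random(n_hits) < substitution_rate
    for ci, cj in coupled_col_pairs:
        switch = rng.random(n_hits) < coupled_rate
        mutate[:, ci - 1] = switch
        mutate[:, cj - 1] = switch
    for r in range(n_hits):
        row = query.copy()
        row[mutate[r]] = alt[mutate[r]]
        rows.append(row)
    return Msa(ids=[f"query"] + [f"hit{i}" for i in range(1, n_seqs)],
               rows=["".join(r) for r in rows], query_index=0)


def family_by_depth(depths: Sequence[int], seed: int = 0,
                    **kwargs) -> Dict[int, Msa]:
    """One family per configured depth (N rows each), shared query."""
    out = {}
    for n in depths:
        out[n] = make_protein_family(n_seqs=n, seed=seed, **kwargs)
    return out


def make_labeled_table(n: int = 2000, n_features: int = 20,
                       informative_idx: Sequence[int] = (0, 1, 2),
                       coefficients: Optional[Sequence[float]] = None,
                       noise_sd: float = 0.5,
                       seed: int = 0) -> LabeledDataset:
    """Feature table with planted logistic signal.

    Features are i.i.d. standard normal; the label is Bernoulli of a
    sigmoid over the informative columns (default coefficient magnitude 2)
    plus Gaussian noise, with the intercept set to the negated median of
    the linear predictor so classes stay near balance.
    """
    informative = list(informative_idx)
    if coefficients is None:
        coefficients = [2.0] * len(informative)
    if len(coefficients) != len(informative):
        raise SaasError("one coefficient per informative feature required")
    if not informative and any(c != 0 for c in coefficients):
        raise SaasError("nonzero coefficients with no informative features")
    if any(i >= n_features for i in informative):
        raise SaasError("informative index outside feature range")
    rng = _rng(seed)
    X = rng.standard_normal((n, n_features))
    z = X[:, informative] @ np.asarray(coefficients, dtype=float) \
        if informative else np.zeros(n)
    z = z + noise_sd * rng.standard_normal(n)
    z = z - np.median(z)  # intercept calibration: balance ~= 0.5
    p = 1.0 / (1.0 + np.exp(-z))
    y = (rng.random(n) < p).astype(int)
    names = [f"F{i:03d}" for i in range(n_features)]
    return LabeledDataset(features=pd.DataFrame(X, columns=names), labels=y)


def make_annotated_library(n_proteins: int = 5, length: int = 120,
                           annotations_per_protein: int = 12,
                           seed: int = 0) -> List[ProteinRecord]:
    """Random proteins carrying randomly placed annotations of all types.

    The first protein is guaranteed to lack at least one annotation type,
    exercising the SRD = 1 branch downstream.
    """
    rng = _rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    proteins: List[ProteinRecord] = []
    for k in range(n_proteins):
        seq = "".join(aa[rng.integers(0, 20, size=length)])
        anns: List[Annotation] = []
        banned = {ANNOTATION_TYPES[k % len(ANNOTATION_TYPES)]} if k == 0 else set()
        for _ in range(annotations_per_protein):
            t = ANNOTATION_TYPES[rng.integers(len(ANNOTATION_TYPES))]
            if t in banned:
                continue
            start = int(rng.integers(1, length + 1))
            span = int(rng.integers(0, 12))
            anns.append(Annotation(type=t, start=start,
                                   end=min(length, start + span)))
        proteins.append(ProteinRecord(protein_id=f"LIB{k:03d}", sequence=seq,
                                      annotations=anns))
    return proteins


# ---------------------------------------------------------------------------
# hand-authored AAindex fixture (synthetic values, real flat-file dialect)

_AAINDEX1_ORDER = "ARNDCQEGHILKMFPSTWYV"

_INDEX1_ENTRIES = {
    # synthetic per-residue scales; 20 values in flat-file order
    "SYNH010101": [1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5,
                   3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2],
    "SYNV020101": [88.6, 173.4, 114.1, 111.1, 108.5, 143.8, 138.4, 60.1,
                   153.2, 166.7, 166.7, 168.6, 162.9, 189.9, 112.7, 89.0,
                   116.1, 227.8, 193.6, 140.0],
    "SYNP030101": [0.0, 52.0, 3.38, 49.7, 1.48, 3.53, 49.9, 0.0, 51.6,
                   0.13, 0.13, 49.5, 1.43, 0.35, 1.58, 1.67, 1.66, 2.1,
                   1.61, 0.13],
    "SYNF040101": [-0.5, 3.0, 0.2, 3.0, -1.0, 0.2, 3.0, 0.0, -0.5, -1.8,
                   -1.8, 3.0, -1.3, -2.5, 0.0, 0.3, -0.4, -3.4, -2.3, -1.5],
}

_INDEX1_MISSING = ("SYNM050101",
                   [0.61, 0.6, 0.06, 0.46, 1.07, 0.0, 0.47, 0.07, 0.61,
                    2.22, 1.53, 1.15, 1.18, 2.02, 1.95, 0.05, 0.05, None,
                    2.65, 1.32])


def _matrix_lines(rng: np.random.Generator, asymmetric: bool = False
                  ) -> List[str]:
    """Lower-triangular (or full, for the asymmetric case) matrix block."""
    vals = np.round(rng.normal(0.0, 2.0, size=(20, 20)), 1)
    sym = np.tril(vals) + np.tril(vals, -1).T
    if not asymmetric:
        return ["  " + " ".join(f"{sym[i, j]:6.1f}" for j in range(i + 1))
                for i in range(20)]
    asym = sym.copy()
    asym[0, 1] = sym[0, 1] + 3.7  # break symmetry in one full-square cell
    return ["  " + " ".join(f"{asym[i, j]:6.1f}" for j in range(20))
            for i in range(20)]


def aaindex_fixture_text(seed: int = 0) -> str:
    """A small AAindex flat file: complete and NA-flagged per-residue
    indices, two symmetric matrices, and one asymmetric matrix that a
    conforming reader must drop."""
    rng = _rng(seed)
    blocks: List[str] = []
    for acc, vals in _INDEX1_ENTRIES.items():
        blocks.append(_index1_block(acc, vals))
    blocks.append(_index1_block(*_INDEX1_MISSING))
    for acc in ("SYNM2A0101", "SYNM2B0101"):
        lines = [f"H {acc}",
                 "D Synthetic symmetric residue-pair matrix",
                 f"M rows = {_AAINDEX1_ORDER}, cols = {_AAINDEX1_ORDER}"]
        lines += _matrix_lines(rng)
        blocks.append("\n".join(lines))
    lines = ["H SYNM3X0101",
             "D Synthetic asymmetric matrix (must be dropped)",
             f"M rows = {_AAINDEX1_ORDER}, cols = {_AAINDEX1_ORDER}"]
    lines += _matrix_lines(rng, asymmetric=True)
    blocks.append("\n".join(lines))
    return "\n//\n".join(blocks) + "\n//\n"


def _index1_block(accession: str, values: Sequence[Optional[float]]) -> str:
    def fmt(v: Optional[float]) -> str:
        return "NA" if v is None else f"{v:7.2f}"
    head = (f"H {accession}\n"
            "D Synthetic per-residue index\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T"
            "     G/W     H/Y     I/V")
    row1 = "  " + " ".join(fmt(v) for v in values[:10])
    row2 = "  " + " ".join(fmt(v) for v in values[10:])
    return f"{head}\n{row1}\n{row2}"


def write_aaindex_fixture(path, seed: int = 0) -> None:
    from pathlib import Path
    Path(path).write_text(aaindex_fixture_text(seed))
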