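"""Assembly of per-substitution feature rows from whatever inputs exist.

Each feature family is computed only when its inputs are supplied (an
alignment for the evolutionary and coevolutionary families, an AAindex
database for the physicochemical family, an annotated library for the SRD
family); absent families contribute missing values that the training-set
median imputes downstream.  Externally computed feature tables can be
merged by record key, replacing the third-party predictor battery with a
pluggable input.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .features.annot import annotation_feature_vector
from .features.coevo import DEFAULT_DEPTHS, coevolution_vector
from .features.evo import evo_feature_vector
from .features.physchem import build_physchem_vector
from .records import AaindexEntry, Msa, ProteinRecord, Pssm, SaasError, SaasRecord

META_COLUMNS = ("protein_id", "wt", "position", "mut", "label")


def feature_row(saas: SaasRecord,
                protein: Optional[ProteinRecord] = None,
                msa: Optional[Msa] = None,
                pssm: Optional[Pssm] = None,
                aaindex: Optional[Sequence[AaindexEntry]] = None,
                library: Optional[Sequence[ProteinRecord]] = None,
                msa_by_depth: Optional[Mapping[int, Msa]] = None,
                depths: Sequence[int] = DEFAULT_DEPTHS) -> Dict[str, float]:
    """All available feature families for one substitution."""
    if protein is not None:
        saas.check_against(protein)
    out: Dict[str, float] = {}
    if msa is not None or pssm is not None:
        if msa is not None:
            out.update(evo_feature_vector(msa, saas, pssm=pssm))
        else:
            from .features.evo import pssm_features
            out.update(pssm_features(pssm, saas))
    if aaindex:
        out.update(build_physchem_vector(aaindex, saas))
    if library is not None and protein is not None:
        out.update(annotation_feature_vector(protein, saas.position, library))
    if msa_by_depth is not None:
        out.update(coevolution_vector(msa_by_depth, saas, depths=depths))
    return out


def extract_feature_table(records: Sequence[SaasRecord],
                          proteins: Optional[Mapping[str, ProteinRecord]] = None,
                          msas: Optional[Mapping[str, Msa]] = None,
                          aaindex: Optional[Sequence[AaindexEntry]] = None,
                          library: Optional[Sequence[ProteinRecord]] = None,
                          msas_by_depth: Optional[Mapping[str, Mapping[int, Msa]]] = None,
                          depths: Sequence[int] = DEFAULT_DEPTHS,
                          external: Optional[pd.DataFrame] = None,
                          ) -> pd.DataFrame:
    """One row per substitution: meta columns then named features.

    ``external`` merges pre-computed features keyed by
    (protein_id, wt, position, mut).
    """
    rows: List[Dict[str, object]] = []
    for saas in records:
        protein = proteins.get(saas.protein_id) if proteins else None
        row: Dict[str, object] = {
            "protein_id": saas.protein_id, "wt": saas.wt,
            "position": saas.position, "mut": saas.mut,
            "label": saas.label or "",
        }
        row.update(feature_row(
            saas, protein=protein,
            msa=msas.get(saas.protein_id) if msas else None,
            aaindex=aaindex, library=library,
            msa_by_depth=(msas_by_depth.get(saas.protein_id)
                          if msas_by_depth else None),
            depths=depths))
        rows.append(row)
    df = pd.DataFrame(rows)
    if external is not None:
        key = list(META_COLUMNS[:4])
        missing = [c for c in key if c not in external.columns]
        if missing:
            raise SaasError(f"external feature table lacks key columns {missing}")
        df = df.merge(external, on=key, how="left",
                      suffixes=("", "_external"))
    return df


def table_to_dataset(df: pd.DataFrame):
    """Split a feature table into the LabeledDataset the modelling layer
    expects (meta columns dropped; label required)."""
    from .dataset import LabeledDataset
    from .records import FUNCTIONAL, NEUTRAL

    if "label" not in df.columns:
        raise SaasError("feature table has no label column")
    labels = df["label"].map({FUNCTIONAL: 1, NEUTRAL: 0})
    if labels.isna().any():
        raise SaasError("feature table contains unlabelled rows")
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    features = df[feature_cols].astype(float)
    return LabeledDataset(features=features,
                          labels=labels.to_numpy(dtype=int))
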