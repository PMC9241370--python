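"""Labelled-dataset assembly, stratified splitting and standardization.

The benchmark (80%) / independent (20%) split is stratified per class with
round-half-up class sizes — the only rounding rule that sends a 6367
functional + 6498 neutral table to 5094/5198 benchmark and 1273/1300
independent records.  Standardization is z-score with parameters fitted on
the benchmark set only and applied unchanged to the independent set;
missing values are imputed with the benchmark median before scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import FUNCTIONAL, NEUTRAL, SaasError, SaasRecord

LABEL_CODES = {NEUTRAL: 0, FUNCTIONAL: 1}


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels (functional = 1, neutral = 0).

    ``records`` optionally carries the originating substitution records,
    row-aligned with ``features``.
    """

    features: pd.DataFrame
    labels: np.ndarray
    records: Optional[List[SaasRecord]] = None
    split_tag: Optional[str] = None  # "benchmark" | "independent"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise SaasError("features and labels are not row-aligned")
        if self.records is not None and len(self.records) != len(self.labels):
            raise SaasError("records and labels are not row-aligned")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise SaasError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def feature_names(self) -> List[str]:
        return list(self.features.columns)

    @classmethod
    def from_records(cls, records: Sequence[SaasRecord],
                     feature_rows: Sequence[Dict[str, float]],
                     split_tag: Optional[str] = None) -> "LabeledDataset":
        labels = []
        for r in records:
            if r.label not in LABEL_CODES:
                raise SaasError(f"record {r.substitution} is unlabelled")
            labels.append(LABEL_CODES[r.label])
        return cls(features=pd.DataFrame(list(feature_rows)),
                   labels=np.array(labels), records=list(records),
                   split_tag=split_tag)

    def subset(self, idx: np.ndarray, split_tag: Optional[str] = None
               ) -> "LabeledDataset":
        recs = [self.records[i] for i in idx] if self.records else None
        return LabeledDataset(
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx], records=recs, split_tag=split_tag)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(dataset: LabeledDataset, benchmark_fraction: float = 0.8,
                     seed: int = 0) -> Tuple[LabeledDataset, LabeledDataset]:
    """Per-class stratified random split into (benchmark, independent).

    Each class contributes ``round_half_up(fraction * class_size)`` records
    to the benchmark set, sampled uniformly without replacement.
    """
    if not (0.0 < benchmark_fraction < 1.0):
        raise SaasError("benchmark_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    bench_idx: List[int] = []
    indep_idx: List[int] = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(dataset.labels == cls)
        if cls_idx.size == 0:
            raise SaasError(f"class {cls} has no records; cannot stratify")
        n_bench = _round_half_up(benchmark_fraction * cls_idx.size)
        chosen = rng.choice(cls_idx, size=n_bench, replace=False)
        chosen_set = set(chosen.tolist())
        bench_idx.extend(sorted(chosen_set))
        indep_idx.extend(int(i) for i in cls_idx if int(i) not in chosen_set)
    bench_idx_arr = np.array(sorted(bench_idx), dtype=int)
    indep_idx_arr = np.array(sorted(indep_idx), dtype=int)
    return (dataset.subset(bench_idx_arr, "benchmark"),
            dataset.subset(indep_idx_arr, "independent"))


@dataclass
class StandardizationParams:
    """Per-feature mean / SD / median, fitted on the benchmark set only."""

    means: pd.Series
    sds: pd.Series
    medians: pd.Series
    sd_epsilon: float = 1e-12

    @property
    def feature_names(self) -> List[str]:
        return list(self.means.index)


def fit_standardizer(benchmark: LabeledDataset,
                     ddof: int = 0) -> StandardizationParams:
    """Fit z-score parameters (population SD by default, ``ddof=1`` for the
    sample convention) plus imputation medians, ignoring missing values."""
    if len(benchmark) == 0:
        raise SaasError("cannot fit a standardizer on an empty dataset")
    df = benchmark.features
    return StandardizationParams(
        means=df.mean(skipna=True),
        sds=df.std(ddof=ddof, skipna=True).fillna(0.0),
        medians=df.median(skipna=True),
    )


def apply_standardizer(params: StandardizationParams,
                       dataset: LabeledDataset) -> LabeledDataset:
    """Impute with the fitted medians then z-score with the fitted
    parameters; features with SD below epsilon map to 0."""
    df = dataset.features
    unknown = [c for c in params.feature_names if c not in df.columns]
    if unknown:
        raise SaasError(f"dataset lacks fitted features: {unknown}")
    df = df[params.feature_names].copy()
    df = df.fillna(params.medians)
    sds = params.sds.copy()
    degenerate = sds < params.sd_epsilon
    sds[degenerate] = 1.0
    out = (df - params.means) / sds
    out.loc[:, degenerate] = 0.0
    return LabeledDataset(features=out, labels=dataset.labels.copy(),
                          records=list(dataset.records) if dataset.records else None,
                          split_tag=dataset.split_tag)


def standardize_pair(benchmark: LabeledDataset, independent: LabeledDataset,
                     ddof: int = 0) -> Tuple[LabeledDataset, LabeledDataset,
                                             StandardizationParams]:
    """Fit on the benchmark set, apply to both; the independent set never
    influences the parameters."""
    params = fit_standardizer(benchmark, ddof=ddof)
    return (apply_standardizer(params, benchmark),
            apply_standardizer(params, independent), params)
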