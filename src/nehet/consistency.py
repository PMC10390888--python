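"""Cross-dataset consistency filtering of screen features.

Functional-screen features (drug sensitivities, gene effect scores) are
noisier than molecular profiling, so before clustering or association each
feature is scored for interstudy reproducibility: for a feature measured
in k datasets, all C(k,2) pairwise Pearson correlations over shared cell
lines are computed and summarized by Fisher-z meta-analysis into one
pooled consistency r with a p-value. Dependency features are kept at
pooled r > 0.4; drug features at Benjamini-Hochberg adjusted p < 0.05
(adjustment across all features of the modality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .association import MULTITEST_METHOD, meta_pool
from .core import FeatureMatrix, NehetError

__all__ = [
    "PairCorrelation",
    "ConsistencyRecord",
    "ConsistencyFilter",
    "count_pairs",
    "feature_consistency",
    "consistency_table",
    "adjust_records",
    "select_consistent",
]

# |r|=1 pairs (e.g. a dataset duplicated verbatim) would make Fisher z
# infinite; clip just inside the open interval so pooling round-trips to 1
# within float tolerance.
_R_CLIP = 1.0 - 1e-12


@dataclass
class PairCorrelation:
    dataset_a: str
    dataset_b: str
    r: float
    n_shared: int


@dataclass
class ConsistencyRecord:
    feature_id: str
    pair_correlations: list[PairCorrelation]
    k_datasets: int
    n_pairs: int
    pooled_r: float
    p_value: float
    p_adjusted: float = float("nan")
    excluded_pairs: list[tuple[str, str, int]] = field(default_factory=list)


def count_pairs(k: int) -> int:
    """Number of unordered dataset pairs, C(k, 2) = k(k-1)/2."""
    k = int(k)
    if k < 0:
        raise NehetError(f"dataset count must be nonnegative, got {k}")
    return k * (k - 1) // 2


def _dataset_label(fm: FeatureMatrix, idx: int) -> str:
    return getattr(fm, "label", None) or f"dataset{idx + 1}"


def feature_consistency(
    feature_id: str,
    datasets: Sequence[FeatureMatrix],
    min_shared: int = 10,
    model: str = "random",
) -> ConsistencyRecord:
    """Interstudy consistency of one feature across datasets.

    Computes a Pearson r for every unordered pair of datasets measuring
    the feature, over samples where both measurements are non-missing;
    pairs with fewer than ``min_shared`` shared samples are excluded and
    recorded. The pair correlations are pooled by Fisher-z meta-analysis
    weighted by n_shared - 3.
    """
    min_shared = max(int(min_shared), 4)
    present: list[tuple[str, pd.Series]] = []
    for i, fm in enumerate(datasets):
        if feature_id in set(fm.feature_ids):
            row = fm.values.loc[feature_id].dropna()
            present.append((_dataset_label(fm, i), row))
    if len(present) < 2:
        raise NehetError(
            f"feature {feature_id!r} present in {len(present)} dataset(s); need >= 2"
        )
    pairs: list[PairCorrelation] = []
    excluded: list[tuple[str, str, int]] = []
    for (la, ra), (lb, rb) in combinations(present, 2):
        shared = ra.index.intersection(rb.index)
        n = len(shared)
        if n < min_shared:
            excluded.append((la, lb, n))
            continue
        x, y = ra[shared].to_numpy(), rb[shared].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            excluded.append((la, lb, n))
            continue
        r = float(stats.pearsonr(x, y).statistic)
        pairs.append(PairCorrelation(la, lb, r, n))
    if not pairs:
        raise NehetError(
            f"feature {feature_id!r}: no dataset pair with >= {min_shared} shared samples"
        )
    pooled = meta_pool(
        [(f"{p.dataset_a}|{p.dataset_b}", float(np.clip(p.r, -_R_CLIP, _R_CLIP)), p.n_shared) for p in pairs],
        model=model,
    )
    return ConsistencyRecord(
        feature_id=feature_id,
        pair_correlations=pairs,
        k_datasets=len(present),
        n_pairs=len(pairs),
        pooled_r=pooled.pooled_r,
        p_value=pooled.p_value,
        excluded_pairs=excluded,
    )


def consistency_table(
    datasets: Sequence[FeatureMatrix],
    min_shared: int = 10,
    model: str = "random",
) -> list[ConsistencyRecord]:
    """Consistency records for every feature measured in >= 2 datasets,
    BH-adjusted jointly across the returned records."""
    features: list[str] = []
    seen: set[str] = set()
    for fm in datasets:
        for fid in fm.feature_ids:
            if fid not in seen:
                seen.add(fid)
                features.append(fid)
    records: list[ConsistencyRecord] = []
    for fid in features:
        try:
            records.append(
                feature_consistency(fid, datasets, min_shared=min_shared, model=model)
            )
        except NehetError:
            continue
    if not records:
        raise NehetError("no feature has sufficient cross-dataset overlap")
    return adjust_records(records)


def adjust_records(records: Sequence[ConsistencyRecord]) -> list[ConsistencyRecord]:
    """Populate p_adjusted by Benjamini-Hochberg across the given records."""
    records = list(records)
    if not records:
        raise NehetError("no consistency records")
    adj = multipletests([r.p_value for r in records], method=MULTITEST_METHOD)[1]
    for rec, p in zip(records, adj):
        rec.p_adjusted = float(p)
    return records


def select_consistent(
    records: Sequence[ConsistencyRecord],
    modality: str,
    r_threshold: float = 0.4,
    alpha: float = 0.05,
) -> list[str]:
    """Features passing the modality's consistency criterion.

    ``dependency``: pooled r strictly above ``r_threshold``.
    ``drug``: BH-adjusted p strictly below ``alpha``.
    Returned sorted by pooled r, descending.
    """
    records = list(records)
    if not records:
        raise NehetError("no consistency records")
    if modality in ("dependency", "dependency_rnai", "dependency_crispr"):
        hits = [r for r in records if r.pooled_r > r_threshold]
    elif modality == "drug":
        if any(not np.isfinite(r.p_adjusted) for r in records):
            raise NehetError("p_adjusted not populated; run adjust_records first")
        hits = [r for r in records if r.p_adjusted < alpha]
    else:
        raise NehetError(f"modality must be 'drug' or 'dependency', got {modality!r}")
    hits.sort(key=lambda r: -r.pooled_r)
    return [r.feature_id for r in hits]


def records_to_frame(records: Sequence[ConsistencyRecord], selected: Sequence[str] = ()) -> pd.DataFrame:
    sel = set(selected)
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "k_datasets": r.k_datasets,
                "n_pairs": r.n_pairs,
                "pooled_r": r.pooled_r,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "selected": r.feature_id in sel,
            }
            for r in records
        ]
    )


class ConsistencyFilter(BaseEstimator):
    """Cross-dataset consistency feature filter (scikit-learn style).

    Fit on a list of ``FeatureMatrix`` datasets re-measuring the same
    features; exposes the per-feature records and the selected feature
    ids.

    Parameters
    ----------
    modality : {"drug", "dependency"}
        Selection rule: drug uses adjusted p < ``alpha``; dependency uses
        pooled r > ``r_threshold``.
    min_shared : int, default=10
        Minimum shared cell lines per dataset pair.
    model : {"random", "fixed"}, default="random"
        Meta-analysis model for pooling pair correlations.
    """

    def __init__(
        self,
        modality: str = "drug",
        min_shared: int = 10,
        r_threshold: float = 0.4,
        alpha: float = 0.05,
        model: str = "random",
    ):
        self.modality = modality
        self.min_shared = min_shared
        self.r_threshold = r_threshold
        self.alpha = alpha
        self.model = model

    def fit(self, X: Sequence[FeatureMatrix], y=None):
        self.records_ = consistency_table(
            X, min_shared=self.min_shared, model=self.model
        )
        self.selected_features_ = select_consistent(
            self.records_,
            self.modality,
            r_threshold=self.r_threshold,
            alpha=self.alpha,
        )
        return self

    def transform(self, X: FeatureMatrix) -> FeatureMatrix:
        """Restrict a matrix to the selected consistent features."""
        if not hasattr(self, "selected_features_"):
            raise NehetError("ConsistencyFilter is not fitted")
        keep = [f for f in X.feature_ids if f in set(self.selected_features_)]
        if not keep:
            raise NehetError("no selected feature present in the matrix")
        return FeatureMatrix(X.values.loc[keep], X.modality)
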