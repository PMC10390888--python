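"""Panel clustering recipes.

Three recipes mirror how different data types are clustered:

* expression — keep genes with sample standard deviation > 0.4 (log2
  scale), project samples onto the top 10 principal components, then Ward
  hierarchical clustering;
* rppa / metabolite — Ward clustering on all available features, no
  filtering or PCA;
* drug / dependency — restrict to a consistency-filtered feature list
  (see :mod:`nehet.consistency`), then Ward clustering.

Ward linkage uses the criterion applied to Euclidean distances (the
"ward.D2" convention of mainstream libraries). Features are not rescaled
by default; ``standardize=True`` z-scores feature columns first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

from .core import ExpressionMatrix, FeatureMatrix, NehetError, StudyPanel

__all__ = [
    "ClusteringResult",
    "PanelClusterer",
    "filter_variable_genes",
    "pca_reduce",
    "ward_cluster",
    "cluster_panel",
]


@dataclass
class ClusteringResult:
    """Ward merge tree over samples with optional PCA provenance."""

    sample_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix, heights in column 2
    pcs_used: int | None = None
    variance_explained: np.ndarray | None = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Partition into k clusters; labels are 1..k keyed by sample id."""
        if not (1 <= k <= len(self.sample_ids)):
            raise NehetError(f"k must be in [1, {len(self.sample_ids)}], got {k}")
        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "linkage": self.linkage.tolist(),
            "pcs_used": self.pcs_used,
            "variance_explained": None
            if self.variance_explained is None
            else list(map(float, self.variance_explained)),
            "linkage_method": "ward",
        }


def filter_variable_genes(
    expr: ExpressionMatrix, sd_threshold: float = 0.4
) -> ExpressionMatrix:
    """Keep genes whose sample standard deviation (n-1 denominator)
    strictly exceeds ``sd_threshold``; row order preserved."""
    sds = expr.values.std(axis=1, ddof=1, skipna=True)
    keep = expr.values.index[sds > sd_threshold]
    if len(keep) == 0:
        raise NehetError(f"no gene exceeds sd threshold {sd_threshold}")
    return ExpressionMatrix(expr.values.loc[keep])


def pca_reduce(
    expr: ExpressionMatrix | FeatureMatrix, n_components: int = 10
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto leading principal components.

    Centers each gene across samples and returns (samples x n_components
    score frame, per-component variance-explained fractions).
    """
    X = expr.values.T  # samples x genes
    if X.isna().any().any():
        raise NehetError("matrix contains missing values; impute or drop first")
    max_nc = min(X.shape)
    if not (1 <= n_components <= max_nc):
        raise NehetError(
            f"n_components must be in [1, {max_nc}] for a "
            f"{expr.shape[0]}x{expr.shape[1]} matrix, got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(X.to_numpy())
    frame = pd.DataFrame(
        scores, index=X.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return frame, pca.explained_variance_ratio_.copy()


def ward_cluster(points, sample_ids: Sequence[str] | None = None) -> ClusteringResult:
    """Agglomerative Ward clustering of samples on Euclidean distances.

    ``points`` is a samples x features frame/array with no missing values.
    Deterministic given input order; exact distance ties are broken by the
    lowest merge-index pair (scipy's nearest-neighbor chain convention).
    """
    if isinstance(points, pd.DataFrame):
        ids = list(points.index) if sample_ids is None else list(sample_ids)
        arr = points.to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        ids = (
            [f"s{i}" for i in range(arr.shape[0])]
            if sample_ids is None
            else list(sample_ids)
        )
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise NehetError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(arr)):
        raise NehetError("missing/non-finite values present; impute or drop first")
    if len(ids) != arr.shape[0]:
        raise NehetError("sample_ids length mismatch")
    Z = linkage(arr, method="ward", metric="euclidean")
    return ClusteringResult(sample_ids=ids, linkage=Z)


EXPRESSION_RECIPE = {"sd_threshold": 0.4, "n_pcs": 10}


def cluster_panel(
    panel: StudyPanel,
    modality: str,
    sd_threshold: float = 0.4,
    n_pcs: int = 10,
    consistent_features: Sequence[str] | None = None,
    standardize: bool = False,
) -> ClusteringResult:
    """Cluster a panel's samples with the recipe matching the modality.

    expression: variance filter -> PCA -> Ward. rppa/metabolite (and other
    molecular modalities): Ward on all features. drug/dependency: Ward on
    the supplied ``consistent_features`` only (required).
    """
    fm = panel.matrix(modality)
    if modality == "expression":
        filtered = filter_variable_genes(ExpressionMatrix(fm.values), sd_threshold)
        complete = filtered.values.dropna(axis=0)
        if complete.shape[0] == 0:
            raise NehetError("no complete gene rows after variance filter")
        n_pcs_eff = min(n_pcs, *complete.shape)
        scores, varexp = pca_reduce(ExpressionMatrix(complete), n_pcs_eff)
        res = ward_cluster(scores)
        res.pcs_used = n_pcs_eff
        res.variance_explained = varexp
        return res
    if modality in ("drug", "dependency_rnai", "dependency_crispr"):
        if not consistent_features:
            raise NehetError(
                f"{modality} clustering requires a consistent-feature list"
            )
        keep = [f for f in fm.feature_ids if f in set(consistent_features)]
        if not keep:
            raise NehetError("no consistent feature present in the matrix")
        values = fm.values.loc[keep]
    else:
        values = fm.values  # rppa, metabolite, ...: all available features
    points = values.dropna(axis=0).T
    if points.shape[1] == 0:
        raise NehetError("no complete feature rows to cluster on")
    if standardize:
        points = (points - points.mean(axis=0)) / points.std(axis=0, ddof=1)
        points = points.dropna(axis=1)
    return ward_cluster(points)


class PanelClusterer(ClusterMixin, BaseEstimator):
    """Ward panel clustering estimator (scikit-learn style).

    Fits on ``X`` as samples x features. ``recipe="expression"`` applies
    the variance filter and PCA reduction first; ``recipe="all_features"``
    clusters on every column; ``recipe="screen"`` restricts columns to
    ``consistent_features``. ``fit`` sets ``linkage_``, ``labels_`` (when
    ``n_clusters`` is given), ``pcs_used_`` and ``variance_explained_``.
    """

    def __init__(
        self,
        recipe: str = "all_features",
        n_clusters: int | None = None,
        sd_threshold: float = 0.4,
        n_pcs: int = 10,
        consistent_features: Sequence[str] | None = None,
        standardize: bool = False,
    ):
        self.recipe = recipe
        self.n_clusters = n_clusters
        self.sd_threshold = sd_threshold
        self.n_pcs = n_pcs
        self.consistent_features = consistent_features
        self.standardize = standardize

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.index = [f"s{i}" for i in range(X.shape[0])]
            X.columns = [f"f{j}" for j in range(X.shape[1])]
        fm = FeatureMatrix(
            X.T, {"expression": "expression", "screen": "drug"}.get(self.recipe, "rppa")
        )
        panel = StudyPanel("fit", {fm.modality: fm})
        result = cluster_panel(
            panel,
            fm.modality,
            sd_threshold=self.sd_threshold,
            n_pcs=self.n_pcs,
            consistent_features=self.consistent_features,
            standardize=self.standardize,
        )
        self.result_ = result
        self.sample_ids_ = result.sample_ids
        self.linkage_ = result.linkage
        self.pcs_used_ = result.pcs_used
        self.variance_explained_ = result.variance_explained
        self.n_features_in_ = X.shape[1]
        if self.n_clusters is not None:
            assign = result.cut(self.n_clusters)
            self.labels_ = np.array([assign[s] for s in result.sample_ids])
        return self
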