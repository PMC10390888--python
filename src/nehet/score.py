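"""Quantitative neuroendocrine (NE) scoring of expression profiles.

The NE score of a sample is

    score = (correl_NE - correl_nonNE) / 2

where ``correl_NE`` (resp. ``correl_nonNE``) is the Pearson correlation
between the sample's expression over the signature genes and the
signature's NE (resp. non-NE) group reference vector. The score lies in
[-1, +1]; positive predicts an NE state, negative a non-NE state, and the
magnitude reflects confidence.

Signature genes missing from a profile are dropped per sample, so the
number of genes actually used may differ between samples and is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import ExpressionMatrix, NehetError, SignatureTable

__all__ = ["NEScoreResult", "ScoreSet", "NEScorer", "score_sample", "score_matrix", "aggregate_by_group"]


@dataclass
class NEScoreResult:
    sample_id: str
    corr_ne: float
    corr_non_ne: float
    score: float
    n_genes_used: int


class ScoreSet(Mapping):
    """Mapping sample_id -> NEScoreResult, with unscorable samples reported.

    ``failures`` maps each sample that failed its preconditions (too few
    usable signature genes, or a constant restricted profile) to the reason.
    """

    def __init__(self, scores: dict[str, NEScoreResult], failures: dict[str, str]):
        self._scores = scores
        self.failures = failures

    def __getitem__(self, key):
        return self._scores[key]

    def __iter__(self):
        return iter(self._scores)

    def __len__(self):
        return len(self._scores)

    def score_map(self) -> dict[str, float]:
        return {sid: res.score for sid, res in self._scores.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "corr_ne": r.corr_ne,
                    "corr_non_ne": r.corr_non_ne,
                    "score": r.score,
                    "n_genes_used": r.n_genes_used,
                }
                for r in self._scores.values()
            ]
        )


def _score_values(x: np.ndarray, ne_ref: np.ndarray, non_ne_ref: np.ndarray) -> tuple[float, float, float]:
    if np.ptp(x) == 0:
        raise NehetError("restricted profile is constant; correlation undefined")
    corr_ne = float(stats.pearsonr(x, ne_ref).statistic)
    corr_non_ne = float(stats.pearsonr(x, non_ne_ref).statistic)
    return corr_ne, corr_non_ne, (corr_ne - corr_non_ne) / 2.0


def score_sample(
    profile: Mapping[str, float] | pd.Series,
    signature: SignatureTable,
    min_genes: int = 10,
    sample_id: str = "sample",
) -> NEScoreResult:
    """Score one expression profile against an NE signature.

    Parameters
    ----------
    profile
        Mapping gene -> expression value (missing genes may be absent or
        NaN). Only signature genes are used.
    signature
        Signature with NE / non-NE reference vectors.
    min_genes
        Minimum usable signature genes; fewer raises ``NehetError``.
    """
    if isinstance(profile, pd.Series):
        profile = profile.to_dict()
    min_genes = max(int(min_genes), 2)
    vals, ne_ref, non_ne_ref = [], [], []
    for g, a, b in zip(signature.genes, signature.ne_ref, signature.non_ne_ref):
        v = profile.get(g)
        if v is None or not np.isfinite(v):
            continue
        vals.append(float(v))
        ne_ref.append(a)
        non_ne_ref.append(b)
    n_used = len(vals)
    if n_used < min_genes:
        raise NehetError(
            f"only {n_used} usable signature genes for {sample_id!r} "
            f"(minimum {min_genes})"
        )
    x = np.array(vals)
    ne_ref = np.array(ne_ref)
    non_ne_ref = np.array(non_ne_ref)
    for name, ref in (("NE", ne_ref), ("non-NE", non_ne_ref)):
        if np.ptp(ref) == 0:
            raise NehetError(f"{name} reference is constant over usable genes")
    corr_ne, corr_non_ne, score = _score_values(x, ne_ref, non_ne_ref)
    return NEScoreResult(sample_id, corr_ne, corr_non_ne, score, n_used)


def score_matrix(
    expr: ExpressionMatrix,
    signature: SignatureTable,
    min_genes: int = 10,
) -> ScoreSet:
    """Score every sample (column) of an expression matrix.

    Samples failing the per-sample preconditions are recorded in the
    returned ``ScoreSet.failures`` rather than silently dropped; if no
    sample is scorable a ``NehetError`` is raised.
    """
    scores: dict[str, NEScoreResult] = {}
    failures: dict[str, str] = {}
    for sid in expr.sample_ids:
        try:
            scores[sid] = score_sample(
                expr.values[sid], signature, min_genes=min_genes, sample_id=sid
            )
        except NehetError as exc:
            failures[sid] = str(exc)
    if not scores:
        raise NehetError(f"no scorable sample among {len(expr.sample_ids)}")
    return ScoreSet(scores, failures)


def aggregate_by_group(
    expr: ExpressionMatrix, groups: Mapping[str, str]
) -> ExpressionMatrix:
    """Average expression per gene within sample groups (e.g. lineages).

    Returns one column per group (ordered by group name) holding per-gene
    means over non-missing values.
    """
    if not groups:
        raise NehetError("empty group map")
    missing = [s for s in groups if s not in set(expr.sample_ids)]
    if missing:
        raise NehetError(f"group map refers to unknown sample(s): {missing[:5]}")
    by_group: dict[str, list[str]] = {}
    for sid, grp in groups.items():
        by_group.setdefault(str(grp), []).append(sid)
    cols = {}
    for grp in sorted(by_group):
        cols[grp] = expr.values[by_group[grp]].mean(axis=1, skipna=True)
    out = pd.DataFrame(cols, index=expr.values.index)
    return ExpressionMatrix(out)


class NEScorer(TransformerMixin, BaseEstimator):
    """Signature-based NE-score transformer (scikit-learn style).

    Accepts ``X`` as samples x genes: a DataFrame whose columns are gene
    ids, or a bare array whose columns follow the signature's gene order.
    ``transform`` returns an ``(n_samples, 1)`` array of NE scores in
    [-1, 1]; ``score_frame`` returns the full per-sample table.

    Parameters
    ----------
    signature : SignatureTable
        Required at fit time.
    min_genes : int, default=10
        Minimum usable signature genes per sample.
    """

    def __init__(self, signature: SignatureTable | None = None, min_genes: int = 10):
        self.signature = signature
        self.min_genes = min_genes

    def fit(self, X, y=None):
        if self.signature is None:
            raise NehetError("NEScorer requires a signature")
        X = self._as_frame(X)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.genes_used_ = [g for g in self.signature.genes if g in set(X.columns)]
        if len(self.genes_used_) < max(int(self.min_genes), 2):
            raise NehetError(
                f"only {len(self.genes_used_)} signature genes present in X"
            )
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "genes_used_")
        return self.score_frame(X)["score"].to_numpy().reshape(-1, 1)

    def score_frame(self, X) -> pd.DataFrame:
        check_is_fitted(self, "genes_used_")
        X = self._as_frame(X)
        expr = ExpressionMatrix(X.T)
        scores = score_matrix(expr, self.signature, min_genes=self.min_genes)
        if scores.failures:
            raise NehetError(
                f"unscorable sample(s): {sorted(scores.failures)[:5]}"
            )
        frame = scores.to_frame().set_index("sample_id")
        return frame.loc[[str(s).strip() for s in X.index]]

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise NehetError("X must be 2-dimensional (samples x genes)")
        if X.shape[1] != len(self.signature.genes):
            raise NehetError(
                "array X must have one column per signature gene; "
                "pass a DataFrame for named gene columns"
            )
        return pd.DataFrame(
            X,
            index=[f"s{i}" for i in range(X.shape[0])],
            columns=list(self.signature.genes),
        )
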