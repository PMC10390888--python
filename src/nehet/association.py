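"""NE-score/feature association and correlation meta-analysis.

Per-study associations are Pearson correlations with exact t-distribution
p-values and Benjamini-Hochberg adjustment across the features of a
matrix. Cross-study summaries use Fisher z-transformed correlations pooled
by inverse variance (var(z) = 1/(n-3)); the random-effects model adds a
DerSimonian-Laird between-study variance. The amplification-adjusted model
is an ordinary least-squares regression of a gene's expression on the NE
score plus a 0/1 amplification covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FeatureMatrix, MetaResult, NehetError, StudyRecord

__all__ = [
    "AssociationRecord",
    "AdjustedModelResult",
    "correlate_features",
    "select_by_adjusted_p",
    "meta_pool",
    "meta_by_group",
    "adjusted_association",
    "bulk_sc_agreement",
]

MULTITEST_METHOD = "fdr_bh"  # stamped into outputs by the CLI


@dataclass
class AssociationRecord:
    feature_id: str
    r: float
    n: int
    p_value: float
    p_adjusted: float = float("nan")


@dataclass
class AdjustedModelResult:
    coef_ne: float
    coef_amp: float
    se_ne: float
    se_amp: float
    p_ne: float
    p_amp: float
    n: int


def _pairwise_complete(x: pd.Series, scores: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for sid, v in x.items():
        s = scores.get(sid)
        if s is None or not np.isfinite(s) or not np.isfinite(v):
            continue
        xs.append(float(v))
        ys.append(float(s))
    return np.array(xs), np.array(ys)


def correlate_features(
    features: FeatureMatrix,
    ne_scores: Mapping[str, float],
    min_n: int = 10,
) -> list[AssociationRecord]:
    """Correlate every feature with the NE score over shared samples.

    Uses pairwise-complete observations per feature; features with fewer
    than ``min_n`` usable samples or a constant vector are skipped.
    p-values come from the exact t transform (n-2 df) and are BH-adjusted
    across all tested features of the matrix.
    """
    records: list[AssociationRecord] = []
    for fid in features.feature_ids:
        x, y = _pairwise_complete(features.values.loc[fid], ne_scores)
        if len(x) < max(min_n, 4) or np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        res = stats.pearsonr(x, y)
        records.append(
            AssociationRecord(fid, float(res.statistic), len(x), float(res.pvalue))
        )
    if not records:
        raise NehetError("no feature testable against the NE scores")
    adj = multipletests([r.p_value for r in records], method=MULTITEST_METHOD)[1]
    for rec, p in zip(records, adj):
        rec.p_adjusted = float(p)
    return records


def select_by_adjusted_p(
    records: Sequence[AssociationRecord], threshold: float
) -> list[str]:
    """Features whose BH-adjusted p falls below ``threshold``, sorted by r
    (most positive first)."""
    if not records:
        raise NehetError("no association records")
    if not (0 < threshold <= 1):
        raise NehetError(f"threshold must lie in (0, 1], got {threshold}")
    hits = [rec for rec in records if rec.p_adjusted < threshold]
    hits.sort(key=lambda rec: -rec.r)
    return [rec.feature_id for rec in hits]


def _as_study_records(per_study: Iterable) -> list[StudyRecord]:
    out = []
    for i, item in enumerate(per_study):
        if isinstance(item, StudyRecord):
            out.append(item)
        elif len(item) == 3:
            out.append(StudyRecord(str(item[0]), float(item[1]), int(item[2])))
        else:
            out.append(StudyRecord(f"study{i + 1}", float(item[0]), int(item[1])))
    return out


def meta_pool(per_study: Iterable, model: str = "random") -> MetaResult:
    """Pool per-study Pearson correlations via Fisher's z transform.

    Each study contributes z = atanh(r) with variance 1/(n-3); the pooled z
    is the inverse-variance-weighted mean, back-transformed to r with a 95%
    CI and a two-sided normal p-value. ``model="random"`` adds the
    DerSimonian-Laird between-study variance tau^2 to each study's
    variance; ``model="fixed"`` pools with within-study variances only.

    Requires every n >= 4 and |r| < 1 (z is undefined at |r| = 1).
    """
    if model not in ("fixed", "random"):
        raise NehetError(f"model must be 'fixed' or 'random', got {model!r}")
    recs = _as_study_records(per_study)
    if not recs:
        raise NehetError("no studies to pool")
    for rec in recs:
        if rec.n < 4:
            raise NehetError(f"study {rec.study_id!r} has n={rec.n} < 4")
        if not abs(rec.r) < 1:
            raise NehetError(
                f"study {rec.study_id!r} has |r| = 1; Fisher z undefined"
            )
    z = np.array([np.arctanh(rec.r) for rec in recs])
    v = np.array([1.0 / (rec.n - 3) for rec in recs])
    w = 1.0 / v
    z_fixed = float(np.sum(w * z) / np.sum(w))
    tau2 = 0.0
    if model == "random" and len(recs) > 1:
        q = float(np.sum(w * (z - z_fixed) ** 2))
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (len(recs) - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    z_pooled = float(np.sum(w_star * z) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    crit = stats.norm.ppf(0.975)
    p = float(2 * stats.norm.sf(abs(z_pooled) / se))
    return MetaResult(
        per_study=recs,
        pooled_r=float(np.tanh(z_pooled)),
        ci_low=float(np.tanh(z_pooled - crit * se)),
        ci_high=float(np.tanh(z_pooled + crit * se)),
        p_value=p,
        heterogeneity_tau2=tau2,
        model=model,
    )


def meta_by_group(
    records: Iterable[tuple[str, str, float, int]], model: str = "random"
) -> dict[str, MetaResult]:
    """Pool (feature, study) correlation records within groups.

    ``records`` holds (feature_id, group_id, r, n) tuples — e.g. every
    compound of one mechanism-of-action class across every screen. All
    records of a group are pooled jointly via :func:`meta_pool`; groups are
    independent of each other.
    """
    grouped: dict[str, list[StudyRecord]] = {}
    for fid, gid, r, n in records:
        grouped.setdefault(str(gid), []).append(
            StudyRecord(f"{fid}", float(r), int(n))
        )
    if not grouped:
        raise NehetError("no records to pool")
    return {gid: meta_pool(recs, model=model) for gid, recs in grouped.items()}


def adjusted_association(
    expr_gene: Mapping[str, float],
    ne_scores: Mapping[str, float],
    amplification: Mapping[str, int],
) -> AdjustedModelResult:
    """OLS of a gene's expression on NE score controlling for amplification.

    Fits expression ~ intercept + NE score + amplification over complete
    cases and reports each covariate's coefficient, standard error, and
    two-sided p-value. Requires >= 10 complete cases, non-constant
    covariates, and |corr(score, amplification)| <= 0.999.
    """
    shared = [
        s
        for s in expr_gene
        if s in ne_scores
        and s in amplification
        and np.isfinite(expr_gene[s])
        and np.isfinite(ne_scores[s])
        and amplification[s] is not None
    ]
    if len(shared) < 10:
        raise NehetError(f"only {len(shared)} complete cases (minimum 10)")
    y = np.array([expr_gene[s] for s in shared], dtype=float)
    score = np.array([ne_scores[s] for s in shared], dtype=float)
    amp = np.array([amplification[s] for s in shared], dtype=float)
    for name, x in (("NE score", score), ("amplification", amp)):
        if np.ptp(x) == 0:
            raise NehetError(f"{name} covariate is constant")
    r_cov = float(stats.pearsonr(score, amp).statistic)
    if abs(r_cov) > 0.999:
        raise NehetError(f"covariates collinear (|r| = {abs(r_cov):.4f} > 0.999)")
    X = sm.add_constant(np.column_stack([score, amp]))
    fit = sm.OLS(y, X).fit()
    return AdjustedModelResult(
        coef_ne=float(fit.params[1]),
        coef_amp=float(fit.params[2]),
        se_ne=float(fit.bse[1]),
        se_amp=float(fit.bse[2]),
        p_ne=float(fit.pvalues[1]),
        p_amp=float(fit.pvalues[2]),
        n=len(shared),
    )


def bulk_sc_agreement(
    bulk_scores: Mapping[str, float],
    sc_scores: Mapping,
) -> tuple[float, int, dict[str, float]]:
    """Agreement between bulk and single-cell NE scores per cell line.

    ``sc_scores`` maps (line, cell) -> score (tuple keys) or
    line -> iterable of cell scores. Each line's cells are averaged
    unweighted; the returned r is the Pearson correlation between bulk
    scores and per-line mean single-cell scores over lines with both
    (at least 4 required).
    """
    per_line: dict[str, list[float]] = {}
    for key, val in sc_scores.items():
        if isinstance(key, tuple):
            line = str(key[0])
            per_line.setdefault(line, []).append(float(val))
        else:
            per_line.setdefault(str(key), []).extend(float(v) for v in np.atleast_1d(val))
    per_line_mean = {line: float(np.mean(v)) for line, v in per_line.items() if v}
    shared = sorted(set(bulk_scores) & set(per_line_mean))
    if len(shared) < 4:
        raise NehetError(f"only {len(shared)} lines with both bulk and single-cell scores")
    b = np.array([bulk_scores[line] for line in shared])
    s = np.array([per_line_mean[line] for line in shared])
    r = float(stats.pearsonr(b, s).statistic)
    return r, len(shared), per_line_mean
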