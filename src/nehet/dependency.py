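"""Multi-criteria prioritization of selective gene vulnerabilities.

A gene is a credible selective dependency when its RNAi and CRISPR effect
scores agree (Pearson r > 0.4 across shared cell lines) and both
anticorrelate with the gene's own expression (r < -0.4): lines expressing
the gene highly are the lines that need it. Effect scores follow the
DepMap convention — more negative means stronger dependency. Selected
genes are then profiled for lineage selectivity by correlating their
effect scores with NE scores: negative r means high-NE lines are more
dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .core import ExpressionMatrix, FeatureMatrix, NehetError

__all__ = ["VulnerabilityRecord", "VulnerabilityScreen", "screen_vulnerabilities", "lineage_selectivity"]


@dataclass
class VulnerabilityRecord:
    gene: str
    r_rnai_crispr: float
    r_rnai_expr: float
    r_crispr_expr: float
    n_rnai_crispr: int
    n_rnai_expr: int
    n_crispr_expr: int
    selected: bool
    r_effect_ne: dict[str, float] = field(default_factory=dict)
    n_effect_ne: dict[str, int] = field(default_factory=dict)


def _pair_r(a: pd.Series, b: pd.Series, min_n: int) -> tuple[float, int] | None:
    shared = a.dropna().index.intersection(b.dropna().index)
    if len(shared) < min_n:
        return None
    x, y = a[shared].to_numpy(), b[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic), len(shared)


def screen_vulnerabilities(
    rnai: FeatureMatrix,
    crispr: FeatureMatrix,
    expr: ExpressionMatrix,
    min_n: int = 8,
    r_consistency: float = 0.4,
    r_anticorr: float = -0.4,
) -> list[VulnerabilityRecord]:
    """Screen genes for cancer-selective dependency evidence.

    For every gene present in all three matrices computes, on
    pairwise-complete shared samples, the RNAi-CRISPR, RNAi-expression and
    CRISPR-expression Pearson correlations; a gene is selected when
    r(RNAi, CRISPR) > ``r_consistency`` and both effect-expression
    correlations fall below ``r_anticorr`` (strict inequalities). Genes
    with constant effect scores or insufficient overlap are skipped.
    """
    genes = [
        g
        for g in rnai.feature_ids
        if g in set(crispr.feature_ids) and g in set(expr.feature_ids)
    ]
    if not genes:
        raise NehetError("no gene shared across RNAi, CRISPR and expression matrices")
    min_n = max(int(min_n), 4)
    records: list[VulnerabilityRecord] = []
    for g in genes:
        rn, cr, ex = rnai.values.loc[g], crispr.values.loc[g], expr.values.loc[g]
        rc = _pair_r(rn, cr, min_n)
        re_ = _pair_r(rn, ex, min_n)
        ce = _pair_r(cr, ex, min_n)
        if rc is None or re_ is None or ce is None:
            continue
        selected = (
            rc[0] > r_consistency and re_[0] < r_anticorr and ce[0] < r_anticorr
        )
        records.append(
            VulnerabilityRecord(
                gene=g,
                r_rnai_crispr=rc[0],
                r_rnai_expr=re_[0],
                r_crispr_expr=ce[0],
                n_rnai_crispr=rc[1],
                n_rnai_expr=re_[1],
                n_crispr_expr=ce[1],
                selected=selected,
            )
        )
    if not records:
        raise NehetError("no gene with sufficient cross-matrix overlap")
    return records


def lineage_selectivity(
    records: Sequence[VulnerabilityRecord],
    ne_scores: Mapping[str, float],
    effect: FeatureMatrix,
    min_n: int = 8,
) -> list[VulnerabilityRecord]:
    """Correlate selected genes' effect scores with NE scores.

    Populates ``r_effect_ne[effect.modality]`` on each selected record; a
    negative value means high-NE lines carry more-negative effect scores,
    i.e. an NE-selective dependency. Genes absent from the effect matrix
    (or with insufficient overlap) are skipped and left unpopulated.
    """
    score_series = pd.Series({k: v for k, v in ne_scores.items()}, dtype=float)
    present = set(effect.feature_ids)
    for rec in records:
        if not rec.selected or rec.gene not in present:
            continue
        res = _pair_r(effect.values.loc[rec.gene], score_series, max(int(min_n), 4))
        if res is None:
            continue
        rec.r_effect_ne[effect.modality] = res[0]
        rec.n_effect_ne[effect.modality] = res[1]
    return list(records)


def records_to_frame(records: Sequence[VulnerabilityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "gene": r.gene,
            "r_rnai_crispr": r.r_rnai_crispr,
            "r_rnai_expr": r.r_rnai_expr,
            "r_crispr_expr": r.r_crispr_expr,
            "n_rnai_crispr": r.n_rnai_crispr,
            "n_rnai_expr": r.n_rnai_expr,
            "n_crispr_expr": r.n_crispr_expr,
            "selected": r.selected,
        }
        for mod, val in r.r_effect_ne.items():
            row[f"r_ne_{mod}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


class VulnerabilityScreen(BaseEstimator):
    """Selective-dependency screen estimator (scikit-learn style).

    ``fit(rnai, crispr, expr)`` computes the three per-gene correlations
    and sets ``records_`` and ``selected_genes_``; ``add_ne_selectivity``
    annotates selected genes with their NE-score correlation.

    Parameters
    ----------
    min_n : int, default=8
        Minimum shared samples per correlation. Screens can be small (a
        handful of lines per lineage); instability is surfaced through the
        reported n rather than refusal.
    r_consistency, r_anticorr : float
        Strict selection thresholds for the RNAi-CRISPR agreement and the
        effect-expression anticorrelations.
    """

    def __init__(
        self,
        min_n: int = 8,
        r_consistency: float = 0.4,
        r_anticorr: float = -0.4,
    ):
        self.min_n = min_n
        self.r_consistency = r_consistency
        self.r_anticorr = r_anticorr

    def fit(self, rnai: FeatureMatrix, crispr: FeatureMatrix, expr: ExpressionMatrix):
        self.records_ = screen_vulnerabilities(
            rnai,
            crispr,
            expr,
            min_n=self.min_n,
            r_consistency=self.r_consistency,
            r_anticorr=self.r_anticorr,
        )
        self.selected_genes_ = [r.gene for r in self.records_ if r.selected]
        return self

    def add_ne_selectivity(self, ne_scores: Mapping[str, float], effect: FeatureMatrix):
        if not hasattr(self, "records_"):
            raise NehetError("VulnerabilityScreen is not fitted")
        lineage_selectivity(self.records_, ne_scores, effect, min_n=self.min_n)
        return self
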