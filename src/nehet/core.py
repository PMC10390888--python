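"""Shared domain containers for cell-line panel analysis.

Matrices follow the genes/features x samples orientation used by the
expression and screen files this package consumes. Values are real-valued
(expression is conventionally log2(TPM+1), but that is a documentation
convention, not enforced). Missing values are explicit NaN markers; every
downstream correlation uses pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NehetError",
    "FeatureMatrix",
    "ExpressionMatrix",
    "SignatureTable",
    "SampleAnnotation",
    "StudyPanel",
    "MetaResult",
    "StudyRecord",
    "validate_panel",
    "align_samples",
]

MODALITIES = frozenset(
    {
        "expression",
        "rppa",
        "metabolite",
        "drug",
        "dependency_rnai",
        "dependency_crispr",
        "mirna",
        "histone_ptm",
    }
)


class NehetError(ValueError):
    """Domain error raised on contract violations."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i).strip() for i in ids]
    seen: set[str] = set()
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise NehetError(f"duplicate {what} id(s): {sorted(set(dups))}")
    return ids


class FeatureMatrix:
    """Named features x samples matrix with a declared modality.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns, or a
        2-D array accompanied by ``feature_ids`` and ``sample_ids``.
    modality
        One of the recognized modalities. For ``drug`` matrices the
        convention is that a lower value means higher sensitivity.
    """

    def __init__(
        self,
        values,
        modality: str,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ):
        if modality not in MODALITIES:
            raise NehetError(f"unknown modality {modality!r}")
        if isinstance(values, pd.DataFrame):
            df = values.copy()
            df.index = _check_unique(df.index, "feature")
            df.columns = _check_unique(df.columns, "sample")
        else:
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 2:
                raise NehetError("values must be 2-dimensional")
            if feature_ids is None or sample_ids is None:
                raise NehetError("feature_ids and sample_ids required for array input")
            df = pd.DataFrame(
                arr,
                index=_check_unique(feature_ids, "feature"),
                columns=_check_unique(sample_ids, "sample"),
            )
        df = df.astype(float)
        with np.errstate(invalid="ignore"):
            bad = np.isinf(df.to_numpy())
        if bad.any():
            raise NehetError("matrix contains non-finite (infinite) values")
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise NehetError("matrix must have at least one feature and one sample")
        self.values = df
        self.modality = modality

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover
        f, s = self.shape
        return f"<{type(self).__name__} {self.modality}: {f} features x {s} samples>"


class ExpressionMatrix(FeatureMatrix):
    """Genes x samples log-scale expression matrix (convention log2(TPM+1))."""

    def __init__(self, values, gene_ids=None, sample_ids=None):
        super().__init__(
            values, "expression", feature_ids=gene_ids, sample_ids=sample_ids
        )

    @property
    def gene_ids(self) -> list[str]:
        return self.feature_ids


@dataclass
class SignatureTable:
    """Gene signature with group reference vectors.

    The canonical signature holds 25 NE and 25 non-NE genes, each with its
    mean expression (or weight) in the NE and in the non-NE cell-line
    reference group; any signature of at least three genes is accepted.
    """

    genes: list[str]
    ne_ref: np.ndarray
    non_ne_ref: np.ndarray
    group: list[str]

    def __post_init__(self):
        self.genes = _check_unique(self.genes, "signature gene")
        self.ne_ref = np.asarray(self.ne_ref, dtype=float)
        self.non_ne_ref = np.asarray(self.non_ne_ref, dtype=float)
        n = len(self.genes)
        if n < 2:
            raise NehetError("signature must contain at least 2 genes")
        if not (len(self.ne_ref) == len(self.non_ne_ref) == len(self.group) == n):
            raise NehetError("signature columns must all have the same length")
        bad_groups = set(self.group) - {"NE", "non-NE"}
        if bad_groups:
            raise NehetError(f"unknown signature group label(s): {sorted(bad_groups)}")
        for name, ref in (("ne_ref", self.ne_ref), ("non_ne_ref", self.non_ne_ref)):
            if not np.all(np.isfinite(ref)):
                raise NehetError(f"{name} contains non-finite values")
            if np.ptp(ref) == 0:
                raise NehetError(f"{name} is constant; correlation undefined")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "group": self.group,
                "ne_ref": self.ne_ref,
                "non_ne_ref": self.non_ne_ref,
            }
        )


@dataclass
class SampleAnnotation:
    """Per-sample metadata; ``amplification`` houses the MYCN-status covariate."""

    sample_id: str
    lineage: str = ""
    study: str = ""
    amplification: int | None = None
    tf_class: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.sample_id = str(self.sample_id).strip()
        if self.amplification is not None and self.amplification not in (0, 1):
            raise NehetError(
                f"amplification must be 0/1 or None, got {self.amplification!r}"
            )


@dataclass
class StudyPanel:
    """One dataset: modality-keyed matrices plus sample annotations."""

    study_id: str
    matrices: dict[str, FeatureMatrix]
    annotations: list[SampleAnnotation] = field(default_factory=list)
    ne_scores: dict[str, float] | None = None

    def matrix(self, modality: str) -> FeatureMatrix:
        if modality not in self.matrices:
            raise NehetError(
                f"panel {self.study_id!r} has no {modality!r} matrix "
                f"(available: {sorted(self.matrices)})"
            )
        return self.matrices[modality]

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": a.sample_id,
                    "lineage": a.lineage,
                    "study": a.study,
                    "amplification": a.amplification,
                    "tf_class": a.tf_class,
                }
                for a in self.annotations
            ]
        )


@dataclass
class StudyRecord:
    """One study's contribution to a meta-analysis."""

    study_id: str
    r: float
    n: int


@dataclass
class MetaResult:
    """Meta-analytically pooled correlation with CI and heterogeneity."""

    per_study: list[StudyRecord]
    pooled_r: float
    ci_low: float
    ci_high: float
    p_value: float
    heterogeneity_tau2: float
    model: str

    def __post_init__(self):
        if not (self.ci_low <= self.pooled_r <= self.ci_high):
            raise NehetError("pooled_r must lie within its confidence interval")
        if self.heterogeneity_tau2 < 0:
            raise NehetError("tau2 must be nonnegative")


def validate_panel(panel: StudyPanel) -> list[str]:
    """Check panel invariants; returns one diagnostic string per violation.

    An empty list means the panel is well formed. Checked: unique
    annotation sample ids, declared modalities consistent with matrix keys,
    every matrix sample annotated, and every annotated sample present in at
    least one matrix.
    """
    diags: list[str] = []
    seen: set[str] = set()
    for ann in panel.annotations:
        if ann.sample_id in seen:
            diags.append(f"duplicate sample id in annotations: {ann.sample_id!r}")
        seen.add(ann.sample_id)
    matrix_samples: set[str] = set()
    for key, fm in panel.matrices.items():
        if fm.modality != key:
            diags.append(
                f"matrix registered under {key!r} declares modality {fm.modality!r}"
            )
        matrix_samples.update(fm.sample_ids)
        if panel.annotations:
            missing = sorted(set(fm.sample_ids) - seen)
            for sid in missing:
                diags.append(
                    f"sample {sid!r} in {key} matrix is absent from annotations"
                )
    for ann in panel.annotations:
        if matrix_samples and ann.sample_id not in matrix_samples:
            diags.append(
                f"annotated sample {ann.sample_id!r} appears in no matrix"
            )
    return diags


def align_samples(a: FeatureMatrix, b: FeatureMatrix) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Restrict two matrices to their shared samples, in identical order.

    The shared samples keep the order in which they appear in ``a``;
    aligning a matrix with itself is the identity.
    """
    shared_set = set(a.sample_ids) & set(b.sample_ids)
    if not shared_set:
        raise NehetError(
            f"no shared samples between matrices "
            f"({len(a.sample_ids)} vs {len(b.sample_ids)} samples)"
        )
    shared = [s for s in a.sample_ids if s in shared_set]
    out_a = FeatureMatrix(a.values.loc[:, shared], a.modality)
    out_b = FeatureMatrix(b.values.loc[:, shared], b.modality)
    return out_a, out_b
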