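"""Synthetic multi-study cell-line panel generator with planted NE structure.

Emulates the statistical structure the analysis pipeline assumes, without
any external download:

* a latent NE state per cell line, drawn per lineage from a truncated
  normal on [-1, 1] (NE-type lineages high, others low);
* a 50-gene signature whose NE genes load positively and non-NE genes
  negatively on the state, plus per-lineage marker genes and pure-noise
  background genes; reference vectors are the group means of the top and
  bottom state quartiles, emitted as a SignatureTable;
* omic feature blocks (RPPA, metabolites) with planted correlations
  f = rho * z + sqrt(1 - rho^2) * noise against the standardized state z;
* several drug screens re-measuring shared compounds on overlapping line
  subsets: a consistent drug has one latent profile observed per screen
  with noise set so that the expected interstudy correlation equals the
  configured reliability; null drugs are independent noise per screen;
* RNAi and CRISPR effect scores as two noisy observations of a shared
  essentiality that anticorrelates with the planted gene's expression
  (selective genes) or is independent of it (null genes);
* a MYCN-like amplification flag drawn from a logistic model on the state,
  with the gene's expression a * amp + b * state + noise;
* per-line single-cell profiles with line-specific within-line state
  spread and independent dropout zeroing.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .core import (
    ExpressionMatrix,
    FeatureMatrix,
    NehetError,
    SampleAnnotation,
    SignatureTable,
    StudyPanel,
)

__all__ = [
    "LineageConfig",
    "FeatureBlockConfig",
    "DrugScreenConfig",
    "DependencyConfig",
    "MycnConfig",
    "SingleCellConfig",
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticPanelSet",
    "generate_panel",
    "write_fixtures",
]


@dataclass(frozen=True)
class LineageConfig:
    name: str
    n_lines: int
    state_mean: float
    state_sd: float


@dataclass(frozen=True)
class FeatureBlockConfig:
    modality: str
    n_planted: int = 10
    n_null: int = 30
    rho_low: float = 0.4
    rho_high: float = 0.7


@dataclass(frozen=True)
class DrugScreenConfig:
    n_datasets: int = 4
    reliability: float = 0.8
    n_consistent: int = 20
    n_null: int = 80
    lines_per_dataset: int = 50
    # mechanism-of-action classes cycled over the consistent drugs, each
    # with the planted correlation between drug value and the NE state
    # (lower value = more sensitive, so negative rho = NE-selective drug)
    moa_classes: tuple = (
        ("MEKi", -0.4),
        ("HSP90i", -0.4),
        ("BCLi", 0.4),
        ("misc", 0.0),
    )


@dataclass(frozen=True)
class DependencyConfig:
    n_selective: int = 10
    n_null: int = 40
    effect_expr_rho: float = -0.7
    reliability: float = 0.8
    # loading of each selective gene's expression on the NE state; high
    # |loading| makes a lineage-selective (NE or non-NE) dependency, zero
    # a cancer-selective one. Cycled if shorter than n_selective.
    lineage_loadings: tuple = (0.9, 0.9, 0.9, -0.9, 0.0, 0.0)


@dataclass(frozen=True)
class MycnConfig:
    logistic_slope: float = 1.5
    amp_effect: float = 2.0
    ne_effect: float = 1.5
    noise_sd: float = 0.5


@dataclass(frozen=True)
class SingleCellConfig:
    cells_per_line: int = 30
    within_line_sd_low: float = 0.1
    within_line_sd_high: float = 0.4
    dropout_rate: float = 0.2
    n_background: int = 50


DEFAULT_LINEAGES = (
    LineageConfig("SCLC", 15, 0.6, 0.3),
    LineageConfig("neuroblastoma", 15, 0.5, 0.3),
    LineageConfig("lung_adeno", 15, -0.5, 0.3),
    LineageConfig("melanoma", 15, -0.4, 0.3),
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    lineages: tuple = DEFAULT_LINEAGES
    n_ne_genes: int = 25
    n_non_ne_genes: int = 25
    signature_effect: float = 1.0
    n_background_genes: int = 200
    n_markers_per_lineage: int = 30
    marker_effect: float = 2.0
    expression_noise_sd: float = 0.5
    feature_blocks: tuple = (
        FeatureBlockConfig("rppa"),
        FeatureBlockConfig("metabolite"),
    )
    drugs: DrugScreenConfig = DrugScreenConfig()
    dependency: DependencyConfig = DependencyConfig()
    mycn: MycnConfig = MycnConfig()
    single_cell: SingleCellConfig = SingleCellConfig()

    def validate(self) -> None:
        if self.n_ne_genes < 2 or self.n_non_ne_genes < 2:
            raise NehetError("need at least 2 genes per signature group")
        for lin in self.lineages:
            if lin.state_sd < 0 or lin.n_lines < 1:
                raise NehetError(f"invalid lineage config {lin}")
        for blk in self.feature_blocks:
            for rho in (blk.rho_low, blk.rho_high):
                if not -1 <= rho <= 1:
                    raise NehetError(f"feature rho {rho} outside [-1, 1]")
        for name, val in (
            ("drug reliability", self.drugs.reliability),
            ("dependency reliability", self.dependency.reliability),
            ("dropout rate", self.single_cell.dropout_rate),
        ):
            if not 0 <= val <= 1:
                raise NehetError(f"{name} must lie in [0, 1], got {val}")
        if not -1 <= self.dependency.effect_expr_rho <= 1:
            raise NehetError("effect_expr_rho must lie in [-1, 1]")
        if self.expression_noise_sd < 0 or self.mycn.noise_sd < 0:
            raise NehetError("noise sds must be nonnegative")
        if self.drugs.lines_per_dataset > sum(l.n_lines for l in self.lineages):
            raise NehetError("lines_per_dataset exceeds total lines")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    """Ground truth of one generated panel set."""

    state: dict[str, float]
    lineage: dict[str, str]
    amplification: dict[str, int]
    feature_rho: dict[str, dict[str, float]]
    consistent_drugs: list[str]
    null_drugs: list[str]
    drug_moa: dict[str, str]
    moa_rho: dict[str, float]
    drug_rho: dict[str, float]
    selective_genes: list[str]
    null_dep_genes: list[str]
    dep_loading: dict[str, float]
    cell_states: dict[str, float]
    cell_line_map: dict[str, str]
    config_hash: str
    seed: int

    def to_json_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticPanelSet:
    """Bulk panel, screen datasets, single-cell panel, signature, truth."""

    bulk: StudyPanel
    screens: list[StudyPanel]
    single_cell: StudyPanel
    signature: SignatureTable
    truth: SyntheticTruth

    def __iter__(self):
        return iter((self.bulk, self.screens, self.single_cell, self.truth))

    def screen(self, study_id: str) -> StudyPanel:
        for p in self.screens:
            if p.study_id == study_id:
                return p
        raise NehetError(f"no screen dataset {study_id!r}")

    @property
    def drug_datasets(self) -> list[FeatureMatrix]:
        return [p.matrix("drug") for p in self.screens if "drug" in p.matrices]


def _draw_states(rng: np.random.Generator, cfg: GeneratorConfig):
    lines, states, lineages = [], [], []
    for lin in cfg.lineages:
        if lin.state_sd == 0:
            s = np.full(lin.n_lines, float(np.clip(lin.state_mean, -1, 1)))
        else:
            a = (-1 - lin.state_mean) / lin.state_sd
            b = (1 - lin.state_mean) / lin.state_sd
            s = truncnorm.rvs(
                a, b, loc=lin.state_mean, scale=lin.state_sd,
                size=lin.n_lines, random_state=rng,
            )
        for i, val in enumerate(s):
            lines.append(f"{lin.name}_L{i + 1:02d}")
            states.append(float(val))
            lineages.append(lin.name)
    return lines, np.array(states), lineages


def _noise(rng, sd, size):
    return rng.normal(0.0, sd, size=size) if sd > 0 else np.zeros(size)


def _expression_block(rng, cfg, lines, states, lineages):
    """Bulk expression rows: signature, lineage markers, background."""
    n = len(lines)
    beta = cfg.signature_effect
    rows, names = [], []
    ne_genes = [f"NE_G{i + 1:02d}" for i in range(cfg.n_ne_genes)]
    nn_genes = [f"NN_G{i + 1:02d}" for i in range(cfg.n_non_ne_genes)]
    for g in ne_genes:
        base = rng.uniform(2, 8)
        rows.append(base + beta * states + _noise(rng, cfg.expression_noise_sd, n))
        names.append(g)
    for g in nn_genes:
        base = rng.uniform(2, 8)
        rows.append(base - beta * states + _noise(rng, cfg.expression_noise_sd, n))
        names.append(g)
    lineage_arr = np.array(lineages)
    for lin in cfg.lineages:
        member = (lineage_arr == lin.name).astype(float)
        for j in range(cfg.n_markers_per_lineage):
            base = rng.uniform(2, 8)
            rows.append(
                base
                + cfg.marker_effect * member
                + _noise(rng, cfg.expression_noise_sd, n)
            )
            names.append(f"MK_{lin.name}_{j + 1:02d}")
    for j in range(cfg.n_background_genes):
        base = rng.uniform(2, 8)
        rows.append(base + _noise(rng, max(cfg.expression_noise_sd, 0.0), n))
        names.append(f"BG_G{j + 1:03d}")
    return names, rows, ne_genes, nn_genes


def _signature_from_bulk(expr: pd.DataFrame, states, ne_genes, nn_genes):
    order = np.argsort(states)
    q = max(2, len(states) // 4)
    low = expr.columns[order[:q]]
    high = expr.columns[order[-q:]]
    genes = ne_genes + nn_genes
    ne_ref = expr.loc[genes, high].mean(axis=1).to_numpy()
    non_ne_ref = expr.loc[genes, low].mean(axis=1).to_numpy()
    group = ["NE"] * len(ne_genes) + ["non-NE"] * len(nn_genes)
    return SignatureTable(genes, ne_ref, non_ne_ref, group)


def _planted_feature(rng, z, rho):
    eps = rng.normal(size=len(z))
    return rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps


def generate_panel(config: GeneratorConfig | None = None, seed: int | None = None) -> SyntheticPanelSet:
    """Generate the full multi-study panel set plus ground truth.

    Deterministic given the config (two calls with the same config yield
    identical panels). ``seed`` overrides ``config.seed`` when given.
    """
    cfg = config or GeneratorConfig()
    if seed is not None:
        cfg = GeneratorConfig(**{**asdict_shallow(cfg), "seed": int(seed)})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    lines, states, lineages = _draw_states(rng, cfg)
    n = len(lines)
    z = (states - states.mean()) / states.std()

    # --- bulk expression ---------------------------------------------------
    names, rows, ne_genes, nn_genes = _expression_block(rng, cfg, lines, states, lineages)

    # MYCN-like amplification model
    amp = (rng.random(n) < expit(cfg.mycn.logistic_slope * states)).astype(int)
    mycn_base = rng.uniform(3, 6)
    names.append("MYCN_like")
    rows.append(
        mycn_base
        + cfg.mycn.amp_effect * amp
        + cfg.mycn.ne_effect * states
        + _noise(rng, cfg.mycn.noise_sd, n)
    )

    # dependency genes: expression component shared with the essentiality
    dep = cfg.dependency
    loadings = [
        dep.lineage_loadings[i % len(dep.lineage_loadings)]
        for i in range(dep.n_selective)
    ]
    selective_genes = [f"DEP_G{i + 1:02d}" for i in range(dep.n_selective)]
    null_dep_genes = [f"DEPN_G{i + 1:02d}" for i in range(dep.n_null)]
    dep_expr: dict[str, np.ndarray] = {}
    for g, lam in zip(selective_genes, loadings):
        x = lam * z + np.sqrt(max(0.0, 1 - lam**2)) * rng.normal(size=n)
        dep_expr[g] = x
        names.append(g)
        rows.append(rng.uniform(2, 8) + x)
    for g in null_dep_genes:
        x = rng.normal(size=n)
        dep_expr[g] = x
        names.append(g)
        rows.append(rng.uniform(2, 8) + x)

    expr_df = pd.DataFrame(np.vstack(rows), index=names, columns=lines)
    signature = _signature_from_bulk(expr_df, states, ne_genes, nn_genes)

    # --- omic feature blocks ----------------------------------------------
    feature_rho: dict[str, dict[str, float]] = {}
    omic_matrices: dict[str, FeatureMatrix] = {}
    for blk in cfg.feature_blocks:
        rho_map: dict[str, float] = {}
        frows, fnames = [], []
        for i in range(blk.n_planted):
            rho = float(rng.uniform(blk.rho_low, blk.rho_high))
            if rng.random() < 0.5:
                rho = -rho
            fid = f"{blk.modality}_p{i + 1:02d}"
            rho_map[fid] = rho
            fnames.append(fid)
            frows.append(_planted_feature(rng, z, rho))
        for i in range(blk.n_null):
            fid = f"{blk.modality}_n{i + 1:02d}"
            rho_map[fid] = 0.0
            fnames.append(fid)
            frows.append(rng.normal(size=n))
        feature_rho[blk.modality] = rho_map
        omic_matrices[blk.modality] = FeatureMatrix(
            pd.DataFrame(np.vstack(frows), index=fnames, columns=lines), blk.modality
        )

    annotations = [
        SampleAnnotation(line, lineage=lin, study="bulk", amplification=int(a))
        for line, lin, a in zip(lines, lineages, amp)
    ]
    bulk = StudyPanel(
        "bulk",
        {"expression": ExpressionMatrix(expr_df), **omic_matrices},
        annotations=annotations,
    )

    # --- drug screens -------------------------------------------------------
    drugs = cfg.drugs
    consistent = [f"drug_C{i + 1:03d}" for i in range(drugs.n_consistent)]
    nulls = [f"drug_N{i + 1:03d}" for i in range(drugs.n_null)]
    moa_names = [m for m, _ in drugs.moa_classes]
    moa_rho = {m: float(r) for m, r in drugs.moa_classes}
    drug_moa = {
        d: moa_names[i % len(moa_names)] for i, d in enumerate(consistent)
    }
    drug_rho = {d: moa_rho[drug_moa[d]] for d in consistent}
    latent = {
        d: _planted_feature(rng, z, drug_rho[d]) for d in consistent
    }
    rel = drugs.reliability
    screens: list[StudyPanel] = []
    for d_idx in range(drugs.n_datasets):
        subset = np.sort(rng.choice(n, size=drugs.lines_per_dataset, replace=False))
        cols = [lines[i] for i in subset]
        drows, dnames = [], []
        for d in consistent:
            obs = np.sqrt(rel) * latent[d][subset] + np.sqrt(1 - rel) * rng.normal(
                size=len(subset)
            )
            drows.append(obs)
            dnames.append(d)
        for d in nulls:
            drows.append(rng.normal(size=len(subset)))
            dnames.append(d)
        fm = FeatureMatrix(
            pd.DataFrame(np.vstack(drows), index=dnames, columns=cols), "drug"
        )
        fm.label = f"drug_screen_{d_idx + 1}"
        screens.append(
            StudyPanel(
                fm.label,
                {"drug": fm},
                annotations=[
                    SampleAnnotation(c, lineage=lineages[i], study=fm.label)
                    for c, i in zip(cols, subset)
                ],
            )
        )

    # --- dependency screens (RNAi + CRISPR) --------------------------------
    rho_ee = dep.effect_expr_rho
    rel_d = dep.reliability
    rnai_rows, crispr_rows, dep_names = [], [], []
    for g in selective_genes:
        ess = rho_ee * dep_expr[g] + np.sqrt(max(0.0, 1 - rho_ee**2)) * rng.normal(size=n)
        rnai_rows.append(np.sqrt(rel_d) * ess + np.sqrt(1 - rel_d) * rng.normal(size=n))
        crispr_rows.append(np.sqrt(rel_d) * ess + np.sqrt(1 - rel_d) * rng.normal(size=n))
        dep_names.append(g)
    for g in null_dep_genes:
        rnai_rows.append(rng.normal(size=n))
        crispr_rows.append(rng.normal(size=n))
        dep_names.append(g)
    for mod, mat_rows, study in (
        ("dependency_rnai", rnai_rows, "rnai"),
        ("dependency_crispr", crispr_rows, "crispr"),
    ):
        fm = FeatureMatrix(
            pd.DataFrame(np.vstack(mat_rows), index=dep_names, columns=lines), mod
        )
        fm.label = study
        screens.append(
            StudyPanel(
                study,
                {mod: fm},
                annotations=[
                    SampleAnnotation(line, lineage=lin, study=study)
                    for line, lin in zip(lines, lineages)
                ],
            )
        )

    # --- single cells -------------------------------------------------------
    sc = cfg.single_cell
    wsd = rng.uniform(sc.within_line_sd_low, sc.within_line_sd_high, size=n)
    sc_genes = ne_genes + nn_genes + [f"BG_G{j + 1:03d}" for j in range(sc.n_background)]
    bases = {g: rng.uniform(2, 8) for g in sc_genes}
    cell_cols, cell_states, cell_line_map = [], {}, {}
    profiles = []
    beta = cfg.signature_effect
    for li, line in enumerate(lines):
        cs = states[li] + _noise(rng, wsd[li], sc.cells_per_line)
        for ci in range(sc.cells_per_line):
            col = f"{line}.c{ci + 1:02d}"
            cell_cols.append(col)
            cell_states[col] = float(cs[ci])
            cell_line_map[col] = line
            vals = np.empty(len(sc_genes))
            for gi, g in enumerate(sc_genes):
                if g.startswith("NE_"):
                    mu = bases[g] + beta * cs[ci]
                elif g.startswith("NN_"):
                    mu = bases[g] - beta * cs[ci]
                else:
                    mu = bases[g]
                vals[gi] = mu
            vals += _noise(rng, cfg.expression_noise_sd, len(sc_genes))
            profiles.append(vals)
    sc_df = pd.DataFrame(np.array(profiles).T, index=sc_genes, columns=cell_cols)
    if sc.dropout_rate > 0:
        mask = rng.random(sc_df.shape) < sc.dropout_rate
        sc_df = sc_df.mask(mask, 0.0)
    single_cell = StudyPanel(
        "single_cell",
        {"expression": ExpressionMatrix(sc_df)},
        annotations=[
            SampleAnnotation(
                c,
                lineage=dict(zip(lines, lineages))[cell_line_map[c]],
                study="single_cell",
                extra={"cell_line": cell_line_map[c]},
            )
            for c in cell_cols
        ],
    )

    truth = SyntheticTruth(
        state=dict(zip(lines, map(float, states))),
        lineage=dict(zip(lines, lineages)),
        amplification=dict(zip(lines, map(int, amp))),
        feature_rho=feature_rho,
        consistent_drugs=consistent,
        null_drugs=nulls,
        drug_moa=drug_moa,
        moa_rho=moa_rho,
        drug_rho=drug_rho,
        selective_genes=selective_genes,
        null_dep_genes=null_dep_genes,
        dep_loading=dict(zip(selective_genes, map(float, loadings))),
        cell_states=cell_states,
        cell_line_map=cell_line_map,
        config_hash=cfg.hash(),
        seed=cfg.seed,
    )
    return SyntheticPanelSet(bulk, screens, single_cell, signature, truth)


def asdict_shallow(cfg: GeneratorConfig) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def write_fixtures(config: GeneratorConfig, out_dir) -> dict:
    """Serialize a generated panel set as TSV + JSON fixtures.

    Writes every matrix, the annotations, the signature, the truth JSON,
    and a manifest recording the seed, config hash and file list; returns
    the manifest dict.
    """
    from . import io as nio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = generate_panel(config)
    files: list[str] = []

    def _write_matrix(fm: FeatureMatrix, name: str):
        path = out / name
        nio.write_matrix(fm, path)
        files.append(name)

    _write_matrix(panels.bulk.matrix("expression"), "bulk_expression.tsv")
    for blk in config.feature_blocks:
        _write_matrix(panels.bulk.matrix(blk.modality), f"bulk_{blk.modality}.tsv")
    for p in panels.screens:
        mod = next(iter(p.matrices))
        _write_matrix(p.matrix(mod), f"{p.study_id}.tsv")
    _write_matrix(panels.single_cell.matrix("expression"), "sc_expression.tsv")
    panels.bulk.annotation_frame().to_csv(out / "annotations.tsv", sep="\t", index=False)
    files.append("annotations.tsv")
    nio.write_signature(panels.signature, out / "signature.tsv")
    files.append("signature.tsv")
    (out / "truth.json").write_text(json.dumps(panels.truth.to_json_dict(), indent=1))
    files.append("truth.json")
    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
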