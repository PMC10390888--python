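import numpy as np
import pytest
from scipy import stats

from nehet.core import NehetError
from nehet.dependency import (
    VulnerabilityScreen,
    lineage_selectivity,
    screen_vulnerabilities,
)

from conftest import make_matrix


def exact_corr_vector(x, rho, rng):
    """Construct y with Pearson r(x, y) exactly rho (Gram-Schmidt)."""
    x = np.asarray(x, dtype=float)
    e = rng.normal(size=len(x))
    xc = x - x.mean()
    ec = e - e.mean()
    ec = ec - (ec @ xc) / (xc @ xc) * xc  # orthogonal to x
    return rho * xc / np.linalg.norm(xc) + np.sqrt(1 - rho**2) * ec / np.linalg.norm(ec)


class TestScreenVulnerabilities:
    def test_perfect_selective_dependency(self):
        rng = np.random.default_rng(0)
        expr_v = rng.normal(size=30)
        rnai = make_matrix(-expr_v[None, :], "dependency_rnai", features=["G"])
        crispr = make_matrix(-expr_v[None, :], "dependency_crispr", features=["G"])
        expr = make_matrix(expr_v[None, :], "expression", features=["G"])
        (rec,) = screen_vulnerabilities(rnai, crispr, expr, min_n=8)
        assert rec.r_rnai_crispr == pytest.approx(1.0)
        assert rec.r_rnai_expr == pytest.approx(-1.0)
        assert rec.r_crispr_expr == pytest.approx(-1.0)
        assert rec.selected

    def test_independent_noise_not_selected(self):
        rng = np.random.default_rng(1)
        rnai = make_matrix(rng.normal(size=(1, 50)), "dependency_rnai", features=["G"])
        crispr = make_matrix(rng.normal(size=(1, 50)), "dependency_crispr", features=["G"])
        expr = make_matrix(rng.normal(size=(1, 50)), "expression", features=["G"])
        (rec,) = screen_vulnerabilities(rnai, crispr, expr, min_n=8)
        assert not rec.selected
        assert abs(rec.r_rnai_crispr) < 0.4

    def test_boundary_correlation_exactly_0p4_not_selected(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        rnai_v = base
        crispr_v = exact_corr_vector(base, 0.4, rng)  # r(rnai, crispr) = 0.4
        expr_v = -base  # both anticorrelation criteria pass easily
        rnai = make_matrix(rnai_v[None, :], "dependency_rnai", features=["G"])
        crispr = make_matrix(crispr_v[None, :], "dependency_crispr", features=["G"])
        expr = make_matrix(expr_v[None, :], "expression", features=["G"])
        (rec,) = screen_vulnerabilities(rnai, crispr, expr, min_n=8)
        assert rec.r_rnai_crispr == pytest.approx(0.4, abs=1e-12)
        assert not rec.selected

    def test_selection_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        n = 40
        expr_v = rng.normal(size=n)
        noise = 0.3 * rng.normal(size=(2, n))
        rnai_v = -expr_v + noise[0]
        crispr_v = -expr_v + noise[1]
        mk = lambda v, mod: make_matrix(v[None, :], mod, features=["G"])
        r1 = screen_vulnerabilities(
            mk(rnai_v, "dependency_rnai"), mk(crispr_v, "dependency_crispr"),
            mk(expr_v, "expression"),
        )[0]
        r2 = screen_vulnerabilities(
            mk(3.5 * rnai_v - 2, "dependency_rnai"),
            mk(0.25 * crispr_v + 7, "dependency_crispr"),
            mk(expr_v, "expression"),
        )[0]
        assert r1.selected == r2.selected
        assert r1.r_rnai_crispr == pytest.approx(r2.r_rnai_crispr, abs=1e-12)

    def test_identical_modalities_give_unit_consistency(self, panels):
        rnai = panels.screen("rnai").matrix("dependency_rnai")
        expr = panels.bulk.matrix("expression")
        recs = screen_vulnerabilities(rnai, rnai, expr, min_n=8)
        assert all(r.r_rnai_crispr == pytest.approx(1.0) for r in recs)

    def test_planted_screen_sensitivity_and_specificity(self, panels):
        rnai = panels.screen("rnai").matrix("dependency_rnai")
        crispr = panels.screen("crispr").matrix("dependency_crispr")
        expr = panels.bulk.matrix("expression")
        recs = screen_vulnerabilities(rnai, crispr, expr, min_n=8)
        selected = {r.gene for r in recs if r.selected}
        truth = panels.truth
        sens = len(selected & set(truth.selective_genes)) / len(truth.selective_genes)
        spec = 1 - len(selected & set(truth.null_dep_genes)) / len(truth.null_dep_genes)
        assert sens >= 0.8
        assert spec >= 0.95

    def test_no_shared_genes_errors(self):
        a = make_matrix(np.eye(2), "dependency_rnai", features=["g1", "g2"])
        b = make_matrix(np.eye(2), "dependency_crispr", features=["g3", "g4"])
        e = make_matrix(np.eye(2), "expression", features=["g1", "g2"])
        with pytest.raises(NehetError, match="no gene"):
            screen_vulnerabilities(a, b, e)


class TestLineageSelectivity:
    def test_effect_equal_to_negated_score_is_ne_selective(self):
        rng = np.random.default_rng(0)
        score_v = rng.normal(size=30)
        scores = {f"s{j}": score_v[j] for j in range(30)}
        effect = make_matrix(-score_v[None, :], "dependency_rnai", features=["G"])
        from nehet.dependency import VulnerabilityRecord

        rec = VulnerabilityRecord("G", 1, -1, -1, 30, 30, 30, selected=True)
        lineage_selectivity([rec], scores, effect)
        assert rec.r_effect_ne["dependency_rnai"] == pytest.approx(-1.0)

    def test_orthogonal_effect_near_zero(self):
        rng = np.random.default_rng(1)
        score_v = rng.normal(size=200)
        scores = {f"s{j}": score_v[j] for j in range(200)}
        effect = make_matrix(rng.normal(size=(1, 200)), "dependency_rnai", features=["G"])
        from nehet.dependency import VulnerabilityRecord

        rec = VulnerabilityRecord("G", 1, -1, -1, 200, 200, 200, selected=True)
        lineage_selectivity([rec], scores, effect)
        assert abs(rec.r_effect_ne["dependency_rnai"]) < 0.2

    def test_absent_gene_skipped_without_error(self):
        from nehet.dependency import VulnerabilityRecord

        rec = VulnerabilityRecord("MISSING", 1, -1, -1, 30, 30, 30, selected=True)
        effect = make_matrix(np.random.default_rng(0).normal(size=(1, 30)),
                             "dependency_rnai", features=["G"])
        out = lineage_selectivity([rec], {f"s{j}": 0.1 * j for j in range(30)}, effect)
        assert out[0].r_effect_ne == {}

    def test_planted_ne_selective_gene_recovered(self, panels, bulk_scores):
        # selective genes whose expression loads +0.9 on the NE state have
        # essentiality anticorrelated with it: expected effect-score vs
        # NE-score correlation ~ sqrt(0.8) * (-0.7) * 0.9 = -0.56
        truth = panels.truth
        ne_sel = [g for g, lam in truth.dep_loading.items() if lam > 0.8]
        rnai = panels.screen("rnai").matrix("dependency_rnai")
        crispr = panels.screen("crispr").matrix("dependency_crispr")
        expr = panels.bulk.matrix("expression")
        screen = VulnerabilityScreen().fit(rnai, crispr, expr)
        screen.add_ne_selectivity(bulk_scores.score_map(), rnai)
        got = [
            r.r_effect_ne["dependency_rnai"]
            for r in screen.records_
            if r.gene in ne_sel and "dependency_rnai" in r.r_effect_ne
        ]
        assert got, "no NE-selective planted gene survived the screen"
        assert np.mean(got) == pytest.approx(-0.56, abs=0.2)
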