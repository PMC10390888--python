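import numpy as np
import pytest
from scipy import stats

from nehet.association import (
    adjusted_association,
    bulk_sc_agreement,
    correlate_features,
    meta_by_group,
    meta_pool,
    select_by_adjusted_p,
)
from nehet.core import NehetError
from nehet.simulate import GeneratorConfig, LineageConfig, generate_panel

from conftest import make_matrix


def bh_step_up(pvals):
    """Brute-force Benjamini-Hochberg step-up, the independent oracle."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top  # 1-based rank of this p-value
        running_min = min(running_min, pvals[idx] * m / rank)
        adj[idx] = running_min
    return adj


class TestCorrelateFeatures:
    def test_self_and_negated_feature(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=20)
        scores = {f"s{j}": s[j] for j in range(20)}
        fm = make_matrix(np.vstack([s, -s]), "rppa")
        recs = {r.feature_id: r for r in correlate_features(fm, scores)}
        assert recs["f0"].r == pytest.approx(1.0)
        assert recs["f1"].r == pytest.approx(-1.0)

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=60)
        f = 0.6 * z + np.sqrt(1 - 0.36) * rng.normal(size=60)
        scores = {f"s{j}": z[j] for j in range(60)}
        fm = make_matrix(f[None, :], "rppa")
        (rec,) = correlate_features(fm, scores)
        assert rec.r == pytest.approx(0.6, abs=0.2)
        assert rec.p_adjusted >= rec.p_value

    def test_bh_adjustment_matches_brute_force_step_up(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=30)
        fm = make_matrix(rng.normal(size=(18, 30)) + 0.3 * z, "rppa")
        scores = {f"s{j}": z[j] for j in range(30)}
        recs = correlate_features(fm, scores)
        oracle = bh_step_up(np.array([r.p_value for r in recs]))
        np.testing.assert_allclose([r.p_adjusted for r in recs], oracle, atol=1e-12)

    def test_min_n_excludes_sparse_features(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(2, 20))
        arr[1, 5:] = np.nan
        fm = make_matrix(arr, "rppa")
        scores = {f"s{j}": float(j) for j in range(20)}
        recs = correlate_features(fm, scores, min_n=10)
        assert [r.feature_id for r in recs] == ["f0"]

    def test_nothing_testable_errors(self):
        fm = make_matrix(np.ones((1, 12)), "rppa")
        with pytest.raises(NehetError):
            correlate_features(fm, {f"s{j}": float(j) for j in range(12)})


class TestSelectByAdjustedP:
    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=40)
        fm = make_matrix(rng.normal(size=(30, 40)) + np.outer(rng.uniform(0, 1, 30), z), "rppa")
        recs = correlate_features(fm, {f"s{j}": z[j] for j in range(40)})
        strict = select_by_adjusted_p(recs, 0.05)
        loose = select_by_adjusted_p(recs, 0.1)
        assert set(strict) <= set(loose)

    def test_all_null_returns_empty(self):
        from nehet.association import AssociationRecord

        recs = [AssociationRecord("f", 0.1, 20, 1.0, 1.0)]
        assert select_by_adjusted_p(recs, 0.05) == []

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_domain(self, bad):
        from nehet.association import AssociationRecord

        recs = [AssociationRecord("f", 0.1, 20, 0.5, 0.5)]
        with pytest.raises(NehetError):
            select_by_adjusted_p(recs, bad)

    def test_planted_panel_recovery(self):
        # 10 true features at rho 0.5, 90 null, n=60: BH at 0.05 should
        # recover at least 8 of the 10
        rng = np.random.default_rng(17)
        z = rng.normal(size=60)
        rows = [0.5 * z + np.sqrt(0.75) * rng.normal(size=60) for _ in range(10)]
        rows += [rng.normal(size=60) for _ in range(90)]
        fm = make_matrix(np.vstack(rows), "rppa")
        recs = correlate_features(fm, {f"s{j}": z[j] for j in range(60)})
        hits = set(select_by_adjusted_p(recs, 0.05))
        assert len(hits & {f"f{i}" for i in range(10)}) >= 8


class TestMetaPool:
    def test_identical_studies_pool_to_common_value(self):
        m = meta_pool([(0.5, 27), (0.5, 27)], model="random")
        assert m.pooled_r == pytest.approx(0.5)
        assert m.heterogeneity_tau2 == 0.0

    def test_single_study_degenerate(self):
        m = meta_pool([("s1", 0.4, 30)], model="fixed")
        se = 1 / np.sqrt(27)
        z = np.arctanh(0.4)
        assert m.pooled_r == pytest.approx(0.4)
        assert m.ci_low == pytest.approx(np.tanh(z - stats.norm.ppf(0.975) * se))
        assert m.ci_high == pytest.approx(np.tanh(z + stats.norm.ppf(0.975) * se))

    def test_fixed_effect_matches_hand_computed_fisher_z_average(self):
        # z1=atanh(0.3), w1=25; z2=atanh(0.6), w2=16; back-transformed
        # weighted mean = 0.4294547 (cross-checked against r-metafor FE)
        m = meta_pool([(0.3, 28), (0.6, 19)], model="fixed")
        assert m.pooled_r == pytest.approx(0.4294547, abs=1e-6)

    def test_dersimonian_laird_matches_reference(self):
        # same fixture under the DL random-effects model (r-metafor: DL
        # pooled r 0.4398204, tau2 0.02233506)
        m = meta_pool([(0.3, 28), (0.6, 19)], model="random")
        assert m.pooled_r == pytest.approx(0.4398204, abs=1e-6)
        assert m.heterogeneity_tau2 == pytest.approx(0.0223351, abs=1e-6)

    def test_equal_n_fixed_equals_mean_of_fisher_z(self):
        rs = [0.1, 0.35, 0.6]
        m = meta_pool([(r, 20) for r in rs], model="fixed")
        assert m.pooled_r == pytest.approx(np.tanh(np.mean(np.arctanh(rs))))

    def test_fixed_pooled_within_study_range(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            rs = rng.uniform(-0.9, 0.9, size=4)
            ns = rng.integers(5, 60, size=4)
            m = meta_pool(list(zip(rs, ns)), model="fixed")
            assert min(rs) - 1e-12 <= m.pooled_r <= max(rs) + 1e-12

    @pytest.mark.parametrize("bad", [[(0.5, 3)], [(1.0, 20)], [(-1.0, 20)]])
    def test_domain_errors(self, bad):
        with pytest.raises(NehetError):
            meta_pool(bad)


class TestMetaByGroup:
    def test_single_record_equals_meta_pool(self):
        out = meta_by_group([("d1", "MEK", 0.3, 25)])
        ref = meta_pool([(0.3, 25)])
        assert out["MEK"].pooled_r == pytest.approx(ref.pooled_r)

    def test_groups_are_independent(self):
        recs_a = [("d1", "A", 0.3, 25), ("d2", "A", 0.5, 30)]
        recs_b = [("d3", "B", -0.4, 40)]
        joint = meta_by_group(recs_a + recs_b)
        alone = meta_by_group(recs_a)
        assert joint["A"].pooled_r == pytest.approx(alone["A"].pooled_r)

    def test_empty_input_errors(self):
        with pytest.raises(NehetError):
            meta_by_group([])

    def test_planted_moa_class_recovered(self, panels):
        # all compounds of the BCLi class across all screens, correlated
        # with the latent state; the observed-scale planted correlation is
        # sqrt(reliability) * rho = sqrt(0.8) * 0.4
        truth = panels.truth
        state = truth.state
        records = []
        for screen, fm in zip(panels.screens, panels.drug_datasets):
            for d in truth.consistent_drugs:
                if truth.drug_moa[d] != "BCLi":
                    continue
                vals = fm.values.loc[d].dropna()
                r = stats.pearsonr(
                    vals.to_numpy(), np.array([state[s] for s in vals.index])
                ).statistic
                records.append((d, "BCLi", float(r), len(vals)))
        out = meta_by_group(records)["BCLi"]
        planted = np.sqrt(0.8) * 0.4
        assert out.ci_low <= planted <= out.ci_high


class TestAdjustedAssociation:
    def test_expression_exactly_linear_in_score(self):
        rng = np.random.default_rng(0)
        score = {f"s{j}": rng.normal() for j in range(50)}
        amp = {f"s{j}": int(rng.random() < 0.4) for j in range(50)}
        expr = {k: 2 * v for k, v in score.items()}
        res = adjusted_association(expr, score, amp)
        assert res.coef_ne == pytest.approx(2.0, abs=1e-10)
        assert res.coef_amp == pytest.approx(0.0, abs=1e-10)

    def test_expression_exactly_linear_in_amplification(self):
        rng = np.random.default_rng(1)
        score = {f"s{j}": rng.normal() for j in range(50)}
        amp = {f"s{j}": int(rng.random() < 0.5) for j in range(50)}
        expr = {k: 3.0 * amp[k] for k in score}
        res = adjusted_association(expr, score, amp)
        assert res.coef_amp == pytest.approx(3.0, abs=1e-10)
        assert res.coef_ne == pytest.approx(0.0, abs=1e-10)

    def test_generator_mycn_model_recovered(self):
        # four lineages of 25 lines: amp effect 2, state effect 1.5,
        # noise 0.5 at n=100 should both come back within +-0.3
        cfg = GeneratorConfig(
            seed=5,
            lineages=(
                LineageConfig("SCLC", 25, 0.6, 0.3),
                LineageConfig("neuroblastoma", 25, 0.5, 0.3),
                LineageConfig("lung_adeno", 25, -0.5, 0.3),
                LineageConfig("melanoma", 25, -0.4, 0.3),
            ),
        )
        ps = generate_panel(cfg)
        expr = ps.bulk.matrix("expression").values.loc["MYCN_like"].to_dict()
        res = adjusted_association(expr, ps.truth.state, ps.truth.amplification)
        assert res.coef_amp == pytest.approx(2.0, abs=0.3)
        assert res.coef_ne == pytest.approx(1.5, abs=0.3)
        assert res.n == 100

    def test_orthogonal_amplification_leaves_marginal_slope(self):
        # with amp independent of the score, the adjusted NE coefficient
        # converges to the marginal regression slope
        rng = np.random.default_rng(8)
        n = 2000
        score_v = rng.normal(size=n)
        amp_v = (rng.random(n) < 0.3).astype(int)
        y = 1.2 * score_v + 0.7 * amp_v + rng.normal(scale=0.5, size=n)
        ids = [f"s{j}" for j in range(n)]
        res = adjusted_association(
            dict(zip(ids, y)), dict(zip(ids, score_v)), dict(zip(ids, amp_v))
        )
        marginal = np.polyfit(score_v, y, 1)[0]
        assert res.coef_ne == pytest.approx(marginal, abs=0.05)

    def test_collinear_covariates_rejected(self):
        score = {f"s{j}": float(j % 2) for j in range(20)}
        amp = {f"s{j}": j % 2 for j in range(20)}
        expr = {f"s{j}": float(j) for j in range(20)}
        with pytest.raises(NehetError, match="collinear"):
            adjusted_association(expr, score, amp)

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(0)
        score = {f"s{j}": rng.normal() for j in range(20)}
        amp = {f"s{j}": 1 for j in range(20)}
        with pytest.raises(NehetError, match="constant"):
            adjusted_association(score, score, amp)


class TestBulkScAgreement:
    def test_cells_equal_to_bulk_give_perfect_agreement(self):
        bulk = {f"L{i}": 0.1 * i - 0.3 for i in range(6)}
        sc = {(line, f"c{k}"): v for line, v in bulk.items() for k in range(3)}
        r, n, means = bulk_sc_agreement(bulk, sc)
        assert r == pytest.approx(1.0)
        assert n == 6
        assert means["L0"] == pytest.approx(bulk["L0"])

    def test_negated_single_cells_give_minus_one(self):
        bulk = {f"L{i}": 0.2 * i for i in range(5)}
        sc = {(line, "c0"): -v for line, v in bulk.items()}
        r, _, _ = bulk_sc_agreement(bulk, sc)
        assert r == pytest.approx(-1.0)

    def test_too_few_shared_lines_errors(self):
        bulk = {"L0": 0.1, "L1": 0.2}
        sc = {("L0", "c0"): 0.1, ("L1", "c0"): 0.2}
        with pytest.raises(NehetError, match="lines"):
            bulk_sc_agreement(bulk, sc)

    def test_generator_panels_agree(self, panels, bulk_scores):
        from nehet.score import score_matrix

        sc_scores = score_matrix(
            panels.single_cell.matrix("expression"), panels.signature, min_genes=10
        )
        tuples = {
            (panels.truth.cell_line_map[c], c): res.score
            for c, res in sc_scores.items()
        }
        r, n, _ = bulk_sc_agreement(bulk_scores.score_map(), tuples)
        assert n == 60
        assert r >= 0.8
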