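"""Edge association, selection, summary values and summary models."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import neurocpm as cpm
from neurocpm.core import CpmConfig, mass_association, summary_matrix


class TestPearsonAssociation:
    def test_perfect_correlation(self):
        r, p = cpm.pearson_association([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_worked_example(self):
        # sum of deviation products 3.0 over sqrt(5*5)
        r, p = cpm.pearson_association([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_constant_edge_convention(self):
        r, p = cpm.pearson_association([1.0, 1.0, 1.0], [1, 2, 3])
        assert (r, p) == (0.0, 1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = cpm.pearson_association(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cpm.pearson_association([1, 2], [1, 2])

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cpm.pearson_association([1, 2, 3], [5, 5, 5])

    def test_permutation_oracle_rank_agreement(self):
        """t-based p agrees in rank order with the exact permutation p.

        For n=8 the permutation null can be enumerated exactly (8! score
        relabelings); over a battery of random vector pairs the two
        p-value definitions must order the battery almost identically.
        """
        n = 8
        perms = np.array(list(itertools.permutations(range(n))))
        rng = np.random.default_rng(11)
        t_ps, perm_ps = [], []
        for _ in range(30):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r_obs, p_t = cpm.pearson_association(x, y)
            xc = (x - x.mean()) / x.std()
            yc = (y - y.mean()) / y.std()
            r_all = (yc[perms] @ xc) / n
            perm_p = np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12)
            t_ps.append(p_t)
            perm_ps.append(perm_p)
        rho = stats.spearmanr(t_ps, perm_ps).statistic
        assert rho > 0.99


class TestRobustAssociation:
    def test_clean_data_matches_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = 2 * x + 1 + rng.normal(scale=1e-6, size=60)
        r, p = cpm.robust_association(x, y)
        assert r == pytest.approx(1.0, abs=1e-4)
        assert p < 1e-6

    def test_collapses_to_pearson_when_weights_are_one(self):
        """When every IRLS weight converges to 1 the robust association
        reduces exactly to the Pearson one (same r, same p machinery)."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(scale=0.2, size=200)
        # a wide tuning constant guarantees no Gaussian residual is clipped
        config = CpmConfig(huber_c=50.0)
        rr, pr = cpm.robust_association(x, y, config=config)
        rp, pp = cpm.pearson_association(x, y)
        assert rr == pytest.approx(rp, abs=1e-6)
        assert pr == pytest.approx(pp, abs=1e-6)

    def test_near_pearson_at_default_constant_on_gaussian_data(self):
        """At the default Huber constant only mild tail down-weighting
        remains, so robust and Pearson stay close on clean data."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(scale=0.2, size=200)
        rr, pr = cpm.robust_association(x, y)
        rp, pp = cpm.pearson_association(x, y)
        assert rr == pytest.approx(rp, abs=0.02)
        assert pr == pytest.approx(pp, abs=0.02)

    def test_resists_single_gross_outlier(self):
        x = np.arange(1.0, 21.0)
        y = 2 * x
        y_dirty = y.copy()
        y_dirty[-1] += 50 * y.std()
        assoc_rob = mass_association(x[:, None], y_dirty, method="robust")
        assoc_ols = mass_association(x[:, None], y_dirty, method="pearson")
        rob_dev = abs(assoc_rob.slope[0] - 2.0)
        ols_dev = abs(assoc_ols.slope[0] - 2.0)
        assert rob_dev < 0.1 * 2.0
        assert rob_dev < ols_dev

    def test_matches_statsmodels_rlm(self):
        """Independent cross-check of the Huber IRLS slope."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = 1.5 * x + rng.normal(size=80)
        y[::11] += 8  # sprinkle outliers
        assoc = mass_association(x[:, None], y, method="robust")
        ref = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT()).fit()
        assert assoc.slope[0] == pytest.approx(ref.params[1], abs=5e-3)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        for method in ("pearson", "robust"):
            a1 = mass_association(x[:, None], y, method=method)
            a2 = mass_association(-x[:, None], y, method=method)
            assert a2.r[0] == pytest.approx(-a1.r[0], abs=1e-9)
            assert a2.p[0] == pytest.approx(a1.p[0], abs=1e-9)

    def test_zero_mad_falls_back_to_ols(self):
        x = np.arange(10.0)
        y = 3 * x + 1  # exact fit, all residuals zero
        r, p = cpm.robust_association(x, y)
        assert r == pytest.approx(1.0)


class TestSelectEdges:
    def test_masks_disjoint_and_exhaustive_at_alpha_one(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        sel = cpm.select_edges(X, y, alpha=1.0, method="pearson")
        assert not (sel.pos_mask & sel.neg_mask).any()
        np.testing.assert_array_equal(
            sel.pos_mask | sel.neg_mask,
            (sel.association.p < 1.0) & (sel.association.r != 0),
        )
        assert (sel.pos_mask | sel.neg_mask).all()  # no constant edges here

    def test_high_snr_recovers_planted_edges(self, small_cohort):
        cohort, truth = small_cohort
        sel = cpm.select_edges(cohort.edges, cohort.scores, alpha=0.01)
        assert set(truth.pos_edge_indices) <= set(np.flatnonzero(sel.pos_mask))
        assert set(truth.neg_edge_indices) <= set(np.flatnonzero(sel.neg_mask))

    def test_affine_score_invariance(self):
        """Masks are unchanged by y -> a*y + b with a > 0."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 15))
        y = rng.normal(size=40)
        for method in ("pearson", "robust"):
            s1 = cpm.select_edges(X, y, alpha=0.2, method=method)
            s2 = cpm.select_edges(X, 3.5 * y + 100, alpha=0.2, method=method)
            np.testing.assert_array_equal(s1.pos_mask, s2.pos_mask)
            np.testing.assert_array_equal(s1.neg_mask, s2.neg_mask)

    def test_constant_score_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="constant"):
            cpm.select_edges(X, np.ones(10), alpha=0.01)


class TestSummaryValues:
    def _selection(self, pos, neg, e):
        sel = cpm.select_edges(
            np.random.default_rng(0).normal(size=(6, e)),
            np.arange(6.0), alpha=1.0, method="pearson",
        )
        sel.pos_mask = np.zeros(e, bool)
        sel.neg_mask = np.zeros(e, bool)
        sel.pos_mask[list(pos)] = True
        sel.neg_mask[list(neg)] = True
        return sel

    def test_direct_sum(self):
        sel = self._selection(pos=[0, 2], neg=[], e=3)
        pair = cpm.summary_values(np.array([0.2, -0.1, 0.4]), sel)
        assert pair.pos_sum == pytest.approx(0.6)
        assert pair.neg_sum == 0.0

    def test_union_additivity(self):
        rng = np.random.default_rng(7)
        w = rng.uniform(-1, 1, size=10)
        sel = self._selection(pos=[1, 3], neg=[5, 8], e=10)
        pair = cpm.summary_values(w, sel)
        assert pair.pos_sum + pair.neg_sum == pytest.approx(
            w[sel.pos_mask | sel.neg_mask].sum()
        )

    def test_linearity_in_edge_vector(self):
        rng = np.random.default_rng(8)
        sel = self._selection(pos=[0, 4], neg=[2], e=6)
        w1, w2 = rng.normal(size=6), rng.normal(size=6)
        p1 = cpm.summary_values(w1, sel)
        p2 = cpm.summary_values(w2, sel)
        p12 = cpm.summary_values(2 * w1 + w2, sel)
        assert p12.pos_sum == pytest.approx(2 * p1.pos_sum + p2.pos_sum)
        assert p12.neg_sum == pytest.approx(2 * p1.neg_sum + p2.neg_sum)

    def test_clipped_mode(self):
        sel = self._selection(pos=[0, 1], neg=[2], e=3)
        pair = cpm.summary_values(np.array([0.5, -0.3, 0.2]), sel, summary="clipped")
        assert pair.pos_sum == pytest.approx(0.5)  # negative weight clipped out
        assert pair.neg_sum == 0.0  # positive weight clipped out

    def test_matrix_form_matches_scalar(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 8))
        sel = self._selection(pos=[0, 3], neg=[6], e=8)
        pos, neg = summary_matrix(X, sel)
        for i in range(5):
            pair = cpm.summary_values(X[i], sel)
            assert pos[i] == pytest.approx(pair.pos_sum)
            assert neg[i] == pytest.approx(pair.neg_sum)


class TestSummaryModel:
    def test_exact_line(self):
        model = cpm.fit_summary_model([1, 2, 3], [3, 5, 7], side="positive")
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert cpm.predict_score(model, 3) == pytest.approx(7.0)

    def test_degenerate_falls_back_to_mean(self):
        with pytest.warns(UserWarning, match="constant"):
            model = cpm.fit_summary_model([0, 0, 0], [90, 100, 110], side="negative")
        assert model.degenerate
        assert cpm.predict_score(model, 12.3) == pytest.approx(100.0)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(10)
        s = rng.normal(size=30)
        y = 4 * s + rng.normal(size=30)
        model = cpm.fit_summary_model(s, y, side="positive")
        resid = y - (model.slope * s + model.intercept)
        assert abs(resid @ s) < 1e-8 * abs(y @ s)

    def test_prediction_is_affine(self):
        model = cpm.fit_summary_model([1, 2, 4], [10, 12, 18], side="positive")
        p = cpm.predict_score
        assert p(model, 1) + p(model, 2) - p(model, 0) == pytest.approx(p(model, 3))

    def test_refuses_tiny_training_set(self):
        with pytest.raises(ValueError):
            cpm.fit_summary_model([1, 2], [1, 2], side="positive")


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_association_sign_consistency(seed):
    """r and the fitted slope always share a sign, both methods."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(25, 6))
    y = rng.normal(size=25)
    for method in ("pearson", "robust"):
        assoc = mass_association(X, y, method=method)
        nonzero = assoc.r != 0
        assert np.all(np.sign(assoc.r[nonzero]) == np.sign(assoc.slope[nonzero]))
        assert np.all((assoc.p >= 0) & (assoc.p <= 1))
        assert np.all(np.abs(assoc.r) <= 1)
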