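"""Survival statistics against hand oracles and independent libraries."""

import numpy as np
import pytest
from scipy import stats

import latentsurv as ls
from latentsurv.survstats import SurvivalRecord

from conftest import random_survival


def three_records():
    return [SurvivalRecord("a", 1, 1), SurvivalRecord("b", 2, 1),
            SurvivalRecord("c", 3, 1)]


class TestCox:
    def test_hand_partial_likelihood_maximizer(self):
        """Newton solution matches a grid search of the hand-written partial
        likelihood L(b) = e^b/(2e^b+1) * 1/(1+e^b) for x=(1,0,1), all events."""
        grid = np.linspace(-5, 5, 400001)
        loglik = grid - np.log(2 * np.exp(grid) + 1) - np.log(1 + np.exp(grid))
        beta_grid = grid[np.argmax(loglik)]
        fit = ls.fit_univariate_cox([1, 0, 1], three_records())
        assert fit.beta == pytest.approx(beta_grid, abs=1e-3)
        assert fit.converged

    def test_score_test_equals_logrank_for_binary_covariate(self):
        """The Cox score statistic at beta=0 equals the two-group log-rank
        chi-square when event times are distinct (the classic identity)."""
        rng = np.random.default_rng(3)
        for _trial in range(5):
            x = rng.integers(0, 2, 30).astype(float)
            if x.min() == x.max():
                continue
            recs = random_survival(30, rng, hazard=0.02, censor_max=120)
            fit = ls.fit_univariate_cox(x, recs)
            g0 = [r for r, xi in zip(recs, x) if xi == 0]
            g1 = [r for r, xi in zip(recs, x) if xi == 1]
            chi2, _, p = ls.logrank_test([g0, g1])
            assert fit.score_chi2 == pytest.approx(chi2, abs=1e-8)
            assert fit.p_value == pytest.approx(p, abs=1e-8)

    def test_matches_lifelines_on_continuous_covariate(self):
        """Coefficient and standard error agree with an independent Efron-tie
        Cox implementation."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        recs = random_survival(80, rng, hazard=0.02, censor_max=150, x=x, beta=0.7)
        fit = ls.fit_univariate_cox(x, recs)
        df = pd.DataFrame({"T": [r.time for r in recs],
                           "E": [r.event for r in recs], "x": x})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(cph.params_["x"], rel=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_null_score_pvalues_approximately_uniform(self):
        """Randomly permuted covariates give uniform score-test p-values."""
        rng = np.random.default_rng(11)
        recs = random_survival(40, rng, hazard=0.02, censor_max=150)
        x = rng.normal(size=40)
        pvals = []
        for _ in range(500):
            xp = rng.permutation(x)
            pvals.append(ls.fit_univariate_cox(xp, recs).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="non-identifiable"):
            ls.fit_univariate_cox([1.0, 1.0, 1.0], three_records())

    def test_too_few_events_rejected(self):
        recs = [SurvivalRecord("a", 1, 1), SurvivalRecord("b", 2, 0),
                SurvivalRecord("c", 3, 0)]
        with pytest.raises(ValueError, match="2 events"):
            ls.fit_univariate_cox([1, 0, 1], recs)


class TestSelection:
    def test_risky_feature_selected(self):
        """A latent feature tracking the planted risk label passes screening;
        pure-noise features mostly do not."""
        import pandas as pd
        rng = np.random.default_rng(2)
        n = 200
        label = rng.integers(0, 2, n).astype(float)
        recs = random_survival(n, rng, hazard=1 / 400, censor_max=3000,
                               x=label, beta=np.log(3))
        Z = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"z{i}" for i in range(10)])
        Z["z0"] = label + 0.05 * rng.normal(size=n)
        selected, table = ls.select_survival_features(Z, recs)
        assert "z0" in selected
        assert len(table) == 10

    def test_alpha_one_selects_everything(self):
        import pandas as pd
        rng = np.random.default_rng(4)
        recs = random_survival(50, rng, hazard=0.01, censor_max=300)
        Z = pd.DataFrame(rng.normal(size=(50, 5)),
                         columns=[f"z{i}" for i in range(5)])
        selected, _ = ls.select_survival_features(Z, recs, alpha=1.0)
        assert len(selected) == 5

    def test_empty_selection_raises(self):
        import pandas as pd
        rng = np.random.default_rng(6)
        recs = random_survival(50, rng, hazard=0.01, censor_max=300)
        Z = pd.DataFrame(rng.normal(size=(50, 3)),
                         columns=[f"z{i}" for i in range(3)])
        with pytest.raises(ls.EmptySelectionError):
            ls.select_survival_features(Z, recs, alpha=1e-12)


class TestKaplanMeier:
    @pytest.mark.parametrize("times,events,exp_times,exp_surv", [
        ((1, 2, 3), (1, 0, 1), (1, 3), (2 / 3, 0.0)),
        ((1, 2, 3, 4), (1, 1, 1, 1), (1, 2, 3, 4), (0.75, 0.5, 0.25, 0.0)),
    ])
    def test_product_limit_by_hand(self, times, events, exp_times, exp_surv):
        recs = [SurvivalRecord(f"p{i}", t, e)
                for i, (t, e) in enumerate(zip(times, events))]
        curve = ls.kaplan_meier(recs)
        assert np.allclose(curve.times, exp_times)
        assert np.allclose(curve.survival, exp_surv)

    def test_all_censored_curve_stays_at_one(self):
        recs = [SurvivalRecord(f"p{i}", t, 0) for i, t in enumerate((1, 2, 3))]
        curve = ls.kaplan_meier(recs)
        assert curve.times.size == 0
        assert curve.probability_at(2.5) == 1.0

    def test_converges_to_generating_exponential(self):
        """Pointwise error against S(t)=exp(-lambda t) shrinks with n."""
        lam = 0.01
        grid = np.linspace(10, 300, 30)
        mads = []
        for i, n in enumerate((50, 200, 800)):
            rng = np.random.default_rng(20 + i)
            t = rng.exponential(1 / lam, n)
            recs = [SurvivalRecord(f"p{j}", float(tj), 1) for j, tj in enumerate(t)]
            curve = ls.kaplan_meier(recs)
            est = np.array([curve.probability_at(g) for g in grid])
            mads.append(np.abs(est - np.exp(-lam * grid)).mean())
        assert mads[2] < mads[0]


class TestLogrank:
    def test_hand_computed_statistic(self):
        """O_A=2, E_A=5/6, V=17/36 gives chi-square 49/17."""
        A = [SurvivalRecord("a1", 1, 1), SurvivalRecord("a2", 2, 1)]
        B = [SurvivalRecord("b1", 3, 1), SurvivalRecord("b2", 4, 1)]
        chi2, df, p = ls.logrank_test([A, B])
        assert chi2 == pytest.approx(49 / 17, abs=1e-10)
        assert df == 1

    def test_identical_groups_give_zero(self):
        g = [SurvivalRecord("a", 1, 1), SurvivalRecord("b", 5, 0),
             SurvivalRecord("c", 9, 1)]
        g2 = [SurvivalRecord("d", 1, 1), SurvivalRecord("e", 5, 0),
              SurvivalRecord("f", 9, 1)]
        chi2, _, p = ls.logrank_test([g, g2])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariant_under_group_swap(self):
        rng = np.random.default_rng(8)
        g1 = random_survival(20, rng, hazard=0.02, censor_max=100)
        g2 = random_survival(25, rng, hazard=0.05, censor_max=100)
        a = ls.logrank_test([g1, g2])
        b = ls.logrank_test([g2, g1])
        assert a[0] == pytest.approx(b[0], abs=1e-10)

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(9)
        g1 = random_survival(30, rng, hazard=0.02, censor_max=150)
        g2 = random_survival(35, rng, hazard=0.05, censor_max=150)
        chi2, _, p = ls.logrank_test([g1, g2])
        res = lifelines_stats.logrank_test(
            [r.time for r in g1], [r.time for r in g2],
            [r.event for r in g1], [r.event for r in g2])
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ls.logrank_test([three_records(), []])


class TestBH:
    def test_step_up_by_hand(self):
        """min over j>=i of p_(j) m/j: all four collapse to 0.04."""
        adj = ls.bh_adjust((0.01, 0.02, 0.03, 0.04))
        assert np.allclose(adj, 0.04)

    @pytest.mark.parametrize("p", [[0.5], [0.2, 0.2, 0.2]])
    def test_equal_or_single_pvalues_unchanged(self, p):
        assert np.allclose(ls.bh_adjust(p), p)

    def test_matches_statsmodels_and_properties(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(13)
        p = rng.uniform(size=100)
        adj = ls.bh_adjust(p)
        _, expected, _, _ = sm.multipletests(p, method="fdr_bh")
        assert np.allclose(adj, expected, atol=1e-12)
        assert (adj >= p - 1e-15).all()
        # order of significance preserved: smaller p never gets larger adj
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ls.bh_adjust([0.5, 1.5])
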