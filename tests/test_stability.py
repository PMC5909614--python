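import math
import warnings

import numpy as np
import pandas as pd
import pytest

from phenoscan import (
    LineObservations,
    SimDatabase,
    build_stability_dataset,
    enumerate_subsets,
    fit_variance_model,
    simulate_crossed_panel,
    stability_statistics,
)
from phenoscan.stability import _CrossedML, chernoff_log10_sf

from _oracles import exhaustive_best_and_ties


class TestEnumerateSubsets:
    def test_eleven_choose_seven(self):
        subsets = enumerate_subsets(11, 7)
        assert len(subsets) == 330
        assert len(set(subsets)) == 330
        assert subsets == sorted(subsets)  # lexicographic
        assert all(len(s) == 7 for s in subsets)

    @pytest.mark.parametrize("n,k,count", [(4, 4, 1), (5, 2, 10), (6, 1, 6)])
    def test_small_counts(self, n, k, count):
        assert len(enumerate_subsets(n, k)) == count

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_subsets(5, 6)
        with pytest.raises(ValueError):
            enumerate_subsets(5, 0)


def _panel_observations(db, n_lines, rng):
    """Lines observed at every site-year, perturbed database rows."""
    obs = []
    rows = rng.integers(0, db.n_sets, n_lines)
    for i, row in enumerate(rows):
        sim = db.anthesis[row]
        if (sim <= 0).any():
            continue
        dates = {
            s: int(v + rng.integers(-2, 3))
            for s, v in zip(db.site_ids, sim)
        }
        dates = {s: max(1, v) for s, v in dates.items()}
        obs.append(LineObservations(f"L{i:03d}", dates))
    return obs


class TestBuildStabilityDataset:
    def test_search_count_bookkeeping(self, small_db):
        rng = np.random.default_rng(21)
        sub = SimDatabase(
            params=small_db.params.iloc[:300].reset_index(drop=True),
            anthesis=small_db.anthesis[:300],
            site_ids=small_db.site_ids,
        )
        obs = _panel_observations(sub, 15, rng)
        ds = build_stability_dataset(sub, obs, k=10, min_lines=1)
        prov = ds.provenance
        assert prov["n_searches_attempted"] == len(obs) * 11  # C(11,10) = 11
        assert (
            len(ds.table)
            + prov["n_dropped_ties"]
            + prov["n_dropped_inexpressible"]
            == prov["n_searches_attempted"]
        )

    def test_survivors_match_per_search_tie_flags(self, small_db):
        """Surviving rows equal a brute-force recount of untied searches."""
        rng = np.random.default_rng(22)
        sub = SimDatabase(
            params=small_db.params.iloc[:200].reset_index(drop=True),
            anthesis=small_db.anthesis[:200, :5],
            site_ids=small_db.site_ids[:5],
        )
        obs = _panel_observations(sub, 12, rng)
        subsets = [
            tuple(sub.site_ids[i] for i in s) for s in enumerate_subsets(5, 3)
        ]
        ds = build_stability_dataset(sub, obs, subsets=subsets, min_lines=1)
        expected = 0
        for s in enumerate_subsets(5, 3):
            cols = list(s)
            for o in obs:
                oracle = exhaustive_best_and_ties(
                    sub.anthesis[:, cols],
                    [o.dates[sub.site_ids[c]] for c in cols],
                )
                if oracle is not None and oracle[2] == 0:
                    expected += 1
        assert len(ds.table) == expected

    def test_min_lines_filter_drops_subsets(self, small_db):
        rng = np.random.default_rng(23)
        obs = _panel_observations(small_db, 8, rng)
        with pytest.raises(ValueError):
            # impossible coverage requirement: nothing survives
            build_stability_dataset(small_db, obs, k=7, min_lines=10**6)

    def test_line_with_all_ties_contributes_nothing(self):
        # two identical rows: every search ties
        anth = np.array([[50, 60], [50, 60], [70, 80]], dtype=np.int32)
        params = pd.DataFrame(
            {"p1": [200.0, 300.0, 400.0], "p2": [1.0] * 3,
             "p2o": [12.0] * 3, "phint": [45.0] * 3}
        )
        db = SimDatabase(params=params, anthesis=anth, site_ids=["A", "B"])
        obs = [LineObservations("L0", {"A": 50, "B": 60})]
        with pytest.raises(ValueError):
            build_stability_dataset(
                db, obs, subsets=[("A", "B"), ("A",), ("B",)], min_lines=1
            )


def balanced_loglik_oracle(y_matrix, mu, var_line, var_subset, var_resid):
    """Closed-form ML log-likelihood for a complete L x E crossed panel.

    Uses the exact eigenstructure of the compound-symmetric covariance
    (Kronecker projections), entirely independent of the Woodbury-based
    implementation it checks.
    """
    L, E = y_matrix.shape
    n = L * E
    gbar = y_matrix.mean()
    lbar = y_matrix.mean(axis=1)
    ebar = y_matrix.mean(axis=0)
    lam_grand = E * var_line + L * var_subset + var_resid
    lam_line = E * var_line + var_resid
    lam_sub = L * var_subset + var_resid
    lam_res = var_resid
    logdet = (
        math.log(lam_grand)
        + (L - 1) * math.log(lam_line)
        + (E - 1) * math.log(lam_sub)
        + (L - 1) * (E - 1) * math.log(lam_res)
    )
    resid = y_matrix - lbar[:, None] - ebar[None, :] + gbar
    quad = (
        n * (gbar - mu) ** 2 / lam_grand
        + E * ((lbar - gbar) ** 2).sum() / lam_line
        + L * ((ebar - gbar) ** 2).sum() / lam_sub
        + (resid**2).sum() / lam_res
    )
    return -0.5 * (n * math.log(2 * math.pi) + logdet + quad)


class TestVarianceModelFit:
    def test_loglik_matches_closed_form_on_balanced_panel(self):
        rng = np.random.default_rng(31)
        t = simulate_crossed_panel(50.0, 4.0, 7.0, 2.0, 20, 8, rng)
        y = t["value"].to_numpy().reshape(20, 8)
        _, lc = np.unique(t["line_id"], return_inverse=True)
        _, sc = np.unique(t["subset"], return_inverse=True)
        ml = _CrossedML(t["value"].to_numpy(), lc, sc, 20, 8)
        for vl, ve, vr in [(16, 49, 4), (1, 1, 1), (20, 0.01, 3), (5, 60, 10)]:
            ll, mu = ml.loglik(vl, ve, vr)
            assert ll == pytest.approx(
                balanced_loglik_oracle(y, mu, vl, ve, vr), abs=1e-8
            )

    def test_matches_statsmodels_reference(self):
        """Likelihood agrees with MixedLM at its fitted parameters, and the
        in-package optimum is at least as good."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(32)
        t = simulate_crossed_panel(100.0, 10.0, 20.0, 5.0, 40, 10, rng,
                                   missing_rate=0.1)
        t2 = t.copy()
        t2["g"] = 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm(
                "value ~ 1", t2, groups="g", re_formula="0",
                vc_formula={"line": "0 + C(line_id)", "subset": "0 + C(subset)"},
            ).fit(reml=False)
        _, lc = np.unique(t["line_id"], return_inverse=True)
        _, sc = np.unique(t["subset"], return_inverse=True)
        ml = _CrossedML(t["value"].to_numpy(), lc, sc, lc.max() + 1, sc.max() + 1)
        ll_at_sm, _ = ml.loglik(sm_fit.vcomp[0], sm_fit.vcomp[1], sm_fit.scale)
        assert ll_at_sm == pytest.approx(sm_fit.llf, abs=1e-4)
        mine = fit_variance_model(t, "value", include_subset_effect=True)
        assert mine.loglik >= sm_fit.llf - 1e-6

    def test_boundary_null_estimated_at_zero(self):
        """Data with no subset effect: the subset variance collapses."""
        rng = np.random.default_rng(33)
        t = simulate_crossed_panel(100.0, 10.0, 0.0, 5.0, 80, 20, rng)
        full = fit_variance_model(t, "value", True)
        red = fit_variance_model(t, "value", False)
        total = full.var_line + full.var_subset + full.var_resid
        assert full.var_subset <= 0.01 * total
        res = stability_statistics(full, red)
        assert res.lrt_stat == pytest.approx(0.0, abs=0.2)

    def test_parameter_recovery(self):
        """Replicate fits recover the generating variances on average."""
        rng = np.random.default_rng(34)
        mu_t, sl, se, sr = 100.0, 10.0, 20.0, 5.0
        fits = []
        for _ in range(15):
            t = simulate_crossed_panel(mu_t, sl, se, sr, 200, 50, rng)
            fits.append(fit_variance_model(t, "value", True))
        assert np.mean([f.mu for f in fits]) == pytest.approx(mu_t, rel=0.10)
        assert np.mean([f.var_line for f in fits]) == pytest.approx(sl**2, rel=0.10)
        assert np.mean([f.var_subset for f in fits]) == pytest.approx(se**2, rel=0.10)
        assert np.mean([f.var_resid for f in fits]) == pytest.approx(sr**2, rel=0.10)

    def test_aic_bic_definitions(self):
        rng = np.random.default_rng(35)
        t = simulate_crossed_panel(10.0, 1.0, 1.0, 1.0, 15, 6, rng)
        fit = fit_variance_model(t, "value", True)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 4)
        assert fit.bic == pytest.approx(-2 * fit.loglik + 4 * math.log(fit.n_obs))
        red = fit_variance_model(t, "value", False)
        assert red.n_params == 3

    def test_requires_two_levels(self):
        t = pd.DataFrame({"line_id": ["a", "a"], "subset": [0, 1], "value": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_variance_model(t, "value", True)


class TestStabilityStatistics:
    def _fit(self, mu, vl, ve, vr, ll, full=True):
        from phenoscan import VarianceModelFit

        return VarianceModelFit(
            mu=mu, var_line=vl, var_subset=ve if full else None, var_resid=vr,
            loglik=ll, n_obs=100, n_params=4 if full else 3, converged=True,
        )

    def test_boundary_lrt_zero(self):
        full = self._fit(100, 1, 0.0, 1, -50.0)
        red = self._fit(100, 1, None, 1, -50.0, full=False)
        assert stability_statistics(full, red, null="half_df").p_value == 1.0
        assert stability_statistics(full, red, null="mixture").p_value == 0.5

    def test_mixture_reference_value(self):
        """LRT 2.706 under the 50:50 mixture: p = 0.5 P(chi2_1 > 2.706)."""
        full = self._fit(100, 1, 0.5, 1, -50.0 + 2.706 / 2)
        red = self._fit(100, 1, None, 1, -50.0, full=False)
        res = stability_statistics(full, red, null="mixture")
        assert res.p_value == pytest.approx(0.0499, abs=2e-4)

    def test_iov_and_variance_share(self):
        full = self._fit(100.0, 1.0, 1.0, 2.0, -10.0)
        red = self._fit(100.0, 1.0, None, 2.0, -11.0, full=False)
        res = stability_statistics(full, red)
        assert res.iov_pct == pytest.approx(1.0)  # sd 1 over mean 100
        assert res.var_pct_subset == pytest.approx(25.0)  # 1/(1+1+2)

    def test_chernoff_bound_for_extreme_lrt(self):
        full = self._fit(100, 1, 50.0, 1, 0.0)
        red = self._fit(100, 1, None, 1, -16000.0, full=False)
        res = stability_statistics(full, red)
        assert res.p_value == 0.0
        assert res.p_method == "half_df:chernoff"
        assert res.log10_p == pytest.approx(chernoff_log10_sf(32000.0, 0.5))
        assert res.log10_p < -6000

    def test_chernoff_bound_is_an_upper_bound(self):
        from scipy.stats import chi2

        for x in (5.0, 50.0, 500.0):
            exact = math.log10(chi2.sf(x, 0.5))
            assert chernoff_log10_sf(x, 0.5) >= exact

    def test_inconsistent_fits_rejected(self):
        full = self._fit(100, 1, 0.5, 1, -60.0)
        red = self._fit(100, 1, None, 1, -50.0, full=False)
        with pytest.raises(RuntimeError, match="inconsistent"):
            stability_statistics(full, red)
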