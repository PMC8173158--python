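"""Metropolis-Hastings sampler and the sign-split K-S sensitivity scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiaging import scoring, sensitivity

from ._oracles import ks_two_sample_bruteforce


def _standard_normal_logpdf(x):
    return -0.5 * float(np.dot(x, x))


class TestMhSample:
    def test_same_seed_gives_identical_trajectories(self):
        a = sensitivity.mh_sample(_standard_normal_logpdf, [0.0], 1.0, 2000, 200, seed=4)
        b = sensitivity.mh_sample(_standard_normal_logpdf, [0.0], 1.0, 2000, 200, seed=4)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.accepted, b.accepted)

    def test_recovers_gaussian_moments_within_monte_carlo_error(self):
        chain = sensitivity.mh_sample(
            _standard_normal_logpdf, [0.0], 2.4, n_samples=20_000, burn_in=5_000, seed=0
        )
        draws = chain.kept[:, 0]
        # integrated autocorrelation time from the empirical autocorrelation
        tau = _iact(draws)
        se_mean = np.sqrt(tau / draws.size)
        assert abs(draws.mean()) < 3 * se_mean
        se_var = np.sqrt(2.0 * tau / draws.size)  # var(x^2) = 2 for N(0,1)
        assert abs(draws.var() - 1.0) < 3 * se_var
        assert 0.0 < chain.acceptance_rate < 1.0

    def test_tiny_proposal_accepts_nearly_everything(self):
        chain = sensitivity.mh_sample(
            _standard_normal_logpdf, [0.0], 1e-6, n_samples=2000, burn_in=100, seed=1
        )
        assert chain.acceptance_rate > 0.999
        assert np.ptp(chain.kept[:, 0]) < 0.01  # barely moves

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            sensitivity.mh_sample(lambda x: np.nan, [0.0], 1.0, 100, 10, seed=0)

    def test_burn_in_bound(self):
        with pytest.raises(ValueError):
            sensitivity.mh_sample(_standard_normal_logpdf, [0.0], 1.0, 100, 100, seed=0)


def _iact(x, max_lag=200):
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[x.size - 1 :][: max_lag]
    acf = acf / acf[0]
    # initial positive sequence cutoff
    tau = 1.0
    for lag in range(1, max_lag):
        if acf[lag] <= 0:
            break
        tau += 2.0 * acf[lag]
    return tau


class TestKsSensitivity:
    def test_equals_scipy_two_sample_oracle_exactly(self):
        rng = np.random.default_rng(2)
        theta = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
        out = theta["a"].to_numpy() * 2 + rng.standard_normal(500) * 0.3
        ks = sensitivity.ks_sensitivity(theta, out)
        for col in theta.columns:
            z = (theta[col] - theta[col].mean()) / theta[col].std(ddof=0)
            neg, pos = out[(z < 0).to_numpy()], out[(z >= 0).to_numpy()]
            expected = stats.ks_2samp(neg, pos, method="asymp").statistic
            assert ks[col] == pytest.approx(expected, abs=1e-12)
            assert ks[col] == pytest.approx(ks_two_sample_bruteforce(neg, pos), abs=1e-12)

    def test_sign_output_gives_statistic_one(self):
        rng = np.random.default_rng(3)
        theta = pd.DataFrame({"a": rng.standard_normal(400)})
        out = np.sign(theta["a"] - theta["a"].mean())
        ks = sensitivity.ks_sensitivity(theta, out)
        assert ks["a"] == pytest.approx(1.0)

    def test_independent_output_stays_at_null_level(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            theta = pd.DataFrame({"a": rng.standard_normal(300)})
            out = rng.standard_normal(300)
            vals.append(sensitivity.ks_sensitivity(theta, out)["a"])
        # two-sample K-S null mean ~ sqrt(pi/2)/sqrt(n_eff) for equal halves
        n_eff = 150 / 2
        null_mean = np.sqrt(np.pi / 2.0) / np.sqrt(n_eff)
        se = null_mean / np.sqrt(50)
        assert np.mean(vals) < null_mean + 2 * 5 * se  # generous but bounded

    def test_one_sided_coordinate_flagged_nan(self):
        theta = pd.DataFrame({"a": np.abs(np.random.default_rng(0).standard_normal(50))})
        ks = sensitivity.ks_sensitivity(theta, np.arange(50.0), normalize=False)
        assert np.isnan(ks["a"])


class TestRunSensitivity:
    @staticmethod
    def _fitted_scan(seed=0, n_samples=4000, burn_in=1000):
        rng = np.random.default_rng(seed)
        sites = [f"cg{i}" for i in range(8)]
        aging_sites = sites[:4]
        dis_sites = sites[4:]
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, 8)), columns=sites)
        # the aging outcome is driven only by cg0; the disease outcome by cg4
        y_aging = (X["cg0"] > 0).astype(float)
        y_dis = (X["cg4"] > 0).astype(float)
        aging_scorer = scoring.fit_score_regressor(X[aging_sites], y_aging, 30, seed)
        dis_scorer = scoring.fit_score_regressor(X[dis_sites], y_dis, 30, seed + 1)
        means = pd.Series(0.0, index=sites)
        sds = pd.Series(1.0, index=sites)
        return sensitivity.run_sensitivity(
            means, sds, aging_scorer, aging_sites, {"AD": dis_scorer},
            {"AD": dis_sites}, n_samples=n_samples, burn_in=burn_in, seed=seed,
        ), aging_sites, dis_sites

    def test_planted_driver_dominates_differential(self):
        result, aging_sites, dis_sites = self._fitted_scan(seed=1)
        diff = result.differential["AD"]
        # cg0 drives only the aging scorer: large positive differential;
        # cg4 drives only the disease scorer: large negative differential
        assert diff["cg0"] == diff.max()
        assert diff["cg4"] == diff.min()
        assert diff["cg0"] > 0.3
        assert diff["cg4"] < -0.3

    def test_inert_markers_near_null(self):
        result, _, _ = self._fitted_scan(seed=2)
        inert = [c for c in result.ks_aging.index if c not in ("cg0", "cg4")]
        assert result.ks_aging[inert].max() < 0.25
        assert result.ks_aging["cg0"] > 0.5

    def test_ranked_pairs_follow_sort_oracle(self):
        result, aging_sites, dis_sites = self._fitted_scan(seed=3)
        table, freq = sensitivity.rank_aging_nd_pairs(
            result, aging_sites, {"AD": dis_sites}, top_n=100
        )
        scores = table["pair_score"].to_numpy()
        assert np.all(np.diff(scores) <= 1e-12)
        # exhaustive top_n: frequency equals total appearance count
        assert freq.sum() == len(table)
        # the planted pair should rank first
        assert (table.iloc[0]["aging_marker"], table.iloc[0]["disease_marker"]) == ("cg0", "cg4")

    def test_tie_break_is_lexicographic(self):
        diff = pd.DataFrame({"AD": [0.5, 0.5, 0.5, 0.5]}, index=["a", "b", "m1", "m2"])
        result = sensitivity.SensitivityResult(
            ks_aging=pd.Series(dtype=float), ks_disease=pd.DataFrame(),
            ks_common=pd.Series(dtype=float), differential=diff,
        )
        table, _ = sensitivity.rank_aging_nd_pairs(result, ["b", "a"], {"AD": ["m2", "m1"]}, top_n=4)
        assert list(table["aging_marker"]) == ["a", "a", "b", "b"]
        assert list(table["disease_marker"]) == ["m1", "m2", "m1", "m2"]
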