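"""Behavioral model: conflict statistic, likelihoods, diagnostics, fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from arcpipe import model
from arcpipe.model import (
    ModelSpec,
    PosteriorSamples,
    conflict,
    extract_conflict,
    hdi,
    joint_log_likelihood,
    likelihood_of_take,
    modal_estimates,
    posterior_predictive_rmse,
    rhat,
    rt_mean,
    waic,
)


class TestConflict:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.5, 0.25), (0.0, 0.0), (1.0, 0.0), (0.25, 0.1875), (0.75, 0.1875)],
    )
    def test_known_values(self, theta, expected):
        assert conflict(theta) == pytest.approx(expected, abs=1e-15)

    @settings(max_examples=200, derandomize=True)
    @given(theta=st.floats(0.0, 1.0))
    def test_parabola_identity(self, theta):
        assert conflict(theta) + (0.5 - theta) ** 2 == pytest.approx(0.25, abs=1e-12)

    def test_symmetry_about_half(self, rng):
        t = rng.random(1000)
        assert np.allclose(conflict(t), conflict(1 - t))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            conflict(1.2)
        with pytest.raises(ValueError):
            conflict(-0.1)


class TestLikelihoodOfTake:
    def test_zero_coefficients_give_half(self):
        assert likelihood_of_take(np.zeros(4), 0.1, 0.0) == pytest.approx(0.5)

    def test_intercept_only_closed_form(self):
        assert likelihood_of_take([2, 0, 0, 0], 0.1, 0.0) == pytest.approx(
            1 / (1 + math.exp(-2)), rel=1e-12
        )

    def test_risk_indicator_coding(self):
        beta = [0.3, -1.0, -2.5, 0.0]
        t10 = likelihood_of_take(beta, 0.1, 0.0)
        t50 = likelihood_of_take(beta, 0.5, 0.0)
        t90 = likelihood_of_take(beta, 0.9, 0.0)
        assert t50 < t10  # negative 50%-risk offset
        assert t90 < t50
        assert t10 == pytest.approx(1 / (1 + math.exp(-0.3)))

    def test_unknown_risk_level_rejected(self):
        with pytest.raises(ValueError):
            likelihood_of_take(np.zeros(4), 0.3, 0.0)


class TestRtMean:
    def test_zero_conflict(self):
        assert rt_mean(1.0, 5.0, 0.0) == 1.0

    def test_linear_in_conflict(self):
        assert rt_mean(1.0, 0.456, 0.25) == pytest.approx(1.114)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            rt_mean(0.1, -1.0, 0.25)


def _one_trial_dataset(choice, rt_value):
    return pd.DataFrame(
        {
            "participant": ["p1"],
            "trial": [1],
            "risk": [0.1],
            "reward_z": [0.0],
            "choice": [choice],
            "rt": [rt_value],
        }
    )


class TestJointLogLikelihood:
    def test_bernoulli_and_exponential_terms(self):
        # theta = 0.5 contributes ln(0.5); gamma(1, rate 1) at z=1 contributes -1
        params = {"p1": {"beta": np.zeros(4), "alpha0": 1.0, "alpha1": 0.0, "k": 1.0}}
        total, pw = joint_log_likelihood(params, _one_trial_dataset(1.0, 1.0))
        assert total == pytest.approx(math.log(0.5) - 1.0, rel=1e-12)
        assert pw.shape == (1,)

    def test_additivity_over_trials(self):
        ds1 = _one_trial_dataset(1.0, 1.0)
        ds2 = pd.concat([ds1, ds1.assign(trial=2)], ignore_index=True)
        params = {"p1": {"beta": np.zeros(4), "alpha0": 1.0, "alpha1": 0.3, "k": 2.0}}
        t1, _ = joint_log_likelihood(params, ds1)
        t2, _ = joint_log_likelihood(params, ds2)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_matches_scipy_densities(self, rng):
        # independent oracle: scipy bernoulli + gamma log-densities per trial
        n = 50
        risk = rng.choice([0.1, 0.5, 0.9], size=n)
        rz = rng.standard_normal(n)
        ds = pd.DataFrame(
            {
                "participant": "p1",
                "trial": np.arange(1, n + 1),
                "risk": risk,
                "reward_z": rz,
                "choice": rng.integers(0, 2, n).astype(float),
                "rt": rng.gamma(5.0, 0.3, n),
            }
        )
        beta = np.array([0.4, -1.2, -2.8, 3.0])
        a0, a1, k = 0.9, 1.5, 6.0
        params = {"p1": {"beta": beta, "alpha0": a0, "alpha1": a1, "k": k}}
        total, pw = joint_log_likelihood(params, ds)
        theta = likelihood_of_take(beta, risk, rz)
        mu = a0 + a1 * conflict(theta)
        expected = stats.bernoulli.logpmf(ds["choice"], theta) + stats.gamma.logpdf(
            ds["rt"], a=k, scale=mu / k
        )
        assert np.allclose(pw, expected, rtol=1e-10)
        assert total == pytest.approx(expected.sum())

    def test_rt_change_only_moves_gamma_term(self):
        params = {"p1": {"beta": np.zeros(4), "alpha0": 1.0, "alpha1": 0.5, "k": 3.0}}
        t_a, _ = joint_log_likelihood(params, _one_trial_dataset(1.0, 1.0))
        t_b, _ = joint_log_likelihood(params, _one_trial_dataset(1.0, 2.0))
        mu = 1.0 + 0.5 * 0.25
        diff = stats.gamma.logpdf(2.0, a=3.0, scale=mu / 3) - stats.gamma.logpdf(
            1.0, a=3.0, scale=mu / 3
        )
        assert t_b - t_a == pytest.approx(diff, rel=1e-10)

    def test_missing_trials_contribute_nothing(self):
        ds1 = _one_trial_dataset(1.0, 1.0)
        ds2 = pd.concat(
            [ds1, _one_trial_dataset(np.nan, np.nan).assign(trial=2)],
            ignore_index=True,
        )
        params = {"p1": {"beta": np.zeros(4), "alpha0": 1.0, "alpha1": 0.0, "k": 1.0}}
        assert joint_log_likelihood(params, ds1)[0] == pytest.approx(
            joint_log_likelihood(params, ds2)[0]
        )

    def test_nonpositive_rt_rejected(self):
        params = {"p1": {"beta": np.zeros(4), "alpha0": 1.0, "alpha1": 0.0, "k": 1.0}}
        with pytest.raises(ValueError):
            joint_log_likelihood(params, _one_trial_dataset(1.0, -0.5))


class TestWaic:
    @staticmethod
    def _brute_force(ll):
        # direct transcription of the definition, kept independent of the
        # vectorized implementation
        S, N = ll.shape
        lppd = 0.0
        p_waic = 0.0
        for i in range(N):
            col = ll[:, i]
            lppd += math.log(sum(math.exp(v) for v in col) / S)
            mean = sum(col) / S
            p_waic += sum((v - mean) ** 2 for v in col) / (S - 1)
        return -2.0 * (lppd - p_waic)

    def test_matches_brute_force_oracle(self, rng):
        ll = rng.standard_normal((2, 3)) - 1.0
        assert waic(ll) == pytest.approx(self._brute_force(ll), rel=1e-12)
        ll = rng.standard_normal((20, 15)) - 2.0
        assert waic(ll) == pytest.approx(self._brute_force(ll), rel=1e-12)

    def test_identical_draws_have_zero_penalty(self):
        row = np.log([0.2, 0.5, 0.9])
        ll = np.tile(row, (5, 1))
        assert waic(ll) == pytest.approx(-2 * row.sum(), rel=1e-12)

    def test_duplicating_observations_doubles_waic(self, rng):
        ll = rng.standard_normal((10, 6)) - 1.0
        assert waic(np.hstack([ll, ll])) == pytest.approx(2 * waic(ll), rel=1e-12)

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            waic(np.zeros((1, 5)))


class TestHdi:
    def test_standard_normal(self, rng):
        x = rng.standard_normal(200_000)
        lo, hi = hdi(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    def test_uniform_width(self, rng):
        x = rng.random(100_000)
        lo, hi = hdi(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_degenerate_samples(self):
        lo, hi = hdi(np.full(500, 3.7), 0.95)
        assert lo == hi == 3.7

    def test_skewed_interval_is_narrowest(self, rng):
        x = rng.gamma(2.0, 1.0, 100_000)
        lo, hi = hdi(x, 0.9)
        q = np.quantile(x, [0.05, 0.95])
        assert (hi - lo) < (q[1] - q[0])  # narrower than the central interval


class TestRhat:
    @staticmethod
    def _brute_force(chains):
        # split each chain in half, then the classic between/within formula
        arr = np.asarray(chains, float)
        half = arr.shape[1] // 2
        splits = [c[:half] for c in arr] + [c[half: 2 * half] for c in arr]
        m = len(splits)
        n = half
        means = [np.mean(s) for s in splits]
        W = np.mean([np.var(s, ddof=1) for s in splits])
        B = n * np.var(means, ddof=1)
        return math.sqrt(((n - 1) / n * W + B / n) / W)

    def test_iid_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 1000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_matches_brute_force(self, rng):
        chains = rng.standard_normal((3, 40)) + np.array([[0.0], [0.3], [0.1]])
        assert rhat(chains) == pytest.approx(self._brute_force(chains), rel=1e-12)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.standard_normal(200), rng.standard_normal(200) + 10])
        assert rhat(chains) > 1.1

    def test_constant_chains_handled(self):
        assert rhat(np.ones((4, 100))) == 1.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 100)))


def _fake_posterior(draw_map, participants=("p1",)):
    draws = {}
    for name, vals in draw_map.items():
        arr = np.asarray(vals, float)
        draws[name] = arr.reshape(1, -1, len(participants))
    return PosteriorSamples(
        draws=draws,
        participants=list(participants),
        rhat={},
        ess={},
        log_lik=np.zeros((2, 1)),
        spec=ModelSpec(),
        diagnostics=[],
        seed=0,
    )


class TestModalEstimates:
    def test_symmetric_mode_near_mean(self, rng):
        x = rng.standard_normal(4000) + 2.0
        post = _fake_posterior(
            {n: x for n in ["beta0", "beta1", "beta2", "beta3", "alpha0", "alpha1", "k"]}
        )
        est = modal_estimates(post)
        assert est.loc[0, "beta0"] == pytest.approx(x.mean(), abs=0.2)

    def test_skewed_mode_below_mean(self, rng):
        x = rng.gamma(2.0, 2.0, 4000)
        post = _fake_posterior(
            {n: x for n in ["beta0", "beta1", "beta2", "beta3", "alpha0", "alpha1", "k"]}
        )
        est = modal_estimates(post)
        assert est.loc[0, "alpha0"] < x.mean()

    def test_delta_draws(self):
        x = np.full(100, 1.23)
        post = _fake_posterior(
            {n: x for n in ["beta0", "beta1", "beta2", "beta3", "alpha0", "alpha1", "k"]}
        )
        est = modal_estimates(post)
        assert est.loc[0, "k"] == 1.23


class TestExtractConflict:
    def test_zero_betas_give_maximal_conflict(self, design108):
        pe = pd.DataFrame(
            {"participant": ["p1"], "beta0": [0.0], "beta1": [0.0],
             "beta2": [0.0], "beta3": [0.0]}
        )
        out = extract_conflict(pe, design108)
        assert np.allclose(out["d_hat"], 0.25)

    def test_extreme_intercept_kills_conflict(self, design108):
        pe = pd.DataFrame(
            {"participant": ["p1"], "beta0": [10.0], "beta1": [0.0],
             "beta2": [0.0], "beta3": [0.0]}
        )
        out = extract_conflict(pe, design108)
        assert (out["d_hat"] < 0.01).all()

    def test_printed_group_means_closed_form(self):
        # a 50%-risk trial at the mean reward, using the group-level
        # coefficient estimates of the original fit
        design = pd.DataFrame(
            {"trial": [1], "risk": [0.5], "reward": [0.5], "reward_z": [0.0]}
        )
        pe = pd.DataFrame(
            {"participant": ["p1"], "beta0": [0.0], "beta1": [-1.922],
             "beta2": [-4.180], "beta3": [10.652]}
        )
        out = extract_conflict(pe, design)
        theta = 1 / (1 + math.exp(1.922))
        assert out.loc[0, "theta_hat"] == pytest.approx(theta, rel=1e-12)
        assert out.loc[0, "d_hat"] == pytest.approx(0.25 - (0.5 - theta) ** 2, rel=1e-12)

    def test_invariant_holds_for_fitted_estimates(self, design108):
        pe = pd.DataFrame(
            {"participant": ["a", "b"], "beta0": [1.0, -2.0], "beta1": [-1.0, 0.5],
             "beta2": [-3.0, -1.0], "beta3": [8.0, 12.0]}
        )
        out = extract_conflict(pe, design108)
        assert np.allclose(
            out["d_hat"], 0.25 - (0.5 - out["theta_hat"]) ** 2
        )
        assert out["d_hat"].between(0, 0.25).all()


class TestPosteriorPredictiveRmse:
    def test_hand_computed_offsets(self):
        # two participants whose observed rates differ from the model
        # prediction (0.5) by +0.1 and -0.1
        n = 10
        rows = []
        for pid, rate in [("a", 0.6), ("b", 0.4)]:
            choices = np.zeros(n)
            choices[: int(rate * n)] = 1.0
            for t in range(n):
                rows.append(
                    {"participant": pid, "trial": t + 1, "risk": 0.1,
                     "reward_z": 0.0, "choice": choices[t], "rt": 1.0}
                )
        ds = pd.DataFrame(rows)
        zeros = np.zeros(50)
        post = _fake_posterior(
            {
                "beta0": np.stack([zeros, zeros], axis=-1).ravel(),
                "beta1": np.stack([zeros, zeros], axis=-1).ravel(),
                "beta2": np.stack([zeros, zeros], axis=-1).ravel(),
                "beta3": np.stack([zeros, zeros], axis=-1).ravel(),
            },
            participants=("a", "b"),
        )
        assert posterior_predictive_rmse(post, ds) == pytest.approx(0.1, rel=1e-9)


class TestExclusions:
    def test_high_missingness_participant_dropped(self, design108):
        from arcpipe.simulate import GroupParameters, simulate_participants

        ds = simulate_participants(GroupParameters(), 3, design=design108, seed=3)
        # participant 1: erase 27/108 trials (25%)
        target = ds["participant"] == "sub-01"
        idx = ds[target].index[:27]
        ds.loc[idx, ["choice", "rt"]] = np.nan
        kept = model.apply_exclusions(ds)
        assert "sub-01" not in kept["participant"].unique()
        assert set(kept["participant"]) == {"sub-02", "sub-03"}


class TestGradients:
    @pytest.mark.parametrize("variant", ["hierarchical", "non_hierarchical"])
    def test_analytic_matches_finite_differences(self, variant, rng):
        from arcpipe.model import _Posterior, _prepare
        from arcpipe.simulate import GroupParameters, simulate_participants
        from arcpipe.task import generate_design

        d = generate_design(n_trials=12, seed=3)
        ds = simulate_participants(GroupParameters(), 3, design=d, seed=4)
        post = _Posterior(_prepare(ds, False), ModelSpec(variant=variant))
        q = 0.1 * rng.standard_normal(post.dim)
        if variant == "hierarchical":
            q[2 * 4] = 1.0                      # a0G
            i = 2 * 4 + 4
            q[i + 12:i + 15] = 1.0              # a0_j
        else:
            q[4] = 1.0                          # a0
        lp, grad = post.logp_grad(q)
        assert np.isfinite(lp)
        eps = 1e-6
        num = np.empty_like(q)
        for i in range(post.dim):
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            num[i] = (post.logp_grad(qp)[0] - post.logp_grad(qm)[0]) / (2 * eps)
        assert np.max(np.abs(num - grad) / (1 + np.abs(num))) < 1e-6


@pytest.fixture(scope="module")
def quick_fit(small_dataset):
    spec = ModelSpec(n_chains=2, n_steps=400, n_burnin=200, thin=1)
    return model.fit(spec, small_dataset, seed=99)


class TestFit:
    def test_draw_count_matches_settings(self, quick_fit):
        assert quick_fit.stacked("beta0_G").shape[0] == 2 * 200

    def test_rhat_reported_for_group_parameters(self, quick_fit):
        for name in quick_fit.group_mean_names():
            assert name in quick_fit.rhat

    def test_recovery_within_posterior_uncertainty(self, quick_fit, small_dataset):
        # group means should land within a few posterior SDs of the truth
        from arcpipe.simulate import GroupParameters

        g = GroupParameters()
        truth = {"beta1_G": g.beta_G[1], "beta2_G": g.beta_G[2],
                 "beta3_G": g.beta_G[3], "alpha0_G": g.alpha0_G,
                 "alpha1_G": g.alpha1_G}
        for name, tv in truth.items():
            x = quick_fit.stacked(name)
            assert abs(x.mean() - tv) < 4 * x.std() + 0.3, name

    def test_seed_determinism(self, small_dataset, quick_fit):
        spec = ModelSpec(n_chains=2, n_steps=400, n_burnin=200, thin=1)
        refit = model.fit(spec, small_dataset, seed=99)
        assert np.array_equal(refit.stacked("beta3_G"), quick_fit.stacked("beta3_G"))
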