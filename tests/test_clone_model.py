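import numpy as np
import pytest

from kcdyn import clone_model as cm

FROZEN = cm.CloneParams(
    lambda_K=0, lambda_D=0, gamma_K0=0, alpha_K=0, gamma_D0=0, alpha_D=0
)
YULE = cm.CloneParams(
    lambda_K=1.0, lambda_D=0, gamma_K0=0, alpha_K=0, gamma_D0=0, alpha_D=0
)


def _tv(p, q):
    n = max(len(p), len(q))
    p = np.pad(np.asarray(p, float), (0, n - len(p)))
    q = np.pad(np.asarray(q, float), (0, n - len(q)))
    return 0.5 * np.abs(p - q).sum()


def _empirical_marginals(states, kmax, dmax):
    pk = np.bincount(states[:, 0], minlength=kmax + 1)[: kmax + 1] / len(states)
    pd_ = np.bincount(states[:, 1], minlength=dmax + 1)[: dmax + 1] / len(states)
    return pk, pd_


class TestSimulator:
    def test_frozen_clone_never_moves(self):
        traj = cm.simulate_clone(FROZEN, 5.0, seed=0)
        assert traj.final_state == (1, 0, 0)
        assert traj.non_terminating

    def test_yule_law(self):
        # pure birth at rate 1 for t=1: P(K=n) = e^-1 (1-e^-1)^(n-1)
        states = cm.simulate_states(YULE, np.ones(100_000), seed=1)
        n = np.arange(1, 30)
        yule = np.exp(-1.0) * (1 - np.exp(-1.0)) ** (n - 1)
        emp = np.bincount(states[:, 0], minlength=30)[1:30] / len(states)
        assert _tv(emp, yule) < 0.01

    def test_divergent_hazard_forces_exhaustion(self):
        p = cm.CloneParams(lambda_K=0.3, lambda_D=0.0, gamma_K0=2.0, alpha_K=2.0,
                           gamma_D0=5.0, alpha_D=2.0)
        states = cm.simulate_states(p, np.full(200, 30.0), seed=2)
        assert (states[:, 0] == 0).all()
        assert (states[:, 1] == 0).all()

    def test_negative_exponent_refused(self):
        with pytest.raises(ValueError):
            cm.CloneParams(alpha_K=-0.5)

    def test_trajectory_invariants(self):
        traj = cm.simulate_clone(cm.CloneParams(), 10.64, seed=3)
        states = traj.states
        assert (states >= 0).all()
        assert np.all(np.diff(states[:, 2]) >= 0)  # pmNB count nondecreasing
        assert np.all(np.diff(traj.times) >= 0)

    def test_endpoint_simulator_agrees_with_trajectory_simulator(self):
        p = cm.CloneParams()
        t = 6.0
        traj_final = np.array(
            [cm.simulate_clone(p, t, seed=s).final_state for s in range(3000)]
        )
        vec = cm.simulate_states(p, np.full(3000, t), seed=99)
        pk1, pd1 = _empirical_marginals(traj_final, 60, 60)
        pk2, pd2 = _empirical_marginals(vec, 60, 60)
        # two independent 3000-sample empirical laws over ~50 categories have
        # an expected TV near 0.06 even when identical; bound well above that
        assert _tv(pk1, pk2) < 0.09
        assert _tv(pd1, pd2) < 0.09


class TestMasterEquation:
    def test_frozen_point_mass(self):
        me = cm.master_equation(FROZEN, 3.0, k_max=5, d_max=5)
        assert me.grid[1, 0] == pytest.approx(1.0, abs=1e-8)

    def test_yule_marginal(self):
        me = cm.master_equation(YULE, 1.0, k_max=50, d_max=1)
        n = np.arange(1, 40)
        yule = np.exp(-1.0) * (1 - np.exp(-1.0)) ** (n - 1)
        np.testing.assert_allclose(me.marginal_k()[1:40], yule, atol=1e-6)

    def test_probability_conserved(self):
        for t in (0.5, 3.0, 8.0):
            me = cm.master_equation(cm.CloneParams(), t, k_max=80, d_max=80)
            assert me.grid.sum() == pytest.approx(1.0, abs=1e-6)

    def test_small_grid_flagged_unreliable(self):
        me = cm.master_equation(cm.CloneParams(), 8.0, k_max=8, d_max=8)
        assert not me.reliable
        assert me.boundary_mass > 1e-6

    @pytest.mark.parametrize(
        "params",
        [
            cm.CloneParams(),  # accelerated, independent coupling
            cm.CloneParams(coupling_K="symmetric"),
            cm.CloneParams(lambda_K=0.35, lambda_D=0.2, alpha_K=0.0, alpha_D=0.0,
                           gamma_K0=0.1, gamma_D0=0.08),
        ],
        ids=["accelerated-independent", "accelerated-symmetric", "constant-propensity"],
    )
    def test_simulator_matches_master_equation(self, params):
        t = 6.0
        me = cm.master_equation(params, t, k_max=120, d_max=120)
        assert me.boundary_mass < 1e-4
        states = cm.simulate_states(params, np.full(100_000, t), seed=7)
        pk, pd_ = _empirical_marginals(states, 120, 120)
        assert _tv(pk, me.marginal_k()) < 0.02
        assert _tv(pd_, me.marginal_d()) < 0.02


class TestSnapshots:
    def test_frozen_params_flagged_empty(self):
        snap, report = cm.sample_kc_snapshot(FROZEN, 50, seed=0)
        assert report["empty"] and report["n_kept"] == 0
        assert len(snap) == 0

    def test_maturation_crescent(self):
        snap, _ = cm.sample_kc_snapshot(cm.CloneParams(), 8000, horizon=10.64, seed=5)
        bins = np.digitize(snap["size"], [4, 8, 16, 30])
        medians = snap.groupby(bins)["prnb_fraction"].median()
        assert medians.is_monotonic_increasing

    def test_snapshot_matches_age_mixed_master_equation(self):
        params = cm.CloneParams()
        ages = np.linspace(0.5, 10.5, 11)
        # oracle: average the ME marginals over the age grid, apply the same
        # >=4-cell filter, renormalize
        kmax = dmax = 90
        mix = np.zeros((kmax + 1, dmax + 1))
        for a in ages:
            mix += cm.master_equation(params, a, k_max=kmax, d_max=dmax).grid
        mix /= len(ages)
        ktot = np.add.outer(np.arange(kmax + 1), np.arange(dmax + 1))
        mix[ktot < 4] = 0.0
        mix /= mix.sum()
        snap, _ = cm.sample_kc_snapshot(
            params, 11 * 9000, age_law=np.tile(ages, 9000), seed=8
        )
        pk = np.bincount(snap["n_tap"], minlength=kmax + 1)[: kmax + 1] / len(snap)
        pd_ = np.bincount(snap["n_prnb"], minlength=dmax + 1)[: dmax + 1] / len(snap)
        assert _tv(pk, mix.sum(axis=1)) < 0.02
        assert _tv(pd_, mix.sum(axis=0)) < 0.02


class TestMonotonicity:
    def test_higher_differentiation_scale_shrinks_terminal_tap_count(self):
        low = cm.CloneParams(gamma_K0=0.005)
        high = cm.CloneParams(gamma_K0=0.05)
        # coupled comparison on shared seeds
        k_low = cm.simulate_states(low, np.full(4000, 8.0), seed=11)[:, 0]
        k_high = cm.simulate_states(high, np.full(4000, 8.0), seed=11)[:, 0]
        assert k_high.mean() < k_low.mean()
        # stochastic dominance on a few quantiles
        for q in (0.25, 0.5, 0.75, 0.9):
            assert np.quantile(k_high, q) <= np.quantile(k_low, q)

    def test_higher_exponent_with_fixed_cumulative_hazard_delays_differentiation(self):
        # fix the cumulative hazard at tau: gamma0 * tau^(a+1)/(a+1) = const
        tau, total = 10.64, 3.0
        first_diff_medians = []
        for alpha in (1.0, 3.0):
            gamma0 = total * (alpha + 1) / tau ** (alpha + 1)
            p = cm.CloneParams(lambda_K=0.0, lambda_D=0.0, gamma_K0=gamma0,
                               alpha_K=alpha, gamma_D0=0.0, alpha_D=0.0)
            times = []
            for s in range(400):
                traj = cm.simulate_clone(p, tau, seed=s)
                diffs = [t for t, e in zip(traj.times, traj.events)
                         if e == "tap_differentiation"]
                if diffs:
                    times.append(diffs[0])
            first_diff_medians.append(np.median(times))
        assert first_diff_medians[1] > first_diff_medians[0]


class TestFitting:
    @pytest.fixture(scope="class")
    def synthetic_observation(self):
        truth = cm.CloneParams()
        snap, _ = cm.sample_kc_snapshot(truth, 4000, horizon=10.64, seed=11)
        return (
            truth,
            cm.CountDistribution.from_counts(snap["n_tap"]),
            cm.CountDistribution.from_counts(snap["n_prnb"]),
        )

    def test_parameter_recovery_within_bootstrap_cis(self, synthetic_observation):
        truth, obs_tap, obs_prnb = synthetic_observation
        settings = cm.FitSettings(n_sim=2500, maxiter=120)
        fit = cm.fit_clone_model(obs_tap, obs_prnb, "power-law", settings, seed=0)
        # nonparametric bootstrap over the observed KCs
        rng = np.random.default_rng(1)
        boot = []
        n = obs_tap.n_obs
        tap_vals = np.repeat(obs_tap.support, obs_tap.counts())
        prnb_vals = np.repeat(obs_prnb.support, obs_prnb.counts())
        for b in range(8):
            idx = rng.integers(0, len(tap_vals), len(tap_vals))
            bt = cm.CountDistribution.from_counts(tap_vals[idx])
            bp = cm.CountDistribution.from_counts(prnb_vals[rng.integers(0, len(prnb_vals), len(prnb_vals))])
            bf = cm.fit_clone_model(
                bt, bp, "power-law", cm.FitSettings(n_sim=1500, maxiter=60),
                seed=100 + b, x0=fit.params,
            )
            boot.append([bf.params.lambda_K, bf.params.lambda_D,
                         bf.params.alpha_K, bf.params.alpha_D])
        boot = np.asarray(boot)
        lo = np.quantile(boot, 0.025, axis=0)
        hi = np.quantile(boot, 0.975, axis=0)
        true_vals = [truth.lambda_K, truth.lambda_D, truth.alpha_K, truth.alpha_D]
        # allow tiny slack around the percentile interval at this bootstrap size
        for t, a, b_ in zip(true_vals, lo, hi):
            assert a - 0.15 * t <= t <= b_ + 0.15 * t

    def test_nested_constant_model_recovered(self):
        truth = cm.CloneParams(alpha_K=0.0, alpha_D=0.0, gamma_K0=0.08, gamma_D0=0.05)
        snap, _ = cm.sample_kc_snapshot(truth, 3000, horizon=10.64, seed=21)
        obs_tap = cm.CountDistribution.from_counts(snap["n_tap"])
        obs_prnb = cm.CountDistribution.from_counts(snap["n_prnb"])
        settings = cm.FitSettings(n_sim=2000, maxiter=120)
        fit_pow = cm.fit_clone_model(obs_tap, obs_prnb, "power-law", settings, seed=2,
                                     x0=cm.CloneParams(alpha_K=0.3, alpha_D=0.3,
                                                       gamma_K0=0.05, gamma_D0=0.05))
        fit_const = cm.fit_clone_model(obs_tap, obs_prnb, "constant", settings, seed=2,
                                       x0=cm.CloneParams(alpha_K=0, alpha_D=0,
                                                         gamma_K0=0.05, gamma_D0=0.05))
        # the power-law fit finds (nearly) no acceleration and no real NLL gain
        assert fit_pow.params.alpha_K < 0.6
        assert fit_const.nll - fit_pow.nll < 6.0

    def test_empty_observation_fails(self):
        with pytest.raises(ValueError):
            cm.CountDistribution.from_counts([])

    def test_identical_fits_tie(self, synthetic_observation):
        _, obs_tap, obs_prnb = synthetic_observation
        settings = cm.FitSettings(n_sim=1000, maxiter=30)
        f = cm.fit_clone_model(obs_tap, obs_prnb, "power-law", settings, seed=3)
        table = cm.compare_variants([f, f])
        assert table["delta_aic"].iloc[1] == pytest.approx(0.0)
        assert table["tied_with_best"].all()

    def test_mixed_datasets_refused(self, synthetic_observation):
        _, obs_tap, obs_prnb = synthetic_observation
        settings = cm.FitSettings(n_sim=800, maxiter=20)
        f1 = cm.fit_clone_model(obs_tap, obs_prnb, "power-law", settings, seed=4)
        other = cm.CountDistribution.from_counts([4, 5, 6, 7, 8] * 10)
        f2 = cm.fit_clone_model(other, obs_prnb, "power-law", settings, seed=4)
        with pytest.raises(ValueError):
            cm.compare_variants([f1, f2])
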