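"""Windowed objectives, container densities, IDI and confidence limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynia_mc.dynia import (
    DyniaConfig,
    confidence_limits,
    container_density,
    ic_noise_band,
    idi,
    run_dynia,
    select_support,
    windowed_objective,
)
from dynia_mc.experiments import run_replicate
from dynia_mc.parameter_space import (
    ParameterRegistry,
    ParameterSpec,
    SampleMatrix,
)


def naive_windowed(sim, obs, w, metric):
    """Independent double-loop oracle for the moving-window objective."""
    n, T = sim.shape
    out = np.empty((n, T))
    for r in range(n):
        for t in range(T):
            lo, hi = max(0, t - w), min(T, t + w + 1)
            res = [abs(sim[r, i] - obs[i]) for i in range(lo, hi)]
            if metric == "mae":
                out[r, t] = sum(res) / len(res)
            else:
                out[r, t] = (sum(x * x for x in res) / len(res)) ** 0.5
    return out


class TestWindowedObjective:
    def test_perfect_run_scores_zero(self):
        obs = np.linspace(0, 5, 30)
        sim = np.vstack([obs, obs + 1])
        m = windowed_objective(sim, obs, window=3, metric="mae")
        np.testing.assert_allclose(m.values[0], 0.0)
        np.testing.assert_allclose(m.values[1], 1.0)

    def test_hand_computed_example(self):
        # obs=[1,2,3], sim=[2,2,2], w=1: residuals |1|,|0|,|1|; at t=1 the
        # window covers all three -> MAE = 2/3
        m = windowed_objective(np.array([[2.0, 2, 2]]), np.array([1.0, 2, 3]),
                               window=1, metric="mae")
        assert m.values[0, 1] == pytest.approx(2 / 3)
        # truncated edge windows
        assert m.values[0, 0] == pytest.approx(1 / 2)

    def test_window_saturation(self):
        rng = np.random.default_rng(0)
        sim = rng.random((4, 12))
        obs = rng.random(12)
        m = windowed_objective(sim, obs, window=50, metric="rmse")
        whole = np.sqrt(np.mean((sim - obs) ** 2, axis=1))
        for t in range(12):
            np.testing.assert_allclose(m.values[:, t], whole, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            windowed_objective(np.zeros((2, 5)), np.zeros(6), 1, "mae")

    @pytest.mark.parametrize("metric", ["mae", "rmse"])
    def test_matches_naive_double_loop_oracle(self, metric):
        rng = np.random.default_rng(99)
        for _ in range(10):
            sim = rng.normal(size=(20, 50))
            obs = rng.normal(size=50)
            w = int(rng.integers(0, 12))
            fast = windowed_objective(sim, obs, w, metric).values
            slow = naive_windowed(sim, obs, w, metric)
            np.testing.assert_allclose(fast, slow, atol=1e-12, rtol=0)


class TestSelectSupport:
    def test_smallest_errors_selected(self):
        col = np.array([5.0, 1, 4, 0.5, 3, 2, 9, 8, 7, 6])
        idx = select_support(col, 0.2)
        assert sorted(idx) == [1, 3]

    def test_full_fraction_is_identity(self):
        idx = select_support(np.arange(7, dtype=float), 1.0)
        assert sorted(idx) == list(range(7))

    def test_stable_tie_break(self):
        col = np.ones(10)
        col[[3, 7]] = 0.5
        col[0] = 0.1
        # ceil(0.3 * 10) = 3 -> 0, then tie between 3 and 7 resolved by index
        idx = select_support(col, 0.3)
        assert list(idx) == [0, 3, 7]

    def test_all_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            select_support(np.full(5, np.nan), 0.5)


class TestContainerDensity:
    def test_one_value_per_bin(self):
        m = 8
        mids = (np.arange(m) + 0.5) / m
        p = container_density(mids, 0.0, 1.0, m)
        np.testing.assert_allclose(p, 1 / m)

    def test_point_mass(self):
        p = container_density(np.full(20, 0.37), 0.0, 1.0, 10)
        assert p[3] == 1.0 and p.sum() == 1.0

    def test_hand_counted_histogram(self):
        p = container_density(np.array([0.05, 0.15, 0.15, 0.95]), 0.0, 1.0, 10)
        expected = np.zeros(10)
        expected[[0, 1, 9]] = [0.25, 0.5, 0.25]
        np.testing.assert_allclose(p, expected)

    def test_upper_bound_value_counts_in_last_bin(self):
        p = container_density(np.array([1.0, 0.0]), 0.0, 1.0, 4)
        assert p[0] == 0.5 and p[-1] == 0.5

    def test_constant_parameter_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            container_density(np.array([1.0]), 1.0, 1.0, 5)

    def test_out_of_bounds_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = container_density(np.array([-0.5, 2.0]), 0.0, 1.0, 4)
        assert p[0] == 0.5 and p[-1] == 0.5


class TestIdi:
    def test_uniform_gives_zero(self):
        assert idi(np.full(20, 1 / 20)) == pytest.approx(0.0)

    def test_point_mass_gives_one(self):
        p = np.zeros(20)
        p[4] = 1.0
        assert idi(p) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        p = np.zeros(10)
        p[:2] = 0.5
        assert idi(p) == pytest.approx(8 / 9)

    def test_unnormalised_density_rejected(self):
        with pytest.raises(ValueError, match="sums"):
            idi(np.full(10, 0.2))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bounds_and_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(12))
        v = idi(p)
        assert 0.0 <= v <= 1.0
        shuffled = rng.permutation(p)
        assert idi(shuffled) == pytest.approx(v)


class TestConfidenceLimits:
    def test_degenerate_support_has_full_information(self):
        lo, hi, ic = confidence_limits(np.full(9, 0.4), 0.0, 1.0)
        assert lo == hi == 0.4 and ic == 1.0

    def test_uniform_support_gives_baseline_information(self):
        rng = np.random.default_rng(5)
        v = rng.random(100_000)
        lo, hi, ic = confidence_limits(v, 0.0, 1.0)
        assert ic == pytest.approx(0.10, abs=0.01)

    def test_endpoints_only_gives_zero(self):
        v = np.array([0.0, 1.0] * 10)
        _, _, ic = confidence_limits(v, 0.0, 1.0)
        assert ic == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confidence_limits(np.array([]), 0, 1)


def _toy_problem(n=40, T=30, seed=0):
    rng = np.random.default_rng(seed)
    reg = ParameterRegistry(
        [ParameterSpec("a", 0.0, 1.0), ParameterSpec("b", -2.0, 2.0),
         ParameterSpec("k", 3.0, 3.0, distribution="constant")]
    )
    values = np.column_stack(
        [rng.random(n), rng.uniform(-2, 2, n), np.full(n, 3.0)]
    )
    samples = SampleMatrix(values, ["a", "b", "k"], seed=seed)
    t = np.arange(T)
    sim = values[:, [0]] * t  # output driven purely by parameter a
    obs = 0.45 * t
    return reg, samples, sim, obs


class TestRunDynia:
    def test_determinism_and_density_normalisation(self):
        reg, samples, sim, obs = _toy_problem()
        cfg = DyniaConfig(window=3, containers=5, support_fraction=0.25)
        r1 = run_dynia(sim, obs, samples, reg, cfg)
        r2 = run_dynia(sim, obs, samples, reg, cfg)
        for name, pr in r1.parameters.items():
            np.testing.assert_allclose(pr.density.sum(axis=0), 1.0, atol=1e-12)
            np.testing.assert_array_equal(pr.density,
                                          r2.parameters[name].density)
        assert np.all((r1.parameters["a"].idi >= 0)
                      & (r1.parameters["a"].idi <= 1))

    def test_informative_parameter_found_constant_skipped(self):
        reg, samples, sim, obs = _toy_problem()
        cfg = DyniaConfig(window=3, containers=5, support_fraction=0.25)
        r = run_dynia(sim, obs, samples, reg, cfg)
        assert r.skipped == ["k"]
        # a drives the output; b is pure noise
        assert r.parameters["a"].idi.mean() > r.parameters["b"].idi.mean()
        assert r.parameters["a"].ic.mean() > r.parameters["b"].ic.mean()

    def test_degenerate_identical_ensemble_uses_stable_tie_break(self):
        reg, samples, sim, obs = _toy_problem()
        sim = np.zeros_like(sim)
        cfg = DyniaConfig(window=2, containers=5, support_fraction=0.25)
        r = run_dynia(sim, obs, samples, reg, cfg)
        k = r.support.shape[0]
        for t in range(sim.shape[1]):
            assert list(r.support[:, t]) == list(range(k))

    def test_too_few_runs_rejected(self):
        reg, samples, sim, obs = _toy_problem(n=4)
        with pytest.raises(ValueError, match="at least"):
            run_dynia(sim[:2] * np.nan, obs, samples, reg,
                      DyniaConfig(support_fraction=1.0))

    def test_confidence_limits_stay_within_prior_bounds(self):
        reg, samples, sim, obs = _toy_problem()
        r = run_dynia(sim, obs, samples, reg,
                      DyniaConfig(window=3, containers=5, support_fraction=0.3))
        for pr in r.parameters.values():
            spec = reg[pr.name]
            assert np.all(pr.cl_low >= spec.lower)
            assert np.all(pr.cl_high <= spec.upper)
            assert np.all(pr.cl_low <= pr.cl_high)


@pytest.fixture(scope="module")
def replicate(registry):
    return run_replicate(registry, seed=123, n_runs=200)


class TestGroundTruthOrdering:
    """Closed-loop sanity on the surrogate at reduced size."""

    def test_inert_salinity_parameter_less_identifiable_than_cgc(self, replicate):
        assert replicate.idi_mean["X16"] < replicate.idi_mean["X29"]

    def test_inert_information_content_within_null_band(self, replicate):
        for name in ("X16", "X13", "X11"):
            lo, hi = replicate.ic_band[name]
            assert lo <= replicate.ic_mean[name] <= hi

    def test_sensitive_confidence_limits_cover_truth(self):
        """90% support CLs of CGC and WP* bracket the generating value well
        above nominal-minus-15 points (GLUE-style limits are conservative)."""
        from dynia_mc.experiments import ground_truth_recovery

        exp = ground_truth_recovery(seed=7, n_replicates=5, n_runs=200)
        for name in ("X29", "X31"):
            coverage = np.mean(
                [rep.cl_covers_truth[name] for rep in exp.replicates]
            )
            assert coverage >= 0.75


def test_ic_noise_band_brackets_uniform_baseline(registry, samples_small):
    bands = ic_noise_band(samples_small, registry, support_size=10, n_draws=200,
                          seed=3)
    lo, hi = bands["X11"]
    assert lo < 0.10 < hi  # uniform support IC baseline at the 5/95 level
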