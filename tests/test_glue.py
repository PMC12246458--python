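"""NRMSE scoring, behavioural acceptance and prediction bounds."""

import numpy as np
import pytest

from dynia_mc.glue import (
    behavioural_filter,
    nrmse,
    nrmse_report,
    prediction_bounds,
    uncertainty_summary,
)
from dynia_mc.treatment_runner import Ensemble


def _ensemble(values, channels=("a", "b")):
    values = np.asarray(values, dtype=float)
    n, T, c = values.shape
    return Ensemble(
        values=values,
        run_ids=list(range(1, n + 1)),
        time=np.arange(1, T + 1, dtype=float),
        channel_names=list(channels)[:c],
    )


class TestNrmse:
    def test_perfect_fit_is_zero(self):
        obs = np.array([3.0, 4, 5])
        assert nrmse(obs, obs) == 0.0

    def test_hand_checked_value(self):
        # RMSE = 1, mean obs = 10 -> 10%
        assert nrmse(np.array([11.0, 9.0]), np.array([10.0, 10.0])) == \
            pytest.approx(10.0)

    def test_zero_mean_normalisation_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            nrmse(np.array([0.0, 0.0]), np.array([-1.0, 1.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            nrmse(np.zeros(3), np.zeros(4))

    def test_range_normalisation_option(self):
        v = nrmse(np.array([11.0, 9.0]), np.array([8.0, 12.0]),
                  normalization="range")
        assert v == pytest.approx(100 * np.sqrt(((3.0)**2 + (3.0)**2) / 2) / 4)


class TestBehaviouralFilter:
    @pytest.fixture
    def report(self):
        ens = _ensemble(np.stack([
            np.stack([np.full(4, 10.0 + d), np.full(4, 5.0)], axis=-1)
            for d in (0.0, 1.0, 3.0)
        ]))
        obs = {"a": np.full(4, 10.0), "b": np.full(4, 5.0)}
        return nrmse_report(ens, obs)

    def test_infinite_threshold_accepts_everything(self, report):
        bset = behavioural_filter(report, "a", threshold=np.inf)
        assert len(bset) == 3
        np.testing.assert_allclose(bset.weights, 1 / 3)
        assert bset.acceptance_rate == 1.0

    def test_boundary_is_inclusive(self):
        import pandas as pd
        rep = pd.DataFrame({"y": [5.0, 10.0, 10.001]},
                           index=pd.Index([1, 2, 3], name="run_id"))
        bset = behavioural_filter(rep, "y", threshold=10.0)
        assert list(bset.run_ids) == [1, 2]

    def test_zero_acceptance_cites_minimum(self):
        import pandas as pd
        rep = pd.DataFrame({"y": [42.0, 55.0]},
                           index=pd.Index([1, 2], name="run_id"))
        with pytest.raises(ValueError, match="42"):
            behavioural_filter(rep, "y", threshold=10.0)

    def test_threshold_monotonicity(self, report):
        small = behavioural_filter(report, "a", threshold=15.0)
        large = behavioural_filter(report, "a", threshold=40.0)
        assert set(small.run_ids) <= set(large.run_ids)

    def test_invalid_inputs(self, report):
        with pytest.raises(ValueError, match="positive"):
            behavioural_filter(report, "a", threshold=0.0)
        with pytest.raises(KeyError, match="nope"):
            behavioural_filter(report, "nope", threshold=10.0)


class TestPredictionBounds:
    def test_single_run_bounds_collapse_onto_it(self):
        ens = _ensemble(np.arange(8, dtype=float).reshape(1, 4, 2))
        import pandas as pd
        rep = pd.DataFrame({"a": [0.0]}, index=pd.Index([1], name="run_id"))
        bset = behavioural_filter(rep, "a", threshold=1.0)
        b = prediction_bounds(ens, bset, "a", level=0.9)
        np.testing.assert_array_equal(b.lower, b.upper)
        np.testing.assert_array_equal(b.lower, ens.channel("a")[0])

    def test_level_one_is_the_envelope(self):
        rng = np.random.default_rng(1)
        vals = rng.random((20, 6, 1))
        ens = _ensemble(vals, channels=("a",))
        import pandas as pd
        rep = pd.DataFrame({"a": np.zeros(20)},
                           index=pd.Index(ens.run_ids, name="run_id"))
        bset = behavioural_filter(rep, "a", threshold=1.0)
        b = prediction_bounds(ens, bset, "a", level=1.0)
        np.testing.assert_allclose(b.lower, vals[:, :, 0].min(axis=0))
        np.testing.assert_allclose(b.upper, vals[:, :, 0].max(axis=0))

    def test_ninety_percent_band_covers_ninety_percent(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(1000, 5, 1))
        ens = _ensemble(vals, channels=("a",))
        import pandas as pd
        rep = pd.DataFrame({"a": np.zeros(1000)},
                           index=pd.Index(ens.run_ids, name="run_id"))
        bset = behavioural_filter(rep, "a", threshold=1.0)
        b = prediction_bounds(ens, bset, "a", level=0.9)
        sims = ens.channel("a")
        inside = np.mean((sims >= b.lower) & (sims <= b.upper), axis=0)
        np.testing.assert_allclose(inside, 0.9, atol=0.02)

    def test_bands_monotone_in_level(self):
        rng = np.random.default_rng(3)
        ens = _ensemble(rng.random((50, 8, 1)), channels=("a",))
        import pandas as pd
        rep = pd.DataFrame({"a": np.zeros(50)},
                           index=pd.Index(ens.run_ids, name="run_id"))
        bset = behavioural_filter(rep, "a", threshold=1.0)
        b90 = prediction_bounds(ens, bset, "a", level=0.90)
        b95 = prediction_bounds(ens, bset, "a", level=0.95)
        assert np.all(b95.lower <= b90.lower)
        assert np.all(b95.upper >= b90.upper)

    def test_bad_level_rejected(self):
        ens = _ensemble(np.zeros((2, 3, 1)), channels=("a",))
        import pandas as pd
        rep = pd.DataFrame({"a": np.zeros(2)},
                           index=pd.Index([1, 2], name="run_id"))
        bset = behavioural_filter(rep, "a", threshold=1.0)
        with pytest.raises(ValueError, match="level"):
            prediction_bounds(ens, bset, "a", level=1.5)


class TestUncertaintySummary:
    def _bounds(self, lower, upper):
        from dynia_mc.glue import PredictionBounds
        return PredictionBounds(lower=np.asarray(lower, float),
                                upper=np.asarray(upper, float), level=0.9)

    def test_identical_bounds_tie(self):
        obs = {"a": np.array([1.0, 1, 1]), "b": np.array([1.0, 1, 1])}
        bounds = {v: self._bounds([0.5] * 3, [1.5] * 3) for v in obs}
        df = uncertainty_summary(bounds, obs)
        assert list(df["rank"]) == [1, 1]

    def test_zero_width_variable_ranks_most_certain(self):
        obs = {"tight": np.ones(4), "wide": np.ones(4)}
        bounds = {
            "tight": self._bounds(np.ones(4), np.ones(4)),
            "wide": self._bounds(np.zeros(4), np.full(4, 2.0)),
        }
        df = uncertainty_summary(bounds, obs)
        assert df.iloc[0]["variable"] == "tight"
        assert df.iloc[0]["relative_width"] == 0.0
        assert df.iloc[0]["containment"] == 1.0

    def test_noise_injected_channel_ranks_more_uncertain(self):
        """Behavioural spread injected into 'evaporation' must outrank the
        quiet 'transpiration' channel."""
        rng = np.random.default_rng(11)
        T = 50
        base = np.sin(np.linspace(0, 3, T)) + 2.0
        evap = base + rng.normal(0, 0.8, size=(30, T))
        transp = base + rng.normal(0, 0.05, size=(30, T))
        vals = np.stack([evap, transp], axis=-1)
        ens = _ensemble(vals, channels=("evaporation", "transpiration"))
        import pandas as pd
        rep = pd.DataFrame(
            {"evaporation": np.zeros(30)},
            index=pd.Index(ens.run_ids, name="run_id"),
        )
        bset = behavioural_filter(rep, "evaporation", threshold=1.0)
        bounds = {
            v: prediction_bounds(ens, bset, v, 0.9)
            for v in ("evaporation", "transpiration")
        }
        obs = {"evaporation": base, "transpiration": base}
        df = uncertainty_summary(bounds, obs)
        ranks = dict(zip(df["variable"], df["rank"]))
        assert ranks["transpiration"] < ranks["evaporation"]

    def test_needs_two_variables(self):
        with pytest.raises(ValueError, match="two"):
            uncertainty_summary({"a": self._bounds([0], [1])}, {"a": np.ones(1)})
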