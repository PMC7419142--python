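"""Experiment protocol plumbing: seeding, records, summaries, fits."""

import numpy as np
import pandas as pd
import pytest

from cxring import experiments as ex
from cxring.circuit import build_species_circuit
from cxring.fixtures import TINY_WEIGHTS


class TestTrialSeeds:
    def test_deterministic_and_distinct(self):
        assert ex.trial_seed(7, 1, 3) == ex.trial_seed(7, 1, 3)
        assert ex.trial_seed(7, 1, 3) != ex.trial_seed(7, 1, 4)
        assert ex.trial_seed(7, 1, 3) != ex.trial_seed(8, 1, 3)

    def test_counter_scheme_stable_under_extension(self):
        # adding trials must not change the seeds of earlier trials
        first_ten = [ex.trial_seed(0, 1, i) for i in range(10)]
        first_five = [ex.trial_seed(0, 1, i) for i in range(5)]
        assert first_ten[:5] == first_five

    def test_below_31_bits(self):
        assert 0 <= ex.trial_seed(2**40, 99, 99) < 2**31


class TestExponentialFit:
    def test_recovers_parameters(self):
        x = np.linspace(40, 240, 6)
        y = 2.0 * np.exp(0.012 * x)
        fit = ex.fit_exponential(x, y)
        assert fit["a"] == pytest.approx(2.0, rel=1e-3)
        assert fit["b"] == pytest.approx(0.012, rel=1e-3)
        assert fit["r2"] > 0.999

    def test_handles_noise_and_nonpositive(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 8)
        y = 3 * np.exp(0.3 * x) * rng.lognormal(0, 0.05, 8)
        y[0] = 0.0   # dropped
        fit = ex.fit_exponential(x, y)
        assert fit["b"] == pytest.approx(0.3, abs=0.05)

    def test_too_few_points(self):
        fit = ex.fit_exponential(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert np.isnan(fit["b"])


class TestUnwrap:
    def test_continuous_through_wrap(self):
        h = np.array([350.0, 355.0, 0.0, 5.0, 10.0])
        u = ex._unwrap_deg(h)
        assert np.allclose(np.diff(u), 5.0)

    def test_nan_passthrough(self):
        h = np.array([10.0, np.nan, 20.0])
        u = ex._unwrap_deg(h)
        assert np.isnan(u[1]) and np.isfinite(u[0])


class TestStableRange:
    def test_range_width(self):
        df = pd.DataFrame({"factor": [-1, -0.5, 0, 0.5, 1.0],
                           "stable_fraction": [0.1, 0.8, 1.0, 0.9, 0.2]})
        res = ex.ExperimentResult("asymmetry_tolerance", "x", df, df)
        assert ex.stable_factor_range(res) == pytest.approx(1.0)

    def test_empty_range(self):
        df = pd.DataFrame({"factor": [0.0], "stable_fraction": [0.1]})
        res = ex.ExperimentResult("asymmetry_tolerance", "x", df, df)
        assert ex.stable_factor_range(res) == 0.0


class TestTinyProtocols:
    """Protocol plumbing on the 4-octant analogue (fast, not calibrated)."""

    @pytest.fixture(scope="class")
    def tiny(self):
        return build_species_circuit("locust", TINY_WEIGHTS, n_octants=4)

    def test_maintenance_records_reproducible(self, tiny, params):
        kw = dict(n_trials=2, stim_duration=0.5, measure_after=0.5,
                  peak_rate=150.0, seed=5)
        a = ex.run_bump_maintenance(tiny, params, **kw)
        b = ex.run_bump_maintenance(tiny, params, **kw)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert set(a.records.columns) >= {"trial", "seed", "cls", "fwhm",
                                          "peak", "amplitude", "success"}

    def test_zero_weight_circuit_no_bump(self, params):
        from cxring.circuit import WeightVector
        dead = build_species_circuit("locust", WeightVector.zeros(),
                                     n_octants=4)
        res = ex.run_bump_maintenance(dead, params, n_trials=2,
                                      stim_duration=0.5, measure_after=0.5,
                                      peak_rate=150.0, seed=1)
        assert res.meta["success_fraction"] == 0.0

    def test_csv_emission(self, tiny, params, tmp_path):
        res = ex.run_bump_maintenance(tiny, params, n_trials=1,
                                      stim_duration=0.5, measure_after=0.5,
                                      peak_rate=150.0, seed=2)
        res.to_csv(tmp_path)
        assert (tmp_path / "bump_maintenance_records.csv").exists()
        assert (tmp_path / "bump_maintenance_summary.csv").exists()

    def test_heading_change_zero_delta_trivial(self, params):
        # stimulus-driven: the tiny ring tracks the cue even though it is
        # not a self-sustaining attractor
        tiny_fly = build_species_circuit("fly", TINY_WEIGHTS, n_octants=4)
        res = ex.run_heading_change(tiny_fly, params, delta=0.0, n_trials=1,
                                    stim1=0.8, darkness=0.2, stim2=1.5,
                                    peak_rate=150.0, seed=3,
                                    settle_tolerance=45.0)
        rec = res.records.iloc[0]
        assert rec["kind"] == "gradual"
        assert rec["transition_time"] <= 1.0
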