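"""Rogers' random-predator equation: solver, fitting, group means, bands."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from frphylo.frfit import (
    bootstrap_group_band,
    fit_fr,
    group_mean_params,
    params_to_frame,
    rogers_predict,
    rogers_residual,
)

LEVELS = np.array([1, 2, 4, 6, 8, 10, 12], dtype=float)


def synthetic_frame(a, h, T=60.0, levels=LEVELS, reps=3, species="sp", temp=30.0,
                    noise_sd=0.0, rng=None):
    N = np.tile(levels, reps)
    Ne = rogers_predict(N, a, h, T)
    if noise_sd:
        Ne = np.clip(Ne + rng.normal(0, noise_sd, N.size), 0, N)
    return pd.DataFrame(
        {"species": species, "temperature_C": temp, "N_initial_g": N, "net_g": Ne}
    )


class TestRogersSolver:
    def test_zero_attack_rate_gives_zero_consumption(self):
        assert rogers_predict(8.0, 0.0, 2.0, 60.0) == 0.0

    def test_zero_handling_time_is_exponential_depletion(self):
        N, a, T = 7.0, 0.12, 60.0
        assert rogers_predict(N, a, 0.0, T) == pytest.approx(
            N * (1 - math.exp(-a * T)), abs=1e-14
        )

    def test_matches_bisection_root_of_implicit_equation(self):
        N, a, h, T = 6.0, 0.05, 2.0, 60.0
        root = brentq(lambda ne: rogers_residual(ne, N, a, h, T), 0.0, N, xtol=1e-14)
        assert rogers_predict(N, a, h, T) == pytest.approx(root, abs=1e-10)

    def test_residual_zero_at_trivial_point(self):
        assert rogers_residual(0.0, 5.0, 0.0, 2.0, 60.0) == 0.0

    def test_self_consistency_over_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            N = rng.uniform(0.1, 20)
            a = rng.uniform(1e-4, 1.0)
            h = rng.uniform(1e-3, 50.0)
            T = rng.uniform(1.0, 200.0)
            ne = rogers_predict(N, a, h, T)
            assert abs(rogers_residual(ne, N, a, h, T)) < 1e-10

    def test_residual_brackets_root(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            N = rng.uniform(0.5, 15)
            a = rng.uniform(1e-3, 0.5)
            h = rng.uniform(0.1, 30)
            T = rng.uniform(10, 100)
            assert rogers_residual(0.0, N, a, h, T) <= 0
            assert rogers_residual(N, N, a, h, T) >= 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.floats(1e-4, 0.5), h=st.floats(1e-3, 40.0),
        T=st.floats(5.0, 150.0), N=st.floats(0.01, 15.0),
    )
    def test_monotone_in_each_argument(self, a, h, T, N):
        base = rogers_predict(N, a, h, T)
        eps = 1e-4
        assert rogers_predict(N * (1 + eps), a, h, T) >= base - 1e-12
        assert rogers_predict(N, a * (1 + eps), h, T) >= base - 1e-12
        assert rogers_predict(N, a, h, T * (1 + eps)) >= base - 1e-12
        assert rogers_predict(N, a, h * (1 + eps), T) <= base + 1e-12
        assert 0.0 <= base <= N

    def test_saturates_at_T_over_h(self):
        a, h, T = 0.05, 2.5, 60.0
        assert rogers_predict(1e6, a, h, T) == pytest.approx(T / h, rel=1e-3)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            rogers_predict(-1.0, 0.1, 1.0, 60.0)
        with pytest.raises(ValueError):
            rogers_predict(1.0, -0.1, 1.0, 60.0)


class TestFitFR:
    def test_noiseless_round_trip_recovers_parameters(self):
        a, h = 0.08, 1.5
        fit = fit_fr(synthetic_frame(a, h, reps=1), 60.0)
        assert fit.converged
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.h == pytest.approx(h, rel=1e-6)
        assert fit.max_rate * fit.h == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_consumption_flagged_boundary(self):
        df = synthetic_frame(0.0, 1.0, reps=1)
        fit = fit_fr(df, 60.0)
        assert not fit.converged
        assert fit.a < 1e-9

    def test_permutation_invariance(self, rng):
        df = synthetic_frame(0.05, 8.0, noise_sd=0.2, rng=rng)
        fit1 = fit_fr(df, 60.0)
        fit2 = fit_fr(df.sample(frac=1, random_state=3), 60.0)
        assert fit1.a == pytest.approx(fit2.a, rel=1e-9)
        assert fit1.h == pytest.approx(fit2.h, rel=1e-9)

    def test_requires_three_distinct_biomass_levels(self):
        df = synthetic_frame(0.05, 2.0, levels=np.array([4.0, 4.0, 8.0]), reps=1)
        with pytest.raises(ValueError):
            fit_fr(df, 60.0)

    def test_time_rescaling_consistency(self):
        """Refitting data simulated at a different T recovers the same (a, h)."""
        a, h = 0.06, 3.0
        for T in (30.0, 120.0):
            fit = fit_fr(synthetic_frame(a, h, T=T, reps=1), T)
            assert fit.a == pytest.approx(a, rel=1e-6)
            assert fit.h == pytest.approx(h, rel=1e-6)


class TestGroupMeans:
    def _params(self, values, temp=30.0):
        frames = [
            synthetic_frame(a, h, species=f"sp{i}", temp=temp, reps=1)
            for i, (a, h) in enumerate(values)
        ]
        return [fit_fr(f, 60.0) for f in frames]

    def test_identical_parameters_mean_is_common_value(self):
        params = self._params([(0.05, 4.0)] * 5)
        out = group_mean_params(params, {f"sp{i}": "familiar" for i in range(5)})
        assert out.loc[0, "a"] == pytest.approx(0.05, rel=1e-6)
        assert out.loc[0, "h"] == pytest.approx(4.0, rel=1e-6)

    def test_mean_equals_brute_force_sum(self):
        values = [(0.02, 2.0), (0.04, 3.0), (0.06, 5.0), (0.08, 8.0), (0.10, 13.0)]
        params = self._params(values)
        out = group_mean_params(params, {f"sp{i}": "novel" for i in range(5)})
        assert out.loc[0, "a"] == pytest.approx(sum(v[0] for v in values) / 5, rel=1e-6)
        assert out.loc[0, "h"] == pytest.approx(sum(v[1] for v in values) / 5, rel=1e-6)

    def test_missing_species_raises_with_names(self):
        params = self._params([(0.05, 4.0)] * 4)
        with pytest.raises(ValueError, match="sp4"):
            group_mean_params(params, {f"sp{i}": "familiar" for i in range(5)})

    def test_study_shape_yields_ten_group_temperature_means(self):
        params = []
        for temp in (26.0, 28.0, 30.0, 32.0, 34.0):
            params.extend(self._params([(0.05, 4.0)] * 10, temp=temp))
        group_of = {f"sp{i}": ("familiar" if i < 5 else "novel") for i in range(10)}
        out = group_mean_params(params, group_of)
        assert len(out) == 10


class TestBootstrapBand:
    def _group_frame(self, noise_sd, rng):
        frames = [
            synthetic_frame(0.05, 8.0, species=f"sp{i}", noise_sd=noise_sd, rng=rng)
            for i in range(5)
        ]
        return pd.concat(frames, ignore_index=True)

    def test_zero_noise_band_degenerates(self, rng):
        df = self._group_frame(0.0, rng)
        band = bootstrap_group_band(
            df, "familiar", 30.0, 60.0, n_boot=200, seed=0,
            group_of={f"sp{i}": "familiar" for i in range(5)},
        )
        assert np.all(band.upper - band.lower < 1e-8)

    def test_band_contains_point_estimate_and_is_ordered(self, rng):
        for rep in range(20):
            df = self._group_frame(0.3, rng)
            band = bootstrap_group_band(
                df, "familiar", 30.0, 60.0, n_boot=200, seed=rep,
                group_of={f"sp{i}": "familiar" for i in range(5)},
            )
            assert np.all(band.lower <= band.mean + 1e-9)
            assert np.all(band.mean <= band.upper + 1e-9)
            assert np.all(band.lower >= -1e-12)
            assert np.all(np.diff(band.mean) >= -1e-9)  # fitted curve monotone

    def test_same_seed_reproduces_band(self, rng):
        df = self._group_frame(0.3, rng)
        kwargs = dict(group_of={f"sp{i}": "familiar" for i in range(5)})
        b1 = bootstrap_group_band(df, "familiar", 30.0, 60.0, n_boot=100, seed=5, **kwargs)
        b2 = bootstrap_group_band(df, "familiar", 30.0, 60.0, n_boot=100, seed=5, **kwargs)
        assert np.array_equal(b1.lower, b2.lower) and np.array_equal(b1.upper, b2.upper)


def test_params_frame_columns():
    fit = fit_fr(synthetic_frame(0.05, 4.0, reps=1), 60.0)
    df = params_to_frame([fit])
    assert list(df.columns) == [
        "species", "temperature_C", "a", "h", "max_rate", "n_points", "converged", "sse",
    ]
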