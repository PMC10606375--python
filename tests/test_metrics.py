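"""Derived Franz-cell metrics and the replicate statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from dermasim import units
from dermasim.core import DomainError
from dermasim.franz import run_ivrt
from dermasim.metrics import (ExperimentDataset, compare_groups_per_timepoint,
                              cumulative_per_area, layer_accumulation,
                              oneway_anova, permeability_coefficient,
                              recovery_percent, steady_state_flux_and_lag)
from dermasim.presets import build_experiment, default_config


class TestCumulativePerArea:
    def test_hand_arithmetic(self, ivpt_results):
        res = ivpt_results["cream"]
        q = cumulative_per_area(res, 0.64 * units.CM2)
        expected = (units.kg_to_ug(res.cumulative_receptor_amount())) / 0.64
        assert np.allclose(q, expected, rtol=1e-12)
        assert q[0] == 0.0
        assert np.all(np.diff(q) >= -1e-9 * max(q[-1], 1))

    def test_static_receptor_example(self):
        # 1 ug/mL in 4.7 mL over 0.64 cm^2 -> 7.34375 ug/cm^2
        assert 1.0 * 4.7 / 0.64 == pytest.approx(7.34375)

    def test_zero_area_rejected(self, ivpt_results):
        with pytest.raises(DomainError):
            cumulative_per_area(ivpt_results["cream"], 0.0)

    def test_invariant_to_sampling_in_sink_regime(self):
        """With negligible receptor backpressure, adding sampled mass back
        telescopes: Q with and without sampling events agrees."""
        base = dict(vehicle_cells=10, membrane_cells=5,
                    receptor_volume=1e-3)       # 1 L: sink regime
        cfg_s = default_config("ivrt", "ointment", **base)
        cfg_n = default_config("ivrt", "ointment", sampling_times=(), **base)
        a = 0.64 * units.CM2
        q_s = cumulative_per_area(run_ivrt(build_experiment(cfg_s)), a)
        q_n = cumulative_per_area(run_ivrt(build_experiment(cfg_n)), a)
        res_s = run_ivrt(build_experiment(cfg_s))
        t_s = res_s.times
        res_n = run_ivrt(build_experiment(cfg_n))
        common = np.intersect1d(t_s, res_n.times)
        qs = np.array([q_s[np.nonzero(t_s == t)[0][-1]] for t in common])
        qn = np.array([q_n[np.nonzero(res_n.times == t)[0][-1]] for t in common])
        assert np.allclose(qs, qn, rtol=1e-3)


class TestFluxAndLag:
    def test_exact_line(self):
        t = np.linspace(10, 20, 11)
        flux, lag, r2 = steady_state_flux_and_lag(t, 2 * (t - 5),
                                                  fit_window=(10, 20))
        assert flux == pytest.approx(2.0, rel=1e-12)
        assert lag == pytest.approx(5.0, rel=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_flat_series_flags_lag_undefined(self):
        t = np.linspace(0, 10, 6)
        flux, lag, _ = steady_state_flux_and_lag(t, np.full_like(t, 3.0),
                                                 fit_window=(0, 10))
        assert flux == pytest.approx(0.0, abs=1e-12)
        assert lag is None

    def test_noisy_line_recovers_generator(self):
        # Monte-Carlo oracle: slope 2, lag 5, sigma 0.1
        rng = np.random.default_rng(42)
        t = np.linspace(10, 20, 21)
        fluxes, lags = [], []
        for _ in range(300):
            q = 2 * (t - 5) + rng.normal(0, 0.1, t.shape)
            f, l, _ = steady_state_flux_and_lag(t, q, fit_window=(10, 20))
            fluxes.append(f)
            lags.append(l)
        assert np.mean(fluxes) == pytest.approx(2.0, abs=3 * np.std(fluxes) / np.sqrt(300))
        assert np.mean(lags) == pytest.approx(5.0, abs=3 * np.std(lags) / np.sqrt(300))

    def test_time_unit_affine_invariance(self):
        rng = np.random.default_rng(0)
        t = np.linspace(5, 15, 12)
        q = 1.7 * t + rng.normal(0, 0.2, t.shape)
        f_h, lag_h, r2_h = steady_state_flux_and_lag(t, q, fit_window=(5, 15))
        f_m, lag_m, r2_m = steady_state_flux_and_lag(t * 60, q,
                                                     fit_window=(300, 900))
        assert f_m == pytest.approx(f_h / 60, rel=1e-9)
        assert lag_m == pytest.approx(lag_h * 60, rel=1e-9)
        assert r2_m == pytest.approx(r2_h, rel=1e-12)

    def test_window_preconditions(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(DomainError):
            steady_state_flux_and_lag(t, t, fit_window=(8, 30))
        with pytest.raises(DomainError):
            steady_state_flux_and_lag(t[:2], t[:2], fit_window=(0, 10))


class TestPermeabilityCoefficient:
    def test_hand_arithmetic(self):
        # donor 1250 ug / 0.59 mL ~ 2120 ug/mL
        assert permeability_coefficient(2.0, 2120.0) == pytest.approx(
            9.434e-4, rel=1e-3)

    def test_linear_and_degenerate(self):
        assert permeability_coefficient(0.0, 100.0) == 0.0
        assert permeability_coefficient(4.0, 100.0) == pytest.approx(
            2 * permeability_coefficient(2.0, 100.0))
        with pytest.raises(DomainError):
            permeability_coefficient(2.0, 0.0)


class TestLayerAccumulation:
    def test_against_hand_arithmetic(self, ivpt_results):
        res = ivpt_results["cream"]
        # VE-only epidermis: volume 0.64 cm^2 x 56 um at 1 g/cm^3 = 3.584 mg
        amount_ug = units.kg_to_ug(res.group_amount("ve")[-1])
        got = layer_accumulation(res, "epidermis", include_sc_in_epidermis=False)
        assert got == pytest.approx(amount_ug / 3.584, rel=1e-9)

    def test_density_scaling(self, ivpt_results):
        res = ivpt_results["cream"]
        a = layer_accumulation(res, "dermis", density=1000.0)
        b = layer_accumulation(res, "dermis", density=2000.0)
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_ivrt_result_rejected(self, ivrt_results):
        with pytest.raises(DomainError):
            layer_accumulation(ivrt_results["cream"], "epidermis")


class TestRecovery:
    @pytest.mark.parametrize("args, expected", [
        ((1000, 200, (40, 10), 1250), 100.0),
        ((900, 200, (40, 10), 1250), 92.0),
    ])
    def test_hand_arithmetic(self, args, expected):
        assert recovery_percent(*args) == pytest.approx(expected, rel=1e-12)

    def test_ties_to_simulator_conservation(self, ivpt_results):
        res = ivpt_results["ointment"]
        pct = recovery_percent(
            res.group_amount("vehicle")[-1],
            res.receptor_amount()[-1] + res.removed_cum[-1],
            {"sc+ve": res.layer_amount("epidermis")[-1],
             "dermis": res.group_amount("dermis")[-1]},
            res.initial_mass)
        assert pct == pytest.approx(100.0, abs=1e-4)

    def test_zero_dose_rejected(self):
        with pytest.raises(DomainError):
            recovery_percent(1, 1, (), 0)


class TestOneWayAnova:
    def test_identical_groups(self):
        f, p, dfb, dfw = oneway_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        f, p, dfb, dfw = oneway_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0, rel=1e-12)   # MSB = 3, MSW = 1
        assert (dfb, dfw) == (2, 6)

    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=9),
           st.lists(st.floats(-50, 50), min_size=4, max_size=9))
    def test_f_equals_t_squared_for_two_groups(self, a, b):
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return
        f, p, _, _ = oneway_anova([a, b])
        t, pt = stats.ttest_ind(a, b, equal_var=True)
        if np.isfinite(f):
            assert f == pytest.approx(t ** 2, rel=1e-10, abs=1e-10)
            assert p == pytest.approx(pt, rel=1e-10, abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(DomainError):
            oneway_anova([[1, 2]])
        with pytest.raises(DomainError):
            oneway_anova([[1], [2]])


def _dataset(group, times, reps):
    return ExperimentDataset(group=group, times_h=times,
                             replicates={f"r{i}": q for i, q in enumerate(reps)})


class TestCompareGroups:
    def test_dataset_vs_itself_is_null(self):
        t = np.array([12.0, 24.0])
        ds = _dataset("a", t, [t * 1.0, t * 1.1, t * 0.9])
        rows = compare_groups_per_timepoint(ds, ds)
        for row in rows:
            assert row["f_stat"] == pytest.approx(0.0, abs=1e-12)
            assert row["p_value"] == pytest.approx(1.0)

    def test_known_offset_is_detected(self):
        """Power oracle: a 3-pooled-SD mean offset at one time point is
        flagged significant in >= 95 % of seeded replications."""
        rng = np.random.default_rng(2024)
        t = np.array([6.0, 12.0])
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            base = rng.normal(10, 1, size=(2, 5, 2))   # two groups, n = 5
            base[1, :, 1] += 3.0                        # offset at t = 12 only
            ds_a = _dataset("a", t, list(base[0]))
            ds_b = _dataset("b", t, list(base[1]))
            rows = compare_groups_per_timepoint(ds_a, ds_b)
            if rows[1]["significant"]:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_single_replicate_rejected(self):
        t = np.array([1.0, 2.0])
        a = _dataset("a", t, [t])
        b = _dataset("b", t, [t, t * 2])
        with pytest.raises(DomainError):
            compare_groups_per_timepoint(a, b)

    def test_mismatched_grids_rejected(self):
        a = _dataset("a", np.array([1.0, 2.0]), [np.ones(2)] * 2)
        b = _dataset("b", np.array([1.0, 3.0]), [np.ones(2)] * 2)
        with pytest.raises(DomainError):
            compare_groups_per_timepoint(a, b)

    def test_holm_correction_is_conservative(self):
        rng = np.random.default_rng(5)
        t = np.arange(1.0, 9.0)
        a = _dataset("a", t, [rng.normal(10, 1, 8) for _ in range(5)])
        b = _dataset("b", t, [rng.normal(10.5, 1, 8) for _ in range(5)])
        raw = compare_groups_per_timepoint(a, b)
        holm = compare_groups_per_timepoint(a, b, holm=True)
        for r, h in zip(raw, holm):
            assert h["p_value"] >= r["p_value"] - 1e-15
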