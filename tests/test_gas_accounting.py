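"""Tracer volume, N2-based O2 estimation, species rates, H2 attribution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fermbal as fb
from fermbal import gas_accounting as ga
from fermbal.compounds import MOLAR_VOLUME_ML
from fermbal.errors import (BookkeepingError, EstimationError, InputError,
                            TracerError, UncertaintyUnavailableError)
from fermbal.liquid_rates import RatePeriod

from conftest import make_leak_scenario


def _sample(t, n2=0.0, o2=0.0, v=10_000.0, he=0.012):
    rest = 1.0 - n2 - o2 - he
    return ga.GasSample(t, {"n2": n2, "o2": o2, "he": he, "h2": rest}, v)


class TestGasVolume:
    @pytest.mark.parametrize("he_ml, y_he, expected", [
        (120.0, 0.012, 10_000.0),
        (240.0, 0.02, 12_000.0),
    ])
    def test_tracer_dilution(self, he_ml, y_he, expected):
        assert ga.estimate_gas_volume(he_ml, y_he) == pytest.approx(expected)

    def test_detection_floor(self):
        with pytest.raises(TracerError):
            ga.estimate_gas_volume(120.0, 1e-4)

    def test_matches_simulator_truth(self, leak_traj):
        row = leak_traj.gas.iloc[5]
        he_ml = ga.cumulative_tracer_ml(leak_traj.event_log, row["time_d"])
        est = ga.estimate_gas_volume(he_ml, row["y_he"])
        assert est == pytest.approx(row["v_gas_ml"], rel=1e-6)


class TestO2ContaminationRate:
    def test_no_n2_change_is_zero(self):
        rate, w = ga.o2_contamination_rate(_sample(0.0, 0.1),
                                           _sample(10.0, 0.1))
        assert rate == pytest.approx(0.0, abs=1e-12)
        assert w == []

    def test_closed_form_evaluation(self):
        # (0.0373*10000 - 0) / (3.73*10) / 1 L = 10
        rate, _ = ga.o2_contamination_rate(_sample(0.0, 0.0),
                                           _sample(10.0, 0.0373))
        assert rate == pytest.approx(10.0, rel=1e-12)

    def test_validity_warning_when_o2_detectable(self):
        _, w = ga.o2_contamination_rate(_sample(0.0, 0.0),
                                        _sample(5.0, 0.02, o2=0.05))
        assert any("above detection" in msg for msg in w)

    def test_bad_inputs(self):
        with pytest.raises(InputError):
            ga.o2_contamination_rate(_sample(5.0), _sample(5.0))
        s = ga.GasSample(0.0, {"h2": 1.0}, 1000.0)
        with pytest.raises(InputError):
            ga.o2_contamination_rate(s, ga.GasSample(1.0, {"h2": 1.0}, 1000.0))

    def test_missing_gas_volume(self):
        s1 = ga.GasSample(0.0, {"n2": 0.1, "h2": 0.9}, None)
        s2 = ga.GasSample(1.0, {"n2": 0.1, "h2": 0.9}, 1000.0)
        with pytest.raises(EstimationError):
            ga.o2_contamination_rate(s1, s2)

    def test_recovers_true_leak_on_noiseless_simulation(self, leak_traj):
        samples = ga.samples_from_frame(leak_traj.gas, leak_traj.event_log)
        rates, durations, _ = ga._interval_rates(
            samples, RatePeriod(0.0, 32.0), 1.0, leak_traj.event_log)
        est = float(np.average(rates, weights=durations))
        assert est == pytest.approx(220.0, rel=1e-9)

    def test_bias_grows_when_volume_growth_is_ignored(self):
        """With v_gas frozen at its initial value (the third validity
        condition violated), the estimate under-reads the leak and the
        bias grows monotonically with the leak-added volume fraction."""
        v0, dt_days = 10_000.0, 10.0
        biases = []
        for leak in (10.0, 50.0, 200.0, 500.0):
            added = (1 + 3.73) * leak * dt_days
            y2 = 3.73 * leak * dt_days / (v0 + added)
            est, _ = ga.o2_contamination_rate(
                _sample(0.0, 0.0, v=v0), _sample(dt_days, y2, v=v0))
            biases.append((leak - est) / leak)
        assert all(b > 0 for b in biases)
        assert biases == sorted(biases)


class TestO2Uncertainty:
    def test_noiseless_control_gives_zero_se(self, leak_traj, control_traj):
        samples = ga.samples_from_frame(leak_traj.gas, leak_traj.event_log)
        ctrl = ga.samples_from_frame(control_traj.gas,
                                     control_traj.event_log)
        est = ga.o2_rate_with_uncertainty(
            samples, RatePeriod(0.0, 32.0), 1.0, ctrl,
            event_log=leak_traj.event_log,
            control_event_log=control_traj.event_log)
        assert est.rate == pytest.approx(220.0, rel=1e-9)
        assert est.se == pytest.approx(0.0, abs=1e-9)
        assert est.n_intervals == 16

    def test_too_few_control_intervals(self, leak_traj, control_traj):
        samples = ga.samples_from_frame(leak_traj.gas, leak_traj.event_log)
        ctrl = ga.samples_from_frame(control_traj.gas,
                                     control_traj.event_log)[:3]
        with pytest.raises(UncertaintyUnavailableError) as excinfo:
            ga.o2_rate_with_uncertainty(
                samples, RatePeriod(0.0, 32.0), 1.0, ctrl,
                event_log=leak_traj.event_log)
        assert excinfo.value.estimate.rate == pytest.approx(220.0, rel=1e-9)

    def test_control_interval_sd_calibrated_by_monte_carlo(self,
                                                           control_traj):
        """The control-derived interval sd tracks the Monte-Carlo sd of
        interval rates under the injected gas-fraction noise."""
        pooled, per_seed_sd = [], []
        for seed in range(200):
            noisy = fb.apply_noise(control_traj, fb.NoiseSpec(0.0, 0.005),
                                   seed=seed)
            samples = ga.samples_from_frame(noisy.gas,
                                            control_traj.event_log)
            rates, _, _ = ga._interval_rates(samples,
                                             RatePeriod(0.0, 32.0), 1.0)
            pooled.extend(rates)
            per_seed_sd.append(np.std(rates, ddof=1))
        mc_sd = np.std(pooled)
        assert np.median(per_seed_sd) == pytest.approx(mc_sd, rel=0.30)

    def test_two_se_interval_covers_truth_in_most_replicates(
            self, leak_traj, control_traj):
        noise = fb.NoiseSpec(0.0, 0.005)
        period = RatePeriod(0.0, 32.0)
        covered = 0
        for seed in range(100):
            test = fb.apply_noise(leak_traj, noise, seed=seed)
            ctrl = fb.apply_noise(control_traj, noise, seed=10_000 + seed)
            est = ga.o2_rate_with_uncertainty(
                ga.samples_from_frame(test.gas, leak_traj.event_log),
                period, 1.0,
                ga.samples_from_frame(ctrl.gas, control_traj.event_log),
                event_log=leak_traj.event_log,
                control_event_log=control_traj.event_log)
            if abs(est.rate - 220.0) <= 2.0 * est.se:
                covered += 1
        assert covered >= 90


class TestGasSpeciesRate:
    def test_refill_is_fully_discounted(self):
        samples = [ga.GasSample(0.0, {"h2": 1.0}, 2000.0),
                   ga.GasSample(10.0, {"h2": 1.0}, 10_000.0)]
        events = [{"time_d": 5.0, "type": "refill",
                   "volumes_ml": {"h2": 8000.0}}]
        rate = ga.gas_species_rate(samples, events, "h2",
                                   RatePeriod(0.0, 10.0), 1.0)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_methanogenesis_rate_recovered(self, control_traj):
        samples = ga.samples_from_frame(control_traj.gas,
                                        control_traj.event_log)
        rate = ga.gas_species_rate(samples, control_traj.event_log, "ch4",
                                   RatePeriod(0.0, 32.0), 1.0)
        assert rate == pytest.approx(16.5, rel=0.01)

    def test_tracer_rate_is_always_zero(self, leak_traj, rich_traj):
        for traj in (leak_traj, rich_traj):
            samples = ga.samples_from_frame(traj.gas, traj.event_log)
            rate = ga.gas_species_rate(samples, traj.event_log, "he",
                                       RatePeriod(0.0, 32.0), 1.0)
            assert rate == pytest.approx(0.0, abs=1e-9)

    def test_event_without_composition_is_a_bookkeeping_error(self):
        samples = [ga.GasSample(0.0, {"h2": 1.0}, 2000.0),
                   ga.GasSample(10.0, {"h2": 1.0}, 2000.0)]
        with pytest.raises(BookkeepingError):
            ga.gas_species_rate(samples, [{"time_d": 5.0, "type": "refill"}],
                                "h2", RatePeriod(0.0, 10.0), 1.0)


class TestH2Attribution:
    @pytest.mark.parametrize("h2_cons, ch4, attributed, non_ch4", [
        (70.0, 16.5, 66.0, 4.0),
        (30.0, 0.0, 0.0, 30.0),
        (66.0, 16.5, 66.0, 0.0),
    ])
    def test_examples(self, h2_cons, ch4, attributed, non_ch4):
        a, n = fb.attribute_h2(h2_cons, ch4)
        assert a == pytest.approx(attributed)
        assert n == pytest.approx(non_ch4)

    @settings(deadline=None, max_examples=50)
    @given(st.tuples(st.floats(0, 100), st.floats(0, 25)),
           st.tuples(st.floats(0, 100), st.floats(0, 25)))
    def test_linearity(self, a, b):
        (h1, c1), (h2, c2) = a, b
        summed = fb.attribute_h2(h1 + h2, c1 + c2)
        parts = np.add(fb.attribute_h2(h1, c1), fb.attribute_h2(h2, c2))
        assert summed == pytest.approx(tuple(parts), abs=1e-9)


class TestH2O2Ratio:
    def test_stoichiometric_reference_case(self):
        # 2 mmol H2 against 1 mmol O2 (22.414 mL) is the H2-oxidation ratio
        assert fb.h2_o2_ratio(2.0, MOLAR_VOLUME_ML) == pytest.approx(2.0)

    def test_pure_scavenging_scenario_gives_two(self):
        scen = make_leak_scenario(ch4_extent=0.0, scavenge=12.0)
        traj = fb.simulate(scen)
        samples = ga.samples_from_frame(traj.gas, traj.event_log)
        period = RatePeriod(0.0, 32.0)
        h2 = ga.gas_species_rate(samples, traj.event_log, "h2", period, 1.0)
        rates, durations, _ = ga._interval_rates(samples, period, 1.0,
                                                 traj.event_log)
        o2 = float(np.average(rates, weights=durations))
        _, non_ch4 = fb.attribute_h2(-h2, 0.0)
        assert fb.h2_o2_ratio(non_ch4, o2) == pytest.approx(2.0, rel=0.02)

    def test_zero_o2_rate_is_undefined(self):
        with pytest.raises(EstimationError):
            fb.h2_o2_ratio(10.0, 0.0)
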