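"""Simulator: conservation, stoichiometric bookkeeping, noise, community."""

import math

import numpy as np
import pandas as pd
import pytest

import fermbal as fb
from fermbal.compounds import MOLAR_VOLUME_ML
from fermbal.errors import (SimulationError, StepSizeError, ValidationError)
from fermbal.simulator import CommunityLinkSpec, conservation_report

from conftest import FEED, make_control_scenario, make_leak_scenario, \
    make_rich_scenario


def test_zero_extents_at_feed_is_a_fixed_point():
    scen = fb.ReactorScenario(duration=10.0, sample_interval=1.0)
    traj = fb.simulate(scen)
    for comp, feed in FEED.items():
        assert np.allclose(traj.liquid[comp], feed)
    assert all(abs(v) < 1e-12
               for v in traj.truth["phases"][0]["rates"].values())


def test_methanogenesis_shrinks_gas_loop_stoichiometrically():
    # 4 H2 + CO2 -> CH4: net 4 mmol of gas disappear per mmol CH4
    scen = fb.ReactorScenario(
        duration=2.0, sample_interval=1.0,
        rate_schedule=[fb.RatePhase(0.0, 2.0, {"methanogenesis": 16.5})])
    traj = fb.simulate(scen)
    v = traj.gas["v_gas_ml"].to_numpy()
    per_day = (v[0] - v[1])
    assert per_day == pytest.approx(4 * 16.5 * MOLAR_VOLUME_ML, rel=1e-9)


def test_air_leak_adds_n2_at_fixed_ratio_closed_form():
    traj = fb.simulate(make_leak_scenario(duration=32.0, leak=220.0))
    bal = traj.truth["balance"]
    assert bal["leak_mmol"]["n2"] * MOLAR_VOLUME_ML == \
        pytest.approx(3.73 * 220.0 * 32.0, rel=1e-9)
    assert traj.truth["cumulative_o2_ml"] == pytest.approx(220.0 * 32.0,
                                                           rel=1e-9)


@pytest.mark.parametrize("scenario_factory", [
    make_leak_scenario, make_control_scenario, make_rich_scenario])
def test_noiseless_runs_conserve_elements_and_electrons(scenario_factory):
    traj = fb.simulate(scenario_factory())
    report = conservation_report(traj)
    for key in ("C", "H", "O", "N", "He", "electrons"):
        assert abs(report[key]) < 1e-6, key
    # He: no sources or sinks besides refills (and logged vents)
    harvested = any(e["type"] == "harvest" for e in traj.event_log)
    assert abs(report["he_abs_mmol"]) <= (1e-9 if harvested else 0.0)


def test_helium_total_equals_refill_total(rich_traj):
    bal = rich_traj.truth["balance"]
    n_refills = sum(1 for e in rich_traj.event_log if e["type"] == "refill")
    assert bal["final_gas_mmol"][3] == pytest.approx(     # he index
        n_refills * 120.0 / MOLAR_VOLUME_ML, rel=1e-12)


def test_o2_scavenged_when_extent_exceeds_leak(leak_traj):
    # scavenging extent (12 mmol/L/d) > molar leak (220/22.414 = 9.8)
    assert leak_traj.gas["y_o2"].max() < 1e-12


def test_o2_accumulates_when_scavenging_is_too_slow():
    scen = make_leak_scenario(scavenge=2.0)
    traj = fb.simulate(scen)
    assert traj.gas["y_o2"].iloc[-1] > 0.01


def test_gas_pool_driven_negative_raises_with_species_and_time():
    scen = fb.ReactorScenario(
        duration=10.0,
        rate_schedule=[fb.RatePhase(0.0, 10.0, {"methanogenesis": 100.0})],
        refill=fb.RefillSpec(trigger_ml=0.0))
    with pytest.raises(SimulationError, match="h2.*t="):
        fb.simulate(scen)


def test_liquid_driven_negative_raises_step_size_error():
    scen = fb.ReactorScenario(
        duration=10.0,
        rate_schedule=[fb.RatePhase(0.0, 10.0, {"chain_elongation": 300.0})])
    with pytest.raises(StepSizeError):
        fb.simulate(scen)


def test_scenario_validation():
    with pytest.raises(ValidationError):
        fb.ReactorScenario(duration=10.0, leak_schedule=[
            fb.LeakInterval(5.0, 15.0, 100.0)]).validate()
    with pytest.raises(ValidationError):
        fb.ReactorScenario(duration=10.0, rate_schedule=[
            fb.RatePhase(0.0, 5.0, {"methanogenesis": -1.0})]).validate()


def test_refills_are_triggered_and_logged(rich_traj):
    refills = [e for e in rich_traj.event_log if e["type"] == "refill"]
    assert len(refills) > 1
    assert all(e["volumes_ml"]["he"] == 120.0 for e in refills)
    times = [e["time_d"] for e in rich_traj.event_log]
    assert times == sorted(times)


class TestApplyNoise:
    def test_zero_noise_is_identity(self, leak_traj):
        out = fb.apply_noise(leak_traj, fb.NoiseSpec(0.0, 0.0), seed=1)
        pd.testing.assert_frame_equal(out.liquid, leak_traj.liquid)
        pd.testing.assert_frame_equal(out.gas, leak_traj.gas)

    def test_same_seed_reproduces(self, leak_traj):
        a = fb.apply_noise(leak_traj, fb.NoiseSpec(0.05, 0.005), seed=11)
        b = fb.apply_noise(leak_traj, fb.NoiseSpec(0.05, 0.005), seed=11)
        pd.testing.assert_frame_equal(a.liquid, b.liquid)
        pd.testing.assert_frame_equal(a.gas, b.gas)
        c = fb.apply_noise(leak_traj, fb.NoiseSpec(0.05, 0.005), seed=12)
        assert not a.liquid.equals(c.liquid)

    def test_gas_fractions_renormalised(self, leak_traj):
        out = fb.apply_noise(leak_traj, fb.NoiseSpec(0.0, 0.01), seed=5)
        ycols = [c for c in out.gas.columns if c.startswith("y_")]
        sums = out.gas[ycols].sum(axis=1)
        assert np.allclose(sums, 1.0)
        assert (out.gas[ycols].to_numpy() >= 0).all()

    def test_liquid_cv_calibration_monte_carlo(self):
        # 1000 replicate observations of one true value at CV 5%
        liquid = pd.DataFrame({"time_d": np.arange(1000.0),
                               "lactate": np.full(1000, 50.0)})
        gas = pd.DataFrame({"time_d": [0.0], "y_h2": [1.0],
                            "v_gas_ml": [1000.0]})
        traj = fb.Trajectory(liquid, gas, [], {})
        out = fb.apply_noise(traj, fb.NoiseSpec(0.05, 0.0), seed=3)
        vals = out.liquid["lactate"].to_numpy()
        assert 0.04 <= vals.std() / vals.mean() <= 0.06


def _phases_scenario():
    """Five phases with distinct methane rates, for community linking."""
    phases = [fb.RatePhase(10.0 * i, 10.0 * (i + 1),
                           {"methanogenesis": r})
              for i, r in enumerate([2.0, 16.5, 6.0, 12.0, 19.5])]
    return fb.ReactorScenario(duration=50.0, rate_schedule=phases,
                              sample_interval=1.0)


class TestGenerateCommunity:
    link = CommunityLinkSpec(
        taxa=("methanogen", "elongator", "bystander"),
        coefficients={"methanogen": {"ch4": 0.4},
                      "elongator": {"ch4": -0.2}},
        dispersion=math.inf, seed=0)

    def test_monotone_link_gives_perfect_rank_correlation(self):
        traj = fb.simulate(_phases_scenario())
        counts, meta = fb.generate_community(traj, self.link)
        rho = fb.spearman_rho(counts["methanogen"].to_numpy(),
                              meta["ch4"].to_numpy())
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_counts_sum_to_depth_with_finite_dispersion(self):
        traj = fb.simulate(_phases_scenario())
        link = CommunityLinkSpec(
            taxa=("a", "b"), coefficients={"a": {"ch4": 0.1}},
            dispersion=50.0, depth_range=(4977, 4977), seed=2)
        counts, _ = fb.generate_community(traj, link)
        assert (counts.sum(axis=1) == 4977).all()

    def test_seed_reproducibility(self):
        traj = fb.simulate(_phases_scenario())
        link = CommunityLinkSpec(
            taxa=("a", "b"), coefficients={"a": {"ch4": 0.1}},
            dispersion=50.0, seed=7)
        c1, _ = fb.generate_community(traj, link)
        c2, _ = fb.generate_community(traj, link)
        pd.testing.assert_frame_equal(c1, c2)

    def test_degenerate_link_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            CommunityLinkSpec(taxa=("a", "b"),
                              coefficients={"a": {"ch4": 0.0}}).validate()

    def test_correlation_weakens_with_dispersion(self):
        traj = fb.simulate(_phases_scenario())
        mags = {}
        for disp in (1000.0, 2.0):
            rhos = []
            for seed in range(50):
                link = CommunityLinkSpec(
                    taxa=("a", "b"), coefficients={"a": {"ch4": 0.3}},
                    dispersion=disp, seed=seed)
                counts, meta = fb.generate_community(traj, link)
                rhos.append(abs(fb.spearman_rho(
                    counts["a"].to_numpy(), meta["ch4"].to_numpy())))
            mags[disp] = np.mean(rhos)
        assert mags[1000.0] > mags[2.0]
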