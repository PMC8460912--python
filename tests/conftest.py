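"""Shared fixtures: reference scenarios reused across test modules.

Everything is generated at test time by the simulator; nothing is read
from disk. Session scope keeps the (deterministic) simulations from being
re-run per test.
"""

from __future__ import annotations

import pytest

import fermbal as fb
from fermbal import simulator


FEED = {"lactate": 133.0, "acetate": 200.0}

#: extents (mmol L^-1 d^-1) of the multi-reaction reference phase
RICH_EXTENTS = {
    "propionate_fermentation": 0.4,
    "methanogenesis": 10.0,
    "h2_oxidation": 6.0,
    "homopropionate": 0.3,
    "homoacetogenesis": 0.5,
    "chain_elongation": 1.0,
    "butyrate_from_lactate": 1.2,
}


def make_leak_scenario(duration: float = 32.0, leak: float = 220.0,
                       ch4_extent: float = 6.05,
                       scavenge: float = 12.0) -> fb.ReactorScenario:
    """O2-contaminated operation: constant leak, H2-based O2 scavenging
    (extent above the molar leak rate, so O2 stays undetectable), and
    partially inhibited methanogenesis."""
    return fb.ReactorScenario(
        duration=duration,
        rate_schedule=[fb.RatePhase(0.0, duration, {
            "methanogenesis": ch4_extent, "h2_oxidation": scavenge})],
        leak_schedule=[fb.LeakInterval(0.0, duration, leak)],
        # the loop vents above ~12 L, keeping the gas system near the
        # 10 L working charge despite N2 ingress
        refill=fb.RefillSpec(max_volume_ml=12_000.0, vent_to_ml=10_360.0),
    )


def make_control_scenario(duration: float = 32.0,
                          ch4_extent: float = 16.5) -> fb.ReactorScenario:
    """Anoxic control: methanogenesis only, no leak."""
    return fb.ReactorScenario(
        duration=duration,
        rate_schedule=[fb.RatePhase(0.0, duration,
                                    {"methanogenesis": ch4_extent})],
    )


def make_rich_scenario(duration: float = 60.0,
                       sample_interval: float = 0.5) -> fb.ReactorScenario:
    """All shipped reactions active plus a moderate leak, started at the
    CSTR fixed point so the whole run is near steady state."""
    phase = fb.RatePhase(0.0, duration, RICH_EXTENTS)
    base = fb.ReactorScenario(
        duration=duration, rate_schedule=[phase],
        leak_schedule=[fb.LeakInterval(0.0, duration, 120.0)],
        sample_interval=sample_interval)
    init = simulator.steady_state(base, phase)
    return fb.ReactorScenario(
        duration=duration, initial_mM=init, rate_schedule=[phase],
        leak_schedule=[fb.LeakInterval(0.0, duration, 120.0)],
        sample_interval=sample_interval)


@pytest.fixture(scope="session")
def leak_traj() -> fb.Trajectory:
    return fb.simulate(make_leak_scenario())


@pytest.fixture(scope="session")
def control_traj() -> fb.Trajectory:
    return fb.simulate(make_control_scenario())


@pytest.fixture(scope="session")
def rich_traj() -> fb.Trajectory:
    return fb.simulate(make_rich_scenario())


@pytest.fixture(scope="session")
def registry():
    return fb.DEFAULT_REGISTRY
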