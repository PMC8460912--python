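"""Synthetic reactor: a well-mixed CSTR coupled to a closed recirculating
gas reservoir, with stoichiometric reactions at scheduled extents, reservoir
refills, air-leak events and measurement noise.

The simulator is the ground-truth generator for estimator validation: it
embodies the same stoichiometric assumptions the analysis stages invert
(instant transfer of gaseous species to the gas loop, no dissolved gas
pools, no kinetics — process rates are piecewise-constant scenario inputs).
Air leaks add O2 together with 3.73 times as much N2, the composition of
air; that N2 signature is what the gas-accounting stage reads back.

Units: liquid concentrations in mM, gas inventories internally in mmol,
gas I/O in mL at 0 degC / 101.325 kPa (22.414 mL/mmol), time in days.
Integration is explicit Euler at dt = 0.05 d with a negativity guard; the
dynamics are far from stiff at the rates of interest and the fixed step
keeps every conservation statement exactly auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .compounds import (CompoundRegistry, DEFAULT_REACTIONS, DEFAULT_REGISTRY,
                        MOLAR_VOLUME_ML, ReactionSpec, degree_of_reduction)
from .errors import SimulationError, StepSizeError, ValidationError
from .io import GAS_SPECIES

#: volumetric N2:O2 ratio of air — the leak co-signature.
AIR_N2_TO_O2 = 3.73


@dataclass(frozen=True)
class LeakInterval:
    """Air ingress between t_start and t_end at o2_rate mL O2 L^-1 d^-1."""
    t_start: float
    t_end: float
    o2_rate_ml: float


@dataclass(frozen=True)
class RatePhase:
    """Piecewise-constant reaction extents (mmol L^-1 d^-1) on [t_start, t_end)."""
    t_start: float
    t_end: float
    extents: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class RefillSpec:
    """Reservoir recharge: volumes at reference conditions, and the trigger.

    The reservoir is effectively empty when its *limiting* component is:
    the controller tracks, for every species the recharge provides, the
    recharge-equivalent volume ``v(species) / recharge share(species)`` and
    refills when the minimum falls below ``trigger_ml`` (default 20% of the
    10,360 mL recharge). With the default 80:20 H2:CO2 charge, H2 is the
    binding species. Accumulating inert gas (air-derived N2, tracer He,
    ethylene) is not reservoir charge; ``max_volume_ml`` optionally vents
    the loop down to ``vent_to_ml`` at the current composition whenever the
    total exceeds it (logged as a harvest event)."""
    volumes_ml: Mapping[str, float] = field(default_factory=lambda: {
        "h2": 8000.0, "co2": 2000.0, "ethylene": 240.0, "he": 120.0})
    trigger_ml: float = 2072.0  # 20% of the 10,360 mL recharge
    max_volume_ml: Optional[float] = None
    vent_to_ml: float = 10360.0


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise: multiplicative lognormal on liquid concentrations
    (liquid_cv), additive Gaussian on gas fractions (gas_sd)."""
    liquid_cv: float = 0.05
    gas_sd: float = 0.005
    seed: int = 0


@dataclass(frozen=True)
class ReactorScenario:
    """Operating point of the synthetic reactor.

    Defaults mirror the reference operation: 1 L working volume, HRT 14 d,
    feed of 133 mM lactate + 200 mM acetate, reservoir recharged with
    10 L H2:CO2 (80:20) + 240 mL ethylene + 120 mL He.
    """
    duration: float
    liquid_volume: float = 1.0
    hrt: float = 14.0
    feed_mM: Mapping[str, float] = field(default_factory=lambda: {
        "lactate": 133.0, "acetate": 200.0})
    initial_mM: Optional[Mapping[str, float]] = None
    rate_schedule: Sequence[RatePhase] = ()
    leak_schedule: Sequence[LeakInterval] = ()
    refill: RefillSpec = field(default_factory=RefillSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    sample_interval: float = 2.0
    dt: float = 0.05

    def validate(self) -> None:
        if self.hrt <= 0 or self.liquid_volume <= 0 or self.duration <= 0:
            raise ValidationError("hrt, liquid_volume, duration must be > 0")
        for leak in self.leak_schedule:
            if not (0 <= leak.t_start < leak.t_end <= self.duration):
                raise ValidationError(
                    f"leak interval [{leak.t_start}, {leak.t_end}] outside "
                    f"[0, {self.duration}]")
            if leak.o2_rate_ml < 0:
                raise ValidationError("leak rate must be >= 0")
        for phase in self.rate_schedule:
            if phase.t_end <= phase.t_start:
                raise ValidationError("rate phase must have t_end > t_start")
            if any(e < 0 for e in phase.extents.values()):
                raise ValidationError("reaction extents must be >= 0")


@dataclass
class Trajectory:
    """Sampled series plus the ground truth the estimators are judged against."""
    liquid: pd.DataFrame            # time_d + per-compound mM
    gas: pd.DataFrame               # time_d, y_<species>..., v_gas_ml
    event_log: list[dict]
    truth: dict


def simulate(scenario: ReactorScenario,
             reactions: Optional[Mapping[str, ReactionSpec]] = None,
             registry: Optional[CompoundRegistry] = None) -> Trajectory:
    """Run the scenario and return noiseless series plus ground truth.

    Gaseous reaction participants exchange directly with the closed gas
    loop; leaks add O2 (+3.73x N2); the reservoir is recharged whenever its
    total volume falls below the refill trigger, each recharge appended to
    the event log. Only the O2-consuming extent is capped at the O2
    actually present (the physical scavenging limit); any other gas pool
    driven negative raises :class:`SimulationError`.
    """
    scenario.validate()
    reg = registry or DEFAULT_REGISTRY
    rxns = dict(reactions or DEFAULT_REACTIONS)
    for spec in rxns.values():
        spec.validate(reg)

    used = sorted({name for ph in scenario.rate_schedule for name in ph.extents})
    for name in used:
        if name not in rxns:
            raise ValidationError(f"rate schedule references unknown reaction "
                                  f"{name!r}")
    rxn_names = used
    gas_index = {s: i for i, s in enumerate(GAS_SPECIES)}

    liquid_names = sorted(
        set(scenario.feed_mM) | set(scenario.initial_mM or {}) | {
            n for r in rxn_names for n in rxns[r].stoichiometry
            if reg.get(n).phase_default == "liquid"})
    liq_index = {n: i for i, n in enumerate(liquid_names)}

    nu_liq = np.zeros((len(rxn_names), len(liquid_names)))
    nu_gas = np.zeros((len(rxn_names), len(GAS_SPECIES)))
    for k, rname in enumerate(rxn_names):
        for comp, coeff in rxns[rname].coefficients().items():
            if reg.get(comp).phase_default == "gas":
                nu_gas[k, gas_index[comp]] = float(coeff)
            else:
                nu_liq[k, liq_index[comp]] = float(coeff)

    dt = scenario.dt
    n_steps = round(scenario.duration / dt)
    if abs(n_steps * dt - scenario.duration) > 1e-9:
        raise ValidationError("duration must be a multiple of dt")
    sample_every = round(scenario.sample_interval / dt)
    if abs(sample_every * dt - scenario.sample_interval) > 1e-9:
        raise ValidationError("sample_interval must be a multiple of dt")

    # Per-step schedules.
    step_extents = np.zeros((n_steps, len(rxn_names)))
    step_phase = np.full(n_steps, -1)
    phases = list(scenario.rate_schedule) or [
        RatePhase(0.0, scenario.duration, {})]
    for p_i, ph in enumerate(phases):
        i0, i1 = round(ph.t_start / dt), round(ph.t_end / dt)
        step_phase[i0:i1] = p_i
        for rname, ext in ph.extents.items():
            step_extents[i0:i1, rxn_names.index(rname)] = ext
    step_leak = np.zeros(n_steps)
    for leak in scenario.leak_schedule:
        i0, i1 = round(leak.t_start / dt), round(leak.t_end / dt)
        step_leak[i0:i1] += leak.o2_rate_ml

    V = scenario.liquid_volume
    D = 1.0 / scenario.hrt
    feed = np.array([scenario.feed_mM.get(n, 0.0) for n in liquid_names])
    init = feed.copy() if scenario.initial_mM is None else np.array(
        [dict(scenario.initial_mM).get(n, 0.0) for n in liquid_names])
    C = init.copy()
    G = np.zeros(len(GAS_SPECIES))                      # mmol
    refill_mmol = np.array([dict(scenario.refill.volumes_ml).get(s, 0.0)
                            for s in GAS_SPECIES]) / MOLAR_VOLUME_ML
    charge_idx = np.array([i for i, s in enumerate(GAS_SPECIES)
                           if refill_mmol[i] > 0], dtype=int)
    charge_share = refill_mmol[charge_idx] / refill_mmol.sum()

    event_log: list[dict] = []

    def do_refill(t: float) -> None:
        nonlocal G
        G = G + refill_mmol
        event_log.append({"time_d": round(t, 9), "type": "refill",
                          "volumes_ml": dict(scenario.refill.volumes_ml)})

    do_refill(0.0)

    feed_cum = np.zeros(len(liquid_names))              # mmol fed
    withdraw_cum = np.zeros(len(liquid_names))          # mmol withdrawn
    leak_cum = np.zeros(2)                              # mmol O2, N2 in
    refill_cum = refill_mmol.copy()                     # mmol, incl. t=0 fill
    harvest_cum = np.zeros(len(GAS_SPECIES))            # mmol vented
    realized = np.zeros((len(phases), len(rxn_names)))  # extent*dt integral
    leak_by_phase = np.zeros(len(phases))               # mL O2 per L

    o2_i, n2_i = gas_index["o2"], gas_index["n2"]
    samples_liq, samples_gas = [], []

    def record(t: float) -> None:
        total = G.sum()
        samples_liq.append((t, C.copy()))
        samples_gas.append((t, G / total, total * MOLAR_VOLUME_ML))

    for k in range(n_steps):
        t = k * dt
        if k % sample_every == 0:
            record(t)

        # Air leak first: O2 is available to scavengers within the step.
        if step_leak[k] > 0:
            d_o2 = step_leak[k] * V * dt / MOLAR_VOLUME_ML
            G[o2_i] += d_o2
            G[n2_i] += AIR_N2_TO_O2 * d_o2
            leak_cum += (d_o2, AIR_N2_TO_O2 * d_o2)
            if step_phase[k] >= 0:
                leak_by_phase[step_phase[k]] += step_leak[k] * dt

        ext = step_extents[k].copy()
        for r in range(len(rxn_names)):
            if ext[r] > 0 and nu_gas[r, o2_i] < 0:
                cap = G[o2_i] / (-nu_gas[r, o2_i] * V * dt)
                ext[r] = min(ext[r], cap)
        if step_phase[k] >= 0:
            realized[step_phase[k]] += ext * dt

        C = C + (nu_liq.T @ ext) * dt
        G = G + (nu_gas.T @ ext) * V * dt

        # Withdrawal carries the post-reaction, pre-dilution broth so that
        # feed - withdrawal equals the dilution term exactly.
        feed_cum += D * feed * dt * V
        withdraw_cum += D * C * dt * V
        C = C + D * (feed - C) * dt

        if (G < -1e-9).any():
            bad = GAS_SPECIES[int(np.argmin(G))]
            raise SimulationError(
                f"gas pool {bad!r} driven negative at t={t + dt:.2f} d")
        G = np.clip(G, 0.0, None)
        if (C < -1e-9).any():
            bad = liquid_names[int(np.argmin(C))]
            raise StepSizeError(
                f"liquid {bad!r} went negative at t={t + dt:.2f} d; "
                "reduce dt or extents")
        C = np.clip(C, 0.0, None)

        equiv_ml = np.min(G[charge_idx] / charge_share) * MOLAR_VOLUME_ML
        if equiv_ml < scenario.refill.trigger_ml:
            do_refill(t + dt)
            refill_cum += refill_mmol
        cap = scenario.refill.max_volume_ml
        if cap is not None and G.sum() * MOLAR_VOLUME_ML > cap:
            frac = 1.0 - scenario.refill.vent_to_ml / (
                G.sum() * MOLAR_VOLUME_ML)
            vented = G * frac
            G = G - vented
            harvest_cum += vented
            event_log.append({
                "time_d": round(t + dt, 9), "type": "harvest",
                "volumes_ml": {s: float(v * MOLAR_VOLUME_ML) for s, v
                               in zip(GAS_SPECIES, vented)}})

    record(scenario.duration)

    liquid_df = pd.DataFrame(
        {"time_d": [t for t, _ in samples_liq]}
        | {n: [c[liq_index[n]] for _, c in samples_liq]
           for n in liquid_names if n != "h2o"})
    gas_df = pd.DataFrame(
        {"time_d": [t for t, *_ in samples_gas]}
        | {f"y_{s}": [y[gas_index[s]] for _, y, _ in samples_gas]
           for s in GAS_SPECIES}
        | {"v_gas_ml": [v for *_, v in samples_gas]})

    truth_phases = []
    for p_i, ph in enumerate(phases):
        dur = ph.t_end - ph.t_start
        mean_ext = realized[p_i] / dur
        rates: Dict[str, float] = {}
        for n in liquid_names:
            rates[n] = float(mean_ext @ nu_liq[:, liq_index[n]])
        for s in GAS_SPECIES:
            rates[s] = float(mean_ext @ nu_gas[:, gas_index[s]])
        truth_phases.append({
            "t_start": ph.t_start, "t_end": ph.t_end, "rates": rates,
            "o2_contamination_ml_l_d": float(leak_by_phase[p_i] / dur),
        })

    truth = {
        "phases": truth_phases,
        "cumulative_o2_ml": float(leak_cum[0] * MOLAR_VOLUME_ML),
        "he_added_ml": float(refill_cum[gas_index["he"]] * MOLAR_VOLUME_ML),
        "balance": {
            "liquid_names": liquid_names,
            "initial_liquid_mmol": (init * V).tolist(),
            "final_liquid_mmol": (C * V).tolist(),
            "feed_mmol": feed_cum.tolist(),
            "withdrawn_mmol": withdraw_cum.tolist(),
            "final_gas_mmol": G.tolist(),
            "leak_mmol": {"o2": float(leak_cum[0]), "n2": float(leak_cum[1])},
            "refill_mmol": dict(zip(GAS_SPECIES, refill_cum.tolist())),
            "harvest_mmol": dict(zip(GAS_SPECIES, harvest_cum.tolist())),
        },
    }
    return Trajectory(liquid_df, gas_df, event_log, truth)


def conservation_report(traj: Trajectory,
                        registry: Optional[CompoundRegistry] = None
                        ) -> Dict[str, float]:
    """Relative closure error per element (C, H, O, N, He) and for electron
    equivalents: (outputs - inputs) / inputs over the whole run.

    Inputs: initial liquid inventory + feed + air leak + reservoir refills.
    Outputs: withdrawn broth + final liquid + final gas. A noiseless run of
    balanced reactions closes to machine precision.
    """
    reg = registry or DEFAULT_REGISTRY
    bal = traj.truth["balance"]
    names = bal["liquid_names"]

    def weigh(amounts: Mapping[str, float], weight) -> float:
        return sum(a * weight(reg.get(n)) for n, a in amounts.items())

    init_liq = dict(zip(names, bal["initial_liquid_mmol"]))
    final_liq = dict(zip(names, bal["final_liquid_mmol"]))
    fed = dict(zip(names, bal["feed_mmol"]))
    withdrawn = dict(zip(names, bal["withdrawn_mmol"]))
    final_gas = dict(zip(GAS_SPECIES, bal["final_gas_mmol"]))
    leak = {"o2": bal["leak_mmol"]["o2"], "n2": bal["leak_mmol"]["n2"]}
    refill = bal["refill_mmol"]
    harvest = bal["harvest_mmol"]

    report = {}
    weights = {el: (lambda c, el=el: c.count(el))
               for el in ("C", "H", "O", "N", "He")}
    weights["electrons"] = degree_of_reduction
    for label, w in weights.items():
        inp = (weigh(init_liq, w) + weigh(fed, w) + weigh(leak, w)
               + weigh(refill, w))
        out = (weigh(withdrawn, w) + weigh(final_liq, w)
               + weigh(final_gas, w) + weigh(harvest, w))
        report[label] = (out - inp) / max(abs(inp), 1e-9)
    report["he_abs_mmol"] = final_gas["he"] + harvest["he"] - refill["he"]
    return report


def apply_noise(traj: Trajectory, noise: NoiseSpec,
                seed: Optional[int] = None) -> Trajectory:
    """Overlay measurement noise; seed-reproducible, identity at zero noise.

    Liquid concentrations are multiplied by lognormal deviates with median
    1 and shape = CV; gas fractions get additive Gaussian noise, are
    clipped at 0 and renormalised to sum 1. Ground truth, event log and the
    (true) gas volume column are untouched.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    liquid = traj.liquid.copy()
    gas = traj.gas.copy()
    if noise.liquid_cv < 0 or noise.gas_sd < 0:
        raise ValidationError("noise magnitudes must be >= 0")
    if noise.liquid_cv > 0:
        for col in liquid.columns:
            if col != "time_d":
                liquid[col] = liquid[col].to_numpy() * rng.lognormal(
                    0.0, noise.liquid_cv, size=len(liquid))
    if noise.gas_sd > 0:
        ycols = [c for c in gas.columns if c.startswith("y_")]
        Y = gas[ycols].to_numpy()
        Y = np.clip(Y + rng.normal(0.0, noise.gas_sd, size=Y.shape), 0.0, None)
        Y = Y / Y.sum(axis=1, keepdims=True)
        gas[ycols] = Y
    return Trajectory(liquid, gas, traj.event_log, traj.truth)


@dataclass(frozen=True)
class CommunityLinkSpec:
    """Stochastic link from true process rates to taxon abundances.

    Each taxon's log-abundance is an affine function of selected true rates
    (keys of ``coefficients[taxon]`` name rate variables: compound names or
    "o2_contamination"); relative abundances are the softmax across taxa,
    and counts are drawn Dirichlet-multinomial with the given concentration
    (``math.inf`` for deterministic expected counts).
    """
    taxa: Sequence[str]
    coefficients: Mapping[str, Mapping[str, float]]
    intercepts: Mapping[str, float] = field(default_factory=dict)
    dispersion: float = 200.0
    depth_range: tuple[int, int] = (4977, 4977)
    seed: int = 0

    def validate(self) -> None:
        if len(self.taxa) < 2:
            raise ValidationError("need at least 2 taxa")
        if not (self.dispersion > 0):
            raise ValidationError("dispersion must be > 0")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValidationError("depth_range must be positive and ordered")
        if not any(v for row in self.coefficients.values()
                   for v in row.values()):
            raise ValidationError("degenerate link: all coefficients zero")


def generate_community(traj: Trajectory, link: CommunityLinkSpec,
                       times: Optional[Sequence[float]] = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a samples x taxa count table linked to the true rates.

    One sample per truth phase by default (at the sampled time nearest the
    phase midpoint). Returns ``(counts, meta)`` where meta carries each
    sample's time, phase index and the rate variables used in the link.
    """
    link.validate()
    rng = np.random.default_rng(link.seed)
    phases = traj.truth["phases"]
    liquid_times = traj.liquid["time_d"].to_numpy()

    chosen: list[tuple[float, dict]] = []
    if times is None:
        for ph in phases:
            mid = 0.5 * (ph["t_start"] + ph["t_end"])
            t = float(liquid_times[np.argmin(np.abs(liquid_times - mid))])
            chosen.append((t, ph))
    else:
        for t in times:
            if not np.isclose(liquid_times, t).any():
                raise ValidationError(f"time {t} is not a trajectory sample")
            ph = next((p for p in phases
                       if p["t_start"] <= t <= p["t_end"]), phases[-1])
            chosen.append((float(t), ph))

    var_names = sorted({v for row in link.coefficients.values() for v in row})
    counts_rows, meta_rows = [], []
    for i, (t, ph) in enumerate(chosen):
        variables = dict(ph["rates"])
        variables["o2_contamination"] = ph["o2_contamination_ml_l_d"]
        eta = np.array([
            dict(link.intercepts).get(tax, 0.0)
            + sum(c * variables.get(v, 0.0)
                  for v, c in dict(link.coefficients).get(tax, {}).items())
            for tax in link.taxa])
        p = np.exp(eta - eta.max())
        p = p / p.sum()
        lo, hi = link.depth_range
        depth = int(lo if lo == hi else rng.integers(lo, hi + 1))
        if math.isinf(link.dispersion):
            counts = np.round(p * depth).astype(int)
        else:
            q = rng.dirichlet(p * link.dispersion)
            counts = rng.multinomial(depth, q)
        sid = f"s{i:02d}"
        counts_rows.append(pd.Series(counts, index=list(link.taxa), name=sid))
        meta_rows.append({"sample": sid, "time_d": t,
                          "phase": phases.index(ph),
                          **{v: variables.get(v, 0.0) for v in var_names},
                          "o2_contamination": variables["o2_contamination"]})
    counts = pd.DataFrame(counts_rows)
    counts.index.name = "sample"
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return counts, meta


def steady_state(scenario: ReactorScenario, phase: RatePhase,
                 reactions: Optional[Mapping[str, ReactionSpec]] = None,
                 registry: Optional[CompoundRegistry] = None
                 ) -> Dict[str, float]:
    """CSTR fixed point C* = C_feed + r/D for the given phase's extents —
    handy for initialising scenarios near equilibrium."""
    reg = registry or DEFAULT_REGISTRY
    rxns = dict(reactions or DEFAULT_REACTIONS)
    rates: Dict[str, float] = {}
    for rname, ext in phase.extents.items():
        for comp, coeff in rxns[rname].coefficients().items():
            if reg.get(comp).phase_default == "liquid":
                rates[comp] = rates.get(comp, 0.0) + float(coeff) * ext
    out = {}
    names = set(scenario.feed_mM) | set(rates)
    for n in names:
        out[n] = max(0.0, scenario.feed_mM.get(n, 0.0)
                     + rates.get(n, 0.0) * scenario.hrt)
    return out
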