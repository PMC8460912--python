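"""Closed-gas-loop accounting: tracer-based volume, O2 contamination via
the N2 signature of air, species production rates, and H2 attribution.

The central estimator converts the accumulation of N2 in the recirculating
gas into an O2 ingress rate using the volumetric N2:O2 ratio of air (3.73):

    O2 rate [mL L^-1 d^-1] = (Y2*Vgas2 - Y1*Vgas1) / (3.73 * (t2 - t1) * V_L)

with Y the N2 volumetric fraction and Vgas the total system gas volume in
mL. The estimate is valid when no N2 is formed or consumed biologically,
O2 itself stays below the detection limit (otherwise a validity warning is
attached), and the leak-driven growth of the gas volume is either measured
or negligible. The system gas volume can be measured, or inferred from the
He tracer: Vgas = cumulative He added / y_He.

Uncertainty follows the control-reactor convention: the standard deviation
of the per-interval rates of an anoxic control (true rate ~ 0) scaled by
1/sqrt(n intervals) of the test period. Negative interval rates are kept in
all averages — truncation would bias the mean upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .compounds import MOLAR_VOLUME_ML
from .errors import (BookkeepingError, EstimationError, InputError,
                     InsufficientDataError, TracerError,
                     UncertaintyUnavailableError)
from .liquid_rates import RatePeriod
from .simulator import AIR_N2_TO_O2

#: O2 volumetric fraction above which the Eq.-type estimate is flagged.
O2_DETECTION_FRACTION = 0.001
#: He fraction at or below which tracer-based volumes are refused.
HE_DETECTION_FLOOR = 1e-4


@dataclass(frozen=True)
class GasSample:
    """One gas-phase observation: time, volumetric fractions, total volume."""
    t: float
    y: Mapping[str, float]
    v_gas_ml: Optional[float] = None

    def __post_init__(self) -> None:
        y = dict(self.y)
        if any(not (0.0 <= v <= 1.0) for v in y.values()):
            raise InputError(f"t={self.t}: fractions must lie in [0, 1]")
        total = sum(y.values())
        if not (0.98 <= total <= 1.02):
            raise InputError(
                f"t={self.t}: fractions sum to {total:.4f}, outside "
                "[0.98, 1.02]")
        if self.v_gas_ml is not None and self.v_gas_ml <= 0:
            raise InputError(f"t={self.t}: v_gas_ml must be > 0")
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class O2Estimate:
    """O2 contamination rate with its control-derived standard error."""
    rate: float                      # mL O2 L^-1 d^-1
    se: float
    period: RatePeriod
    n_intervals: int
    warnings: tuple[str, ...] = ()


def samples_from_frame(gas: pd.DataFrame,
                       event_log: Optional[Sequence[dict]] = None
                       ) -> list[GasSample]:
    """Build GasSample objects from a gas CSV frame; if ``v_gas_ml`` is
    absent, estimate it per sample from the He tracer and the event log."""
    samples = []
    ycols = {c[2:]: c for c in gas.columns if c.startswith("y_")}
    has_v = "v_gas_ml" in gas.columns
    for _, row in gas.iterrows():
        t = float(row["time_d"])
        y = {s: float(row[c]) for s, c in ycols.items()}
        if has_v and np.isfinite(row["v_gas_ml"]):
            v = float(row["v_gas_ml"])
        elif event_log is not None:
            v = estimate_gas_volume(cumulative_tracer_ml(event_log, t),
                                    y.get("he", 0.0))
        else:
            v = None
        samples.append(GasSample(t, y, v))
    return samples


def cumulative_tracer_ml(event_log: Sequence[dict], t: float,
                         species: str = "he") -> float:
    """Net tracer volume added up to and including time t (refills minus
    harvests)."""
    total = 0.0
    for ev in event_log:
        if ev["time_d"] <= t + 1e-9:
            sign = 1.0 if ev["type"] == "refill" else -1.0
            total += sign * ev["volumes_ml"].get(species, 0.0)
    return total


def estimate_gas_volume(cumulative_he_ml: float, y_he: float) -> float:
    """System gas volume from He dilution: V = added He / He fraction.

    He is assumed inert and fully retained, so 120 mL He observed at a
    fraction of 0.012 implies 10,000 mL of gas.
    """
    if y_he <= HE_DETECTION_FLOOR:
        raise TracerError(
            f"y_he={y_he:g} at/below detection floor {HE_DETECTION_FLOOR}; "
            "tracer volume unreliable")
    if cumulative_he_ml <= 0:
        raise TracerError("no He on record; cannot estimate gas volume")
    return cumulative_he_ml / y_he


def _require_v(sample: GasSample) -> float:
    if sample.v_gas_ml is None:
        raise EstimationError(
            f"t={sample.t}: no gas volume (measured or He-estimated)")
    return sample.v_gas_ml


def o2_contamination_rate(s1: GasSample, s2: GasSample,
                          liquid_volume: float = 1.0,
                          event_log: Optional[Sequence[dict]] = None
                          ) -> tuple[float, list[str]]:
    """Interval O2 ingress rate (mL O2 L^-1 d^-1) from the N2 build-up.

    May be negative under noise; truncation is the caller's decision. A
    validity warning is returned when O2 exceeds the detection threshold in
    either sample (the N2 bookkeeping may then be inaccurate). When an
    event log is given, N2 removed by gas harvests (vents) inside the
    interval is added back, so the estimate stays exact on a loop whose
    volume is kept bounded.
    """
    if s2.t <= s1.t:
        raise InputError("need t2 > t1")
    for s in (s1, s2):
        if "n2" not in s.y:
            raise InputError(f"t={s.t}: sample lacks an N2 fraction")
    v1, v2 = _require_v(s1), _require_v(s2)
    n2_removed_ml = 0.0
    if event_log is not None:
        for ev in event_log:
            if s1.t + 1e-9 < ev["time_d"] <= s2.t + 1e-9:
                sign = -1.0 if ev["type"] == "refill" else 1.0
                n2_removed_ml += sign * ev["volumes_ml"].get("n2", 0.0)
    rate = ((s2.y["n2"] * v2 - s1.y["n2"] * v1 + n2_removed_ml)
            / (AIR_N2_TO_O2 * (s2.t - s1.t)) / liquid_volume)
    warnings = [
        f"O2 fraction {s.y['o2']:.4f} above detection threshold at t={s.t}"
        for s in (s1, s2)
        if s.y.get("o2", 0.0) > O2_DETECTION_FRACTION]
    return rate, warnings


def _interval_rates(samples: Sequence[GasSample], period: RatePeriod,
                    liquid_volume: float,
                    event_log: Optional[Sequence[dict]] = None
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    inside = [s for s in samples
              if period.t_start - 1e-9 <= s.t <= period.t_end + 1e-9]
    if len(inside) < 2:
        raise InsufficientDataError(
            f"{len(inside)} gas sample(s) in period; need >= 2")
    rates, durations, warnings = [], [], []
    for a, b in zip(inside[:-1], inside[1:]):
        r, w = o2_contamination_rate(a, b, liquid_volume, event_log)
        rates.append(r)
        durations.append(b.t - a.t)
        warnings.extend(w)
    return np.array(rates), np.array(durations), warnings


def o2_rate_with_uncertainty(samples: Sequence[GasSample], period: RatePeriod,
                             liquid_volume: float = 1.0,
                             control_samples: Optional[Sequence[GasSample]]
                             = None,
                             control_liquid_volume: Optional[float] = None,
                             event_log: Optional[Sequence[dict]] = None,
                             control_event_log: Optional[Sequence[dict]]
                             = None) -> O2Estimate:
    """Period O2 contamination rate +/- control-derived standard error.

    The point estimate is the duration-weighted mean of per-interval rates;
    the SE is the standard deviation of the control reactor's interval
    rates divided by sqrt(n intervals of the test period). With fewer than
    3 control intervals :class:`UncertaintyUnavailableError` is raised —
    after computing the point estimate, which the exception carries in its
    ``estimate`` attribute.
    """
    rates, durations, warnings = _interval_rates(samples, period,
                                                 liquid_volume, event_log)
    point = float(np.average(rates, weights=durations))
    n = len(rates)
    if control_samples is None:
        err = UncertaintyUnavailableError("no control series provided")
        err.estimate = O2Estimate(point, float("nan"), period, n,
                                  tuple(warnings))
        raise err
    ctrl_period = RatePeriod(control_samples[0].t, control_samples[-1].t,
                             "control")
    ctrl_rates, _, _ = _interval_rates(
        control_samples, ctrl_period,
        control_liquid_volume if control_liquid_volume is not None
        else liquid_volume, control_event_log)
    if len(ctrl_rates) < 3:
        err = UncertaintyUnavailableError(
            f"{len(ctrl_rates)} control interval(s); need >= 3")
        err.estimate = O2Estimate(point, float("nan"), period, n,
                                  tuple(warnings))
        raise err
    se = float(np.std(ctrl_rates, ddof=1) / np.sqrt(n))
    return O2Estimate(point, se, period, n, tuple(warnings))


def gas_species_rate(samples: Sequence[GasSample], event_log: Sequence[dict],
                     species: str, period: RatePeriod,
                     liquid_volume: float = 1.0) -> float:
    """Net volumetric production rate of a gas species, mmol L^-1 d^-1.

    rate = [delta(Y*Vgas) - refill additions + harvest removals] /
    (22.414 * dt * V_L). Refills inside (t1, t2] must carry their
    composition; a gap in the event log over the period raises
    :class:`BookkeepingError`.
    """
    inside = [s for s in samples
              if period.t_start - 1e-9 <= s.t <= period.t_end + 1e-9]
    if len(inside) < 2:
        raise InsufficientDataError("need >= 2 gas samples in period")
    s1, s2 = inside[0], inside[-1]
    v1, v2 = _require_v(s1), _require_v(s2)
    added_ml = 0.0
    for ev in event_log:
        if ev["time_d"] is None:
            raise BookkeepingError("event without time stamp")
        if s1.t + 1e-9 < ev["time_d"] <= s2.t + 1e-9:
            if "volumes_ml" not in ev:
                raise BookkeepingError(
                    f"event at t={ev['time_d']} lacks composition")
            sign = 1.0 if ev["type"] == "refill" else -1.0
            added_ml += sign * ev["volumes_ml"].get(species, 0.0)
    delta_ml = s2.y.get(species, 0.0) * v2 - s1.y.get(species, 0.0) * v1
    return float((delta_ml - added_ml)
                 / (MOLAR_VOLUME_ML * (s2.t - s1.t) * liquid_volume))


def attribute_h2(h2_consumption: float, ch4_production: float
                 ) -> tuple[float, float]:
    """Split H2 consumption into the methanogenic share (4 mol H2 per mol
    CH4) and the remainder ("non-CH4 H2 consumption"). Linear in both
    arguments; rates in mmol L^-1 d^-1."""
    ch4_attributed = 4.0 * ch4_production
    return ch4_attributed, h2_consumption - ch4_attributed


def h2_o2_ratio(non_ch4_h2: float, o2_rate_ml: float) -> float:
    """Molar ratio of non-methanogenic H2 consumption to O2 ingress.

    The H2:O2 = 2 stoichiometry of direct H2 oxidation is the reference
    value; ratios above 2 indicate additional H2 sinks.
    """
    if o2_rate_ml <= 0:
        raise EstimationError("undefined ratio: O2 rate must be > 0")
    return non_ch4_h2 / (o2_rate_ml / MOLAR_VOLUME_ML)
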