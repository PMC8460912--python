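"""End-to-end orchestration from a declarative run configuration.

A run config (YAML/JSON mapping) provides either a ``scenario`` block to
simulate or ``inputs`` paths to measured series, plus period definitions
and operating parameters. Stages execute in order — simulate, rates, gas,
electrons, compare (when a control is configured), community (when counts
or a community link are present) — exchanging only typed tables, and every
artifact is written as CSV/TSV/JSON under the output directory. Identical
config + seeds yield byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import community as community_mod
from . import electron_balance, gas_accounting, io, liquid_rates, simulator
from .comparisons import comparison_table
from .errors import UncertaintyUnavailableError, ValidationError

log = logging.getLogger("fermbal")

ALL_STAGES = ("simulate", "rates", "gas", "electrons", "compare", "community")


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a mapping")
    return cfg


def scenario_from_dict(block: Mapping[str, Any], *, liquid_volume: float,
                       hrt: float, feed_mM: Mapping[str, float]
                       ) -> simulator.ReactorScenario:
    """Build a ReactorScenario from a config block; reactor-level values
    (volume, HRT, feed) come from the top-level config."""
    phases = [simulator.RatePhase(p["t_start"], p["t_end"],
                                  dict(p.get("extents", {})))
              for p in block.get("rate_schedule", [])]
    leaks = [simulator.LeakInterval(l["t_start"], l["t_end"],
                                    l["o2_rate_ml"])
             for l in block.get("leak_schedule", [])]
    noise = simulator.NoiseSpec(**block.get("noise", {}))
    refill = simulator.RefillSpec(**block.get("refill", {}))
    return simulator.ReactorScenario(
        duration=block["duration"], liquid_volume=liquid_volume, hrt=hrt,
        feed_mM=dict(feed_mM), initial_mM=block.get("initial_mM"),
        rate_schedule=phases, leak_schedule=leaks, refill=refill,
        noise=noise, sample_interval=block.get("sample_interval", 2.0),
        dt=block.get("dt", 0.05))


def _periods(cfg: Mapping[str, Any]) -> list[liquid_rates.RatePeriod]:
    periods = [liquid_rates.RatePeriod(p["t_start"], p["t_end"],
                                       p.get("label",
                                             f"{p['t_start']:g}-{p['t_end']:g}"))
               for p in cfg.get("periods", [])]
    if not periods:
        raise ValidationError("config defines no periods")
    for a, b in zip(periods[:-1], periods[1:]):
        if b.t_start < a.t_end - 1e-9:
            raise ValidationError(
                f"periods {a.label!r} and {b.label!r} overlap")
    return periods


def _acquire(cfg: Mapping[str, Any], block_key: str, outdir: Path,
             prefix: str, seed_offset: int):
    """Simulate or read one reactor's data; returns (liquid, gas, events,
    truth-or-None)."""
    block = cfg.get(block_key)
    if block is None:
        return None
    if "scenario" in block:
        scen = scenario_from_dict(
            block["scenario"], liquid_volume=cfg.get("liquid_volume", 1.0),
            hrt=cfg.get("hrt", 14.0), feed_mM=cfg.get("feed_mM", {}))
        traj = simulator.simulate(scen)
        if block.get("apply_noise", True) and (
                scen.noise.liquid_cv or scen.noise.gas_sd):
            seed = int(cfg.get("seed", 0)) + seed_offset
            traj = simulator.apply_noise(traj, scen.noise, seed=seed)
        io.write_liquid_csv(traj.liquid, outdir / f"{prefix}liquid.csv")
        io.write_gas_csv(traj.gas, outdir / f"{prefix}gas.csv")
        io.write_event_log(traj.event_log, outdir / f"{prefix}events.json")
        (outdir / f"{prefix}truth.json").write_text(
            json.dumps(traj.truth, indent=1, sort_keys=True))
        return traj.liquid, traj.gas, traj.event_log, traj
    paths = block.get("inputs", {})
    liquid = io.read_liquid_csv(paths["liquid"]) if "liquid" in paths else None
    gas = io.read_gas_csv(paths["gas"]) if "gas" in paths else None
    events = io.read_event_log(paths["events"]) if "events" in paths else []
    return liquid, gas, events, None


def run(cfg: Mapping[str, Any], outdir: Optional[str | Path] = None,
        stages: Optional[Sequence[str]] = None) -> dict:
    """Execute the configured stages; returns the machine-readable summary
    (also written to ``summary.json``)."""
    t0 = time.perf_counter()
    stages = tuple(stages or ALL_STAGES)
    outdir = Path(outdir or cfg.get("outdir", "fermbal_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    hrt = cfg.get("hrt", 14.0)
    V = cfg.get("liquid_volume", 1.0)
    feed = dict(cfg.get("feed_mM", {}))
    periods = _periods(cfg)
    summary: dict[str, Any] = {"stages": [], "periods": {}}

    def stage_done(name: str) -> None:
        summary["stages"].append(name)
        log.info("stage %-9s done at %.2f s", name, time.perf_counter() - t0)

    test = _acquire(cfg, "test", outdir, "", seed_offset=0)
    if test is None:
        raise ValidationError("config needs a 'test' block "
                              "(scenario or inputs)")
    control = _acquire(cfg, "control", outdir, "control_", seed_offset=1)
    liquid, gas, events, traj = test
    if traj is not None:
        stage_done("simulate")

    method = cfg.get("rates_method", "regression")
    rates = liquid_rates.rate_table(liquid, periods, feed, hrt,
                                    method=method)
    rates.to_csv(outdir / "rates.csv", index=False)
    ctrl_rates = None
    if control is not None and control[0] is not None:
        ctrl_rates = liquid_rates.rate_table(control[0], periods, feed, hrt,
                                             method=method)
        ctrl_rates.to_csv(outdir / "control_rates.csv", index=False)
    stage_done("rates")

    if not ({"gas", "electrons"} & set(stages)):
        text = json.dumps(summary, indent=1, sort_keys=True)
        (outdir / "summary.json").write_text(text)
        return summary

    samples = gas_accounting.samples_from_frame(gas, events)
    ctrl_samples = None
    if control is not None and control[1] is not None:
        ctrl_samples = gas_accounting.samples_from_frame(control[1],
                                                         control[2])
    gas_rows = []
    for period in periods:
        label = period.label
        try:
            est = gas_accounting.o2_rate_with_uncertainty(
                samples, period, V, ctrl_samples, event_log=events,
                control_event_log=None if control is None else control[2])
        except UncertaintyUnavailableError as err:
            est = err.estimate
            log.warning("period %s: O2 SE unavailable (%s)", label, err)
        sp_rates = {s: gas_accounting.gas_species_rate(samples, events, s,
                                                       period, V)
                    for s in ("h2", "ch4", "he")}
        h2_cons = max(0.0, -sp_rates["h2"])
        attributed, non_ch4 = gas_accounting.attribute_h2(
            h2_cons, max(0.0, sp_rates["ch4"]))
        ratio = (gas_accounting.h2_o2_ratio(non_ch4, est.rate)
                 if est.rate > 0 else float("nan"))
        gas_rows.append({
            "period": label, "o2_rate_ml_l_d": est.rate, "o2_se": est.se,
            "n_intervals": est.n_intervals,
            "h2_rate": sp_rates["h2"], "ch4_rate": sp_rates["ch4"],
            "he_rate": sp_rates["he"], "non_ch4_h2_consumption": non_ch4,
            "h2_o2_ratio": ratio,
            "warnings": "; ".join(est.warnings)})
        summary["periods"].setdefault(label, {})["o2_rate_ml_l_d"] = est.rate
        summary["periods"][label]["o2_se"] = est.se
        summary["periods"][label]["ch4_rate"] = sp_rates["ch4"]
        summary["periods"][label]["non_ch4_h2_consumption"] = non_ch4
    gas_table = pd.DataFrame(gas_rows)
    gas_table.to_csv(outdir / "gas_rates.csv", index=False)
    stage_done("gas")

    if "electrons" not in stages:
        text = json.dumps(summary, indent=1, sort_keys=True)
        (outdir / "summary.json").write_text(text)
        return summary

    ledger_frames = []
    for period, row in zip(periods, gas_rows):
        ledger = electron_balance.build_ledger(
            rates, {"h2": row["h2_rate"], "ch4": row["ch4_rate"]},
            max(0.0, row["o2_rate_ml_l_d"]), period, feed, hrt, V,
            period_label=period.label)
        rep = electron_balance.ledger_report(ledger)
        rep.insert(0, "period", period.label)
        ledger_frames.append(rep)
        summary["periods"][period.label]["electron_error_pct"] = \
            ledger.error_pct
    pd.concat(ledger_frames).to_csv(outdir / "electron_ledger.csv",
                                    index=False)
    stage_done("electrons")

    if "compare" in stages and ctrl_rates is not None:
        contrasts = comparison_table(rates, ctrl_rates)
        contrasts.to_csv(outdir / "contrasts.csv", index=False)
        stage_done("compare")
    else:
        log.info("compare stage skipped: no control configured")

    counts, meta = (None, None) if "community" not in stages else \
        _community_inputs(cfg, traj)
    if counts is not None:
        seed = int(cfg.get("seed", 0)) + 2
        depth = cfg.get("rarefaction_depth")
        rare = community_mod.rarefy(counts, depth, seed=seed)
        rel = community_mod.filter_abundant(
            community_mod.relative_abundance(rare),
            cfg.get("abundance_threshold", 0.01))
        covar_cols = cfg.get("covariates", ["o2_contamination"])
        covars = community_mod.period_mean_covariates(meta, covar_cols)
        corr = community_mod.spearman_matrix(
            rel, covars, alpha=cfg.get("alpha", 0.01), seed=seed,
            bh=cfg.get("bh_correction", False))
        corr.rho.to_csv(outdir / "correlation_rho.csv")
        corr.p.to_csv(outdir / "correlation_p.csv")
        corr.mask.to_csv(outdir / "correlation_mask.csv")
        summary["n_significant_correlations"] = int(
            corr.mask.to_numpy().sum() // 2)
        stage_done("community")
    else:
        log.info("community stage skipped: no counts or link configured")

    text = json.dumps(summary, indent=1, sort_keys=True)
    (outdir / "summary.json").write_text(text)
    return summary


def _community_inputs(cfg: Mapping[str, Any], traj):
    block = cfg.get("community")
    if block is None:
        return None, None
    if "counts" in block:
        counts = io.read_count_table(block["counts"])
        meta = pd.read_csv(block["meta"], index_col=0)
        return counts, meta
    if "link" in block:
        if traj is None:
            raise ValidationError(
                "community link requires a simulated scenario")
        link_cfg = dict(block["link"])
        if "depth_range" in link_cfg:
            link_cfg["depth_range"] = tuple(link_cfg["depth_range"])
        link_cfg.setdefault("seed", int(cfg.get("seed", 0)) + 3)
        link = simulator.CommunityLinkSpec(**link_cfg)
        counts, meta = simulator.generate_community(traj, link,
                                                    times=block.get("times"))
        return counts, meta
    return None, None
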