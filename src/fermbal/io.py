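"""Readers/writers for the plain-text interchange formats.

Liquid series CSV: column ``time_d`` plus one column per compound with a
unit suffix (``lactate_mM`` or ``lactate_gL``); everything is normalised to
mM on read. Gas series CSV: ``time_d`` + fraction columns ``y_h2`` ... plus
optional ``v_gas_ml``. Event log: JSON list of
``{"time_d": t, "type": "refill"|"harvest", "volumes_ml": {species: mL}}``.
Count table: TSV, first column the sample id, taxa as columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .compounds import CompoundRegistry, DEFAULT_REGISTRY, mass_to_molar
from .errors import InputError

GAS_SPECIES = ("h2", "co2", "ch4", "he", "o2", "n2", "ethylene")


def read_liquid_csv(path: str | Path,
                    registry: Optional[CompoundRegistry] = None
                    ) -> pd.DataFrame:
    """Read a liquid time series; returns time_d + per-compound mM columns."""
    raw = pd.read_csv(path)
    if "time_d" not in raw.columns:
        raise InputError(f"{path}: missing time_d column")
    out = pd.DataFrame({"time_d": raw["time_d"].astype(float)})
    for col in raw.columns:
        if col == "time_d":
            continue
        if col.endswith("_mM"):
            out[col[:-3]] = raw[col].astype(float)
        elif col.endswith("_gL"):
            name = col[:-3]
            out[name] = [mass_to_molar(v, name, registry)
                         for v in raw[col].astype(float)]
        else:
            raise InputError(f"{path}: column {col!r} lacks a _mM/_gL suffix")
    _check_monotone(out["time_d"], path)
    return out


def write_liquid_csv(series: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"time_d": series["time_d"]})
    for col in series.columns:
        if col != "time_d":
            out[f"{col}_mM"] = series[col]
    out.to_csv(path, index=False)


def read_gas_csv(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    if "time_d" not in raw.columns:
        raise InputError(f"{path}: missing time_d column")
    _check_monotone(raw["time_d"], path)
    return raw


def write_gas_csv(gas: pd.DataFrame, path: str | Path) -> None:
    gas.to_csv(path, index=False)


def read_event_log(path: str | Path) -> list[dict]:
    events = json.loads(Path(path).read_text())
    for ev in events:
        if ev.get("type") not in ("refill", "harvest"):
            raise InputError(f"{path}: bad event type {ev.get('type')!r}")
    return sorted(events, key=lambda e: e["time_d"])


def write_event_log(events: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(events, indent=1, sort_keys=True))


def read_count_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table.values < 0).any():
        raise InputError(f"{path}: negative counts")
    return table.astype(int)


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def _check_monotone(time_d: pd.Series, path) -> None:
    t = time_d.to_numpy()
    if len(t) > 1 and (t[1:] <= t[:-1]).any():
        raise InputError(f"{path}: time_d must be strictly increasing")
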