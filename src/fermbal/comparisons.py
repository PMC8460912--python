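"""Test-vs-control contrasts: percent changes, fold changes, and aligned
comparison tables.

Stored values are never rounded; integer rounding (half away from zero)
happens only in the report layer, which phrases signs as "less"/"higher"
the way reactor comparisons are usually written up. When a claimed percent
figure is supplied for cross-checking, the report flags any disagreement
with the value recomputed from the operands rather than silently matching
the claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .errors import AlignmentError, UndefinedContrastError


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (45.8 -> 46)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent_change(test: float, control: float) -> float:
    """Signed percent change 100*(test/control - 1); unrounded."""
    if control == 0:
        raise UndefinedContrastError("control rate is zero")
    return 100.0 * (test / control - 1.0)


def rate_as_pct_of_control(test: float, control: float) -> float:
    """test as a percentage of control: 100*test/control; unrounded."""
    if control <= 0:
        raise UndefinedContrastError("control rate must be > 0")
    return 100.0 * test / control


def fold_change(test: float, control: float) -> float:
    """Plain ratio test/control."""
    if control <= 0:
        raise UndefinedContrastError("control rate must be > 0")
    return test / control


@dataclass(frozen=True)
class Contrast:
    compound: str
    period: str
    test_rate: float
    control_rate: float
    pct_change: float     # unrounded, signed
    fold: float


def comparison_table(test_rates: pd.DataFrame, control_rates: pd.DataFrame
                     ) -> pd.DataFrame:
    """One contrast per (period, compound) present in both rate tables.

    Ordering is deterministic (period, then compound); input row order is
    irrelevant. Period labels present in one table but not the other raise
    :class:`AlignmentError` listing the unmatched labels.
    """
    p_test = set(test_rates["period"])
    p_ctrl = set(control_rates["period"])
    if p_test != p_ctrl:
        raise AlignmentError(
            f"unmatched period labels: only-test={sorted(p_test - p_ctrl)}, "
            f"only-control={sorted(p_ctrl - p_test)}")
    merged = test_rates.merge(control_rates, on=["period", "compound"],
                              suffixes=("_test", "_control"))
    rows = []
    for _, row in merged.iterrows():
        t, c = row["rate_test"], row["rate_control"]
        rows.append({
            "period": row["period"], "compound": row["compound"],
            "test_rate": t, "control_rate": c,
            "pct_change": percent_change(t, c) if c != 0 else float("nan"),
            "fold": fold_change(t, c) if c > 0 else float("nan"),
        })
    out = pd.DataFrame(rows).sort_values(["period", "compound"],
                                         kind="mergesort")
    return out.reset_index(drop=True)


def render_contrast(compound: str, test: float, control: float,
                    claimed_pct: Optional[int] = None) -> str:
    """Human-readable sentence for one contrast, e.g.
    '63% less ch4 (6.05 of 16.5 mmol L-1 d-1)'."""
    pct = percent_change(test, control)
    word = "less" if pct < 0 else "higher"
    shown = round_half_away(abs(pct))
    text = (f"{shown}% {word} {compound} "
            f"({test:g} of {control:g} mmol L-1 d-1)")
    if claimed_pct is not None and claimed_pct != shown:
        text += (f" [recomputed {shown}% differs from claimed "
                 f"{claimed_pct}%]")
    return text


def render_report(contrasts: pd.DataFrame,
                  claimed: Optional[Mapping[tuple[str, str], int]] = None
                  ) -> str:
    """Plain-text report over a contrast table; ``claimed`` optionally maps
    (period, compound) to a previously reported integer percent figure."""
    lines = []
    for _, row in contrasts.iterrows():
        key = (row["period"], row["compound"])
        lines.append(
            f"{row['period']}: "
            + render_contrast(row["compound"], row["test_rate"],
                              row["control_rate"],
                              None if claimed is None else claimed.get(key)))
    return "\n".join(lines)
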