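"""Flow-cytometry-style analysis of per-event dual-excitation ratios.

Events carry a 405-excited intensity, a 488-excited intensity and a second
marker (Annexin-V- or TMRM-like). The per-event ratio is plain i405/i488;
events whose i488 falls below the intensity floor are flagged excluded
rather than producing infinities. Quadrant gating partitions included
events by a ratio threshold and a marker threshold into four fractions that
sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

EVENT_COLUMNS = ("event_id", "i405", "i488", "marker")


def _check_table(table: pd.DataFrame) -> None:
    for col in ("i405", "i488"):
        if col not in table.columns:
            raise ValidationError(f"event table missing column {col!r}")
    if "event_id" in table.columns and table["event_id"].duplicated().any():
        raise ValidationError("event ids are not unique")
    if (table[["i405", "i488"]] < 0).any().any():
        raise ValidationError("event intensities must be >= 0")


def compute_event_ratio(
    table: pd.DataFrame, intensity_floor: float = 1.0
) -> pd.DataFrame:
    """Return a copy with ``ratio`` and ``included`` columns.

    ratio = i405/i488 where i488 >= intensity_floor; other events are
    excluded (ratio NaN), never infinite.
    """
    _check_table(table)
    out = table.copy()
    i488 = out["i488"].to_numpy(dtype=float)
    i405 = out["i405"].to_numpy(dtype=float)
    included = i488 >= intensity_floor
    ratio = np.full(len(out), np.nan)
    np.divide(i405, i488, out=ratio, where=included)
    out["ratio"] = ratio
    out["included"] = included
    return out


@dataclass
class QuadrantFractions:
    """Fractions of included events by (ratio, marker) high/low state."""

    low_low: float
    low_high: float
    high_low: float
    high_high: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.low_low, self.low_high, self.high_low, self.high_high)


def quadrant_gate(
    table: pd.DataFrame, ratio_threshold: float, marker_threshold: float
) -> QuadrantFractions:
    """Quadrant fractions of included events; fractions sum to 1.

    ``high`` means strictly above the threshold. The table must already
    carry a ``ratio`` column (see :func:`compute_event_ratio`).
    """
    if ratio_threshold <= 0 or marker_threshold <= 0:
        raise ValidationError("gate thresholds must be > 0")
    if "ratio" not in table.columns:
        table = compute_event_ratio(table)
    if "marker" not in table.columns:
        raise ValidationError("event table missing column 'marker'")
    inc = table["included"] if "included" in table.columns else table["ratio"].notna()
    sub = table.loc[inc]
    n = len(sub)
    if n == 0:
        raise ValidationError("quadrant_gate: zero included events")
    hi_r = sub["ratio"].to_numpy() > ratio_threshold
    hi_m = sub["marker"].to_numpy() > marker_threshold
    return QuadrantFractions(
        low_low=float((~hi_r & ~hi_m).sum() / n),
        low_high=float((~hi_r & hi_m).sum() / n),
        high_low=float((hi_r & ~hi_m).sum() / n),
        high_high=float((hi_r & hi_m).sum() / n),
    )


def control_ratio_gate(control_table: pd.DataFrame, sd_mult: float = 3.0) -> float:
    """Default ratio gate from a designated control sample: mean + 3 sd of
    included control ratios."""
    if "ratio" not in control_table.columns:
        control_table = compute_event_ratio(control_table)
    vals = control_table.loc[control_table["ratio"].notna(), "ratio"].to_numpy()
    if len(vals) < 2:
        raise ValidationError("control sample needs >= 2 included events")
    return float(vals.mean() + sd_mult * vals.std(ddof=1))
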