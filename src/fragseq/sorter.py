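"""Biosorter size calibration: TOF -> fragment diameter.

A large-fragment biosorter reports time-of-flight (TOF), which is linear in
object size.  Calibration fits ordinary least squares ``TOF = slope * size
+ intercept`` on standard beads (e.g. 60, 125, 175 µm) and inverts the line
to size fragments and to predict TOF sort gates for a target diameter
range.  The regression direction is TOF-on-size, matching how the standard
curve is acquired; with noisy calibration this differs from size-on-TOF.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError


@dataclass
class BeadCalibration:
    bead_sizes: np.ndarray  # µm, one entry per reading
    tof_readings: np.ndarray  # sorter units
    slope: float  # sorter units per µm
    intercept: float  # sorter units
    r_squared: float

    def to_json(self, path) -> None:
        payload = {
            "bead_sizes_um": list(map(float, self.bead_sizes)),
            "tof_readings": list(map(float, self.tof_readings)),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "BeadCalibration":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["bead_sizes_um"], float),
            np.asarray(d["tof_readings"], float),
            float(d["slope"]),
            float(d["intercept"]),
            float(d["r_squared"]),
        )


def fit_calibration(bead_sizes, tof_readings) -> BeadCalibration:
    """OLS fit of TOF on bead size.

    Multiple readings per bead size enter as individual points (no
    pre-averaging), preserving least-squares weighting.
    """
    sizes = np.asarray(bead_sizes, dtype=float)
    tof = np.asarray(tof_readings, dtype=float)
    if sizes.shape != tof.shape:
        raise ValidationError("bead_sizes and tof_readings must have equal length")
    if np.unique(sizes).size < 2:
        raise ValidationError("degenerate design: need >= 2 distinct bead sizes")
    slope, intercept = np.polyfit(sizes, tof, 1)
    fitted = slope * sizes + intercept
    ss_res = float(np.sum((tof - fitted) ** 2))
    ss_tot = float(np.sum((tof - tof.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope == 0:
        raise ValidationError("calibration slope is zero; TOF carries no size signal")
    return BeadCalibration(sizes, tof, float(slope), float(intercept), r2)


def size_from_tof(cal: BeadCalibration, table: pd.DataFrame) -> pd.DataFrame:
    """Invert the calibration line: size = (TOF - intercept) / slope.

    Negative predicted sizes are kept and flagged in a ``size_flag`` column
    rather than silently clamped.
    """
    if cal.slope == 0:
        raise ValidationError("calibration slope is zero")
    out = table.copy()
    out["size"] = (out["tof"] - cal.intercept) / cal.slope
    negative = out["size"] <= 0
    out["size_flag"] = np.where(negative, "nonpositive", "ok")
    if negative.any():
        warnings.warn(f"{int(negative.sum())} fragments with non-positive predicted size")
    return out


def predict_gate(cal: BeadCalibration, size_lo: float, size_hi: float) -> tuple[float, float]:
    """Forward-map a diameter gate to TOF bounds, returned ascending."""
    if not np.isfinite(cal.slope):
        raise ValidationError("calibration is not fitted")
    if size_lo > size_hi:
        raise ValidationError("size_lo must be <= size_hi")
    a = cal.slope * size_lo + cal.intercept
    b = cal.slope * size_hi + cal.intercept
    return (a, b) if a <= b else (b, a)


def gate_fragments(table: pd.DataFrame, size_lo: float, size_hi: float) -> pd.DataFrame:
    """Subset fragments whose size lies in the closed interval [lo, hi].

    Closed on both ends: published gates like 211–325 and 326–457 µm tile
    the size range without overlap.
    """
    if table["size"].isna().any():
        raise ValidationError("fragment sizes must be set before gating")
    mask = (table["size"] >= size_lo) & (table["size"] <= size_hi)
    return table[mask]
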