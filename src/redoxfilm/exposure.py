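"""Residual-activity analysis across repeated air exposures.

An enzyme-film electrode that is activated, exposed to air, and re-assayed
loses a roughly constant fraction of its catalytic activity per exposure
cycle, so the retained activity follows a geometric law
(1 - r)^n.  This module quantifies the per-cycle loss r from a series of
normalized activities and predicts cumulative retention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .voltammetry import Trace, plateau_current

__all__ = [
    "ExposureSeries",
    "residual_activity",
    "cumulative_retention",
    "fit_per_cycle_loss",
    "LossFit",
    "write_series",
    "read_series",
]

# default H2-oxidation readout window, V vs SHE (catalytic plateau range)
DEFAULT_WINDOW = (-0.3, 0.2)


@dataclass
class ExposureSeries:
    """Per-cycle residual activities, cycle 0 being the pre-exposure assay.

    Activities are dimensionless fractions normalized so that
    ``activity[0] == 1``.
    """

    cycle_index: np.ndarray
    activity: np.ndarray
    exposure_duration_h: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cycle_index = np.asarray(self.cycle_index, dtype=int)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.cycle_index.size != self.activity.size:
            raise ValueError("cycle_index and activity must have equal length")
        if self.cycle_index.size and self.cycle_index[0] != 0:
            raise ValueError("series must start at cycle 0 (pre-exposure)")
        if np.any(self.activity < 0):
            raise ValueError("activities must be non-negative")

    def normalized(self) -> "ExposureSeries":
        """Rescale so the pre-exposure activity is exactly 1."""
        a0 = self.activity[0]
        if a0 <= 0:
            raise ValueError("pre-exposure activity must be positive")
        return ExposureSeries(
            self.cycle_index.copy(),
            self.activity / a0,
            self.exposure_duration_h,
            dict(self.meta),
        )


def residual_activity(
    before: Trace,
    after: Trace,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """Fraction of the H2-oxidation plateau current retained after exposure.

    Ratio of the forward-scan plateau medians of the two traces over the
    same potential window; invariant to a common rescaling of both traces.
    """
    ref = plateau_current(before, window).current
    if ref <= 0:
        raise ValueError("reference plateau current must be positive")
    return plateau_current(after, window).current / ref


def cumulative_retention(per_cycle_loss: float, n_cycles: int) -> float:
    """Retained activity fraction (1 - r)^n after ``n_cycles`` exposures."""
    if not (0.0 <= per_cycle_loss <= 1.0):
        raise ValueError("per-cycle loss must lie in [0, 1]")
    if n_cycles < 0:
        raise ValueError("cycle count must be non-negative")
    return (1.0 - per_cycle_loss) ** n_cycles


@dataclass(frozen=True)
class LossFit:
    """Per-cycle loss estimate with its standard error and fit diagnostics."""

    r: float
    stderr: float
    slope: float
    r_squared: float
    n_cycles: int


def fit_per_cycle_loss(series: ExposureSeries) -> LossFit:
    """Per-cycle activity loss r from least squares on log(activity).

    Fits log(activity) = a + b * cycle and reports r = 1 - exp(b); the
    standard error of r follows by the delta method.  Requires at least
    three cycles and strictly positive activities.
    """
    s = series.normalized()
    if s.activity.size < 3:
        raise ValueError("need at least three cycles to fit a per-cycle loss")
    if np.any(s.activity <= 0):
        raise ValueError("activities must be positive for a log-linear fit")
    res = stats.linregress(s.cycle_index, np.log(s.activity))
    retention = math.exp(res.slope)
    r = 1.0 - min(retention, 1.0)  # constant/growing series -> no loss
    stderr = retention * res.stderr if math.isfinite(res.stderr) else 0.0
    return LossFit(
        r=r,
        stderr=stderr,
        slope=res.slope,
        r_squared=res.rvalue**2,
        n_cycles=int(s.activity.size - 1),
    )


def write_series(series: ExposureSeries, path) -> None:
    """Write an exposure series as a two-column CSV (cycle, activity)."""
    import pandas as pd

    df = pd.DataFrame({"cycle": series.cycle_index, "activity": series.activity})
    with open(path, "w") as fh:
        if series.exposure_duration_h is not None:
            fh.write(f"# exposure_duration_h: {series.exposure_duration_h}\n")
        for key, val in series.meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_series(path) -> ExposureSeries:
    """Read an exposure series CSV written by :func:`write_series`."""
    import pandas as pd

    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    dur = meta.pop("exposure_duration_h", None)
    return ExposureSeries(
        cycle_index=df["cycle"].to_numpy(),
        activity=df["activity"].to_numpy(),
        exposure_duration_h=float(dur) if dur is not None else None,
        meta=meta,
    )
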