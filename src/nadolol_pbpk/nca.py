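"""Non-compartmental analysis and population summary envelopes.

AUC uses the linear trapezoid; the terminal slope (lambda_z) comes from a
log-linear regression on the last 5 points or the last 20 % of the sampled
time span, whichever selects more points.  Percentiles use linear
interpolation between order statistics; box whiskers are the data minimum
and maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import ConcentrationProfile

__all__ = [
    "PKParameters",
    "VPCSummary",
    "BoxSummary",
    "run_nca",
    "vpc_summary",
    "box_summary",
]

MIN_LAMBDA_POINTS = 5
TERMINAL_SPAN_FRACTION = 0.2


@dataclass(frozen=True)
class PKParameters:
    """Model-free PK parameters from one concentration-time profile.

    ``cl_ml_min`` is Dose/AUC_0-inf for IV and the apparent CL/F for oral.
    ``auc_0_inf``, ``cl_ml_min``, ``t_half_h`` and ``lambda_z_per_h`` are
    None when no valid (negative) terminal slope could be estimated.
    """

    cmax: float  # ng/mL
    tmax_h: float
    auc_0_t: float  # ng·h/mL
    auc_0_inf: float | None
    cl_ml_min: float | None
    t_half_h: float | None
    lambda_z_per_h: float | None
    route: str = "iv"

    def __post_init__(self) -> None:
        if self.auc_0_inf is not None and self.auc_0_t > self.auc_0_inf + 1e-9:
            raise ValueError("AUC_0-t cannot exceed AUC_0-inf")


@dataclass(frozen=True)
class VPCSummary:
    """Per-time envelopes over a simulated population (ng/mL)."""

    times_h: np.ndarray
    mean: np.ndarray
    minimum: np.ndarray
    maximum: np.ndarray
    p5: np.ndarray
    p95: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stat in ("mean", "minimum", "maximum", "p5", "p95"):
            rows.append(
                pd.DataFrame(
                    {"time_h": self.times_h, "stat": stat, "value": getattr(self, stat)}
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class BoxSummary:
    """Five-number box-plot summary; whiskers are the data min and max."""

    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float


def _lambda_z(times: np.ndarray, conc: np.ndarray) -> float | None:
    """Terminal elimination rate from log-linear regression, or None."""
    span = times[-1] - times[0]
    in_tail = times >= times[-1] - TERMINAL_SPAN_FRACTION * span
    n_tail = max(MIN_LAMBDA_POINTS, int(np.count_nonzero(in_tail)))
    n_tail = min(n_tail, len(times))
    t = times[-n_tail:]
    c = conc[-n_tail:]
    pos = c > 0
    if np.count_nonzero(pos) < 3:
        return None
    slope = np.polyfit(t[pos], np.log(c[pos]), 1)[0]
    if slope >= 0:
        return None
    return -float(slope)


def run_nca(profile: ConcentrationProfile, dose_mg: float, route: str = "iv") -> PKParameters:
    """Non-compartmental analysis of one profile.

    Cmax/Tmax are read from the grid, AUC_0-t by linear trapezoid,
    AUC_0-inf = AUC_0-t + C_last/lambda_z, CL = Dose/AUC_0-inf converted to
    mL/min.  A non-positive terminal slope leaves the extrapolated
    quantities unavailable (None) while AUC_0-t is still returned.
    """
    if route not in ("iv", "oral"):
        raise ValueError(f"unknown route {route!r}")
    if dose_mg <= 0:
        raise ValueError("dose must be > 0")
    t = np.asarray(profile.times_h, dtype=float)
    c = np.asarray(profile.conc_ng_ml, dtype=float)
    if len(t) < 3:
        raise ValueError("NCA requires at least 3 time points")
    if np.any(c < 0):
        raise ValueError("NCA requires non-negative concentrations")

    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])
    auc_0_t = float(np.trapezoid(c, t))

    lam = _lambda_z(t, c) if cmax > 0 else None
    if lam is None:
        return PKParameters(cmax, tmax, auc_0_t, None, None, None, None, route)

    c_last = float(c[c > 0][-1])
    auc_inf = auc_0_t + c_last / lam
    cl_ml_min = dose_mg * 1e6 / auc_inf / 60.0  # ng / (ng·h/mL) -> mL/h -> mL/min
    t_half = math.log(2.0) / lam
    return PKParameters(cmax, tmax, auc_0_t, auc_inf, cl_ml_min, t_half, lam, route)


def _common_grid(profiles: Sequence[ConcentrationProfile]) -> np.ndarray:
    grid = profiles[0].times_h
    for p in profiles[1:]:
        if p.times_h.shape != grid.shape or not np.allclose(p.times_h, grid, atol=1e-9):
            raise ValueError("profiles are not on a common time grid")
    return grid


def vpc_summary(profiles: Sequence[ConcentrationProfile]) -> VPCSummary:
    """Arithmetic mean, min/max and 5th/95th percentile envelopes per time."""
    if len(profiles) < 2:
        raise ValueError("a VPC needs at least 2 profiles")
    grid = _common_grid(profiles)
    mat = np.vstack([p.conc_ng_ml for p in profiles])
    return VPCSummary(
        times_h=grid,
        mean=mat.mean(axis=0),
        minimum=mat.min(axis=0),
        maximum=mat.max(axis=0),
        p5=np.percentile(mat, 5, axis=0),
        p95=np.percentile(mat, 95, axis=0),
    )


def box_summary(values: Iterable[float]) -> BoxSummary:
    """Median, quartiles (linear interpolation) and min/max whiskers."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("box summary of empty data")
    return BoxSummary(
        median=float(np.percentile(arr, 50)),
        q25=float(np.percentile(arr, 25)),
        q75=float(np.percentile(arr, 75)),
        whisker_low=float(arr.min()),
        whisker_high=float(arr.max()),
    )
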