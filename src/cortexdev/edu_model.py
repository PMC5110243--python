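"""Cell-cycle kinetics from cumulative-labeling curves.

Under continuous exposure to a thymidine analogue (EdU/BrdU), the labeled
fraction of a homogeneous cycling population rises linearly with exposure
time and plateaus once every cycling cell has traversed S phase:

    LI(t) = min( GF * (t + Ts) / Tc , GF )

where Tc is the total cell-cycle length, Ts the S-phase length and GF the
growth fraction (the fraction of cells that cycle at all; the plateau
height). A least-squares line through the pre-plateau points has slope
GF/Tc and y-intercept GF*Ts/Tc, so

    Ts = intercept / slope,    Tc = GF / slope,    Tc - Ts = (GF - intercept) / slope.

The plateau is read off the data (time points whose mean labeling index
lies within ``plateau_tol`` of the curve maximum, scanned from the latest
time backwards) and GF is the mean over the plateau observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class FitError(ValueError):
    """Cumulative-labeling fit cannot be performed on the given curve."""


@dataclass
class CellCycleParams:
    """Fitted (or specified) cell-cycle parameters, in hours.

    ``tc``: total cycle length; ``ts``: S-phase length; ``gf``: growth
    fraction in (0, 1]. ``slope``/``intercept``/``r_squared`` describe the
    pre-plateau regression when the object comes from a fit.
    """

    tc: float
    ts: float
    gf: float
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 < self.ts < self.tc):
            raise ValueError(f"require 0 < Ts < Tc, got Ts={self.ts}, Tc={self.tc}")
        if not (0 < self.gf <= 1):
            raise ValueError(f"growth fraction must be in (0, 1], got {self.gf}")

    @property
    def plateau_onset(self) -> float:
        """Time at which the labeling index reaches the plateau: Tc - Ts."""
        return self.tc - self.ts


@dataclass
class LabelingCurve:
    """(time, labeling index) observations from a cumulative-labeling assay."""

    times_h: np.ndarray
    labeling_index: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.labeling_index = np.asarray(self.labeling_index, dtype=float)
        if self.times_h.shape != self.labeling_index.shape:
            raise ValueError("times and labeling indices differ in length")
        if (self.times_h < 0).any():
            raise ValueError("negative exposure time")
        if ((self.labeling_index < 0) | (self.labeling_index > 1)).any():
            raise ValueError("labeling index outside [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"time_h": self.times_h, "labeling_index": self.labeling_index}
        )
        if self.replicate is not None:
            df["replicate"] = self.replicate
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabelingCurve":
        df = pd.read_csv(path)
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(df["time_h"].to_numpy(), df["labeling_index"].to_numpy(), rep)


def predict_labeling(params: CellCycleParams, t) -> np.ndarray | float:
    """Noiseless labeling index min(GF*(t+Ts)/Tc, GF) at time(s) ``t`` (hours)."""
    t_arr = np.asarray(t, dtype=float)
    if (t_arr < 0).any():
        raise ValueError("negative time")
    li = np.minimum(params.gf * (t_arr + params.ts) / params.tc, params.gf)
    return li if t_arr.ndim else float(li)


def fit_cumulative_labeling(
    curve: LabelingCurve,
    plateau_tol: float = 0.02,
    average_replicates: bool = False,
) -> CellCycleParams:
    """Estimate Tc, Ts and GF from a cumulative-labeling curve.

    The plateau is read off the curve of mean labeling index per time
    point: scanning from the latest time backwards, a time point belongs to
    the plateau while its mean lies within ``plateau_tol`` of the curve
    maximum (judging the plateau on per-time means rather than individual
    replicates keeps replicate scatter from spuriously breaking it). GF is
    the mean over all observations at plateau times. A least-squares line
    through the observations at strictly pre-plateau times gives slope
    GF/Tc and y-intercept GF*Ts/Tc; replicates enter the regression as
    individual points unless ``average_replicates`` collapses each time
    point to its mean first. Both choices are invariant to duplicating
    every observation.

    Raises :class:`FitError` when no plateau is detected, fewer than three
    pre-plateau time points remain, or the fitted slope is not positive.
    """
    order = np.argsort(curve.times_h, kind="stable")
    t = curve.times_h[order]
    li = curve.labeling_index[order]
    times = np.unique(t)
    means = np.array([li[t == tt].mean() for tt in times])
    top = means.max()
    # contiguous-from-the-latest-time plateau on the per-time means
    n_plateau = 0
    for v in means[::-1]:
        if top - v <= plateau_tol:
            n_plateau += 1
        else:
            break
    if n_plateau == 0 or n_plateau == len(times):
        raise FitError("no plateau detected; growth fraction unresolvable")
    plateau_start = times[-n_plateau]
    on_plateau = t >= plateau_start
    gf = float(li[on_plateau].mean())
    if len(times) - n_plateau < 3:
        raise FitError(
            f"need >= 3 pre-plateau time points, have {len(times) - n_plateau}"
        )
    if average_replicates:
        t_pre, li_pre = times[:-n_plateau], means[:-n_plateau]
    else:
        t_pre, li_pre = t[~on_plateau], li[~on_plateau]
    res = stats.linregress(t_pre, li_pre)
    if res.slope <= 0:
        raise FitError(f"non-positive slope {res.slope:.4g}; curve does not rise")
    ts = float(res.intercept / res.slope)
    tc = float(gf / res.slope)
    return CellCycleParams(
        tc=tc,
        ts=ts,
        gf=gf,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
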