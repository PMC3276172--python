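"""Growth-curve fitness components and the LSC relative-fitness score.

Microcultivation yields an optical-density (OD) time series per strain,
environment and run. Three mitotic fitness components are extracted:

* lag (h) — population adaptation time, read off as the intersection of
  the maximum-slope tangent of ln(OD) with the initial baseline;
* doubling time (h) — ln 2 divided by the maximum specific growth rate
  (the steepest sliding-window slope of ln OD);
* efficiency (OD units) — total change in population density.

The LSC score compares a strain's ln-transformed component against the
reference (wild-type) ln-mean in each run and sums the squared
deviations over runs:

    LSC_ij = Σ_r [ mean_k ln(wt_kjr) − ln(x_ijr) ]²

Efficiency is inverted (reciprocal before the log) so that for every
component a larger value means worse than the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "GrowthCurve",
    "FitnessComponents",
    "LSCScore",
    "extract_fitness",
    "lsc_score",
    "lsc_table",
]

OD_FLOOR = 0.001


@dataclass
class GrowthCurve:
    strain: str
    environment: str
    run: int
    time_min: np.ndarray
    od: np.ndarray
    blank: float = 0.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_min.shape != self.od.shape:
            raise ValueError("time and OD vectors differ in length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class FitnessComponents:
    strain: str
    environment: str
    run: int
    lag_h: float
    doubling_h: float
    efficiency: float
    is_grower: bool = True

    @property
    def ln_lag(self) -> float:
        return math.log(self.lag_h) if self.lag_h > 0 else float("nan")

    @property
    def ln_doubling(self) -> float:
        return math.log(self.doubling_h) if self.doubling_h > 0 else float("nan")

    @property
    def ln_efficiency(self) -> float:
        return math.log(self.efficiency) if self.efficiency > 0 else float("nan")


@dataclass
class LSCScore:
    strain: str
    trait: str
    value: float
    n_runs: int
    n_wt: int


def extract_fitness(
    curve: GrowthCurve,
    median_window: int = 3,
    slope_window: int = 9,
    min_slope: float = 1e-3,
) -> FitnessComponents:
    """Extract lag, doubling time and efficiency from one curve.

    OD − blank is smoothed with a running median (window 3 points) and
    the maximum specific growth rate taken as the steepest slope of a
    sliding 9-point least-squares line on ln(OD); defaults suit 20-min
    sampling.
    Curves whose maximum slope does not exceed ``min_slope`` per hour
    are flagged non-growers (NaN components).
    """
    if curve.time_min.size < max(10, slope_window):
        raise ValueError("too few timepoints for extraction")
    t_h = curve.time_min / 60.0
    if t_h[-1] - t_h[0] < 8.0:
        raise ValueError("curve shorter than 8 h")
    od = np.maximum(median_filter(curve.od - curve.blank, size=median_window,
                                  mode="nearest"), OD_FLOOR)
    ln_od = np.log(od)

    # steepest sliding-window slope; windows are scored by the lower
    # confidence bound (slope − 2·SE) so that noisy low-OD windows,
    # where ln(OD) fluctuations are largest, cannot win on noise alone
    w = slope_window
    best_score = -np.inf
    slope = intercept = 0.0
    for i in range(ln_od.size - w + 1):
        tt, yy = t_h[i : i + w], ln_od[i : i + w]
        b, a = np.polyfit(tt, yy, 1)
        resid = yy - (a + b * tt)
        sxx = float(np.sum((tt - tt.mean()) ** 2))
        se = math.sqrt(max(float(np.sum(resid**2)), 0.0) / (w - 2) / sxx)
        score = b - 2.0 * se
        if score > best_score:
            best_score, slope, intercept = score, b, a
    if slope <= min_slope:
        return FitnessComponents(
            curve.strain, curve.environment, curve.run,
            lag_h=float("nan"), doubling_h=float("nan"),
            efficiency=float("nan"), is_grower=False,
        )
    baseline = float(ln_od[0])
    lag_h = max((baseline - intercept) / slope, 0.0)
    doubling_h = math.log(2) / slope
    efficiency = float(np.max(od) - od[0])
    return FitnessComponents(
        curve.strain, curve.environment, curve.run,
        lag_h=lag_h, doubling_h=doubling_h, efficiency=efficiency,
    )


def lsc_score(
    x_logs: Sequence[float],
    wt_logs: Sequence[Sequence[float]],
    strain: str = "",
    trait: str = "",
) -> LSCScore:
    """LSC for one strain × trait from per-run log measurements.

    ``x_logs[r]`` is the strain's (single) log measurement in run r;
    ``wt_logs[r]`` the reference replicate log measurements of that run.
    """
    if len(x_logs) < 1 or len(x_logs) != len(wt_logs):
        raise ValueError("need the same positive number of runs for strain and reference")
    total = 0.0
    n_wt = 0
    for xr, wtr in zip(x_logs, wt_logs):
        wtr = np.asarray(wtr, dtype=float)
        if wtr.size < 1:
            raise ValueError("each run needs at least one reference measurement")
        if not np.isfinite(xr) or not np.all(np.isfinite(wtr)):
            raise ValueError("non-finite log measurement")
        total += (wtr.mean() - xr) ** 2
        n_wt = max(n_wt, wtr.size)
    return LSCScore(strain=strain, trait=trait, value=total,
                    n_runs=len(x_logs), n_wt=n_wt)


def lsc_table(
    components: pd.DataFrame,
    reference: str,
    invert: tuple[str, ...] = ("efficiency",),
) -> pd.DataFrame:
    """LSC per strain × trait from a long component table.

    ``components`` columns: strain, environment, run, component, value
    (raw, positive). A trait is a component × environment combination.
    Components in ``invert`` are reciprocal-transformed before the log
    so all components share the larger-is-worse direction.
    """
    required = {"strain", "environment", "run", "component", "value"}
    if not required.issubset(components.columns):
        raise ValueError(f"components table needs columns {sorted(required)}")
    df = components.copy()
    if (df["value"] <= 0).any():
        raise ValueError("non-positive component value")
    df["logval"] = np.where(
        df["component"].isin(invert), -np.log(df["value"]), np.log(df["value"])
    )
    rows = []
    for (env, comp), sub in df.groupby(["environment", "component"]):
        trait = f"{comp}:{env}"
        ref = sub[sub["strain"] == reference]
        if ref.empty:
            raise ValueError(f"reference {reference!r} missing for trait {trait}")
        ref_means = ref.groupby("run")["logval"].mean()
        ref_sizes = ref.groupby("run")["logval"].size()
        for strain, ssub in sub[sub["strain"] != reference].groupby("strain"):
            per_run = ssub.groupby("run")["logval"].mean()
            runs = [r for r in per_run.index if r in ref_means.index]
            if not runs:
                continue
            val = sum((ref_means[r] - per_run[r]) ** 2 for r in runs)
            rows.append(
                {
                    "strain": strain,
                    "trait": trait,
                    "lsc": val,
                    "n_runs": len(runs),
                    "n_wt": int(ref_sizes[runs].max()),
                }
            )
    return pd.DataFrame(rows)
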