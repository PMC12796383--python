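"""Logistic growth-curve modelling of wing-disc volume time courses.

The third larval instar (L3) of *Drosophila* spans roughly 72-118 hours
after egg laying (h AEL), during which the wing imaginal disc grows towards
a final size.  Volume over developmental time is described by a three
parameter logistic,

    V(t) = Asym / (1 + exp((tmid - t) / scal)),

where ``Asym`` is the asymptotic maximum volume (the carrying capacity),
``tmid`` the time at which V = Asym/2 (the inflection point) and ``scal``
a time-scale controlling steepness.  The relative growth rate is the time
derivative of V normalised to the instantaneous volume,

    rate(t) = (dV/dt) / V(t) = (1/scal) * (1 - V(t)/Asym),

which for a logistic declines monotonically from ~1/scal early in L3
towards zero as the disc approaches its final size.  Uncertainty on the
rate curve is estimated by stratified case bootstrap: individual disc
measurements are resampled with replacement within each timepoint, the
curve refit, and the per-time SD across refits reported as a ribbon.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "VolumeSeries",
    "LogisticFit",
    "GrowthRateSeries",
    "FitConvergenceError",
    "logistic_volume",
    "normalize_volumes",
    "fit_logistic",
    "relative_growth_rate",
    "bootstrap_growth_rate",
    "default_time_grid",
]

#: CSV column names for volume tables.
TIME_COL, VOLUME_COL, REPLICATE_COL = "time_h", "volume", "replicate"


class FitConvergenceError(RuntimeError):
    """Raised when the nonlinear least-squares refinement fails."""


@dataclass(frozen=True)
class VolumeSeries:
    """Replicate-resolved volume-vs-time observations for one condition.

    Parameters
    ----------
    data
        DataFrame with columns ``time_h`` (h AEL), ``volume`` (> 0) and
        ``replicate`` (identifier within timepoint).
    dimensionless
        True once volumes have been normalised to the mean initial volume.
    truth
        Optional planted ground-truth record carried by synthetic data.
    """

    data: pd.DataFrame
    dimensionless: bool = False
    truth: dict | None = None

    def __post_init__(self) -> None:
        missing = {TIME_COL, VOLUME_COL, REPLICATE_COL} - set(self.data.columns)
        if missing:
            raise ValueError(f"volume table missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("empty volume table")
        if not (self.data[VOLUME_COL] > 0).all():
            raise ValueError("all volumes must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.data[TIME_COL].to_numpy(dtype=float)

    @property
    def volumes(self) -> np.ndarray:
        return self.data[VOLUME_COL].to_numpy(dtype=float)

    @property
    def n_timepoints(self) -> int:
        return self.data[TIME_COL].nunique()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "VolumeSeries":
        return cls(pd.read_csv(path), **kwargs)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class LogisticFit:
    """Fitted logistic parameters with residual diagnostics."""

    asym: float
    tmid: float
    scal: float
    residual_sse: float
    converged: bool
    n_obs: int

    def __post_init__(self) -> None:
        if self.asym <= 0 or self.scal <= 0:
            raise ValueError("fitted Asym and scal must be positive")
        if self.residual_sse < 0:
            raise ValueError("negative SSE")

    def predict(self, t) -> np.ndarray:
        return logistic_volume(np.asarray(t, dtype=float), self.asym, self.tmid, self.scal)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GrowthRateSeries:
    """Relative growth rate (per hour) on a time grid, optionally with a
    bootstrap-SD ribbon."""

    times: np.ndarray
    rate: np.ndarray
    boot_sd: np.ndarray | None = None
    n_boot: int = 0
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_h": self.times, "rate_per_h": self.rate})
        if self.boot_sd is not None:
            out["boot_sd"] = self.boot_sd
        return out


def logistic_volume(t, asym: float, tmid: float, scal: float):
    """Three-parameter logistic volume model."""
    t = np.asarray(t, dtype=float)
    return asym / (1.0 + np.exp((tmid - t) / scal))


def normalize_volumes(series: VolumeSeries) -> VolumeSeries:
    """Express volumes as dimensionless ratios to the mean initial volume.

    Every volume is divided by the mean volume observed at the earliest
    timepoint, so the normalised series has mean 1 at its start.  Applying
    the operation twice is a no-op.
    """
    t0 = series.data[TIME_COL].min()
    initial = series.data.loc[series.data[TIME_COL] == t0, VOLUME_COL]
    if len(initial) == 0:
        raise ValueError("no observations at the earliest timepoint")
    divisor = float(initial.mean())
    data = series.data.copy()
    data[VOLUME_COL] = data[VOLUME_COL] / divisor
    return dataclasses.replace(series, data=data, dimensionless=True)


def _self_start(t: np.ndarray, v: np.ndarray, asym_factor: float) -> tuple[float, float, float]:
    """Initial values in the spirit of a self-starting logistic: pick a
    provisional asymptote above the data, linearise via the logit and
    regress on time."""
    asym0 = asym_factor * v.max()
    p = np.clip(v / asym0, 1e-6, 1 - 1e-6)
    y = np.log(p / (1 - p))  # y = (t - tmid)/scal
    slope, intercept = np.polyfit(t, y, 1)
    if slope <= 0:  # non-increasing data; keep a weakly informative start
        slope = 1.0 / max(np.ptp(t), 1.0)
        intercept = -slope * np.median(t)
    return asym0, -intercept / slope, 1.0 / slope


def fit_logistic(series: VolumeSeries, asym_factor: float = 1.05) -> LogisticFit:
    """Least-squares fit of the logistic volume model.

    Starting values are generated from the data (no manual initialisation):
    Asym0 = ``asym_factor`` x max observed volume, then tmid0 and scal0 from
    a linear regression of logit(V/Asym0) on t, followed by nonlinear
    refinement of the residual sum of squares.

    Raises
    ------
    ValueError
        Fewer than 4 distinct timepoints, or degenerate (constant) volumes.
    FitConvergenceError
        The optimiser failed to converge.
    """
    if series.n_timepoints < 4:
        raise ValueError("logistic fit requires >= 4 distinct timepoints")
    t, v = series.times, series.volumes
    if np.ptp(v) == 0:
        raise ValueError("degenerate data: all volumes identical")

    p0 = _self_start(t, v, asym_factor)

    def resid(p):
        return logistic_volume(t, *p) - v

    def jac(p):
        asym, tmid, scal = p
        z = np.exp((tmid - t) / scal)
        denom = (1.0 + z) ** 2
        d_asym = 1.0 / (1.0 + z)
        d_tmid = -asym * z / (scal * denom)
        d_scal = asym * z * (tmid - t) / (scal**2 * denom)
        return np.column_stack([d_asym, d_tmid, d_scal])

    sol = least_squares(resid, p0, jac=jac, method="lm", xtol=1e-12, ftol=1e-12)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise FitConvergenceError(f"logistic fit did not converge: {sol.message}")
    asym, tmid, scal = (float(x) for x in sol.x)
    if scal < 0:  # (Asym,tmid,scal) -> same curve under no symmetry; negative scal = decay
        raise FitConvergenceError("fit converged to a decreasing logistic (scal < 0)")
    sse = float(np.sum(sol.fun**2))
    return LogisticFit(asym=asym, tmid=tmid, scal=scal, residual_sse=sse,
                       converged=True, n_obs=len(v))


def relative_growth_rate(fit: LogisticFit, times) -> GrowthRateSeries:
    """Relative growth rate (dV/dt)/V on a time grid, in closed form.

    For the logistic the derivative divided by the instantaneous volume is
    exactly ``(1/scal) * (1 - V(t)/Asym)``; no numeric differentiation is
    involved.  The rate is strictly positive and strictly decreasing in t.
    """
    t = np.asarray(times, dtype=float)
    # 1 - V/Asym = 1/(1 + exp((t - tmid)/scal)), numerically stable form
    rate = (1.0 / fit.scal) / (1.0 + np.exp((t - fit.tmid) / fit.scal))
    return GrowthRateSeries(times=t, rate=rate)


def default_time_grid(series: VolumeSeries, step: float = 0.5) -> np.ndarray:
    """Evaluation grid covering the observed time range at ``step`` h."""
    t = series.times
    return np.arange(t.min(), t.max() + step / 2, step)


def bootstrap_growth_rate(
    series: VolumeSeries,
    times,
    n_boot: int = 500,
    seed: int | None = None,
    max_failure_fraction: float = 0.2,
) -> GrowthRateSeries:
    """Bootstrap-SD ribbon for the relative growth-rate curve.

    Disc measurements are resampled with replacement *within* each
    timepoint (stratified case resampling, preserving the unequal per-time
    design), the logistic refit on each resample and the rate curve
    evaluated on the grid.  ``boot_sd`` is the per-time SD across
    successful refits; the failed-refit count is surfaced on the result.
    """
    fit = fit_logistic(series)  # must succeed on the original data
    t_grid = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)

    groups = [idx.to_numpy() for _, idx in series.data.groupby(TIME_COL).groups.items()]
    curves = np.empty((n_boot, t_grid.size))
    n_failed = 0
    for b in range(n_boot):
        take = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        resampled = dataclasses.replace(series, data=series.data.loc[take].reset_index(drop=True))
        try:
            bfit = fit_logistic(resampled)
        except (FitConvergenceError, ValueError):
            n_failed += 1
            curves[b] = np.nan
            continue
        curves[b] = relative_growth_rate(bfit, t_grid).rate
    if n_failed > max_failure_fraction * n_boot:
        raise FitConvergenceError(
            f"{n_failed}/{n_boot} bootstrap refits failed; data too degenerate for a ribbon"
        )
    if n_failed:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap refits failed and were dropped")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(curves, axis=0, ddof=1)
    return GrowthRateSeries(
        times=t_grid,
        rate=relative_growth_rate(fit, t_grid).rate,
        boot_sd=sd,
        n_boot=n_boot - n_failed,
        n_failed=n_failed,
    )
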