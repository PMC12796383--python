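"""Two-regime calibration of a hypoxia-reporter dose-response curve.

A transcriptional HIF-1alpha reporter responds to decreasing environmental
oxygen below some threshold and saturates near normoxia.  Its calibration
curve (normalised mean nuclear intensity I versus % environmental O2) is
modelled piecewise:

    I = m*O2 + k       within the responsive range (default 5.0-18.0% O2)
    I = c              within the plateau range   (default 18.0-20.9% O2)

with m < 0 for a functioning sensor.  Two derived quantities summarise the
sensor: the *sensitivity breakpoint* (c - k)/m, the mildest hypoxia the
sensor detects, where the two regimes intersect; and the *dynamic range*
(m*5.0 + k)/c, the fold-increase in intensity from the breakpoint down to
5% O2.  Intensities are normalised to the normoxia (20.9% O2) group mean
before fitting, which makes both derived quantities invariant to the raw
intensity scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PiecewiseCalibration",
    "NORMOXIA_O2",
    "normalize_to_normoxia",
    "fit_piecewise",
    "sensitivity",
    "dynamic_range",
    "bootstrap_breakpoint",
]

NORMOXIA_O2 = 20.9
O2_COL, INTENSITY_COL, REPLICATE_COL, BATCH_COL = "o2_percent", "intensity", "replicate", "batch"


class NonResponsiveSensorError(ValueError):
    """Fitted slope is non-negative: the sensor shows no hypoxia response."""


@dataclass(frozen=True)
class PiecewiseCalibration:
    """Fitted two-regime sensor model with derived characteristics.

    ``breakpoint_o2`` and ``dynamic_range_fold`` are None when the fit is
    flagged non-responsive (m >= 0).
    """

    m: float  # responsive-line slope, intensity per %O2
    k: float  # responsive-line intercept
    c: float  # plateau constant
    responsive_range: tuple[float, float]
    plateau_range: tuple[float, float]
    responsive: bool
    breakpoint_o2: float | None = None
    dynamic_range_fold: float | None = None

    def predict(self, o2) -> np.ndarray:
        """Piecewise model evaluated at O2 levels (line below breakpoint)."""
        o2 = np.asarray(o2, dtype=float)
        bp = self.breakpoint_o2 if self.breakpoint_o2 is not None else self.responsive_range[1]
        return np.where(o2 < bp, self.m * o2 + self.k, self.c)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def normalize_to_normoxia(
    table: pd.DataFrame,
    normoxia_level: float = NORMOXIA_O2,
    by_batch: bool = False,
) -> pd.DataFrame:
    """Normalise intensities to the normoxia-group mean.

    Every intensity is divided by the mean intensity of the normoxia
    (default 20.9% O2) group, so the normalised normoxia mean is 1.  With
    ``by_batch=True`` each batch is normalised to its own normoxia
    controls.
    """
    def _scale(df: pd.DataFrame) -> pd.DataFrame:
        ref = df.loc[df[O2_COL] == normoxia_level, INTENSITY_COL]
        if len(ref) == 0:
            raise ValueError(f"no normoxia ({normoxia_level}% O2) group to normalise to")
        mean = float(ref.mean())
        if mean <= 0:
            raise ValueError("normoxia group mean must be positive")
        out = df.copy()
        out[INTENSITY_COL] = out[INTENSITY_COL] / mean
        return out

    if by_batch:
        if BATCH_COL not in table.columns:
            raise ValueError("by_batch=True requires a 'batch' column")
        return (table.groupby(BATCH_COL, group_keys=False, sort=False)[table.columns.tolist()]
                .apply(_scale).reset_index(drop=True))
    return _scale(table)


def fit_piecewise(
    table: pd.DataFrame,
    responsive_range: tuple[float, float] = (5.0, 18.0),
    plateau_range: tuple[float, float] = (18.0, NORMOXIA_O2),
    per_level_mean: bool = True,
    include_boundary_in_both: bool = False,
) -> PiecewiseCalibration:
    """Fit the responsive line and the plateau constant.

    (m, k) come from ordinary least squares over the responsive-range
    points and c is the plain mean over plateau-range points (a zero-slope
    regression).  By default each O2 level contributes its per-level mean
    intensity to the regression ("average intensities"); set
    ``per_level_mean=False`` to weight by replicate.  The boundary level
    shared by the two stated ranges (18.0%) belongs to the plateau, where
    the sensor no longer responds; ``include_boundary_in_both=True``
    assigns it to both regimes instead.

    A fit with m >= 0 is returned flagged non-responsive, with breakpoint
    and dynamic range withheld.
    """
    o2 = table[O2_COL].to_numpy(dtype=float)
    inten = table[INTENSITY_COL].to_numpy(dtype=float)
    lo_r, hi_r = responsive_range
    lo_p, hi_p = plateau_range

    if per_level_mean:
        levels = np.unique(o2)
        means = np.array([inten[o2 == lv].mean() for lv in levels])
        o2, inten = levels, means

    if include_boundary_in_both:
        in_resp = (o2 >= lo_r) & (o2 <= hi_r)
    else:
        in_resp = (o2 >= lo_r) & (o2 < hi_r)
    in_plat = (o2 >= lo_p) & (o2 <= hi_p)

    if np.unique(o2[in_resp]).size < 2:
        raise ValueError("need >= 2 distinct O2 levels in the responsive range")
    if not in_plat.any():
        raise ValueError("need >= 1 O2 level in the plateau range")

    m, k = (float(x) for x in np.polyfit(o2[in_resp], inten[in_resp], 1))
    c = float(inten[in_plat].mean())

    fit = PiecewiseCalibration(m=m, k=k, c=c, responsive_range=(lo_r, hi_r),
                               plateau_range=(lo_p, hi_p), responsive=m < 0)
    if not fit.responsive:
        return fit
    return dataclasses.replace(fit, breakpoint_o2=(c - k) / m,
                               dynamic_range_fold=(m * lo_r + k) / c)


def sensitivity(fit: PiecewiseCalibration) -> float:
    """Sensitivity breakpoint: the O2 level where line and plateau meet.

    Returns (c - k)/m, the mildest hypoxia the sensor responds to; the
    responsive line evaluated there equals c by construction.
    """
    if not fit.responsive or fit.m >= 0:
        raise NonResponsiveSensorError("sensitivity undefined for m >= 0")
    return (fit.c - fit.k) / fit.m


def dynamic_range(fit: PiecewiseCalibration, floor_o2: float = 5.0) -> float:
    """Fold-increase in intensity from the breakpoint down to ``floor_o2``.

    Computed as (m*floor_o2 + k)/c; exceeds 1 for any responsive sensor
    with the floor below the breakpoint.
    """
    if not fit.responsive or fit.m >= 0:
        raise NonResponsiveSensorError("dynamic range undefined for m >= 0")
    bp = sensitivity(fit)
    if floor_o2 >= bp:
        raise ValueError(f"floor_o2={floor_o2} must lie below the breakpoint {bp:.2f}% O2")
    return (fit.m * floor_o2 + fit.k) / fit.c


def bootstrap_breakpoint(
    table: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    **fit_kwargs,
) -> tuple[float, tuple[float, float]]:
    """Percentile bootstrap CI on the breakpoint (resampling replicates
    within O2 level).  An extension beyond the basic calibration — the
    point estimate itself carries no CI otherwise."""
    rng = np.random.default_rng(seed)
    groups = [idx.to_numpy() for _, idx in table.groupby(O2_COL).groups.items()]
    bps = []
    for _ in range(n_boot):
        take = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        fit = fit_piecewise(table.loc[take], **fit_kwargs)
        if fit.responsive:
            bps.append(fit.breakpoint_o2)
    bps = np.asarray(bps)
    if bps.size == 0:
        raise NonResponsiveSensorError("all bootstrap fits non-responsive")
    return float(np.median(bps)), (float(np.percentile(bps, 2.5)),
                                   float(np.percentile(bps, 97.5)))
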