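"""ROI-based fluorescence and count quantification.

Implements the study's measurement rules on single-plane images with
user-supplied compartment masks (the anterior/posterior boundary is drawn
from a lineage marker, not inferred here):

* mean fluorescence intensity over the above-threshold pixels of an ROI
  (fixed or Otsu threshold);
* posterior/anterior (P/A) compartment intensity ratios, the perturbed
  compartment normalised to its internal control;
* fluorescence-positive area as a percentage of compartment area;
* per-nucleus red/green ratios for ratiometric timer reporters;
* trichome density from four inter-vein ROI counts (a cell-density proxy);
* pupariation T50, the time at which half a larval cohort has pupariated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "RoiQuantification",
    "CompartmentRatio",
    "T50Result",
    "roi_mean_intensity",
    "pa_ratio",
    "area_fraction",
    "red_green_ratio",
    "trichome_density",
    "t50_pupariation",
]


@dataclass(frozen=True)
class RoiQuantification:
    """Intensity/area summary of one ROI.

    ``mean_intensity`` is NaN (and ``has_signal`` False) when no pixel in
    the ROI clears the threshold.
    """

    n_pixels: int
    n_signal_pixels: int
    mean_intensity: float
    area_fraction_pct: float
    threshold: float

    @property
    def has_signal(self) -> bool:
        return self.n_signal_pixels > 0


@dataclass(frozen=True)
class CompartmentRatio:
    """Dimensionless P/A intensity ratio with its compartment means."""

    value: float
    a_mean: float
    p_mean: float


@dataclass(frozen=True)
class T50Result:
    """Cohort pupariation-timing summary; ``censored`` when the cohort
    never reaches 50% pupariated within the observation window."""

    t50_h: float
    censored: bool


def _resolve_threshold(image: np.ndarray, roi: np.ndarray, threshold) -> float:
    """Fixed numeric threshold, or Otsu on the ROI histogram."""
    if threshold == "otsu":
        values = image[roi]
        if np.ptp(values) == 0:
            # constant ROI: any sub-value threshold keeps every pixel
            return float(values.flat[0]) - 1.0
        return float(threshold_otsu(values))
    return float(threshold)


def _check_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return mask


def roi_mean_intensity(image, roi_mask, threshold="otsu") -> RoiQuantification:
    """Average fluorescence intensity over an ROI's signal pixels.

    A binary signal mask is formed from ROI pixels strictly above the
    threshold (``threshold='otsu'`` computes it from the ROI histogram, or
    pass a fixed value); the mean is taken over signal pixels only, per
    the single-confocal-plane convention.
    """
    image = np.asarray(image, dtype=float)
    roi = _check_mask(image, roi_mask)
    thr = _resolve_threshold(image, roi, threshold)
    signal = roi & (image > thr)
    n_sig = int(signal.sum())
    mean = float(image[signal].mean()) if n_sig else math.nan
    return RoiQuantification(
        n_pixels=int(roi.sum()),
        n_signal_pixels=n_sig,
        mean_intensity=mean,
        area_fraction_pct=100.0 * n_sig / int(roi.sum()),
        threshold=thr,
    )


def pa_ratio(quant_a: RoiQuantification, quant_p: RoiQuantification) -> CompartmentRatio:
    """Posterior/anterior mean-intensity ratio (P normalised to A)."""
    if not quant_a.has_signal or not quant_p.has_signal:
        raise ValueError("both compartments need defined (signal-bearing) means")
    if quant_a.mean_intensity <= 0:
        raise ValueError("anterior mean must be positive")
    return CompartmentRatio(value=quant_p.mean_intensity / quant_a.mean_intensity,
                            a_mean=quant_a.mean_intensity, p_mean=quant_p.mean_intensity)


def area_fraction(image, compartment_mask, threshold="otsu") -> float:
    """Percentage of a compartment's area occupied by fluorescence-positive
    pixels (above-threshold within the compartment)."""
    return roi_mean_intensity(image, compartment_mask, threshold).area_fraction_pct


def red_green_ratio(red, green, nuclei_mask) -> tuple[pd.DataFrame, float]:
    """Per-nucleus red/green intensity ratio and its cohort mean.

    Nuclei are the connected components of the thresholded nuclear mask
    (touching nuclei are not split).  Each nucleus contributes mean(red) /
    mean(green) over its pixels; nuclei with zero green mean are flagged
    ``excluded`` and left out of the summary.  Ratios are invariant to a
    common rescaling of both channels.
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape:
        raise ValueError("red and green channels must have identical shapes")
    mask = _check_mask(red, nuclei_mask)
    labels, n_nuclei = ndimage.label(mask)
    idx = np.arange(1, n_nuclei + 1)
    red_means = ndimage.mean(red, labels=labels, index=idx)
    green_means = ndimage.mean(green, labels=labels, index=idx)
    excluded = green_means <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(excluded, np.nan, red_means / np.where(excluded, 1.0, green_means))
    table = pd.DataFrame({"nucleus": idx, "red_mean": red_means, "green_mean": green_means,
                          "ratio": ratios, "excluded": excluded}).set_index("nucleus")
    kept = table.loc[~table["excluded"], "ratio"]
    summary = float(kept.mean()) if len(kept) else math.nan
    return table, summary


def trichome_density(counts, roi_area: float, allow_nonstandard: bool = False) -> float:
    """Trichome (socket) density: mean per-ROI count over the ROI area.

    The standard protocol counts four equally sized inter-vein ROIs per
    wing; a different number of ROIs must be acknowledged explicitly with
    ``allow_nonstandard=True``.
    """
    counts = list(counts)
    if len(counts) != 4 and not allow_nonstandard:
        raise ValueError(
            f"expected 4 inter-vein ROI counts, got {len(counts)}; "
            "pass allow_nonstandard=True to deviate from the protocol"
        )
    if not counts:
        raise ValueError("no ROI counts provided")
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    return float(np.mean(counts)) / roi_area


def t50_pupariation(table: pd.DataFrame, cohort_size: int | None = None) -> T50Result:
    """Time at which 50% of the cohort has pupariated.

    ``table`` holds observation times (``time_h``) and cumulative
    pupariated counts (``n_pupariated``).  If an observation lands exactly
    on a cumulative fraction of 0.5 its time is returned; otherwise the
    crossing is linearly interpolated between the bracketing observations.
    A cohort that never reaches 50% is reported censored (t50 = NaN).
    """
    if cohort_size is None:
        cohort_size = table.attrs.get("cohort_size")
    if cohort_size is None:
        raise ValueError("cohort_size required (not found in table.attrs)")
    times = table["time_h"].to_numpy(dtype=float)
    counts = table["n_pupariated"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("observation times must be strictly increasing")
    if np.any(np.diff(counts) < 0) or np.any(counts > cohort_size):
        raise ValueError("cumulative counts must be non-decreasing and <= cohort size")
    frac = counts / cohort_size
    at = np.flatnonzero(np.isclose(frac, 0.5))
    if at.size:
        return T50Result(t50_h=float(times[at[0]]), censored=False)
    above = np.flatnonzero(frac > 0.5)
    if above.size == 0:
        return T50Result(t50_h=math.nan, censored=True)
    j = above[0]
    if j == 0:  # already past 50% at the first observation
        return T50Result(t50_h=float(times[0]), censored=False)
    f0, f1 = frac[j - 1], frac[j]
    t0, t1 = times[j - 1], times[j]
    return T50Result(t50_h=float(t0 + (0.5 - f0) / (f1 - f0) * (t1 - t0)), censored=False)
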