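"""Synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here with a
known truth record, so the whole pipeline is testable without downloads:
logistic volume trajectories, expression matrices with planted growth-rate
tracking / anti-tracking / null genes, two-regime oxygen-response tables,
two-compartment disc images and cumulative pupariation curves.

Noise model
-----------
All measurements (volumes, expression, intensities) are positive and
heteroscedastic, so noise is multiplicative log-normal throughout: a true
value ``x`` is observed as ``x * exp(eps)`` with ``eps ~ N(0, sigma)`` and
``sigma = sqrt(ln(1 + cv^2))``, which makes the sample coefficient of
variation equal to the requested ``noise_cv``.

Study-condition defaults
------------------------
* Expression design: 7 timepoints at 80, 88, 96, 104, 112, 116 and 118 h
  AEL with 3 biological replicates each except n = 2 at 80 h.
* Volume design: timepoints every 4 h from 72 h AEL plus a final 118 h
  point, n = 6 discs per timepoint except n = 5 at 84 h.
* Planted growth truth: logistic parameters chosen so that the relative
  growth rate of the (normalised) curve is 0.09 /h at 72 h and 0.02 /h at
  118 h, the deceleration observed over L3.
* Planted sensor truth: responsive line and plateau intersecting at
  17.09% O2 with a 4.0-fold intensity increase at 5% O2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .growth import VolumeSeries, logistic_volume
from .screen import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "DEFAULT_GROWTH_TRUTH",
    "DEFAULT_SENSOR_TRUTH",
    "DEFAULT_O2_LEVELS",
    "gen_volume_series",
    "gen_expression_timecourse",
    "gen_oxygen_response",
    "gen_disc_image",
    "gen_pupariation_counts",
    "noise_sigma",
    "write_gmt",
    "read_gmt",
    "write_truth",
]

# Planted logistic truth: rate(72 h) = 0.09 /h, rate(118 h) = 0.02 /h, V(72) = 1.
DEFAULT_GROWTH_TRUTH = {"asym": 21.642861603442917, "tmid": 104.08323490242148,
                        "scal": 10.59772654511899}
# Planted sensor truth: breakpoint (c-k)/m = 17.09% O2, (5m+k)/c = 4.0-fold.
DEFAULT_SENSOR_TRUTH = {"m": -0.24813895781637718, "k": 5.240694789081886, "c": 1.0}
# Calibration O2 levels spanning both regimes with >= 2 points each.
DEFAULT_O2_LEVELS = (5.0, 8.0, 11.0, 14.0, 18.0, 20.9)

_RNASEQ_TIMEPOINTS = (80.0, 88.0, 96.0, 104.0, 112.0, 116.0, 118.0)
_RNASEQ_REPLICATES = (2, 3, 3, 3, 3, 3, 3)
_VOLUME_TIMEPOINTS = tuple(float(t) for t in range(72, 117, 4)) + (118.0,)
_VOLUME_REPLICATES = tuple(5 if t == 84.0 else 6 for t in _VOLUME_TIMEPOINTS)


def noise_sigma(cv: float) -> float:
    """Log-scale SD giving a log-normal factor the requested CV."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class SimulationConfig:
    """Shared design of a simulated experiment.

    Defaults mirror the bulk RNA-seq time-course design (seven timepoints
    from 80 to 118 h AEL, triplicates except duplicates at 80 h); use
    :meth:`volume_design` for the disc-volume cohort design.
    """

    seed: int = 0
    noise_cv: float = 0.05
    timepoints: tuple[float, ...] = _RNASEQ_TIMEPOINTS
    replicates_per_timepoint: tuple[int, ...] = _RNASEQ_REPLICATES

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        if len(self.replicates_per_timepoint) != tp.size:
            raise ValueError("replicates_per_timepoint must align with timepoints")
        if any(r < 1 for r in self.replicates_per_timepoint):
            raise ValueError("each timepoint needs >= 1 replicate")

    @classmethod
    def volume_design(cls, seed: int = 0, noise_cv: float = 0.05) -> "SimulationConfig":
        """Disc-volume cohort: 4-h sampling over L3, n = 6 (n = 5 at 84 h)."""
        return cls(seed=seed, noise_cv=noise_cv,
                   timepoints=_VOLUME_TIMEPOINTS,
                   replicates_per_timepoint=_VOLUME_REPLICATES)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth attached to a generated dataset."""

    gene_class: dict[str, str] = field(default_factory=dict)
    logistic: dict[str, float] = field(default_factory=dict)
    sensor: dict[str, float] = field(default_factory=dict)
    compartment_means: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _noise_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, noise_sigma(cv), size=size))


# ---------------------------------------------------------------------------
# Volumes


def gen_volume_series(
    config: SimulationConfig,
    asym: float = DEFAULT_GROWTH_TRUTH["asym"],
    tmid: float = DEFAULT_GROWTH_TRUTH["tmid"],
    scal: float = DEFAULT_GROWTH_TRUTH["scal"],
) -> VolumeSeries:
    """Simulate a disc-volume cohort from the logistic growth model.

    For each timepoint ``t`` the configured number of replicate volumes is
    drawn as ``V(t) * exp(eps)`` with log-normal multiplicative noise.
    """
    if asym <= 0 or scal <= 0:
        raise ValueError("asym and scal must be positive")
    rng = config.rng()
    rows = []
    for t, n in zip(config.timepoints, config.replicates_per_timepoint):
        v_true = logistic_volume(t, asym, tmid, scal)
        vols = v_true * _noise_factor(rng, config.noise_cv, n)
        rows.extend((t, v, r + 1) for r, v in enumerate(vols))
    data = pd.DataFrame(rows, columns=["time_h", "volume", "replicate"])
    truth = PlantedTruth(logistic={"asym": asym, "tmid": tmid, "scal": scal})
    return VolumeSeries(data=data, truth=truth.to_dict())


# ---------------------------------------------------------------------------
# Expression


def gen_expression_timecourse(
    config: SimulationConfig,
    n_tracking: int = 100,
    n_anti: int = 100,
    n_null: int = 800,
    rate_profile=None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate a normalised expression matrix with planted gene classes.

    * ``tracking`` genes follow a positive affine transform of the growth
      rate profile (expression falls as the rate falls),
    * ``anti_tracking`` genes a negative affine transform (expression
      rises as the rate falls),
    * ``null`` genes vary independently of the rate.

    Values represent post-normalisation abundances (one column per
    replicate, named ``<timepoint>_rep<k>``); all values are positive.
    """
    if n_tracking < 0 or n_anti < 0 or n_null < 0 or n_tracking + n_anti + n_null < 1:
        raise ValueError("need at least one gene in total")
    tp = np.asarray(config.timepoints, dtype=float)
    if rate_profile is None:
        g = DEFAULT_GROWTH_TRUTH
        rate_profile = (1.0 / g["scal"]) / (1.0 + np.exp((tp - g["tmid"]) / g["scal"]))
    rate_profile = np.asarray(rate_profile, dtype=float)
    if rate_profile.size != tp.size:
        raise ValueError("rate_profile length must match the number of timepoints")

    rng = config.rng()
    rate_unit = (rate_profile - rate_profile.min()) / max(np.ptp(rate_profile), 1e-300)

    genes, classes, profiles = [], [], []

    def add(prefix: str, label: str, count: int, make_profile) -> None:
        for i in range(count):
            genes.append(f"{prefix}{i + 1:04d}")
            classes.append(label)
            profiles.append(make_profile())

    # affine transforms on a [0,1]-scaled rate keep every value positive
    def _tracking():
        return rng.uniform(20, 200) * rate_unit + rng.uniform(1, 10)

    def _anti():
        slope = rng.uniform(20, 200)
        return -slope * rate_unit + slope + rng.uniform(1, 10)

    add("trk", "tracking", n_tracking, _tracking)
    add("ant", "anti_tracking", n_anti, _anti)
    # null genes: per-timepoint levels independent of the rate
    add("nul", "null", n_null,
        lambda: rng.lognormal(np.log(rng.uniform(5, 50)), 0.3, size=tp.size))

    profiles = np.asarray(profiles)
    cols, values = [], []
    for j, (t, n) in enumerate(zip(config.timepoints, config.replicates_per_timepoint)):
        for r in range(n):
            cols.append(f"{t:g}_rep{r + 1}")
            values.append(profiles[:, j] * _noise_factor(rng, config.noise_cv, len(genes)))
    df = pd.DataFrame(np.column_stack(values), index=pd.Index(genes, name="gene"), columns=cols)
    truth = PlantedTruth(gene_class=dict(zip(genes, classes)),
                         extra={"rate_profile": rate_profile.tolist()})
    return ExpressionMatrix(df), truth


# ---------------------------------------------------------------------------
# Oxygen response


def gen_oxygen_response(
    config: SimulationConfig,
    m: float = DEFAULT_SENSOR_TRUTH["m"],
    k: float = DEFAULT_SENSOR_TRUTH["k"],
    c: float = DEFAULT_SENSOR_TRUTH["c"],
    levels=DEFAULT_O2_LEVELS,
    reps: int = 6,
) -> pd.DataFrame:
    """Simulate a normalised sensor-response table with two planted regimes.

    Below the breakpoint ``(c - k)/m`` the mean intensity follows the
    responsive line ``m*O2 + k``; at or above it, the plateau constant
    ``c``.  Multiplicative noise per ``config.noise_cv``.  Returns a table
    with columns ``o2_percent``, ``intensity``, ``replicate`` and a
    ``truth`` entry in ``DataFrame.attrs``.
    """
    if m >= 0:
        raise ValueError("m must be negative: intensity rises as O2 falls")
    levels = [float(x) for x in levels]
    breakpoint_o2 = (c - k) / m
    if not (min(levels) < breakpoint_o2 < max(levels)):
        raise ValueError(f"breakpoint {breakpoint_o2:.3f}% O2 outside the spanned range")
    rng = config.rng()
    rows = []
    for o2 in levels:
        mean = m * o2 + k if o2 < breakpoint_o2 else c
        vals = mean * _noise_factor(rng, config.noise_cv, reps)
        rows.extend((o2, v, r + 1) for r, v in enumerate(vals))
    df = pd.DataFrame(rows, columns=["o2_percent", "intensity", "replicate"])
    df.attrs["truth"] = PlantedTruth(sensor={"m": m, "k": k, "c": c,
                                             "breakpoint_o2": breakpoint_o2}).to_dict()
    return df


# ---------------------------------------------------------------------------
# Disc images


@dataclass(frozen=True)
class SyntheticDiscImage:
    """A simulated single-plane disc image with compartment masks."""

    image: np.ndarray
    pouch_mask: np.ndarray
    a_mask: np.ndarray  # anterior compartment
    p_mask: np.ndarray  # posterior compartment
    truth: dict


def gen_disc_image(
    config: SimulationConfig,
    shape: tuple[int, int] = (128, 128),
    a_mean: float = 100.0,
    p_mean: float = 100.0,
    background: float = 0.0,
    positive_fraction_p: float = 1.0,
) -> SyntheticDiscImage:
    """Simulate a two-compartment wing-pouch image.

    The pouch is an elliptical mask split into anterior (left) and
    posterior (right) halves by a vertical boundary.  All anterior pouch
    pixels carry signal at ``a_mean``; a stated fraction of posterior
    pixels (deterministically the first ones in raster order, so the
    planted area fraction is exact) carry signal at ``p_mean``, the rest
    background.  Multiplicative noise applies to signal pixels only.
    """
    if len(shape) != 2 or min(shape) < 8:
        raise ValueError("shape must be 2-D with both sides >= 8 pixels")
    if not (a_mean > background >= 0 and p_mean > background):
        raise ValueError("compartment means must exceed background >= 0")
    if not 0.0 <= positive_fraction_p <= 1.0:
        raise ValueError("positive_fraction_p must lie in [0, 1]")

    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    pouch = ((yy - cy) / (0.4 * h)) ** 2 + ((xx - cx) / (0.4 * w)) ** 2 <= 1.0
    a_mask = pouch & (xx < cx)
    p_mask = pouch & (xx >= cx)

    image = np.full(shape, float(background))
    rng = config.rng()
    image[a_mask] = a_mean * _noise_factor(rng, config.noise_cv, int(a_mask.sum()))

    p_idx = np.flatnonzero(p_mask.ravel())
    n_pos = int(round(positive_fraction_p * p_idx.size))
    pos_idx = p_idx[:n_pos]  # raster order: deterministic, exact fraction
    flat = image.ravel()
    flat[pos_idx] = p_mean * _noise_factor(rng, config.noise_cv, n_pos)

    truth = PlantedTruth(
        compartment_means={"A": a_mean, "P": p_mean},
        extra={"background": background,
               "positive_fraction_p": n_pos / p_idx.size if p_idx.size else 0.0,
               "n_positive_p": n_pos},
    )
    return SyntheticDiscImage(image=image, pouch_mask=pouch, a_mask=a_mask,
                              p_mask=p_mask, truth=truth.to_dict())


# ---------------------------------------------------------------------------
# Pupariation


def gen_pupariation_counts(
    config: SimulationConfig,
    n_larvae: int = 210,
    t50_true: float = 120.0,
    spread: float = 4.0,
    observation_times=None,
) -> pd.DataFrame:
    """Simulate a cumulative pupariation-count table.

    Individual pupariation times are drawn from a logistic distribution
    centred at ``t50_true`` with scale ``spread`` (h); counts are recorded
    at each observation time (default: every 4 h from ``t50_true - 24`` to
    ``t50_true + 24``, emulating 4-hourly scoring).
    """
    if n_larvae <= 0:
        raise ValueError("n_larvae must be positive")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    if observation_times is None:
        observation_times = np.arange(t50_true - 24, t50_true + 24 + 1e-9, 4.0)
    obs = np.asarray(observation_times, dtype=float)
    if obs.size < 1 or not np.all(np.diff(obs) > 0):
        raise ValueError("observation_times must be increasing")
    rng = config.rng()
    u = rng.uniform(size=n_larvae)
    # logistic inverse CDF; spread=0 degenerates to a point mass at t50
    times = t50_true + spread * np.log(u / (1.0 - u))
    counts = (times[None, :] <= obs[:, None]).sum(axis=1)
    df = pd.DataFrame({"time_h": obs, "n_pupariated": counts})
    df.attrs["cohort_size"] = n_larvae
    df.attrs["truth"] = PlantedTruth(extra={"t50_true": t50_true, "spread": spread}).to_dict()
    return df


# ---------------------------------------------------------------------------
# File output helpers


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    """Write gene sets in standard GMT (name, description, members)."""
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_truth(truth: dict, path) -> None:
    """Sidecar JSON truth record for a generated dataset."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
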