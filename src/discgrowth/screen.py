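"""Growth-rate correlation screen over expression time courses.

Given a gene x (timepoint, replicate) matrix of normalised expression and
the relative growth-rate profile evaluated at the same timepoints, the
screen computes one Pearson correlation coefficient r per gene between its
time-course profile (replicate means) and the declining growth rate, and
classifies genes with r above / below a strict +-0.8 threshold as
positively / negatively rate-correlated.  Selected genes feed a
hypergeometric gene-set over-representation test; for heatmap display,
profiles are max-normalised per gene and clustered by Ward's minimum
variance criterion on Euclidean distances (the "ward.D2" flavour: the
input distances enter the Lance-Williams recurrence unsquared).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ScreenResult",
    "ClusteredHeatmap",
    "summarise_replicates",
    "correlate_with_growth_rate",
    "classify_genes",
    "max_normalize",
    "cluster_genes",
    "enrich",
]

_COL_RE = re.compile(r"^(?P<tp>[0-9.]+)_rep(?P<rep>\d+)$")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x replicate normalised expression, columns ``<timepoint>_rep<k>``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        for col in self.data.columns:
            if not _COL_RE.match(str(col)):
                raise ValueError(f"column {col!r} not of the form '<timepoint>_rep<k>'")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def timepoints(self) -> np.ndarray:
        tps = sorted({float(_COL_RE.match(str(c))["tp"]) for c in self.data.columns})
        return np.asarray(tps)

    def replicate_columns(self, timepoint: float) -> list[str]:
        return [c for c in self.data.columns
                if float(_COL_RE.match(str(c))["tp"]) == float(timepoint)]

    @classmethod
    def from_table(cls, path, sep: str | None = None) -> "ExpressionMatrix":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep, index_col=0))

    def to_table(self, path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep)


@dataclass(frozen=True)
class ScreenResult:
    """Per-gene correlation with the growth rate and three-way class.

    ``table`` columns: ``r`` (NaN where undefined) and, after
    :func:`classify_genes`, ``class`` in {positive, negative, unselected,
    undefined}.
    """

    table: pd.DataFrame
    threshold: float | None = None

    @property
    def r(self) -> pd.Series:
        return self.table["r"]

    def genes_in_class(self, label: str) -> list[str]:
        return self.table.index[self.table["class"] == label].tolist()


@dataclass(frozen=True)
class ClusteredHeatmap:
    """Max-normalised matrix with a Ward.D2 gene dendrogram."""

    matrix: pd.DataFrame  # rows reordered to dendrogram leaf order
    gene_order: np.ndarray  # permutation of input row indices
    merges: list[tuple[int, int, float]]  # (cluster_i, cluster_j, height)
    linkage_matrix: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return np.asarray([h for _, _, h in self.merges])


def summarise_replicates(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Collapse replicates to a gene x timepoint mean matrix."""
    out = {}
    for tp in matrix.timepoints:
        cols = matrix.replicate_columns(tp)
        if not cols:
            raise ValueError(f"no replicate columns for timepoint {tp}")
        out[tp] = matrix.data[cols].mean(axis=1)
    return pd.DataFrame(out, index=matrix.genes)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise product-moment correlation of matrix ``x`` against ``y``.

    Rows (or a ``y``) with zero variance yield NaN rather than raising.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))


def correlate_with_growth_rate(profiles: pd.DataFrame, rate_profile) -> ScreenResult:
    """Pearson r of each gene's time-course profile against the growth rate.

    ``profiles`` is the gene x timepoint mean matrix; ``rate_profile`` the
    relative growth rate evaluated at the same timepoints.  Zero-variance
    (constant) profiles are flagged undefined (r = NaN), never propagated.
    """
    rate = np.asarray(rate_profile, dtype=float)
    if profiles.shape[1] != rate.size:
        raise ValueError(f"profile width {profiles.shape[1]} != rate length {rate.size}")
    if rate.size < 3:
        raise ValueError("need >= 3 timepoints for a meaningful correlation")
    r = _pearson_rows(profiles.to_numpy(dtype=float), rate)
    return ScreenResult(table=pd.DataFrame({"r": r}, index=profiles.index))


def classify_genes(result: ScreenResult, threshold: float = 0.8) -> ScreenResult:
    """Three-way classification at a strict |r| threshold.

    Strict inequalities: a gene at exactly r = threshold is unselected.
    Undefined (constant-profile) genes form their own class.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    r = result.table["r"]
    cls = pd.Series("unselected", index=r.index, dtype=object)
    cls[r > threshold] = "positive"
    cls[r < -threshold] = "negative"
    cls[r.isna()] = "undefined"
    table = result.table.assign(**{"class": cls})
    return ScreenResult(table=table, threshold=threshold)


def max_normalize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene's profile to its own maximum (row max = 1).

    Idempotent.  All-zero rows have no meaningful scale and are rejected,
    naming the offending genes.
    """
    row_max = profiles.max(axis=1)
    bad = profiles.index[row_max <= 0].tolist()
    if bad:
        raise ValueError(f"cannot max-normalise all-zero gene rows: {bad[:10]}")
    return profiles.div(row_max, axis=0)


def cluster_genes(normalised: pd.DataFrame) -> ClusteredHeatmap:
    """Hierarchical clustering of max-normalised profiles (ward.D2).

    Euclidean distances between gene profiles are agglomerated under
    Ward's minimum-variance criterion with the unsquared distances
    entering the Lance-Williams recurrence — the behaviour of R's
    ``hclust(method="ward.D2")``.  Returns the reordered matrix, the leaf
    permutation and the merge tree.
    """
    if normalised.shape[0] < 2:
        raise ValueError("clustering needs >= 2 genes")
    values = normalised.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in the profile matrix")
    z = linkage(values, method="ward")
    order = leaves_list(z)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return ClusteredHeatmap(matrix=normalised.iloc[order], gene_order=order,
                            merges=merges, linkage_matrix=z)


def enrich(
    selected: list[str],
    universe: list[str],
    gene_sets: dict[str, list[str]],
    ease: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-set over-representation by the hypergeometric tail.

    For each set, p = P(X >= overlap) drawing ``len(selected)`` genes
    without replacement from a universe containing the set.  ``ease=True``
    applies the conservative EASE variant (overlap decremented by one
    before the tail; overlap <= 1 then gives p = 1).  Gene sets are
    intersected with the universe before testing.  Benjamini-Hochberg q
    values are reported across tested sets; ``retained`` flags raw
    p < ``alpha``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected)
    stray = sel - uni
    if stray:
        raise ValueError(f"selected genes not in universe: {sorted(stray)[:5]}")
    rows = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        overlap = len(in_uni & sel)
        k_eff = max(overlap - 1, 0) if ease else overlap
        if ease and overlap <= 1:
            p = 1.0
        else:
            p = float(hypergeom.sf(k_eff - 1, len(uni), len(in_uni), len(sel)))
        rows.append((name, overlap, len(in_uni), len(sel), len(uni), min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                      "list_size", "universe_size", "p"]).set_index("gene_set")
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["retained"] = out["p"] < alpha
    return out
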