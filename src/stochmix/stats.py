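"""Statistical coarse-graining of per-cell barcode data.

Intrinsic (cell-to-cell) uptake noise is suppressed by averaging over
subpopulations: cells are ordered by a tag intensity and grouped into bins
of equal length ``r`` (1D), partitioned on a 2D mesh of two tag intensities
with an occupancy floor of 30 cells per bin, or clustered hierarchically on
their full barcode vector.  By the Law of Large Numbers the standard
deviation of bin means of an independent channel falls as 1/sqrt(r).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .tables import channel_columns

__all__ = [
    "BinScheme",
    "BinnedData",
    "CorrelationMatrix",
    "DistributionSummary",
    "ordered_binning",
    "moving_average",
    "mesh_binning_2d",
    "cluster_bins",
    "correlation_matrix",
    "summarize",
    "combination_count",
]

#: Occupancy floor for 2D mesh bins (cells per bin).
DEFAULT_MIN_COUNT = 30


@dataclass(frozen=True)
class BinScheme:
    """Binning layout for :func:`mesh_binning_2d`.

    ``n_x`` × ``n_y`` equal-width mesh on linear or log10 tag intensity;
    bins holding fewer than ``min_count`` cells are merged into the nearest
    occupied bin (by centroid) or dropped, per ``sparse``.
    """

    n_x: int = 8
    n_y: int = 8
    min_count: int = DEFAULT_MIN_COUNT
    scale: Literal["linear", "log"] = "log"
    sparse: Literal["merge", "drop"] = "merge"

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("mesh must have at least one bin per axis")
        if self.min_count < 1:
            raise ValueError("min_count must be at least 1")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.sparse not in ("merge", "drop"):
            raise ValueError(f"unknown sparse policy {self.sparse!r}")


@dataclass
class BinnedData:
    """Per-bin counts, channel means and SDs.

    ``table`` columns: ``bin_id``, ``count``, ``<channel>_mean``,
    ``<channel>_sd`` for every channel, plus mesh coordinates
    (``center_x``, ``center_y``, ``ix``, ``iy``) for 2D binning.
    ``dropped`` counts cells excluded by partial-tail or sparse-bin policy.
    """

    table: pd.DataFrame
    total_n: int
    dropped: int = 0
    channels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy()

    def mean(self, channel: str) -> np.ndarray:
        return self.table[f"{channel}_mean"].to_numpy()

    def sd(self, channel: str) -> np.ndarray:
        return self.table[f"{channel}_sd"].to_numpy()


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations between channels.

    ``undefined`` flags entries involving a zero-variance channel; those
    values are NaN but explicitly marked rather than silently propagated.
    """

    rho: pd.DataFrame
    n: int
    scale: str
    n_excluded: int = 0
    undefined: pd.DataFrame | None = None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.rho.loc[pair[0], pair[1]])


@dataclass
class DistributionSummary:
    """Mean, SD, CV and histogram of one channel."""

    channel: str
    n: int
    mean: float
    sd: float
    cv: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    scale: str = "linear"
    n_excluded: int = 0


def _bin_stats(
    cells: pd.DataFrame, labels: np.ndarray, channels: Sequence[str]
) -> pd.DataFrame:
    """Count + per-channel mean and SD per group label (ddof=0)."""
    g = cells.groupby(pd.Series(labels, index=cells.index, name="bin_id"), sort=True)
    out = g.size().rename("count").to_frame()
    for ch in channels:
        out[f"{ch}_mean"] = g[ch].mean()
        out[f"{ch}_sd"] = g[ch].std(ddof=0)
    return out.reset_index()


def ordered_binning(cells: pd.DataFrame, order_by: str, r: int) -> BinnedData:
    """Equal-length binning along one tag's intensity order.

    Cells are stably sorted by ``order_by``; consecutive runs of ``r`` cells
    form the bins; a final partial run of fewer than ``r`` cells is dropped
    so every bin averages exactly ``r`` cells.  Means and SDs of *all*
    channels are returned per bin; output length is ``n // r``.
    """
    n = len(cells)
    if r < 1:
        raise ValueError("bin length r must be at least 1")
    if n < r:
        raise ValueError(f"need at least r={r} cells, got {n}")
    channels = channel_columns(cells)
    ordered = cells.sort_values(order_by, kind="stable").reset_index(drop=True)
    n_bins = n // r
    kept = ordered.iloc[: n_bins * r]
    labels = np.repeat(np.arange(n_bins), r)
    table = _bin_stats(kept, labels, channels)
    return BinnedData(
        table=table,
        total_n=n_bins * r,
        dropped=n - n_bins * r,
        channels=list(channels),
        meta={"mode": "ordered", "order_by": order_by, "r": r},
    )


def moving_average(cells: pd.DataFrame, order_by: str, window: int) -> pd.DataFrame:
    """Centered moving average along the tag-ordered sequence.

    Dimensionality is preserved (one smoothed row per cell); the ends use
    shrunken windows.  ``window`` must be odd and no larger than ``n``.
    """
    n = len(cells)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > n:
        raise ValueError("window larger than the number of cells")
    channels = channel_columns(cells)
    ordered = cells.sort_values(order_by, kind="stable").reset_index(drop=True)
    out = ordered.copy()
    out[channels] = (
        ordered[channels].rolling(window, center=True, min_periods=1).mean()
    )
    return out


def _merge_sparse(
    table: pd.DataFrame, min_count: int, channels: Sequence[str]
) -> pd.DataFrame:
    """Merge under-occupied bins into their nearest occupied neighbour.

    Repeatedly takes the smallest bin below the floor and pools it with the
    occupied bin whose centroid (in the binning scale) is closest; centroids
    and channel means update count-weighted.  Terminates because each step
    removes one bin.
    """
    work = table.copy().reset_index(drop=True)
    while len(work) > 1 and work["count"].min() < min_count:
        i = int(work["count"].idxmin())
        dx = work["center_x"] - work.at[i, "center_x"]
        dy = work["center_y"] - work.at[i, "center_y"]
        d2 = (dx**2 + dy**2).to_numpy()
        d2[i] = np.inf
        j = int(np.argmin(d2))
        wi, wj = work.at[i, "count"], work.at[j, "count"]
        w = wi + wj
        for col in ["center_x", "center_y"] + [f"{ch}_mean" for ch in channels]:
            work.at[j, col] = (wi * work.at[i, col] + wj * work.at[j, col]) / w
        for ch in channels:  # pooled SD from the two groups' moments
            mi, mj = work.at[i, f"{ch}_mean"], work.at[j, f"{ch}_mean"]
            vi, vj = work.at[i, f"{ch}_sd"] ** 2, work.at[j, f"{ch}_sd"] ** 2
            mu = (wi * mi + wj * mj) / w
            work.at[j, f"{ch}_sd"] = np.sqrt(
                (wi * (vi + (mi - mu) ** 2) + wj * (vj + (mj - mu) ** 2)) / w
            )
        # keep the mesh index of the bigger constituent
        if wi > wj:
            work.at[j, "ix"] = work.at[i, "ix"]
            work.at[j, "iy"] = work.at[i, "iy"]
        work.at[j, "count"] = w
        work = work.drop(index=i).reset_index(drop=True)
    return work


def mesh_binning_2d(
    cells: pd.DataFrame,
    tag_x: str,
    tag_y: str,
    scheme: BinScheme | None = None,
) -> BinnedData:
    """Partition cells on a 2D mesh of two tag intensities.

    The mesh is equal-width on the chosen scale (log10 by default; on the
    log scale, non-positive tag values are excluded and counted).  Bins
    below the occupancy floor are merged into the nearest occupied bin or
    dropped, per the scheme; every reported bin meets the floor.
    ``center_x``/``center_y`` are count-weighted member centroids in the
    binning scale.
    """
    scheme = scheme or BinScheme()
    channels = channel_columns(cells)
    x = cells[tag_x].to_numpy(dtype=float)
    y = cells[tag_y].to_numpy(dtype=float)
    if scheme.scale == "log":
        ok = (x > 0) & (y > 0)
        excluded = int((~ok).sum())
        cells = cells.loc[ok].reset_index(drop=True)
        x, y = np.log10(x[ok]), np.log10(y[ok])
    else:
        excluded = 0
    n = len(cells)
    if n < scheme.min_count:
        raise ValueError(
            f"need at least min_count={scheme.min_count} cells, got {n}"
        )
    ex = np.linspace(x.min(), x.max(), scheme.n_x + 1)
    ey = np.linspace(y.min(), y.max(), scheme.n_y + 1)
    ix = np.clip(np.searchsorted(ex, x, side="right") - 1, 0, scheme.n_x - 1)
    iy = np.clip(np.searchsorted(ey, y, side="right") - 1, 0, scheme.n_y - 1)
    flat = ix * scheme.n_y + iy
    table = _bin_stats(cells, flat, channels)
    table["ix"] = table["bin_id"] // scheme.n_y
    table["iy"] = table["bin_id"] % scheme.n_y
    # member centroids in binning scale
    g = pd.DataFrame({"flat": flat, "x": x, "y": y}).groupby("flat", sort=True)
    table["center_x"] = g["x"].mean().to_numpy()
    table["center_y"] = g["y"].mean().to_numpy()

    dropped = excluded
    if scheme.sparse == "merge":
        table = _merge_sparse(table, scheme.min_count, channels)
    else:
        sparse = table["count"] < scheme.min_count
        dropped += int(table.loc[sparse, "count"].sum())
        table = table.loc[~sparse].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("no bin meets the occupancy floor")
    table["bin_id"] = np.arange(len(table))
    return BinnedData(
        table=table,
        total_n=int(table["count"].sum()),
        dropped=dropped,
        channels=list(channels),
        meta={
            "mode": "mesh2d",
            "tag_x": tag_x,
            "tag_y": tag_y,
            "scheme": scheme,
            "edges_x": ex,
            "edges_y": ey,
        },
    )


def cluster_bins(
    cells: pd.DataFrame,
    barcode_channels: Sequence[str],
    k: int | None = None,
    distance_threshold: float | None = None,
) -> tuple[np.ndarray, BinnedData]:
    """Hierarchical barcode clustering with per-cluster channel means.

    Agglomerative clustering (average linkage, Euclidean) on standardized
    log10 intensities of the barcode channels; cut at ``k`` clusters or at a
    cophenetic ``distance_threshold``.  Returns the per-cell labels and the
    per-cluster renormalized data (means of every channel).
    """
    if not barcode_channels:
        raise ValueError("need at least one barcode channel")
    if (k is None) == (distance_threshold is None):
        raise ValueError("give exactly one of k or distance_threshold")
    n = len(cells)
    if k is not None and (k < 1 or k > n):
        raise ValueError("k must be between 1 and the number of cells")
    X = np.log10(cells[list(barcode_channels)].to_numpy(dtype=float) + 1e-12)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        model = AgglomerativeClustering(
            n_clusters=k,
            distance_threshold=distance_threshold,
            linkage="average",
            metric="euclidean",
        )
        labels = model.fit_predict(X)
    channels = channel_columns(cells)
    table = _bin_stats(cells, labels, channels)
    binned = BinnedData(
        table=table,
        total_n=n,
        channels=list(channels),
        meta={"mode": "cluster", "barcode_channels": list(barcode_channels)},
    )
    return labels, binned


def correlation_matrix(
    cells: pd.DataFrame,
    channels: Sequence[str],
    scale: Literal["linear", "log"] = "linear",
) -> CorrelationMatrix:
    """Pairwise Pearson correlations between channel intensities.

    On the log scale, rows with any non-positive value in the requested
    channels are excluded (count reported).  Zero-variance channels yield
    flagged-undefined entries instead of NaN-poisoning the whole matrix.
    """
    if len(channels) < 2:
        raise ValueError("need at least two channels")
    X = cells[list(channels)].to_numpy(dtype=float)
    excluded = 0
    if scale == "log":
        ok = (X > 0).all(axis=1)
        excluded = int((~ok).sum())
        X = np.log10(X[ok])
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    sd = X.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(X, rowvar=False)
    undef = np.zeros_like(rho, dtype=bool)
    for i in np.flatnonzero(degenerate):
        undef[i, :] = undef[:, i] = True
        rho[i, :] = rho[:, i] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(undef, False)
    idx = list(channels)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        n=X.shape[0],
        scale=scale,
        n_excluded=excluded,
        undefined=pd.DataFrame(undef, index=idx, columns=idx),
    )


def summarize(
    cells: pd.DataFrame,
    channel: str,
    n_hist_bins: int = 50,
    scale: Literal["linear", "log"] = "linear",
) -> DistributionSummary:
    """Mean, SD, CV and a histogram of one channel's distribution."""
    v = cells[channel].to_numpy(dtype=float)
    excluded = 0
    if scale == "log":
        ok = v > 0
        excluded = int((~ok).sum())
        v = v[ok]
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    cv = sd / mean if mean > 0 else float("nan")
    hv = np.log10(v) if scale == "log" else v
    counts, edges = np.histogram(hv, bins=n_hist_bins)
    return DistributionSummary(
        channel=channel,
        n=int(v.size),
        mean=mean,
        sd=sd,
        cv=cv,
        hist_edges=edges,
        hist_counts=counts,
        scale=scale,
        n_excluded=excluded,
    )


def combination_count(n_drugs: int, n_levels: int) -> int:
    """Number of distinct regimens of ``n_drugs`` drugs at ``n_levels``
    concentrations each (zero counts as a level): ``n_levels ** n_drugs``."""
    if n_drugs < 1 or n_levels < 1:
        raise ValueError("n_drugs and n_levels must be at least 1")
    return n_levels**n_drugs
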