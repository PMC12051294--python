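"""SCOPE — Scatter Clusters Of Paired Ends.

Detects long-range intra-chromosomal Hi-C interaction loci (fold-back
regions, inversion-breakpoint dots) from mapped contact pairs:

1. filter pairs by minimum inter-mate distance and minimum MAPQ;
2. 2D binned kernel density estimate of (mate1, mate2) positions on an
   m × m grid over the chromosome with Gaussian smoothing bandwidths;
3. call peak bins above a high quantile of the grid (e.g. the 99.8th
   percentile);
4. hierarchically cluster the peak-bin genomic coordinates and cut the
   tree into k clusters;
5. summarize each cluster (median/min/max per axis, summit bin) and keep
   clusters whose median x- and y-coordinates are separated by at least a
   minimum distance (e.g. 5 Mb);
6. optionally subtract calls also present in a genomic-DNA control or
   overlapping known SV breakpoints.

The standard parameter set (MAPQ >= 10, inter-mate >= 1 Mb, 1024 x 1024
grid, 250 kb bandwidths, 99.8th percentile, k = 12, >= 5 Mb separation)
reflects the published fold-back-region analysis; a narrow-anchor variant
(>= 5 Mb inter-mate, 2048 x 2048 grid, 50 kb bandwidth, 99.99th
percentile, k = 4) gives tighter anchor estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.base import BaseEstimator

from .errors import ScopeggsError
from .tracks import GenomicInterval, IntervalSet

__all__ = [
    "HicPair",
    "PairSet",
    "ScopeParams",
    "KdeGrid",
    "PeakCluster",
    "InteractionCall",
    "filter_pairs",
    "binned_kde_2d",
    "naive_kde_2d",
    "call_peak_bins",
    "cluster_peak_bins",
    "summarize_clusters",
    "filter_by_separation",
    "calls_from_clusters",
    "subtract_background",
    "run_scope",
    "ScopeDetector",
]


@dataclass(frozen=True)
class HicPair:
    """One contact pair: point positions of the two mates (0-based) and the
    pair MAPQ (minimum of the two mates' MAPQs)."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    mapq_pair: int


@dataclass
class PairSet:
    """A table of contact pairs with its chromosome-size map.

    ``df`` columns: chrom_a, pos_a, chrom_b, pos_b, mapq (positions are
    0-based points; intra-chromosomal pairs canonicalized pos_a <= pos_b).
    """

    df: pd.DataFrame
    chrom_sizes: dict[str, int]
    source: str = ""

    def __post_init__(self):
        required = {"chrom_a", "pos_a", "chrom_b", "pos_b", "mapq"}
        missing = required - set(self.df.columns)
        if missing:
            raise ScopeggsError(f"PairSet missing columns: {sorted(missing)}")
        for col in ("chrom_a", "chrom_b"):
            unknown = set(self.df[col].unique()) - set(self.chrom_sizes)
            if unknown:
                raise ScopeggsError(f"pairs on undeclared chromosomes: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.df)

    def points(self, chrom: str) -> np.ndarray:
        """(N, 2) array of intra-chromosomal (pos_a, pos_b) on ``chrom``."""
        sel = (self.df["chrom_a"] == chrom) & (self.df["chrom_b"] == chrom)
        return self.df.loc[sel, ["pos_a", "pos_b"]].to_numpy(dtype=float)


@dataclass
class ScopeParams:
    """Tunable SCOPE parameters (defaults = published broad run)."""

    min_mapq: int = 10
    min_intermate_distance: int = 1_000_000
    grid_size: int = 1024
    bandwidth_x: float = 250_000.0
    bandwidth_y: float = 250_000.0
    peak_quantile: float = 0.998
    k_clusters: int = 12
    min_separation: int = 5_000_000
    kernel_truncation: float = 4.0
    linkage: str = "complete"
    pad: float | None = None  # background-subtraction pad; default 1 bin width

    def __post_init__(self):
        if not (0.0 < self.peak_quantile < 1.0):
            raise ScopeggsError("peak_quantile must be in (0, 1)")
        if self.grid_size < 2:
            raise ScopeggsError("grid_size must be >= 2")
        if self.bandwidth_x <= 0 or self.bandwidth_y <= 0:
            raise ScopeggsError("bandwidths must be > 0")


@dataclass
class KdeGrid:
    """Smoothed 2D contact density on an m × m grid over [start, end).

    z[i, j] is the density at bin centers (x_i, y_j); the first axis is the
    mate-1 (x) coordinate.  Σ z · bin_width² = 1.
    """

    chrom: str
    start: float
    end: float
    m: int
    z: np.ndarray

    @property
    def bin_width(self) -> float:
        return (self.end - self.start) / self.m

    def bin_center(self, idx) -> np.ndarray:
        return self.start + (np.asarray(idx, dtype=float) + 0.5) * self.bin_width


def _kernel_weights(coords, start, h, m, sigma, truncation):
    """Per-point Gaussian weights at nearby bin centers.

    Returns (idx, w): (N, 2r+1) integer bin indices (clipped) and weights,
    zeroed outside the grid or beyond the truncation radius.
    """
    if truncation is None or not np.isfinite(truncation):
        r = m
    else:
        r = max(1, min(m, int(np.ceil(truncation * sigma / h))))
    offs = np.arange(-r, r + 1)
    c0 = start + 0.5 * h
    i0 = np.clip(np.round((coords - c0) / h).astype(np.int64), 0, m - 1)
    idx = i0[:, None] + offs[None, :]
    t = (c0 + idx * h - coords[:, None]) / sigma
    w = np.exp(-0.5 * t * t)
    valid = (idx >= 0) & (idx < m)
    if truncation is not None and np.isfinite(truncation):
        valid &= np.abs(t) <= truncation
    w[~valid] = 0.0
    return np.clip(idx, 0, m - 1), w


def binned_kde_2d(
    points,
    extent: tuple[float, float],
    m: int,
    bandwidths: tuple[float, float],
    truncation: float | None = 4.0,
    chrom: str = "",
    chunk: int = 4096,
) -> KdeGrid:
    """2D Gaussian kernel density estimate accumulated on an m × m grid.

    Each point contributes a separable Gaussian (SDs ``bandwidths``)
    evaluated at its exact offsets from nearby bin centers, truncated at
    ``truncation`` SDs (None disables truncation).  The grid is normalized
    so that Σ z · bin_width² = 1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ScopeggsError("binned_kde_2d: no points")
    if pts.shape[1] != 2:
        raise ScopeggsError("points must be (N, 2)")
    bx, by = bandwidths
    if bx <= 0 or by <= 0:
        raise ScopeggsError("zero bandwidth")
    start, end = float(extent[0]), float(extent[1])
    if end <= start:
        raise ScopeggsError("empty extent")
    if np.any(pts < start) or np.any(pts > end):
        raise ScopeggsError("points outside extent")
    h = (end - start) / m
    z = np.zeros(m * m)
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        ix, wx = _kernel_weights(p[:, 0], start, h, m, bx, truncation)
        iy, wy = _kernel_weights(p[:, 1], start, h, m, by, truncation)
        w2 = wx[:, :, None] * wy[:, None, :]
        flat = ix[:, :, None] * m + iy[:, None, :]
        z += np.bincount(flat.ravel(), weights=w2.ravel(), minlength=m * m)
    total = z.sum() * h * h
    if total <= 0:
        raise ScopeggsError("KDE accumulated zero density (truncation too tight?)")
    return KdeGrid(chrom=chrom, start=start, end=end, m=m, z=(z / total).reshape(m, m))


def naive_kde_2d(
    points,
    extent: tuple[float, float],
    m: int,
    bandwidths: tuple[float, float],
    chrom: str = "",
) -> KdeGrid:
    """Direct O(N·m²) Gaussian-sum oracle: every kernel evaluated at every
    bin center, no truncation; same normalization as :func:`binned_kde_2d`.
    Intended for small inputs (tests and cross-checks)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ScopeggsError("naive_kde_2d: no points")
    bx, by = bandwidths
    if bx <= 0 or by <= 0:
        raise ScopeggsError("zero bandwidth")
    start, end = float(extent[0]), float(extent[1])
    h = (end - start) / m
    centers = start + (np.arange(m) + 0.5) * h
    dx = (centers[None, :] - pts[:, 0][:, None]) / bx  # (N, m)
    dy = (centers[None, :] - pts[:, 1][:, None]) / by
    gx = np.exp(-0.5 * dx * dx)
    gy = np.exp(-0.5 * dy * dy)
    z = gx.T @ gy  # (m, m): sum over points of outer products
    z /= 2.0 * np.pi * bx * by * len(pts)
    total = z.sum() * h * h
    if total <= 0:
        raise ScopeggsError("zero density")
    return KdeGrid(chrom=chrom, start=start, end=end, m=m, z=z / total)


def filter_pairs(pairs: PairSet, params: ScopeParams, intra_only: bool = True) -> PairSet:
    """Keep pairs with mapq >= min_mapq and inter-mate distance >=
    min_intermate_distance (intra-chromosomal only by default); mates are
    canonicalized so pos_a <= pos_b."""
    df = pairs.df.copy()
    lo = np.minimum(df["pos_a"], df["pos_b"])
    hi = np.maximum(df["pos_a"], df["pos_b"])
    intra = df["chrom_a"] == df["chrom_b"]
    df.loc[intra, "pos_a"] = lo[intra]
    df.loc[intra, "pos_b"] = hi[intra]
    keep = df["mapq"] >= params.min_mapq
    if intra_only:
        keep &= intra
    dist = np.abs(df["pos_b"] - df["pos_a"])
    keep &= ~intra | (dist >= params.min_intermate_distance)
    out = df.loc[keep].reset_index(drop=True)
    return PairSet(df=out, chrom_sizes=dict(pairs.chrom_sizes), source=pairs.source)


def call_peak_bins(grid: KdeGrid, peak_quantile: float) -> list[tuple[int, int, float]]:
    """Bins strictly above the empirical (linear-interpolation) quantile of
    all m² grid values, in row-major order."""
    thr = float(np.quantile(grid.z, peak_quantile))
    ii, jj = np.nonzero(grid.z > thr)
    return [(int(i), int(j), float(grid.z[i, j])) for i, j in zip(ii, jj)]


def cluster_peak_bins(
    peaks: list[tuple[int, int, float]],
    k: int,
    grid: KdeGrid,
    linkage: str = "complete",
) -> list[list[tuple[int, int, float]]]:
    """Agglomerative clustering of peak-bin genomic coordinates (bin
    centers, Euclidean distance), tree cut into exactly k clusters.
    Peak order is normalized to row-major first, making ties deterministic.
    """
    if k < 1:
        raise ScopeggsError("k must be >= 1")
    if len(peaks) < k:
        raise ScopeggsError(f"fewer peaks ({len(peaks)}) than clusters requested ({k})")
    peaks = sorted(peaks, key=lambda p: (p[0], p[1]))
    if k == 1:
        return [list(peaks)]
    coords = np.array(
        [[grid.bin_center(i), grid.bin_center(j)] for i, j, _ in peaks], dtype=float
    )
    link = sch.linkage(coords, method=linkage)
    assign = sch.fcluster(link, t=k, criterion="maxclust")
    clusters: dict[int, list] = {}
    for lab, pk in zip(assign, peaks):
        clusters.setdefault(int(lab), []).append(pk)
    return [clusters[lab] for lab in sorted(clusters, key=lambda l: clusters[l][0])]


@dataclass
class PeakCluster:
    """Summary of one peak-bin cluster in genomic coordinates (bin centers)."""

    members: list[tuple[int, int, float]]
    median_x: float
    median_y: float
    min_x: float
    max_x: float
    min_y: float
    max_y: float
    summit: tuple[float, float, float]  # (x, y, z)

    @property
    def separation(self) -> float:
        return abs(self.median_y - self.median_x)

    @property
    def n_bins(self) -> int:
        return len(self.members)


def summarize_clusters(
    clusters: list[list[tuple[int, int, float]]], grid: KdeGrid
) -> list[PeakCluster]:
    """Median/min/max bin-center coordinates per axis and the summit bin
    (maximal z; ties to the smaller row-major index) for each cluster.
    The median of an even-sized set is the midpoint of the central pair."""
    out = []
    for members in clusters:
        if not members:
            raise ScopeggsError("empty peak cluster")
        xs = grid.bin_center([i for i, _, _ in members])
        ys = grid.bin_center([j for _, j, _ in members])
        best = max(enumerate(members), key=lambda t: (t[1][2], -(t[1][0] * grid.m + t[1][1])))[1]
        out.append(
            PeakCluster(
                members=list(members),
                median_x=float(np.median(xs)),
                median_y=float(np.median(ys)),
                min_x=float(xs.min()),
                max_x=float(xs.max()),
                min_y=float(ys.min()),
                max_y=float(ys.max()),
                summit=(float(grid.bin_center(best[0])), float(grid.bin_center(best[1])), best[2]),
            )
        )
    return out


def filter_by_separation(clusters: list[PeakCluster], min_separation: float) -> list[PeakCluster]:
    """Keep clusters whose median x and median y are at least
    ``min_separation`` apart — i.e. genuine long-range loci pairs."""
    return [c for c in clusters if c.separation >= min_separation]


@dataclass
class InteractionCall:
    """A called long-range interaction: two anchor intervals (cluster
    min/max extents widened to bin edges), the summit bin, and a label."""

    anchor_1: GenomicInterval
    anchor_2: GenomicInterval
    summit: tuple[float, float, float]
    n_bins: int
    separation: float
    median_x: float = 0.0
    median_y: float = 0.0
    label: str = ""


def calls_from_clusters(
    clusters: list[PeakCluster], grid: KdeGrid, labels: list[str] | None = None
) -> list[InteractionCall]:
    """Turn summarized clusters into interaction calls; anchor_1 is the
    x-axis (upstream) locus."""
    half = grid.bin_width / 2.0
    L = grid.end
    calls = []
    for idx, c in enumerate(clusters):
        a1 = GenomicInterval(grid.chrom, max(0, int(c.min_x - half)), min(int(L), int(np.ceil(c.max_x + half))))
        a2 = GenomicInterval(grid.chrom, max(0, int(c.min_y - half)), min(int(L), int(np.ceil(c.max_y + half))))
        mx, my = c.median_x, c.median_y
        if a2.start < a1.start:
            a1, a2 = a2, a1
            mx, my = my, mx
        calls.append(
            InteractionCall(
                anchor_1=a1,
                anchor_2=a2,
                summit=c.summit,
                n_bins=c.n_bins,
                separation=c.separation,
                median_x=mx,
                median_y=my,
                label=labels[idx] if labels else "",
            )
        )
    return calls


def _intervals_overlap(a: GenomicInterval, b: GenomicInterval, pad: float) -> bool:
    return a.chrom == b.chrom and a.start < b.end + pad and b.start < a.end + pad


def subtract_background(
    calls: list[InteractionCall],
    control_calls: list[InteractionCall] | None = None,
    sv_breakpoints: IntervalSet | None = None,
    pad: float = 0.0,
) -> list[InteractionCall]:
    """Remove calls also present in the control (both anchors overlap a
    control call's anchors, in either order, each padded by ``pad``) or
    with either anchor overlapping an SV-breakpoint interval (padded)."""
    control_calls = control_calls or []
    sv = list(sv_breakpoints.intervals()) if sv_breakpoints is not None else []
    kept = []
    for call in calls:
        in_control = any(
            (
                _intervals_overlap(call.anchor_1, ctl.anchor_1, pad)
                and _intervals_overlap(call.anchor_2, ctl.anchor_2, pad)
            )
            or (
                _intervals_overlap(call.anchor_1, ctl.anchor_2, pad)
                and _intervals_overlap(call.anchor_2, ctl.anchor_1, pad)
            )
            for ctl in control_calls
        )
        hits_sv = any(
            _intervals_overlap(call.anchor_1, iv, pad) or _intervals_overlap(call.anchor_2, iv, pad)
            for iv in sv
        )
        if not (in_control or hits_sv):
            kept.append(call)
    return kept


def _scope_single_chrom(pairs: PairSet, chrom: str, params: ScopeParams):
    pts = pairs.points(chrom)
    if len(pts) == 0:
        return [], None
    extent = (0.0, float(pairs.chrom_sizes[chrom]))
    grid = binned_kde_2d(
        pts,
        extent,
        params.grid_size,
        (params.bandwidth_x, params.bandwidth_y),
        truncation=params.kernel_truncation,
        chrom=chrom,
    )
    peaks = call_peak_bins(grid, params.peak_quantile)
    if len(peaks) < params.k_clusters:
        return [], grid
    clusters = cluster_peak_bins(peaks, params.k_clusters, grid, linkage=params.linkage)
    summaries = summarize_clusters(clusters, grid)
    far = filter_by_separation(summaries, params.min_separation)
    return calls_from_clusters(far, grid), grid


def run_scope(
    pairs: PairSet,
    params: ScopeParams | None = None,
    control: PairSet | None = None,
    svs: IntervalSet | None = None,
    chrom: str | None = None,
    control_params: ScopeParams | None = None,
) -> tuple[list[InteractionCall], dict]:
    """Full SCOPE pipeline on one chromosome.

    Returns the interaction calls plus a machine-readable run log of all
    parameters and stage counts.  When ``control`` and/or ``svs`` are
    given, calls reproduced in the control or hitting SV breakpoints are
    subtracted (pad defaults to one grid bin width).  The control run uses
    ``control_params`` when given (genomic-DNA controls are typically
    called with their own thresholds), else the main parameters.
    """
    params = params or ScopeParams()
    filtered = filter_pairs(pairs, params)
    chroms = sorted(set(filtered.df["chrom_a"]))
    if chrom is None:
        if len(chroms) > 1:
            raise ScopeggsError(f"multiple chromosomes present ({chroms}); pass chrom=")
        chrom = chroms[0] if chroms else None
    log: dict = {
        "params": asdict(params),
        "n_pairs_in": len(pairs),
        "n_pairs_filtered": len(filtered),
        "chrom": chrom,
    }
    if chrom is None or len(filtered) == 0:
        log["warning"] = "no pairs passed the filters"
        return [], log
    calls, grid = _scope_single_chrom(filtered, chrom, params)
    log["n_calls_prefilter"] = len(calls)
    if grid is not None and (control is not None or svs is not None):
        pad = params.pad if params.pad is not None else grid.bin_width
        control_calls: list[InteractionCall] = []
        if control is not None:
            cp = control_params or params
            ctrl_filtered = filter_pairs(control, cp)
            control_calls, _ = _scope_single_chrom(ctrl_filtered, chrom, cp)
        log["n_control_calls"] = len(control_calls)
        calls = subtract_background(calls, control_calls, svs, pad=pad)
    log["n_calls"] = len(calls)
    if not calls:
        log.setdefault("warning", "no interaction calls")
    return calls, log


class ScopeDetector(BaseEstimator):
    """Scikit-learn-style front end to the SCOPE pipeline.

    Parameters mirror :class:`ScopeParams`.  ``fit`` takes a
    :class:`PairSet` (optionally a control PairSet and SV breakpoints) and
    exposes the calls and run log as fitted attributes.

    Attributes (after fit)
    ----------------------
    calls_ : list[InteractionCall]
    n_calls_ : int
    grid_ : KdeGrid
    runlog_ : dict
    """

    def __init__(
        self,
        min_mapq: int = 10,
        min_intermate_distance: int = 1_000_000,
        grid_size: int = 1024,
        bandwidth_x: float = 250_000.0,
        bandwidth_y: float = 250_000.0,
        peak_quantile: float = 0.998,
        k_clusters: int = 12,
        min_separation: int = 5_000_000,
        kernel_truncation: float = 4.0,
        linkage: str = "complete",
        pad: float | None = None,
        chrom: str | None = None,
    ):
        self.min_mapq = min_mapq
        self.min_intermate_distance = min_intermate_distance
        self.grid_size = grid_size
        self.bandwidth_x = bandwidth_x
        self.bandwidth_y = bandwidth_y
        self.peak_quantile = peak_quantile
        self.k_clusters = k_clusters
        self.min_separation = min_separation
        self.kernel_truncation = kernel_truncation
        self.linkage = linkage
        self.pad = pad
        self.chrom = chrom

    def _params(self) -> ScopeParams:
        return ScopeParams(
            min_mapq=self.min_mapq,
            min_intermate_distance=self.min_intermate_distance,
            grid_size=self.grid_size,
            bandwidth_x=self.bandwidth_x,
            bandwidth_y=self.bandwidth_y,
            peak_quantile=self.peak_quantile,
            k_clusters=self.k_clusters,
            min_separation=self.min_separation,
            kernel_truncation=self.kernel_truncation,
            linkage=self.linkage,
            pad=self.pad,
        )

    def fit(
        self,
        X: PairSet,
        y=None,
        control: PairSet | None = None,
        svs: IntervalSet | None = None,
        control_params: ScopeParams | None = None,
    ):
        params = self._params()
        filtered = filter_pairs(X, params)
        chrom = self.chrom
        if chrom is None:
            chroms = sorted(set(filtered.df["chrom_a"]))
            if len(chroms) != 1:
                raise ScopeggsError("ambiguous chromosome; set chrom=")
            chrom = chroms[0]
        calls, grid = _scope_single_chrom(filtered, chrom, params)
        self.runlog_ = {
            "params": asdict(params),
            "chrom": chrom,
            "n_pairs_in": len(X),
            "n_pairs_filtered": len(filtered),
            "n_calls_prefilter": len(calls),
        }
        if grid is not None and (control is not None or svs is not None):
            pad = params.pad if params.pad is not None else grid.bin_width
            control_calls: list[InteractionCall] = []
            if control is not None:
                cp = control_params or params
                ctrl_filtered = filter_pairs(control, cp)
                control_calls, _ = _scope_single_chrom(ctrl_filtered, chrom, cp)
            self.runlog_["n_control_calls"] = len(control_calls)
            calls = subtract_background(calls, control_calls, svs, pad=pad)
        self.runlog_["n_calls"] = len(calls)
        self.calls_ = calls
        self.grid_ = grid
        self.n_calls_ = len(calls)
        return self

    def fit_predict(self, X: PairSet, y=None, **kwargs) -> list[InteractionCall]:
        return self.fit(X, y, **kwargs).calls_
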