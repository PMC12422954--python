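"""Local genome-size-change rates between two genomes from synteny anchors.

High-confidence whole-genome alignment anchors define a monotone map from
genome A coordinates to genome B coordinates per chromosome pair.  The
derivative of that map is the local size-change rate: rate > 1 means the
region is expanded in genome B relative to A, rate < 1 the converse.
Anchors are filtered by joint quality/length percentiles, the map is fitted
by robust local linear regression with an isotonic projection, and rates
come from centered finite differences on a 1-Mb grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

QUALITY_PERCENTILE = 98.0
LENGTH_PERCENTILE = 95.0
DEFAULT_WINDOW = 1_000_000
DEFAULT_BANDWIDTH = 2_000_000
NEUTRAL_BAND = (0.95, 1.05)
MIN_ANCHORS_PER_CHROM = 20


@dataclass
class AnchorSet:
    """Percentile-filtered synteny anchors."""

    df: pd.DataFrame  # chrom_a, pos_a, chrom_b, pos_b, length, quality
    quality_cut: float
    length_cut: float


def filter_anchors(
    raw: pd.DataFrame,
    quality_percentile: float = QUALITY_PERCENTILE,
    length_percentile: float = LENGTH_PERCENTILE,
    quality_field: str = "quality",
) -> AnchorSet:
    """Retain anchors with quality > Q98 and length > Q95 (both strict).

    Percentiles are taken over the whole input.  Chromosomes with fewer than
    100 anchors trigger a warning (percentiles are then noisy) but the
    filter is still applied.
    """
    need = {"chrom_a", "pos_a", "chrom_b", "pos_b", "length", quality_field}
    if not need.issubset(raw.columns):
        raise ValueError(f"anchor table requires columns {sorted(need)}")
    small = [c for c, n in raw.groupby("chrom_a").size().items() if n < 100]
    if small:
        warnings.warn(
            f"fewer than 100 anchors on {small}; percentile cuts are noisy",
            stacklevel=2,
        )
    qcut = float(np.percentile(raw[quality_field], quality_percentile))
    lcut = float(np.percentile(raw["length"], length_percentile))
    kept = raw[(raw[quality_field] > qcut) & (raw["length"] > lcut)].copy()
    if kept.empty:
        warnings.warn("percentile filter removed every anchor", stacklevel=2)
    return AnchorSet(df=kept.reset_index(drop=True), quality_cut=qcut, length_cut=lcut)


@dataclass
class SizeRateTrack:
    """Fitted size map and local rates on a 1-Mb grid of genome A."""

    df: pd.DataFrame  # chrom_a, start, end, pos_b, rate
    window: int
    bandwidth: float


def _robust_wls(
    xs: np.ndarray, ys: np.ndarray, w0: np.ndarray, x0: float, bisquare_k: float = 4.685
) -> float:
    """Fitted value at x0 of a weighted local line with Tukey-bisquare IRLS.

    The redescending loss nulls anchors displaced by inversions or spurious
    alignments instead of letting them drag the fit.
    """
    w = w0.copy()
    b0 = float(np.average(ys, weights=w))
    for _ in range(4):
        xm = np.column_stack([np.ones_like(xs), xs - x0])
        wls = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(xm * wls[:, None], ys * wls, rcond=None)
        b0 = float(beta[0])
        resid = ys - xm @ beta
        scale = float(np.median(np.abs(resid[w0 > 0]))) / 0.6745
        if scale == 0:
            break
        u = resid / (bisquare_k * scale)
        rob = np.clip(1 - u**2, 0, None) ** 2
        if not np.any(w0 * rob > 0):
            break  # degenerate re-weighting; keep the last fit
        w = w0 * rob
    return b0


def _local_linear(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Robust tricube-weighted local linear fit evaluated on a grid.

    ``bandwidth`` is the kernel support radius; it bounds the resolution of
    the fitted map, so rate changes closer than one bandwidth to a grid
    point blur into it.  Where the kernel holds too few anchors to pin the
    local slope down — chromosome ends, alignment deserts — the radius is
    widened until the effective sample size is adequate.
    """
    out = np.empty_like(grid, dtype=float)
    min_pts, target_n_eff, max_widen = 5, 40.0, 8
    for gi, x0 in enumerate(grid):
        h = bandwidth
        for _ in range(max_widen):
            d = np.abs(x - x0) / h
            w0 = np.clip(1 - d**3, 0, None) ** 3
            sw = w0.sum()
            n_eff = sw**2 / np.sum(w0**2) if sw > 0 else 0.0
            if n_eff >= target_n_eff or n_eff >= 0.8 * len(x):
                break
            h *= 1.4
        use = w0 > 0
        if use.sum() < min_pts:
            nearest = np.argsort(np.abs(x - x0))[:min_pts]
            use = np.zeros_like(use)
            use[nearest] = True
            w0 = np.where(use, 1.0, 0.0)
        out[gi] = _robust_wls(x[use], y[use], w0[use], x0)
    return out


def fit_size_map(
    anchors: AnchorSet,
    window: int = DEFAULT_WINDOW,
    bandwidth: float = DEFAULT_BANDWIDTH,
    min_anchors: int = MIN_ANCHORS_PER_CHROM,
) -> SizeRateTrack:
    """Fit the monotone genome-A -> genome-B position map and its local rate.

    Per chromosome of genome A: robust local linear regression of pos_b on
    pos_a evaluated on half-window offsets of a ``window`` grid, projected
    to a non-decreasing map by isotonic regression; the rate in each window
    is the centered finite difference.  Chromosomes with fewer than
    ``min_anchors`` anchors are skipped.
    """
    rows = []
    for chrom, sub in anchors.df.groupby("chrom_a", sort=False):
        if len(sub) < min_anchors:
            continue
        x = sub["pos_a"].to_numpy(float)
        y = sub["pos_b"].to_numpy(float)
        lo = np.floor(x.min() / window) * window
        hi = np.ceil(x.max() / window) * window
        starts = np.arange(lo, hi, window)
        edges = np.arange(lo, hi + window, window)  # window boundaries
        fit = _local_linear(x, y, edges, bandwidth)
        fit = IsotonicRegression(increasing=True).fit_transform(edges, fit)
        rate = np.diff(fit) / window
        centers_b = (fit[:-1] + fit[1:]) / 2
        for s, r, pb in zip(starts, rate, centers_b):
            rows.append(
                dict(chrom_a=chrom, start=int(s), end=int(s + window), pos_b=pb, rate=float(r))
            )
    return SizeRateTrack(
        df=pd.DataFrame(rows, columns=["chrom_a", "start", "end", "pos_b", "rate"]),
        window=window,
        bandwidth=bandwidth,
    )


def partition_expansion(
    track: SizeRateTrack, neutral_band: tuple[float, float] = NEUTRAL_BAND
) -> pd.DataFrame:
    """Merge contiguous windows into A-expanded / neutral / B-expanded intervals.

    rate < lower band bound -> genome A locally expanded relative to B;
    rate > upper bound -> genome B expanded; inside the band -> neutral.
    """
    low, high = neutral_band
    rows = []
    for chrom, sub in track.df.groupby("chrom_a", sort=False):
        sub = sub.sort_values("start")
        labels = np.where(
            sub["rate"] < low, "A-expanded", np.where(sub["rate"] > high, "B-expanded", "neutral")
        )
        start = prev_label = None
        last_end = None
        for (s, e), lab in zip(sub[["start", "end"]].itertuples(index=False), labels):
            if lab != prev_label:
                if prev_label is not None:
                    rows.append(dict(chrom_a=chrom, start=start, end=last_end, label=prev_label))
                start, prev_label = s, lab
            last_end = e
        rows.append(dict(chrom_a=chrom, start=start, end=last_end, label=prev_label))
    return pd.DataFrame(rows, columns=["chrom_a", "start", "end", "label"])
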