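"""Ancestral haplotype group (AHG) assignment and divergence dating.

Pairwise variant distances between phased haplotypes, computed in fixed
genomic windows, separate recently coancestral haplotype pairs from deeply
diverged ones.  The pooled distance distribution of a structured population
is multimodal; a threshold between the two major modes assigns haplotypes
to founder-indexed AHGs window by window, in a semi-supervised priority
order.  Peak distances convert to divergence times via T/g = D/(2*mu).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .containers import MISSING, VariantMatrix
from .simulate import DEFAULT_GENERATION_TIME, DEFAULT_MU

DEFAULT_WINDOW = 5_000_000
DEFAULT_THRESHOLD = 11_000.0  # variants per Mb
CNV_LOW, CNV_HIGH = 0.6, 1.4
MIN_SITES_PER_WINDOW = 50
IBD_THRESHOLD = 500.0  # per Mb
SMOOTHING_SPAN = 3


@dataclass
class DistanceTensor:
    """Windowed pairwise distances, in variants per Mb."""

    windows: pd.DataFrame  # chrom, start, end
    haplotypes: list[str]
    distances: np.ndarray  # (n_windows, n_hap, n_hap), nan where masked
    n_sites: np.ndarray  # pairwise-complete site counts per window/pair

    def pooled(self) -> np.ndarray:
        """All defined off-diagonal distances (upper triangle, flattened)."""
        iu, ju = np.triu_indices(len(self.haplotypes), k=1)
        vals = self.distances[:, iu, ju].ravel()
        return vals[~np.isnan(vals)]


def window_distances(
    matrix: VariantMatrix,
    window: int = DEFAULT_WINDOW,
    min_sites: int = MIN_SITES_PER_WINDOW,
) -> DistanceTensor:
    """Count pairwise allele differences per window, scaled to per-Mb.

    Sites enter a pair's count only when both haplotypes are non-missing
    (pairwise-complete); pairs with fewer than ``min_sites`` complete sites
    in a window are masked (NaN).
    """
    n_hap = len(matrix.haplotypes)
    if n_hap < 2:
        raise ValueError("need at least 2 haplotypes")
    length = matrix.seq_length or int(matrix.positions[-1]) + 1
    n_win = max(1, int(np.ceil(length / window)))
    win_of_site = np.minimum(matrix.positions // window, n_win - 1)
    dist = np.zeros((n_win, n_hap, n_hap))
    nsit = np.zeros((n_win, n_hap, n_hap), dtype=int)
    g = matrix.genotypes
    for i, j in itertools.combinations(range(n_hap), 2):
        ok = (g[i] != MISSING) & (g[j] != MISSING)
        diff = ok & (g[i] != g[j])
        n_ok = np.bincount(win_of_site[ok], minlength=n_win)
        n_diff = np.bincount(win_of_site[diff], minlength=n_win)
        d = n_diff / (window / 1e6)
        d = np.where(n_ok >= min_sites, d, np.nan)
        dist[:, i, j] = dist[:, j, i] = d
        nsit[:, i, j] = nsit[:, j, i] = n_ok
    windows = pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "start": np.arange(n_win) * window,
            "end": np.minimum((np.arange(n_win) + 1) * window, length),
        }
    )
    return DistanceTensor(
        windows=windows, haplotypes=list(matrix.haplotypes), distances=dist, n_sites=nsit
    )


@dataclass
class PeakEstimate:
    peaks: list[float]  # ascending, variants per Mb
    threshold: float | None
    unimodal: bool


def estimate_peaks(
    tensor: DistanceTensor | np.ndarray, grid_points: int = 512
) -> PeakEstimate:
    """Kernel-density peaks of the pooled window-distance distribution.

    Returns peaks in ascending order and, when at least two peaks exist, a
    suggested threshold at the density minimum between the two largest.
    """
    vals = tensor.pooled() if isinstance(tensor, DistanceTensor) else np.asarray(tensor, float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 distances")
    if np.ptp(vals) == 0:
        return PeakEstimate(peaks=[float(vals[0])], threshold=None, unimodal=True)
    kde = gaussian_kde(vals)
    grid = np.linspace(vals.min(), vals.max(), grid_points)
    dens = kde(grid)
    idx, _ = find_peaks(dens)
    if idx.size == 0:  # monotone density; mode at an edge
        idx = np.array([int(np.argmax(dens))])
    if idx.size < 2:
        return PeakEstimate(peaks=[float(grid[idx[0]])], threshold=None, unimodal=True)
    top2 = idx[np.argsort(dens[idx])[-2:]]
    lo, hi = sorted(grid[top2])
    between = (grid > lo) & (grid < hi)
    threshold = float(grid[between][np.argmin(dens[between])])
    peaks = sorted(float(grid[i]) for i in idx)
    return PeakEstimate(peaks=peaks, threshold=threshold, unimodal=False)


def cnv_mask(
    coverage: np.ndarray | pd.DataFrame,
    low: float = CNV_LOW,
    high: float = CNV_HIGH,
) -> np.ndarray:
    """Keep-mask for windows by normalized coverage: True where coverage is
    within [low, high] bounds (strict exclusion outside)."""
    cov = coverage.to_numpy() if isinstance(coverage, pd.DataFrame) else np.asarray(coverage, float)
    return ~((cov < low) | (cov > high))


@dataclass
class AHGMap:
    """Per-window AHG labels (founder haplotype names; None where masked)."""

    windows: pd.DataFrame
    haplotypes: list[str]
    labels: np.ndarray  # (n_windows, n_hap) object array of founder names / None
    threshold: float
    priority: dict[str, int] = field(default_factory=dict)

    def group_sizes(self) -> pd.Series:
        flat = [l for row in self.labels for l in row if l is not None]
        return pd.Series(flat).value_counts()

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.labels, columns=self.haplotypes)
        out = pd.concat([self.windows.reset_index(drop=True), df], axis=1)
        out.to_csv(path, sep="\t", index=False)


def _mode_filter(labels: np.ndarray, span: int) -> np.ndarray:
    """Remove label runs shorter than the span by majority of a centered
    window; only single-window flips change for the default span of 3."""
    if span < 3:
        return labels
    out = labels.copy()
    half = span // 2
    n = len(labels)
    for w in range(n):
        lo, hi = max(0, w - half), min(n, w + half + 1)
        ctx = [l for l in labels[lo:hi] if l is not None]
        if labels[w] is None or not ctx:
            continue
        vals, counts = np.unique(ctx, return_counts=True)
        mode = vals[np.argmax(counts)]
        if counts.max() > len(ctx) / 2 and mode != labels[w]:
            out[w] = mode
    return out


def assign_ahg(
    tensor: DistanceTensor,
    threshold: float = DEFAULT_THRESHOLD,
    priority: dict[str, int] | None = None,
    window_mask: np.ndarray | None = None,
    smoothing_span: int = SMOOTHING_SPAN,
) -> AHGMap:
    """Founder-indexed AHG assignment per window.

    Haplotypes are processed by priority class (lower rank first; the
    published order puts reference diploids before tetraploids), then input
    order.  The first haplotype founds an AHG; each later haplotype joins
    the AHG of the nearest founder at distance < threshold, else founds a
    new one.  ``window_mask`` is a boolean keep-mask of shape
    (n_windows, n_haplotypes) (e.g. from :func:`cnv_mask`).  A mode filter
    over ``smoothing_span`` windows removes single-window label flips.
    """
    haps = tensor.haplotypes
    prio = priority or {h: 0 for h in haps}
    order = sorted(range(len(haps)), key=lambda i: (prio.get(haps[i], 0), i))
    n_win = len(tensor.windows)
    labels = np.full((n_win, len(haps)), None, dtype=object)
    for w in range(n_win):
        founders: list[int] = []
        for i in order:
            if window_mask is not None and not window_mask[w, i]:
                continue
            d = tensor.distances[w]
            cand = [(d[i, f], f) for f in founders if not np.isnan(d[i, f])]
            if founders and not cand:
                continue  # all distances undefined here -> leave masked
            best = min(cand) if cand else None
            if best is not None and best[0] < threshold:
                labels[w, i] = haps[best[1]]
            else:
                founders.append(i)
                labels[w, i] = haps[i]
    for i in range(len(haps)):
        labels[:, i] = _mode_filter(labels[:, i], smoothing_span)
    return AHGMap(
        windows=tensor.windows,
        haplotypes=haps,
        labels=labels,
        threshold=threshold,
        priority=prio,
    )


def divergence_time(
    d: float,
    mu: float = DEFAULT_MU,
    generation_time: float = DEFAULT_GENERATION_TIME,
    per_mb: bool = False,
) -> float:
    """Divergence time in years from pairwise distance D: T = g * D / (2*mu).

    ``d`` is per site unless ``per_mb`` is set (variants per Mb are divided
    by 1e6 first).
    """
    if mu <= 0 or generation_time <= 0:
        raise ValueError("mu and generation_time must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    per_site = d / 1e6 if per_mb else d
    return generation_time * per_site / (2 * mu)


def ibd_blocks(
    tensor: DistanceTensor, ibd_threshold: float = IBD_THRESHOLD
) -> pd.DataFrame:
    """Maximal runs of windows with pairwise distance below ``ibd_threshold``.

    Long blocks of near-zero divergence indicate identity by descent (a
    recent common ancestor of the two haplotypes in that region).
    """
    rows = []
    win = tensor.windows
    for i, j in itertools.combinations(range(len(tensor.haplotypes)), 2):
        d = tensor.distances[:, i, j]
        in_block = (d < ibd_threshold) & ~np.isnan(d)
        start = None
        for w, flag in enumerate(in_block):
            if flag and start is None:
                start = w
            elif not flag and start is not None:
                rows.append(
                    dict(
                        hap_i=tensor.haplotypes[i],
                        hap_j=tensor.haplotypes[j],
                        chrom=win["chrom"].iloc[start],
                        start=int(win["start"].iloc[start]),
                        end=int(win["end"].iloc[w - 1]),
                        n_windows=w - start,
                    )
                )
                start = None
        if start is not None:
            rows.append(
                dict(
                    hap_i=tensor.haplotypes[i],
                    hap_j=tensor.haplotypes[j],
                    chrom=win["chrom"].iloc[start],
                    start=int(win["start"].iloc[start]),
                    end=int(win["end"].iloc[len(in_block) - 1]),
                    n_windows=len(in_block) - start,
                )
            )
    return pd.DataFrame(
        rows, columns=["hap_i", "hap_j", "chrom", "start", "end", "n_windows"]
    )
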