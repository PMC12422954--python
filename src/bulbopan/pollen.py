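"""Phase validation from single-gamete genotype calls.

A correctly phased diploid assembly makes every gamete look like a simple
crossover mosaic of the two assembly haplotypes: adjacent markers recombine
in at most a few percent of gametes.  A locally mis-phased assembly region
instead swaps the labels of every gamete inside it, so the recombination
fraction of the marker pairs at its borders exceeds 50% and markers inside
it disagree with each gamete's chromosome-wide majority haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest, spearmanr

from .containers import MISSING, GameteMatrix

DEFAULT_BIN_SIZE = 200_000
SWITCH_THRESHOLD = 0.5
LOW_SUPPORT_N = 5


@dataclass
class PhaseReport:
    """Outputs of the gamete-based phase check."""

    pair_r: pd.DataFrame  # chrom, left_bin, right_bin, n_informative, r, low_support
    marker_support: pd.DataFrame  # chrom, bin, n, support, flagged
    gamete_majority: pd.DataFrame  # gamete, chrom, majority (-1 if tied)
    switch_intervals: pd.DataFrame  # chrom, start_bin, end_bin, kind
    phasing_error_rate: float = float("nan")
    error_rate_ci: tuple[float, float] = (float("nan"), float("nan"))
    extras: dict = field(default_factory=dict)


def bin_genotypes(
    calls: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE
) -> GameteMatrix:
    """Aggregate per-site gamete calls into fixed-size bins by majority vote.

    ``calls`` columns: gamete, chrom, pos, call (0/1).  A bin call is the
    majority of its non-missing site calls; empty bins and exact ties are
    missing.
    """
    calls = calls[calls["call"] != MISSING]
    gametes = sorted(calls["gamete"].unique())
    bins = []
    for chrom, sub in calls.groupby("chrom", sort=False):
        top = int(sub["pos"].max()) // bin_size + 1
        for b in range(top):
            bins.append((chrom, b * bin_size, (b + 1) * bin_size))
    bin_df = pd.DataFrame(bins, columns=["chrom", "start", "end"])
    key = {(c, s): i for i, (c, s, _) in enumerate(bin_df.itertuples(index=False))}
    mat = np.full((len(gametes), len(bin_df)), MISSING, dtype=np.int8)
    gidx = {g: i for i, g in enumerate(gametes)}
    grouped = calls.assign(bin_start=(calls["pos"] // bin_size) * bin_size).groupby(
        ["gamete", "chrom", "bin_start"]
    )["call"]
    n1 = grouped.sum()
    n = grouped.count()
    for (g, chrom, bstart), total in n.items():
        ones = n1.loc[(g, chrom, bstart)]
        if ones * 2 > total:
            v = 1
        elif ones * 2 < total:
            v = 0
        else:
            continue  # tie -> missing
        mat[gidx[g], key[(chrom, bstart)]] = v
    return GameteMatrix(gametes=gametes, bins=bin_df, calls=mat)


def recombination_fractions(matrix: GameteMatrix) -> pd.DataFrame:
    """Adjacent-marker recombination fractions.

    r = discordant / informative gametes, where a gamete is informative
    for a pair iff it has non-missing calls at both markers.  Pairs with
    fewer than 5 informative gametes are flagged ``low_support``.
    """
    rows = []
    calls = matrix.calls
    for chrom, idx in matrix.bins.groupby("chrom", sort=False).groups.items():
        idx = list(idx)
        for a, b in zip(idx[:-1], idx[1:]):
            ca, cb = calls[:, a], calls[:, b]
            ok = (ca != MISSING) & (cb != MISSING)
            n_inf = int(ok.sum())
            r = float((ca[ok] != cb[ok]).mean()) if n_inf else float("nan")
            rows.append(
                dict(
                    chrom=chrom,
                    left_bin=a,
                    right_bin=b,
                    n_informative=n_inf,
                    r=r,
                    low_support=n_inf < LOW_SUPPORT_N,
                )
            )
    return pd.DataFrame(rows)


def flag_phase_switches(
    pair_r: pd.DataFrame, threshold: float = SWITCH_THRESHOLD
) -> pd.DataFrame:
    """Turn r > threshold marker pairs into candidate mis-phased intervals.

    A mis-phased block produces flagged pairs at both of its borders, so
    flagged boundaries are paired sequentially into half-open bin intervals
    ``[left+1, right]``; an unpaired trailing boundary is reported as a
    point switch.
    """
    rows = []
    for chrom, sub in pair_r.groupby("chrom", sort=False):
        flagged = sub[(sub["r"] > threshold) & sub["r"].notna()]
        bounds = list(flagged["left_bin"])
        for a, b in zip(bounds[::2], bounds[1::2]):
            rows.append(dict(chrom=chrom, start_bin=a + 1, end_bin=b + 1, kind="interval"))
        if len(bounds) % 2:
            rows.append(
                dict(chrom=chrom, start_bin=bounds[-1] + 1, end_bin=bounds[-1] + 1, kind="point")
            )
    return pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin", "kind"])


def majority_support(matrix: GameteMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker support for each gamete's chromosome-wide majority haplotype.

    The majority haplotype of a gamete x chromosome is its modal non-missing
    call (ties -> undefined, excluded from all denominators).  A marker is
    flagged as potentially mis-phased if fewer than 50% of informative
    gametes support their majority haplotype there.
    """
    maj_rows = []
    chrom_of_bin = matrix.bins["chrom"].to_numpy()
    majority = np.full((len(matrix.gametes), len(matrix.bins)), MISSING, dtype=np.int8)
    for chrom in matrix.bins["chrom"].unique():
        cols = np.flatnonzero(chrom_of_bin == chrom)
        sub = matrix.calls[:, cols]
        n1 = (sub == 1).sum(axis=1)
        n0 = (sub == 0).sum(axis=1)
        maj = np.where(n1 > n0, 1, np.where(n0 > n1, 0, MISSING)).astype(np.int8)
        for g, m in zip(matrix.gametes, maj):
            maj_rows.append(dict(gamete=g, chrom=chrom, majority=int(m)))
        majority[:, cols] = maj[:, None]

    support_rows = []
    for b in range(len(matrix.bins)):
        col = matrix.calls[:, b]
        ok = (col != MISSING) & (majority[:, b] != MISSING)
        n = int(ok.sum())
        if n == 0:
            support_rows.append(
                dict(chrom=chrom_of_bin[b], bin=b, n=0, support=float("nan"), flagged=False)
            )
            continue
        sup = float((col[ok] == majority[ok, b]).mean())
        support_rows.append(
            dict(chrom=chrom_of_bin[b], bin=b, n=n, support=sup, flagged=sup < 0.5)
        )
    return pd.DataFrame(support_rows), pd.DataFrame(maj_rows)


def phasing_error_rate(
    matrix: GameteMatrix, support: pd.DataFrame | None = None
) -> tuple[float, tuple[float, float]]:
    """Proportion of markers that do not support the assembly haplotype.

    Returns the rate with a binomial (Clopper-Pearson) 95% CI.  Raises if no
    marker is evaluable.
    """
    if support is None:
        support, _ = majority_support(matrix)
    evaluable = support[support["n"] > 0]
    if evaluable.empty:
        raise ValueError("no evaluable markers; phasing error rate undefined")
    k = int(evaluable["flagged"].sum())
    n = len(evaluable)
    ci = binomtest(k, n).proportion_ci(0.95)
    return k / n, (float(ci.low), float(ci.high))


def colinearity(pair_r: pd.DataFrame) -> float:
    """Spearman correlation between marker order and cumulative map distance.

    The cumulative genetic distance sum(min(r, 0.5)) should increase with
    physical marker order when the assembly is co-linear with the map.
    """
    rhos = []
    for _, sub in pair_r.groupby("chrom", sort=False):
        d = np.cumsum(np.minimum(sub["r"].fillna(0), 0.5))
        if len(d) > 2 and d.iloc[-1] > 0:
            rhos.append(spearmanr(np.arange(len(d)), d).statistic)
    return float(np.mean(rhos)) if rhos else float("nan")


def phase_report(matrix: GameteMatrix, threshold: float = SWITCH_THRESHOLD) -> PhaseReport:
    """Run the full gamete-based phase check."""
    pair_r = recombination_fractions(matrix)
    support, majority = majority_support(matrix)
    switches = flag_phase_switches(pair_r, threshold)
    rate, ci = phasing_error_rate(matrix, support)
    return PhaseReport(
        pair_r=pair_r,
        marker_support=support,
        gamete_majority=majority,
        switch_intervals=switches,
        phasing_error_rate=rate,
        error_rate_ci=ci,
        extras={"colinearity": colinearity(pair_r)},
    )
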