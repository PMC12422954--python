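"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (Hi-C phasing, gamete-based phase
validation, pangenome construction, introgression calling, ancestral
haplotype grouping, size-rate estimation) is exercised on data produced
here, so each generator returns both the data container and a truth object.

The population simulator uses an infinite-sites model on a two-level star
phylogeny: haplotypes within a group share a recent ancestor (pairwise
per-site divergence ``theta_within``), groups split ``T`` years ago so that
the expected between-group per-site divergence is ``2*mu*T/g``.  Haplotypes
are exchangeable within groups; there is no recombination.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, ContigSet, DepthTrack, GameteMatrix, HiCMatrix, VariantMatrix

#: synonymous substitution rate per site per generation used for dating
DEFAULT_MU = 6.5e-9
#: generation time in years for a perennial grass
DEFAULT_GENERATION_TIME = 2.0


@dataclass
class PopulationTruth:
    """Ground truth of a simulated multi-haplotype population."""

    group_of_haplotype: dict[str, str]
    split_times: dict[tuple[str, str], float]
    mutation_rate: float
    generation_time: float
    seq_length: int
    theta_within: float = 0.0

    def __post_init__(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")
        for pair, t in self.split_times.items():
            if t < 0:
                raise ValueError(f"negative split time for {pair}")

    def expected_density_per_mb(self, hap_i: str, hap_j: str) -> float:
        """Expected pairwise variant density (per Mb) between two haplotypes."""
        gi, gj = self.group_of_haplotype[hap_i], self.group_of_haplotype[hap_j]
        if gi == gj:
            return self.theta_within * 1e6
        t = self.split_times[tuple(sorted((gi, gj)))]
        return 2 * self.mutation_rate * t / self.generation_time * 1e6


@dataclass
class GameteTruth:
    """Crossovers, injected phase flips and noise rates of a gamete panel."""

    crossover_positions: dict[tuple[str, str], list[int]]
    flip_blocks: list[tuple[int, int]]
    error_rate: float
    missing_rate: float

    def __post_init__(self) -> None:
        for key, pos in self.crossover_positions.items():
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"crossover positions not increasing for {key}")
        for r in (self.error_rate, self.missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class ILTruth:
    """Injected donor segments of a synthetic introgression line."""

    segments: list[tuple[str, int, int, str]]
    background_depth: float
    donor_depth: float
    window_size: int = 1_000_000

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _ in self.segments:
            if e <= s:
                raise ValueError("segment end must exceed start")
            if s % self.window_size or e % self.window_size:
                raise ValueError("segments must be aligned to the window grid")
            by_chrom.setdefault(chrom, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError("segments must not overlap")


def _group_depths(
    groups: dict[str, list[str]],
    split_times: float | dict[tuple[str, str], float],
    theta_within: float,
    mu: float,
    gen_time: float,
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Per-group root-to-ancestor branch lengths (per-site) on a star tree.

    Between-group per-site divergence must equal 2*mu*T/g; with terminal
    branches theta_within/2, group branches b satisfy
    b_i + b_j = 2*mu*T_ij/g - theta_within.  A scalar T gives equal depths;
    a per-pair map is fitted by least squares (it need not be additive).
    """
    names = sorted(groups)
    if not isinstance(split_times, dict):
        split_times = {
            pair: float(split_times) for pair in itertools.combinations(names, 2)
        }
    else:
        split_times = {tuple(sorted(k)): float(v) for k, v in split_times.items()}
        for pair in itertools.combinations(names, 2):
            if pair not in split_times:
                raise ValueError(f"missing split time for group pair {pair}")
    for pair, t in split_times.items():
        if t < 0:
            raise ValueError(f"split time for {pair} must be non-negative")

    pairs = list(itertools.combinations(names, 2))
    if len(names) == 1:
        return {names[0]: 0.0}, split_times
    a = np.zeros((len(pairs), len(names)))
    y = np.zeros(len(pairs))
    for r, (gi, gj) in enumerate(pairs):
        a[r, names.index(gi)] = 1
        a[r, names.index(gj)] = 1
        y[r] = 2 * mu * split_times[(gi, gj)] / gen_time - theta_within
    if len(names) == 2:
        b = np.full(2, y[0] / 2)
    else:
        b, *_ = np.linalg.lstsq(a, y, rcond=None)
    b[np.abs(b) < 1e-15] = 0.0
    if np.any(b < 0):
        raise ValueError(
            "split times too small relative to theta_within (negative branch)"
        )
    return dict(zip(names, b)), split_times


def make_population(
    seed: int,
    groups: dict[str, int] | dict[str, list[str]],
    split_times: float | dict[tuple[str, str], float],
    theta_within: float = 0.0,
    seq_length: int = 10_000_000,
    mu: float = DEFAULT_MU,
    generation_time: float = DEFAULT_GENERATION_TIME,
    chrom: str = "chr1",
) -> tuple[VariantMatrix, PopulationTruth]:
    """Simulate a multi-haplotype population with staged divergence.

    Parameters
    ----------
    groups
        Map of group label to either a haplotype count or explicit haplotype
        ids; at least 2 groups unless a single group is explicitly wanted.
    split_times
        Between-group split time(s) in years (scalar or symmetric per-pair map).
    theta_within
        Expected within-group pairwise per-site divergence.
    """
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    if theta_within < 0:
        raise ValueError("theta_within must be non-negative")
    groups_expanded: dict[str, list[str]] = {}
    for g, v in groups.items():
        if isinstance(v, int):
            groups_expanded[g] = [f"{g}_h{i + 1}" for i in range(v)]
        else:
            groups_expanded[g] = list(v)
    haplotypes = [h for g in sorted(groups_expanded) for h in groups_expanded[g]]
    if len(haplotypes) < 2:
        raise ValueError("need at least 2 haplotypes")

    depths, split_map = _group_depths(
        groups_expanded, split_times, theta_within, mu, generation_time
    )
    rng = np.random.default_rng(seed)

    # infinite sites: Poisson mutation counts per branch, globally unique
    # uniform positions (collisions between branches would cancel mutations)
    branches: list[tuple[int, list[str]]] = []
    for g in sorted(groups_expanded):
        branches.append((int(rng.poisson(depths[g] * seq_length)), groups_expanded[g]))
    for g in sorted(groups_expanded):
        for h in groups_expanded[g]:
            branches.append((int(rng.poisson(theta_within / 2 * seq_length)), [h]))
    n_total = sum(n for n, _ in branches)
    all_pos = rng.integers(0, seq_length, size=n_total)
    while True:
        uniq, first = np.unique(all_pos, return_index=True)
        dup = np.ones(n_total, dtype=bool)
        dup[first] = False
        if not dup.any():
            break
        all_pos[dup] = rng.integers(0, seq_length, size=int(dup.sum()))

    order = np.argsort(all_pos, kind="stable")
    rank = np.empty(n_total, dtype=np.int64)
    rank[order] = np.arange(n_total)
    geno = np.zeros((len(haplotypes), n_total), dtype=np.int8)
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    offset = 0
    for n_mut, carriers in branches:
        cols = rank[offset : offset + n_mut]
        offset += n_mut
        for h in carriers:
            geno[hap_index[h], cols] = 1
    # drop sites carried by everyone (fixed differences of the root)
    poly = (geno.sum(axis=0) > 0) & (geno.sum(axis=0) < len(haplotypes))
    vm = VariantMatrix(
        haplotypes=haplotypes,
        positions=all_pos[order][poly],
        genotypes=geno[:, poly],
        chrom=chrom,
        seq_length=seq_length,
    )
    truth = PopulationTruth(
        group_of_haplotype={h: g for g, hs in groups_expanded.items() for h in hs},
        split_times=split_map,
        mutation_rate=mu,
        generation_time=generation_time,
        seq_length=seq_length,
        theta_within=theta_within,
    )
    return vm, truth


def make_assembly_sim(
    seed: int,
    ploidy: int,
    n_contigs: int,
    chrom_lengths: dict[str, int],
    ibd_tracts: list[tuple[str, int, int, tuple[int, ...]]] | None = None,
) -> ContigSet:
    """Tile each haplotype's chromosomes into contigs with known haplotype sets.

    ``ibd_tracts`` are ``(chrom, start, end, haplotypes)`` intervals shared
    identical-by-descent between the listed haplotypes: contigs inside a
    tract exist once, with copy_number = number of sharing haplotypes.
    """
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    ibd_tracts = list(ibd_tracts or [])
    for chrom, s, e, haps in ibd_tracts:
        if chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r} in IBD tract")
        if not (0 <= s < e <= chrom_lengths[chrom]):
            raise ValueError("IBD tract outside chromosome bounds")
        if not set(haps) <= set(range(1, ploidy + 1)) or len(haps) < 2:
            raise ValueError("IBD tract haplotypes must be >=2 labels within ploidy")

    rng = np.random.default_rng(seed)
    rows = []

    def tile(chrom: str, start: int, end: int, hap: int, n: int, hapset: tuple[int, ...], tag: str):
        span = end - start
        n = max(1, min(n, span))  # cannot make more contigs than bases
        w = rng.dirichlet(np.full(n, 8.0)) * span
        bounds = np.concatenate([[0], np.round(np.cumsum(w))]).astype(int)
        bounds[-1] = span
        bounds = np.unique(bounds)
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append(
                dict(
                    contig=f"{chrom}_h{hap}_{tag}{start + s}",
                    chrom=chrom,
                    start=start + int(s),
                    end=start + int(e),
                    length=int(e - s),
                    position=start + int((s + e) // 2),
                    copy_number=len(hapset),
                    true_haps=hapset,
                )
            )

    for chrom, clen in chrom_lengths.items():
        tracts = sorted(t for t in ibd_tracts if t[0] == chrom)
        for hap in range(1, ploidy + 1):
            # intervals of this haplotype not covered by a tract it belongs to
            own = [(s, e, tuple(sorted(hs))) for _, s, e, hs in tracts if hap in hs]
            cursor = 0
            for s, e, hs in sorted(own):
                if s < cursor:
                    raise ValueError("IBD tracts overlap")
                if cursor < s:
                    frac = max(1, round(n_contigs * (s - cursor) / clen))
                    tile(chrom, cursor, s, hap, frac, (hap,), "c")
                if hap == min(hs):  # shared contigs created once
                    frac = max(1, round(n_contigs * (e - s) / clen))
                    tile(chrom, s, e, hap, frac, hs, "ibd")
                cursor = e
            if cursor < clen:
                frac = max(1, round(n_contigs * (clen - cursor) / clen))
                tile(chrom, cursor, clen, hap, frac, (hap,), "c")

    return ContigSet(df=pd.DataFrame(rows), ploidy=ploidy, chrom_lengths=dict(chrom_lengths))


def make_hic(
    contigs: ContigSet,
    intra_boost: float = 5.0,
    rabl_scale: float = 50e6,
    mean_links: float = 100.0,
    seed: int = 0,
) -> HiCMatrix:
    """Poisson-sample a contact matrix with Rabl-like exponential distance decay.

    Expected links between same-chromosome contigs i, j:
    ``mean_links * exp(-|pos_i - pos_j| / rabl_scale)``, multiplied by
    ``intra_boost`` when the contigs share a haplotype (or an IBD copy).
    Cross-chromosome counts are zero.
    """
    if intra_boost <= 1:
        raise ValueError("intra_boost must exceed 1")
    if mean_links <= 0:
        raise ValueError("mean_links must be positive")
    if not (rabl_scale > 0):
        raise ValueError("rabl_scale must be positive")

    rng = np.random.default_rng(seed)
    df = contigs.df
    ids = list(df["contig"])
    pos = df["position"].to_numpy(float)
    chroms = df["chrom"].to_numpy()
    hapsets = [set(h) for h in df["true_haps"]]
    n = len(ids)
    lam = np.zeros((n, n))
    same_chrom = chroms[:, None] == chroms[None, :]
    dist = np.abs(pos[:, None] - pos[None, :])
    lam = mean_links * np.exp(-dist / rabl_scale) * same_chrom
    share = np.array(
        [[bool(hapsets[i] & hapsets[j]) for j in range(n)] for i in range(n)]
    )
    lam *= np.where(share, intra_boost, 1.0)
    counts = rng.poisson(np.triu(lam, k=1))
    counts = counts + counts.T
    return HiCMatrix(ids=ids, counts=counts.astype(float))


def make_gametes(
    n_gametes: int = 96,
    n_bins: int = 2000,
    xover_lambda: float = 2.0,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    flip_blocks: list[tuple[int, int]] | None = None,
    seed: int = 0,
    bin_size: int = 200_000,
    chrom: str = "chr1",
) -> tuple[GameteMatrix, GameteTruth]:
    """Simulate single-gamete haplotype calls along one chromosome.

    Each gamete is an alternating hap1/hap2 mosaic with Poisson(xover_lambda)
    crossovers placed uniformly.  ``flip_blocks`` are half-open bin-index
    intervals whose calls are label-swapped in every gamete, emulating a
    mis-phased assembly region; per-call error and missingness follow.
    """
    if xover_lambda < 0:
        raise ValueError("xover_lambda must be >= 0")
    for r in (error_rate, missing_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must lie in [0, 1)")
    flip_blocks = [tuple(b) for b in (flip_blocks or [])]
    for s, e in flip_blocks:
        if not (0 <= s < e <= n_bins):
            raise ValueError("flip block outside bin range")

    rng = np.random.default_rng(seed)
    calls = np.empty((n_gametes, n_bins), dtype=np.int8)
    xovers: dict[tuple[str, str], list[int]] = {}
    mid = (np.arange(n_bins) + 0.5) * bin_size
    length = n_bins * bin_size
    for g in range(n_gametes):
        k = rng.poisson(xover_lambda)
        cuts = np.sort(rng.uniform(0, length, size=k))
        start_hap = int(rng.integers(0, 2))
        hap = (start_hap + np.searchsorted(cuts, mid)) % 2
        calls[g] = hap
        xovers[(f"g{g + 1}", chrom)] = [int(c) for c in cuts]

    for s, e in flip_blocks:
        calls[:, s:e] = 1 - calls[:, s:e]
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        calls[flip] = 1 - calls[flip]
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING

    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_bins) * bin_size,
            "end": (np.arange(n_bins) + 1) * bin_size,
        }
    )
    gm = GameteMatrix(
        gametes=[f"g{i + 1}" for i in range(n_gametes)], bins=bins, calls=calls
    )
    truth = GameteTruth(
        crossover_positions=xovers,
        flip_blocks=flip_blocks,
        error_rate=error_rate,
        missing_rate=missing_rate,
    )
    return gm, truth


def make_il_depth(
    n_windows: int,
    segments: list[tuple[str, int, int, str]],
    total_reads: int = 5_000_000,
    seed: int = 0,
    background_depth: float = 10.0,
    donor_depth: float = 1000.0,
    recipient_windows: int = 0,
    recipient_depth: float = 2000.0,
    window_size: int = 1_000_000,
    donor_chrom: str = "donor_1H",
    recipient_chrom: str = "recip_1H",
) -> tuple[DepthTrack, ILTruth]:
    """Simulate a GBS read-depth track of an introgression line.

    Donor-genome windows inside injected ``segments`` have expected
    normalized depth ``donor_depth`` (well above the 200 calling threshold);
    donor windows outside segments sit at ``background_depth`` (cross-mapping
    noise); optional recipient-genome windows at ``recipient_depth``.
    Depths are converted to expected read counts and Poisson-sampled.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    truth = ILTruth(
        segments=list(segments),
        background_depth=background_depth,
        donor_depth=donor_depth,
        window_size=window_size,
    )
    for chrom, s, e, _ in truth.segments:
        if chrom != donor_chrom or e > n_windows * window_size:
            raise ValueError("segment outside the donor track")

    rng = np.random.default_rng(seed)
    starts = np.arange(n_windows) * window_size
    expect = np.full(n_windows, background_depth)
    for _, s, e, _ in truth.segments:
        expect[s // window_size : e // window_size] = donor_depth
    lam = expect / 1e6 * total_reads
    counts = rng.poisson(lam)
    rows = pd.DataFrame(
        {
            "chrom": donor_chrom,
            "start": starts,
            "end": starts + window_size,
            "count": counts,
            "origin": "donor",
        }
    )
    if recipient_windows:
        rstarts = np.arange(recipient_windows) * window_size
        rcounts = rng.poisson(
            np.full(recipient_windows, recipient_depth) / 1e6 * total_reads
        )
        rows = pd.concat(
            [
                rows,
                pd.DataFrame(
                    {
                        "chrom": recipient_chrom,
                        "start": rstarts,
                        "end": rstarts + window_size,
                        "count": rcounts,
                        "origin": "recipient",
                    }
                ),
            ],
            ignore_index=True,
        )
    return DepthTrack(df=rows, total_reads=total_reads), truth
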