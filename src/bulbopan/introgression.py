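"""Detection of wild-donor segments in introgression lines (ILs).

Reads of an IL aligned to a hybrid recipient+donor reference pile up on
donor-genome windows only where the line actually carries donor chromatin.
Windows are scored by normalized 1-Mb read depth (count / total x 1e6);
donor windows above a fixed threshold are merged into segments, and each
segment is matched to its closest donor haplotype by identity-by-state
(IBS) distance, with a windowed argmin series to expose mosaic segments
recombined from two donor haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, DepthTrack, VariantMatrix

DEPTH_THRESHOLD = 200.0
WINDOW_SIZE = 1_000_000
GAP_WINDOWS = 1
PERSISTENCE = 3
MIN_INFORMATIVE_SITES = 10


def normalize_depth(track: DepthTrack, total_reads: int | None = None) -> DepthTrack:
    """Add the normalized 1-Mb depth column: count / total aligned reads x 1e6."""
    total = total_reads if total_reads is not None else track.total_reads
    if not total or total <= 0:
        raise ValueError("total aligned read count must be positive")
    df = track.df.copy()
    df["normalized"] = df["count"] / total * 1e6
    return DepthTrack(df=df, total_reads=total)


def call_introgressions(
    track: DepthTrack,
    threshold: float = DEPTH_THRESHOLD,
    gap_windows: int = GAP_WINDOWS,
) -> pd.DataFrame:
    """Donor-genome windows with normalized depth strictly above ``threshold``,
    merged into segments tolerating up to ``gap_windows`` interior cold windows.

    Returns a table with chrom, start, end, n_windows (hot windows only).
    """
    if "normalized" not in track.df.columns:
        raise ValueError("normalize_depth must be applied first")
    if "origin" not in track.df.columns:
        raise ValueError("genome-of-origin labels are required")
    rows = []
    donor = track.df[track.df["origin"] == "donor"]
    for chrom, sub in donor.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        hot = sub[sub["normalized"] > threshold]
        if hot.empty:
            continue
        win = sub["end"].iloc[0] - sub["start"].iloc[0]
        seg_start = seg_end = None
        n_hot = 0
        for s, e in zip(hot["start"], hot["end"]):
            if seg_end is not None and s - seg_end <= gap_windows * win:
                seg_end = e
            else:
                if seg_start is not None:
                    rows.append(dict(chrom=chrom, start=seg_start, end=seg_end, n_windows=n_hot))
                seg_start, seg_end, n_hot = s, e, 0
            n_hot += 1
        rows.append(dict(chrom=chrom, start=seg_start, end=seg_end, n_windows=n_hot))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows"])


@dataclass
class IBSResult:
    """Donor matching of one introgressed segment."""

    distances: dict[str, float]  # donor haplotype -> IBS distance
    assigned: list[str]  # argmin donor(s); >1 entries means ambiguous
    ambiguous: bool
    window_argmin: pd.DataFrame  # window_start, donor (None if undetermined)
    n_sites: int
    undetermined: bool = False
    breakpoints: list[int] = field(default_factory=list)


def ibs_match(
    segment: tuple[str, int, int],
    il_calls: tuple[np.ndarray, np.ndarray],
    donors: VariantMatrix,
    window_size: int = WINDOW_SIZE,
    min_sites: int = MIN_INFORMATIVE_SITES,
) -> IBSResult:
    """Match a segment to the donor haplotype with minimal IBS distance.

    ``il_calls`` is (positions, alleles) of the IL inside the donor
    coordinate system; IBS distance to a donor haplotype is the fraction of
    pairwise-complete sites with differing alleles.  A per-1-Mb-window argmin
    series supports mosaic detection.
    """
    chrom, start, end = segment
    positions, alleles = il_calls
    positions = np.asarray(positions)
    alleles = np.asarray(alleles)
    in_seg = (positions >= start) & (positions < end)
    pos, al = positions[in_seg], alleles[in_seg]

    site_idx = np.searchsorted(donors.positions, pos)
    valid = (site_idx < donors.n_sites) & (donors.positions[np.minimum(site_idx, donors.n_sites - 1)] == pos)
    pos, al, site_idx = pos[valid], al[valid], site_idx[valid]
    informative = al != MISSING

    def dist(hap_row: np.ndarray, sel: np.ndarray) -> float:
        ok = sel & informative & (hap_row[site_idx] != MISSING)
        if ok.sum() == 0:
            return float("nan")
        return float((hap_row[site_idx[ok]] != al[ok]).mean())

    n_inf = int(informative.sum())
    all_sel = np.ones_like(al, dtype=bool)
    distances = {
        h: dist(donors.genotypes[i], all_sel) for i, h in enumerate(donors.haplotypes)
    }
    if n_inf < min_sites:
        return IBSResult(
            distances=distances,
            assigned=[],
            ambiguous=False,
            window_argmin=pd.DataFrame(columns=["window_start", "donor"]),
            n_sites=n_inf,
            undetermined=True,
        )
    dmin = min(v for v in distances.values() if not np.isnan(v))
    assigned = [h for h, v in distances.items() if v == dmin]

    win_rows = []
    for wstart in range(int(start), int(end), window_size):
        sel = (pos >= wstart) & (pos < wstart + window_size)
        wd = {h: dist(donors.genotypes[i], sel) for i, h in enumerate(donors.haplotypes)}
        finite = {h: v for h, v in wd.items() if not np.isnan(v)}
        n_win = int((sel & informative).sum())
        if not finite or n_win < min_sites:
            win_rows.append(dict(window_start=wstart, donor=None))
        else:
            wmin = min(finite.values())
            best = [h for h, v in finite.items() if v == wmin]
            win_rows.append(dict(window_start=wstart, donor=best[0] if len(best) == 1 else None))
    win_df = pd.DataFrame(win_rows)
    res = IBSResult(
        distances=distances,
        assigned=assigned,
        ambiguous=len(assigned) > 1,
        window_argmin=win_df,
        n_sites=n_inf,
    )
    res.breakpoints = find_mosaic_breakpoints(win_df)
    return res


def find_mosaic_breakpoints(
    window_argmin: pd.DataFrame, persistence: int = PERSISTENCE
) -> list[int]:
    """Breakpoints between runs of differing windowed donor assignments.

    Runs shorter than ``persistence`` windows are treated as noise and merged
    into the preceding run; boundaries between the surviving runs are
    returned as indices into the window series (a breakpoint at i separates
    windows i-1 and i).
    """
    series = [d for d in window_argmin["donor"]]
    idx = [i for i, d in enumerate(series) if d is not None]
    if len(idx) < 2:
        return []
    # run-length encode over determined windows
    runs: list[list[int]] = []  # [donor-run member indices]
    labels: list[str] = []
    for i in idx:
        if labels and series[i] == labels[-1]:
            runs[-1].append(i)
        else:
            runs.append([i])
            labels.append(series[i])
    # merge short runs into their predecessor (or successor at the start)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for k, run in enumerate(runs):
            if len(run) < persistence:
                tgt = k - 1 if k > 0 else k + 1
                runs[tgt] = sorted(runs[tgt] + run)
                runs.pop(k)
                labels.pop(k)
                changed = True
                break
    # collapse now-adjacent equal labels
    merged_runs: list[list[int]] = []
    merged_labels: list[str] = []
    for run, lab in zip(runs, labels):
        if merged_labels and lab == merged_labels[-1]:
            merged_runs[-1].extend(run)
        else:
            merged_runs.append(list(run))
            merged_labels.append(lab)
    return [run[0] for run in merged_runs[1:]]
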