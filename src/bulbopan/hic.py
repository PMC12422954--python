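"""Hi-C based haplotype phasing of diploid and autotetraploid assemblies.

The workflow mirrors chromosome-scale phasing practice for heterozygous
assemblies: restrict Hi-C links to contig border windows, regress out the
positional (Rabl) signal, then cluster contigs chromosome-wise in PCA space
of their residual link profiles — a PC1 sign split for diploids, k-means on
PC1/PC2 with recursive refinement for autotetraploids.  Contigs present in
more than one haplotype (IBD copies) are placed by proximity to haplotype
centres; short or unclustered contigs are rescued by a Hi-C majority rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import ContigSet, HiCMatrix

DEFAULT_BORDER_WINDOW = 2_000_000  # bp from a contig end counted as "border"
DEFAULT_MIN_CONTIG_LEN = 1_000_000  # PCA eligibility cutoff


@dataclass
class HaplotypeAssignment:
    """Contig -> haplotype-set assignment with per-contig provenance.

    ``df`` columns: contig, chrom, haps (tuple of int labels or None),
    method ("pca" | "kmeans" | "recursive" | "multicopy" | "majority"),
    flag ("" | "tie" | "no_links" | "short").
    """

    df: pd.DataFrame
    ploidy: int = 2
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, row in self.df.iterrows():
            if row["haps"] is not None and not set(row["haps"]) <= set(
                range(1, self.ploidy + 1)
            ):
                raise ValueError("haplotype labels must lie in 1..ploidy")
        self.df = self.df.set_index("contig", drop=False)

    @property
    def assigned(self) -> pd.DataFrame:
        return self.df[self.df["haps"].notna()]

    @property
    def unassigned(self) -> list[str]:
        return list(self.df.index[self.df["haps"].isna()])

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["haps"] = out["haps"].map(
            lambda h: ",".join(map(str, h)) if h is not None else ""
        )
        out.to_csv(path, sep="\t", index=False)


def build_border_matrix(
    links: pd.DataFrame,
    contigs: ContigSet,
    border_window: float = DEFAULT_BORDER_WINDOW,
) -> HiCMatrix:
    """Count Hi-C links whose both ends map near contig borders.

    ``links`` columns: contig_i, pos_i, contig_j, pos_j (positions within the
    contig, 0-based).  A link is counted iff each end lies within
    ``border_window`` bp of one of its contig's ends; contigs shorter than
    twice the window contribute over their full length.
    """
    ids = contigs.ids
    lengths = contigs.lengths()
    unknown = (set(links["contig_i"]) | set(links["contig_j"])) - set(ids)
    if unknown:
        raise ValueError(f"links reference unknown contigs: {sorted(unknown)[:5]}")

    def near_border(contig: pd.Series, pos: pd.Series) -> pd.Series:
        ln = lengths.loc[contig].to_numpy()
        p = pos.to_numpy(float)
        if np.any((p < 0) | (p >= ln)):
            raise ValueError("link position outside contig bounds")
        return pd.Series((p < border_window) | (ln - p <= border_window))

    keep = near_border(links["contig_i"], links["pos_i"]) & near_border(
        links["contig_j"], links["pos_j"]
    )
    pos_of = {c: k for k, c in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)))
    kept = links[keep.to_numpy()]
    for ci, cj in zip(kept["contig_i"], kept["contig_j"]):
        i, j = pos_of[ci], pos_of[cj]
        if i != j:
            counts[i, j] += 1
            counts[j, i] += 1
    return HiCMatrix(ids=ids, counts=counts, border_restricted=True)


def rabl_normalize(
    matrix: HiCMatrix, contigs: ContigSet
) -> tuple[HiCMatrix, dict]:
    """Regress positional effects out of a contact matrix.

    Fits ``log1p(count) ~ distance + mean distance of the pair to the
    chromosome ends`` over same-chromosome contig pairs and returns the
    residual matrix (cross-chromosome entries stay zero).  The distal-
    proximity predictor captures the telomere/centromere polarization of
    Rabl-configured nuclei.
    """
    df = contigs.df.loc[matrix.ids]
    pos = df["position"].to_numpy(float)
    chroms = df["chrom"].to_numpy()
    chrom_len = {
        c: float(contigs.chrom_lengths.get(c, df.loc[df["chrom"] == c, "end"].max()))
        for c in np.unique(chroms)
    }
    n = len(matrix.ids)
    iu, ju = np.triu_indices(n, k=1)
    same = chroms[iu] == chroms[ju]
    iu, ju = iu[same], ju[same]
    if matrix.counts.max() == 0:
        warnings.warn("all-zero Hi-C matrix; returning zeros", stacklevel=2)
        return HiCMatrix(matrix.ids, np.zeros_like(matrix.counts)), {"r2": np.nan}

    d = np.abs(pos[iu] - pos[ju])
    ends = np.array([chrom_len[c] for c in chroms[iu]])
    edist_i = np.minimum(pos[iu], ends - pos[iu])
    edist_j = np.minimum(pos[ju], ends - pos[ju])
    e = (edist_i + edist_j) / 2
    y = np.log1p(matrix.counts[iu, ju])
    x = np.column_stack([np.ones_like(d), d, e])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0

    out = np.zeros_like(matrix.counts, dtype=float)
    out[iu, ju] = resid
    out[ju, iu] = resid
    diag = {"r2": float(r2), "coef": beta.tolist(), "n_pairs": int(iu.size)}
    return HiCMatrix(matrix.ids, out, matrix.border_restricted), diag


def _profiles(normalized: HiCMatrix, ids: list[str], feature_ids: list[str]) -> np.ndarray:
    """Residual link profile of ``ids`` against ``feature_ids``."""
    idx = [normalized.ids.index(c) for c in ids]
    fidx = [normalized.ids.index(c) for c in feature_ids]
    return normalized.counts[np.ix_(idx, fidx)]


def phase_diploid(
    normalized: HiCMatrix,
    contigs: ContigSet,
    min_contig_len: float = DEFAULT_MIN_CONTIG_LEN,
) -> HaplotypeAssignment:
    """Split contigs into two haplotypes by PC1 sign, chromosome-wise.

    Only single-copy contigs >= ``min_contig_len`` enter the PCA; copy-number-2
    contigs (IBD) are assigned both haplotypes; everything else is left for
    :func:`rescue_unphased`.
    """
    df = contigs.df.loc[[c for c in normalized.ids]]
    rows: list[dict] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        eligible = sub[
            (sub["length"] >= min_contig_len) & (sub["copy_number"] == 1)
        ]["contig"].tolist()
        if len(eligible) < 4:
            raise ValueError(
                f"chromosome {chrom}: fewer than 4 eligible contigs; phasing under-determined"
            )
        feats = _profiles(normalized, eligible, eligible)
        pc1 = PCA(n_components=1, random_state=0).fit_transform(feats)[:, 0]
        for contig, v in zip(eligible, pc1):
            rows.append(
                dict(contig=contig, chrom=chrom, haps=(1,) if v >= 0 else (2,), method="pca", flag="")
            )
        for contig, row in sub.iterrows():
            if contig in eligible:
                continue
            if row["copy_number"] == 2:
                rows.append(dict(contig=contig, chrom=chrom, haps=(1, 2), method="multicopy", flag=""))
            else:
                rows.append(dict(contig=contig, chrom=chrom, haps=None, method="", flag="short"))
    return HaplotypeAssignment(df=pd.DataFrame(rows), ploidy=2)


def _split_silhouette(normalized: HiCMatrix, ids_a: list[str], ids_b: list[str]) -> float:
    """Silhouette of an existing 2-group split on PC1 of the pair's sub-matrix."""
    ids = ids_a + ids_b
    if len(ids_a) < 2 or len(ids_b) < 2:
        return 1.0  # tiny groups cannot be meaningfully re-split
    feats = _profiles(normalized, ids, ids)
    pc1 = PCA(n_components=1, random_state=0).fit_transform(feats)
    labels = np.r_[np.zeros(len(ids_a)), np.ones(len(ids_b))]
    return float(silhouette_score(pc1, labels))


def phase_tetraploid(
    normalized: HiCMatrix,
    contigs: ContigSet,
    ploidy: int = 4,
    min_contig_len: float = DEFAULT_MIN_CONTIG_LEN,
    silhouette_min: float = 0.5,
    max_depth: int = 6,
    seed: int = 0,
) -> HaplotypeAssignment:
    """Cluster single-copy contigs into ``ploidy`` haplotypes; place multi-copy
    contigs at the nearest cluster centres.

    Steps per chromosome: (1) PCA of residual link profiles, k-means with
    k = ploidy on PC1/PC2; (2) clusters whose cumulative length is a multiple
    of one haplotype's expected share are re-split by a sub-PCA; (3) every
    pair of haplotype clusters must separate in a pairwise PCA (silhouette
    on PC1 > ``silhouette_min``), failing pairs are re-clustered recursively
    up to ``max_depth``, irreducible pairs are reported in the diagnostics;
    (4) a contig of copy number c is assigned the c nearest haplotype
    centres in PC space.
    """
    if ploidy < 2:
        raise ValueError("ploidy must be >= 2")
    df = contigs.df.loc[[c for c in normalized.ids]]
    rows: list[dict] = []
    diagnostics: dict = {"inseparable_pairs": [], "recursion_used": False}

    for chrom, sub in df.groupby("chrom", sort=False):
        sc = sub[(sub["copy_number"] == 1) & (sub["length"] >= min_contig_len)]
        sc_ids = sc["contig"].tolist()
        if len(sc_ids) < 2 * ploidy:
            raise ValueError(
                f"chromosome {chrom}: too few single-copy contigs for {ploidy} haplotypes"
            )
        feats = _profiles(normalized, sc_ids, sc_ids)
        pca = PCA(n_components=2, random_state=seed).fit(feats)
        pcs = pca.transform(feats)
        km = KMeans(n_clusters=ploidy, n_init=50, random_state=seed).fit(pcs[:, :2])
        clusters: list[list[str]] = [
            [sc_ids[i] for i in np.flatnonzero(km.labels_ == k)] for k in range(ploidy)
        ]
        clusters = [c for c in clusters if c]
        lengths = sc.set_index("contig")["length"]
        expected = lengths.sum() / ploidy
        method = {c: "kmeans" for c in sc_ids}

        def resplit(ids: list[str], k: int, pc1_only: bool = False) -> list[list[str]]:
            f = _profiles(normalized, ids, ids)
            p = PCA(n_components=min(2, len(ids) - 1), random_state=seed).fit_transform(f)
            if pc1_only:
                p = p[:, :1]
            lab = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(p).labels_
            return [[ids[i] for i in np.flatnonzero(lab == j)] for j in range(k)]

        # cumulative-length inspection: split clusters holding >1 haplotype
        for _ in range(max_depth):
            mult = [max(1, round(sum(lengths[c] for c in cl) / expected)) for cl in clusters]
            if len(clusters) >= ploidy and all(m == 1 for m in mult):
                break
            split_idx = next((i for i, m in enumerate(mult) if m > 1 and len(clusters[i]) >= 2 * m), None)
            if split_idx is None:
                break
            mixed = clusters.pop(split_idx)
            parts = resplit(mixed, mult[split_idx])
            for part in parts:
                for c in part:
                    method[c] = "recursive"
            clusters.extend([p for p in parts if p])
            diagnostics["recursion_used"] = True
        # too many clusters: merge the least-separated pair
        while len(clusters) > ploidy:
            worst, score = None, np.inf
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    s = _split_silhouette(normalized, clusters[a], clusters[b])
                    if s < score:
                        worst, score = (a, b), s
            a, b = worst
            clusters[a] = clusters[a] + clusters[b]
            clusters.pop(b)

        # pairwise-PCA refinement: re-split every cluster pair on PC1 of its
        # own sub-matrix, adopting any split that sharpens the separation;
        # iterate until the clustering is stable under all pairwise PCAs
        for _ in range(max_depth):
            improved = False
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    current = _split_silhouette(normalized, clusters[a], clusters[b])
                    parts = resplit(clusters[a] + clusters[b], 2, pc1_only=True)
                    if not all(parts) or sorted(map(sorted, parts)) == sorted(
                        map(sorted, [clusters[a], clusters[b]])
                    ):
                        continue
                    candidate = _split_silhouette(normalized, parts[0], parts[1])
                    if candidate > current + 1e-9:
                        moved = set(clusters[a]).symmetric_difference(parts[0])
                        for c in moved & (set(clusters[a]) | set(clusters[b])):
                            method[c] = "recursive"
                        clusters[a], clusters[b] = parts
                        diagnostics["recursion_used"] = True
                        improved = True
            if not improved:
                break
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                if _split_silhouette(normalized, clusters[a], clusters[b]) <= silhouette_min:
                    diagnostics["inseparable_pairs"].append((chrom, a + 1, b + 1))

        # deterministic haplotype labels: order clusters by leftmost member position
        order = np.argsort(
            [min(sub.loc[c, "position"] for c in cl) for cl in clusters]
        )
        clusters = [clusters[i] for i in order]
        for label, cl in enumerate(clusters, start=1):
            for c in cl:
                rows.append(
                    dict(contig=c, chrom=chrom, haps=(label,), method=method[c], flag="")
                )

        # multi-copy contigs -> c nearest haplotype centres in PC space
        centres = np.vstack(
            [pcs[[sc_ids.index(c) for c in cl]].mean(axis=0) for cl in clusters]
        )
        multi = sub[(sub["copy_number"] > 1) & (sub["length"] >= min_contig_len)]
        for contig, row in multi.iterrows():
            proj = pca.transform(_profiles(normalized, [contig], sc_ids))[0]
            dist = np.linalg.norm(centres - proj, axis=1)
            k = int(row["copy_number"])
            haps = tuple(sorted(int(i) + 1 for i in np.argsort(dist)[:k]))
            rows.append(dict(contig=contig, chrom=chrom, haps=haps, method="multicopy", flag=""))
        short = sub[sub["length"] < min_contig_len]
        for contig in short["contig"]:
            rows.append(dict(contig=contig, chrom=chrom, haps=None, method="", flag="short"))

    return HaplotypeAssignment(df=pd.DataFrame(rows), ploidy=ploidy, diagnostics=diagnostics)


def rescue_unphased(
    assignment: HaplotypeAssignment,
    matrix: HiCMatrix,
    contigs: ContigSet,
) -> HaplotypeAssignment:
    """Assign leftover contigs by Hi-C majority rule.

    Each unassigned contig receives the haplotype(s) with the largest summed
    link count to already-assigned contigs on its chromosome (top
    ``copy_number`` haplotypes).  Ties at the decision boundary and contigs
    without links stay unassigned, flagged "tie" / "no_links".
    """
    df = assignment.df.copy()
    assigned = df[df["haps"].notna()]
    hap_members: dict[str, dict[int, list[int]]] = {}
    for chrom, sub in assigned.groupby("chrom", sort=False):
        per_hap: dict[int, list[int]] = {}
        for contig, row in sub.iterrows():
            for h in row["haps"]:
                per_hap.setdefault(h, []).append(matrix.ids.index(contig))
        hap_members[chrom] = per_hap

    new_rows = []
    for contig in assignment.unassigned:
        chrom = df.loc[contig, "chrom"]
        per_hap = hap_members.get(chrom, {})
        if not per_hap:
            new_rows.append((contig, None, "", "no_links"))
            continue
        i = matrix.ids.index(contig)
        scores = {
            h: float(matrix.counts[i, idx].sum()) for h, idx in per_hap.items()
        }
        k = int(contigs.df.loc[contig, "copy_number"])
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        if all(v == 0 for v in scores.values()):
            new_rows.append((contig, None, "", "no_links"))
        elif len(ranked) > k and ranked[k - 1][1] == ranked[k][1]:
            new_rows.append((contig, None, "", "tie"))
        else:
            haps = tuple(sorted(h for h, _ in ranked[:k]))
            new_rows.append((contig, haps, "majority", ""))
    updates = {c: (h, m, f) for c, h, m, f in new_rows}
    haps_col, meth_col, flag_col = [], [], []
    for contig, row in df.iterrows():
        h, m, f = updates.get(contig, (row["haps"], row["method"], row["flag"]))
        haps_col.append(h)
        meth_col.append(m)
        flag_col.append(f)
    df = df.assign(haps=pd.Series(haps_col, index=df.index, dtype=object),
                   method=meth_col, flag=flag_col)
    return HaplotypeAssignment(
        df=df.reset_index(drop=True), ploidy=assignment.ploidy, diagnostics=assignment.diagnostics
    )


def assignment_accuracy(
    assignment: HaplotypeAssignment, contigs: ContigSet, weight_by_length: bool = False
) -> float:
    """Fraction of assigned contigs whose haplotype set matches truth, after
    optimal (Hungarian) label matching per chromosome."""
    df = assignment.df
    total_w = 0.0
    correct_w = 0.0
    for chrom, sub in df[df["haps"].notna()].groupby("chrom", sort=False):
        truth = contigs.df.loc[sub.index, "true_haps"]
        labels = sorted({h for t in truth if t for h in t})
        plabels = sorted({h for p in sub["haps"] for h in p})
        conf = np.zeros((len(labels), len(plabels)))
        for contig, row in sub.iterrows():
            t = truth.loc[contig]
            if t is None:
                continue
            for th in t:
                for ph in row["haps"]:
                    conf[labels.index(th), plabels.index(ph)] += 1
        ti, pi = linear_sum_assignment(-conf)
        mapping = {plabels[p]: labels[t] for t, p in zip(ti, pi)}
        for contig, row in sub.iterrows():
            t = truth.loc[contig]
            if t is None:
                continue
            w = float(contigs.df.loc[contig, "length"]) if weight_by_length else 1.0
            total_w += w
            mapped = {mapping.get(h) for h in row["haps"]}
            if mapped == set(t):
                correct_w += w
    return correct_w / total_w if total_w else float("nan")
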