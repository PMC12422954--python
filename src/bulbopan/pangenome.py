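"""Single-copy pangenome construction and probe-region selection.

Single-copy sequence is defined by k-mer occurrence: a region is single
copy when every k-mer covering it occurs no more often than allowed
(once within one haplotype for probe design; up to ploidy times within a
genotype's combined haplotypes for the pangenome).  Single-copy fragments
from all haplotypes are then clustered greedily at 95% identity, and
pangenome composition is summarized as growth curves and core/shell/cloud
classes, including haplotype-specific core sequence (genotype-level core
absent from one haploid of a genotype).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROBE_MIN_LEN = 45
DEFAULT_K = 31
DEFAULT_IDENTITY = 0.95
MIN_FRAGMENT = 100

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an id -> uppercase sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | list[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def cluster_table(clusters: list["PanCluster"]) -> pd.DataFrame:
    """Flat member table of a clustering (one row per member sequence)."""
    rows = [
        dict(cluster_id=c.cluster_id, member=name, unit=unit, length=length,
             representative=c.representative,
             representative_length=c.representative_length)
        for c in clusters
        for name, unit, length in c.members
    ]
    return pd.DataFrame(
        rows, columns=["cluster_id", "member", "unit", "length",
                       "representative", "representative_length"]
    )


@dataclass
class SingleCopyRegions:
    """Unmasked (single-copy) intervals per sequence, 0-based half-open."""

    regions: dict[str, list[tuple[int, int]]]
    sequences: dict[str, str] = field(default_factory=dict)
    k: int = DEFAULT_K
    max_occurrences: int = 1

    def __post_init__(self) -> None:
        for name, ivs in self.regions.items():
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping intervals in {name}")

    def total_length(self) -> int:
        return sum(e - s for ivs in self.regions.values() for s, e in ivs)

    def fragments(self, min_len: int = 0) -> list[tuple[str, int, int, str]]:
        """(name, start, end, sequence) for every interval of length >= min_len."""
        out = []
        for name, ivs in self.regions.items():
            seq = self.sequences.get(name, "")
            for s, e in ivs:
                if e - s >= min_len:
                    out.append((name, s, e, seq[s:e] if seq else ""))
        return out

    def to_bed(self, path) -> None:
        rows = [
            (name, s, e) for name, ivs in self.regions.items() for s, e in ivs
        ]
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
            path, sep="\t", index=False, header=False
        )


def _count_kmers(seqs: dict[str, str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs.values():
        s = seq.upper()
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" in km:
                continue
            rc = revcomp(km)
            can = km if km <= rc else rc
            counts[can] = counts.get(can, 0) + 1
    return counts


def _unmasked_intervals(
    seq: str, counts: dict[str, int], k: int, max_occ: int
) -> list[tuple[int, int]]:
    s = seq.upper()
    n = len(s)
    if n < k:
        return []
    n_kmers = n - k + 1
    bad = np.zeros(n_kmers, dtype=bool)
    for i in range(n_kmers):
        km = s[i : i + k]
        if "N" in km:
            bad[i] = True
            continue
        rc = revcomp(km)
        can = km if km <= rc else rc
        bad[i] = counts[can] > max_occ
    # base i is masked iff any bad k-mer covers it
    cs = np.concatenate([[0], np.cumsum(bad)])
    lo = np.maximum(np.arange(n) - k + 1, 0)
    hi = np.minimum(np.arange(n), n_kmers - 1)
    masked = (cs[hi + 1] - cs[lo]) > 0
    intervals = []
    start = None
    for i, m in enumerate(~masked):
        if m and start is None:
            start = i
        elif not m and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, n))
    return intervals


def mask_repeat_kmers(
    sequence: str | dict[str, str], k: int = DEFAULT_K, max_occurrences: int = 1
) -> SingleCopyRegions:
    """Mask every region covered by a k-mer occurring more than
    ``max_occurrences`` times (canonical, strand-collapsed) genome-wide.

    N-containing k-mers are always masked.  Sequences shorter than ``k``
    yield no unmasked intervals.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    seqs = {"seq": sequence} if isinstance(sequence, str) else dict(sequence)
    for name, s in seqs.items():
        if set(s.upper()) - set("ACGTN"):
            raise ValueError(f"sequence {name} contains non-ACGTN characters")
    counts = _count_kmers(seqs, k)
    regions = {
        name: _unmasked_intervals(s, counts, k, max_occurrences)
        for name, s in seqs.items()
    }
    return SingleCopyRegions(
        regions=regions,
        sequences={n: s.upper() for n, s in seqs.items()},
        k=k,
        max_occurrences=max_occurrences,
    )


def probe_regions(
    regions: SingleCopyRegions, min_len: int = PROBE_MIN_LEN
) -> pd.DataFrame:
    """Candidate FISH-probe intervals: unmasked runs strictly longer than
    ``min_len`` bp."""
    rows = [
        (name, s, e, e - s)
        for name, ivs in regions.regions.items()
        for s, e in ivs
        if e - s > min_len
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])


def single_copy_by_occurrence(
    haplotype_seqs: dict[str, str | dict[str, str]],
    k: int = DEFAULT_K,
    ploidy: int = 2,
    max_occurrences: int | None = None,
) -> dict[str, SingleCopyRegions]:
    """Genotype-level single-copy regions from the combined haplotypes.

    k-mer occurrences are counted across all supplied haplotypes of one
    genotype; a region whose k-mers occur more often than the ploidy allows
    (>= 3 copies in a diploid, >= 5 in a tetraploid) is excluded.  Pass
    ``max_occurrences`` to override the ploidy-derived cutoff.
    """
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    if len(haplotype_seqs) != ploidy:
        raise ValueError(f"expected {ploidy} haplotypes, got {len(haplotype_seqs)}")
    cutoff = ploidy if max_occurrences is None else max_occurrences

    flat: dict[tuple[str, str], str] = {}
    for hap, v in haplotype_seqs.items():
        if isinstance(v, str):
            flat[(hap, "seq")] = v
        else:
            for name, s in v.items():
                flat[(hap, name)] = s
    counts = _count_kmers({f"{h}|{n}": s for (h, n), s in flat.items()}, k)

    out: dict[str, SingleCopyRegions] = {}
    for hap in haplotype_seqs:
        names = {n: s for (h, n), s in flat.items() if h == hap}
        regions = {
            n: _unmasked_intervals(s, counts, k, cutoff) for n, s in names.items()
        }
        out[hap] = SingleCopyRegions(
            regions=regions,
            sequences={n: s.upper() for n, s in names.items()},
            k=k,
            max_occurrences=cutoff,
        )
    return out


@dataclass
class PanCluster:
    """A cluster of mutually similar single-copy fragments."""

    cluster_id: int
    members: list[tuple[str, str, int]]  # (fragment name, unit label, length)
    representative: str
    representative_length: int

    @property
    def units(self) -> frozenset[str]:
        return frozenset(u for _, u, _ in self.members)


def _identity(query: str, target: str) -> float:
    """Best semi-global identity of ``query`` within ``target`` (both strands)."""
    best = 0.0
    for q in (query, revcomp(query)):
        res = edlib.align(q, target, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            best = max(best, 1 - res["editDistance"] / len(query))
    return best


def cluster_single_copy(
    fragments: list[tuple[str, str, str]],
    identity: float = DEFAULT_IDENTITY,
    min_len: int = MIN_FRAGMENT,
    coverage: float = 0.8,
) -> list[PanCluster]:
    """Greedy identity clustering of single-copy fragments.

    ``fragments`` entries are ``(name, unit, sequence)`` where unit is the
    haplotype or genotype label.  Sequences are sorted by length descending;
    each joins the first cluster whose representative matches at
    >= ``identity`` over >= ``coverage`` of the shorter sequence (semi-global
    alignment of the shorter within the longer covers it fully), otherwise it
    founds a new cluster.  Fragments shorter than ``min_len`` are dropped.
    """
    usable = [
        (name, unit, seq.upper())
        for name, unit, seq in fragments
        if len(seq) >= min_len
    ]
    usable.sort(key=lambda t: -len(t[2]))
    clusters: list[PanCluster] = []
    reps: list[str] = []
    for name, unit, seq in usable:
        placed = False
        for ci, rep in enumerate(reps):
            # semi-global alignment embeds the (shorter) query fully in the
            # representative, so query coverage is 1 >= the coverage floor
            if _identity(seq, rep) >= identity:
                clusters[ci].members.append((name, unit, len(seq)))
                placed = True
                break
        if not placed:
            clusters.append(
                PanCluster(
                    cluster_id=len(clusters),
                    members=[(name, unit, len(seq))],
                    representative=name,
                    representative_length=len(seq),
                )
            )
            reps.append(seq)
    return clusters


def growth_curve(
    clusters: list[PanCluster],
    units: list[str],
    n_permutations: int = 100,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Cumulative non-redundant pangenome size over ordered genome additions.

    For each permutation of ``units``, the size after m genomes is the sum of
    representative lengths of clusters first contributed by the leading m
    genomes.  Returns mean and quartiles per m over the permutations (all
    ``len(units)!`` orderings when ``exhaustive``).
    """
    presence = [c.units for c in clusters]
    lengths = np.array([c.representative_length for c in clusters])
    if exhaustive:
        orders = list(itertools.permutations(units))
    else:
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(units)) for _ in range(n_permutations)]
    curves = np.zeros((len(orders), len(units)))
    for oi, order in enumerate(orders):
        first_seen = np.full(len(clusters), len(units))
        for m, unit in enumerate(order):
            for ci, pres in enumerate(presence):
                if unit in pres and m < first_seen[ci]:
                    first_seen[ci] = m
        for m in range(len(units)):
            curves[oi, m] = lengths[first_seen <= m].sum()
    return pd.DataFrame(
        {
            "m": np.arange(1, len(units) + 1),
            "mean": curves.mean(axis=0),
            "q25": np.quantile(curves, 0.25, axis=0),
            "median": np.quantile(curves, 0.5, axis=0),
            "q75": np.quantile(curves, 0.75, axis=0),
        }
    )


@dataclass
class PanClassification:
    """Core / shell / cloud classes at haplotype and genotype level."""

    table: pd.DataFrame  # cluster_id, hap_presence, genotype_presence, class_hap, class_genotype
    hap_specific_core: pd.DataFrame  # cluster_id, genotype, missing_hap

    def class_counts(self, level: str = "genotype") -> pd.Series:
        col = "class_genotype" if level == "genotype" else "class_hap"
        return self.table[col].value_counts()


def classify_presence(
    clusters: list[PanCluster], genotype_of_hap: dict[str, str]
) -> PanClassification:
    """Classify clusters as core (all units), cloud (exactly one) or shell.

    Classification is done both at haplotype level and at genotype level
    (genotype presence = union of its haplotypes').  A genotype-level core
    cluster absent from one haploid of a genotype is flagged as
    haplotype-specific core sequence for that genotype.
    """
    all_haps = set(genotype_of_hap)
    all_genotypes = set(genotype_of_hap.values())

    def classify(present: frozenset, universe: set) -> str:
        if present >= universe:
            return "core"
        if len(present) == 1:
            return "cloud"
        return "shell"

    rows = []
    hs_rows = []
    for c in clusters:
        haps = c.units & all_haps
        genos = frozenset(genotype_of_hap[h] for h in haps)
        cls_h = classify(frozenset(haps), all_haps)
        cls_g = classify(genos, all_genotypes)
        rows.append(
            dict(
                cluster_id=c.cluster_id,
                hap_presence=frozenset(haps),
                genotype_presence=genos,
                class_hap=cls_h,
                class_genotype=cls_g,
            )
        )
        if cls_g == "core":
            for hap, geno in genotype_of_hap.items():
                if hap not in haps:
                    hs_rows.append(dict(cluster_id=c.cluster_id, genotype=geno, missing_hap=hap))
    return PanClassification(
        table=pd.DataFrame(rows),
        hap_specific_core=pd.DataFrame(hs_rows, columns=["cluster_id", "genotype", "missing_hap"]),
    )
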