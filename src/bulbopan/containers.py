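"""In-memory containers for the pipeline's standard inputs.

All coordinates are 0-based, half-open.  Haplotype calls in gamete matrices
are coded ``0`` (haplotype 1), ``1`` (haplotype 2) and ``-1`` (missing);
variant alleles are coded ``0``/``1`` with ``-1`` for missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class VariantMatrix:
    """Haplotypes x biallelic sites, with sorted positions.

    Parameters
    ----------
    haplotypes
        Haplotype identifiers (row labels).
    positions
        Site positions (bp), strictly increasing.
    genotypes
        ``(n_haplotypes, n_sites)`` int8 array of alleles in {0, 1, -1}.
    chrom
        Chromosome name the positions refer to.
    seq_length
        Length (bp) of the coordinate system, if known.
    """

    haplotypes: list[str]
    positions: np.ndarray
    genotypes: np.ndarray
    chrom: str = "chr1"
    seq_length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.haplotypes), self.positions.size):
            raise ValueError("genotype matrix shape does not match haplotypes x sites")
        if self.positions.size > 1 and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def index_of(self, haplotype: str) -> int:
        return self.haplotypes.index(haplotype)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.genotypes.T, columns=self.haplotypes, index=self.positions
        )
        df.index.name = "position"
        df.insert(0, "chrom", self.chrom)
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, seq_length: int | None = None) -> "VariantMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        chrom = str(df.pop("chrom").iloc[0]) if "chrom" in df else "chr1"
        return cls(
            haplotypes=list(df.columns),
            positions=df.index.to_numpy(),
            genotypes=df.to_numpy().T,
            chrom=chrom,
            seq_length=seq_length,
        )

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal phased GT-only VCF (one pseudo-sample per haplotype)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if self.seq_length is not None:
                fh.write(f"##contig=<ID={self.chrom},length={self.seq_length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            cols = "\t".join(self.haplotypes)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
            for j, pos in enumerate(self.positions):
                gts = "\t".join(
                    "." if g == MISSING else str(int(g)) for g in self.genotypes[:, j]
                )
                fh.write(f"{self.chrom}\t{pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


@dataclass
class ContigSet:
    """Contigs with lengths, chromosomal placement and copy numbers.

    ``df`` columns: contig, chrom, start, end, length, position (midpoint, bp),
    copy_number, true_haps (tuple of haplotype labels or None).
    """

    df: pd.DataFrame
    ploidy: int = 2
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    REQUIRED = ("contig", "chrom", "start", "end", "length", "position", "copy_number")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"ContigSet missing columns: {missing}")
        if (self.df["length"] <= 0).any():
            raise ValueError("contig lengths must be positive")
        if (self.df["copy_number"] > self.ploidy).any():
            raise ValueError("copy_number may not exceed ploidy")
        if "true_haps" not in self.df.columns:
            self.df = self.df.assign(true_haps=None)
        self.df = self.df.set_index("contig", drop=False)

    @property
    def ids(self) -> list[str]:
        return list(self.df["contig"])

    def lengths(self) -> pd.Series:
        return self.df["length"]

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["true_haps"] = out["true_haps"].map(
            lambda h: ",".join(map(str, h)) if h else ""
        )
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, ploidy: int = 2) -> "ContigSet":
        df = pd.read_csv(path, sep="\t")
        if "true_haps" in df.columns:
            df["true_haps"] = df["true_haps"].map(
                lambda s: tuple(str(s).split(",")) if isinstance(s, str) and s else None
            )
        return cls(df=df, ploidy=ploidy)


@dataclass
class HiCMatrix:
    """Symmetric contig-by-contig Hi-C link counts."""

    ids: list[str]
    counts: np.ndarray
    border_restricted: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.ids)
        if self.counts.shape != (n, n):
            raise ValueError("count matrix must be square over ids")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("count matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be zero")

    def submatrix(self, ids: Sequence[str]) -> "HiCMatrix":
        idx = [self.ids.index(i) for i in ids]
        return HiCMatrix(list(ids), self.counts[np.ix_(idx, idx)], self.border_restricted)

    def to_links_tsv(self, path: str | Path) -> None:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.counts[i, j] != 0:
                    rows.append((self.ids[i], self.ids[j], self.counts[i, j]))
        pd.DataFrame(rows, columns=["contig_i", "contig_j", "count"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_links_tsv(cls, path: str | Path, ids: Sequence[str] | None = None) -> "HiCMatrix":
        df = pd.read_csv(path, sep="\t")
        if ids is None:
            ids = sorted(set(df["contig_i"]) | set(df["contig_j"]))
        ids = list(ids)
        pos = {c: k for k, c in enumerate(ids)}
        counts = np.zeros((len(ids), len(ids)))
        for ci, cj, n in df.itertuples(index=False):
            counts[pos[ci], pos[cj]] += n
            counts[pos[cj], pos[ci]] += n
        np.fill_diagonal(counts, 0)
        return cls(ids, counts)


@dataclass
class GameteMatrix:
    """Gametes x ordered genomic bins of haplotype calls.

    ``bins`` columns: chrom, start, end (sorted, non-overlapping per
    chromosome).  ``calls`` is ``(n_gametes, n_bins)`` int8 in {0, 1, -1}.
    """

    gametes: list[str]
    bins: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.gametes), len(self.bins)):
            raise ValueError("call matrix shape must be gametes x bins")
        for _, grp in self.bins.groupby("chrom", sort=False):
            if (grp["start"].diff().dropna() <= 0).any():
                raise ValueError("bins must be sorted within chromosomes")
            if (grp["end"].shift() > grp["start"]).fillna(False).any():
                raise ValueError("bins must not overlap")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_tsv(self, path: str | Path) -> None:
        labels = [
            f"{c}:{s}-{e}" for c, s, e in self.bins[["chrom", "start", "end"]].itertuples(index=False)
        ]
        df = pd.DataFrame(self.calls.astype(object), index=self.gametes, columns=labels)
        df = df.replace({0: "0", 1: "1", MISSING: "NA"})
        df.index.name = "gamete"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GameteMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        bins = []
        for lab in df.columns:
            chrom, span = lab.rsplit(":", 1)
            s, e = span.split("-")
            bins.append((chrom, int(s), int(e)))
        calls = df.replace({"NA": MISSING}).astype(np.int8).to_numpy()
        return cls(
            gametes=list(df.index.astype(str)),
            bins=pd.DataFrame(bins, columns=["chrom", "start", "end"]),
            calls=calls,
        )


@dataclass
class DepthTrack:
    """Per-window read counts over a hybrid (recipient + donor) genome.

    ``df`` columns: chrom, start, end, count, origin ("recipient" | "donor")
    and, after normalization, ``normalized``.
    """

    df: pd.DataFrame
    total_reads: int | None = None

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "count", "origin"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"DepthTrack requires columns {sorted(need)}")
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be non-negative")

    def to_bed(self, path: str | Path) -> None:
        cols = ["chrom", "start", "end", "count", "origin"]
        if "normalized" in self.df.columns:
            cols.append("normalized")
        self.df[cols].to_csv(path, sep="\t", index=False, header=True)

    @classmethod
    def from_bed(cls, path: str | Path, total_reads: int | None = None) -> "DepthTrack":
        return cls(pd.read_csv(path, sep="\t"), total_reads=total_reads)


def _jsonable(o):
    if hasattr(o, "__dataclass_fields__"):
        return {k: _jsonable(getattr(o, k)) for k in o.__dataclass_fields__}
    if isinstance(o, dict):
        # tuple keys (e.g. group pairs) become "a|b"
        return {
            "|".join(map(str, k)) if isinstance(k, tuple) else str(k): _jsonable(v)
            for k, v in o.items()
        }
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple, list)):
        return [_jsonable(v) for v in o]
    return o


def dump_json(obj, path: str | Path) -> None:
    """Write a truth/report object (dataclass or dict) as JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1)
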