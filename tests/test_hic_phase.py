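"""Tests of Hi-C border-matrix construction, Rabl normalization and phasing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bulbopan import hic, simulate as sim
from bulbopan.containers import ContigSet, HiCMatrix


def _contigs(entries, ploidy=2, chrom_lengths=None):
    """entries: list of (id, chrom, start, end, copy_number, true_haps)."""
    rows = [
        dict(
            contig=c, chrom=ch, start=s, end=e, length=e - s,
            position=(s + e) // 2, copy_number=cn, true_haps=th,
        )
        for c, ch, s, e, cn, th in entries
    ]
    return ContigSet(df=pd.DataFrame(rows), ploidy=ploidy, chrom_lengths=chrom_lengths or {})


class TestBorderMatrix:
    CS = [
        ("a", "chr1", 0, 5_000_000, 1, (1,)),
        ("b", "chr1", 5_000_000, 10_000_000, 1, (2,)),
        ("c", "chr1", 10_000_000, 13_000_000, 1, (1,)),
    ]

    def test_interior_positions_excluded_border_included(self):
        cs = _contigs(self.CS)
        links = pd.DataFrame(
            dict(contig_i=["a", "a"], pos_i=[2_500_000, 1_900_000],
                 contig_j=["b", "b"], pos_j=[100, 100])
        )
        mat = hic.build_border_matrix(links, cs)
        # 2.5 Mb is interior on a 5-Mb contig; 1.9 Mb is within 2 Mb of an end
        assert mat.counts[0, 1] == 1

    def test_short_contig_fully_within_border(self):
        cs = _contigs(self.CS)
        links = pd.DataFrame(
            dict(contig_i=["c"], pos_i=[1_500_000], contig_j=["a"], pos_j=[0])
        )
        mat = hic.build_border_matrix(links, cs)
        assert mat.counts[2, 0] == 1  # every position of a 3-Mb contig qualifies

    def test_empty_links_give_zero_matrix(self):
        cs = _contigs(self.CS)
        links = pd.DataFrame(columns=["contig_i", "pos_i", "contig_j", "pos_j"])
        mat = hic.build_border_matrix(links, cs)
        assert mat.counts.sum() == 0
        assert mat.border_restricted

    def test_unknown_contig_rejected(self):
        cs = _contigs(self.CS)
        links = pd.DataFrame(dict(contig_i=["zz"], pos_i=[0], contig_j=["a"], pos_j=[0]))
        with pytest.raises(ValueError, match="unknown contigs"):
            hic.build_border_matrix(links, cs)


class TestRablNormalize:
    def test_pure_decay_leaves_no_distance_signal(self):
        rng = np.random.default_rng(0)
        n = 50
        pos = np.sort(rng.uniform(0, 200e6, n))
        entries = [
            (f"c{i}", "chr1", int(p) - 500_000, int(p) + 500_000, 1, (1,))
            for i, p in enumerate(pos)
        ]
        cs = _contigs(entries, chrom_lengths={"chr1": 200_000_000})
        d = np.abs(pos[:, None] - pos[None, :])
        counts = np.round(200 * np.exp(-d / 50e6))
        np.fill_diagonal(counts, 0)
        mat = HiCMatrix([f"c{i}" for i in range(n)], counts)
        norm, diag = hic.rabl_normalize(mat, cs)
        iu, ju = np.triu_indices(n, k=1)
        r = np.corrcoef(d[iu, ju], norm.counts[iu, ju])[0, 1]
        assert abs(r) < 0.05
        assert diag["r2"] > 0.9

    def test_constant_matrix_residuals_zero(self):
        entries = [(f"c{i}", "chr1", i * 10**6, (i + 1) * 10**6, 1, (1,)) for i in range(6)]
        cs = _contigs(entries)
        counts = np.full((6, 6), 7.0)
        np.fill_diagonal(counts, 0)
        mat = HiCMatrix([f"c{i}" for i in range(6)], counts)
        norm, _ = hic.rabl_normalize(mat, cs)
        # intercept absorbs a constant up to collinearity with the predictors
        assert np.abs(norm.counts).max() < 0.2

    def test_all_zero_matrix_warns_and_returns_zeros(self):
        entries = [(f"c{i}", "chr1", i * 10**6, (i + 1) * 10**6, 1, (1,)) for i in range(4)]
        cs = _contigs(entries)
        mat = HiCMatrix([f"c{i}" for i in range(4)], np.zeros((4, 4)))
        with pytest.warns(UserWarning, match="all-zero"):
            norm, _ = hic.rabl_normalize(mat, cs)
        assert norm.counts.sum() == 0

    def test_haplotype_boost_survives_normalization(self, diploid_setup):
        cs, _, norm, _ = diploid_setup
        haps = list(cs.df["true_haps"])
        chroms = list(cs.df["chrom"])
        within, cross = [], []
        for i, j in itertools.combinations(range(len(norm.ids)), 2):
            if chroms[i] != chroms[j]:
                continue
            (within if haps[i] == haps[j] else cross).append(norm.counts[i, j])
        assert np.mean(within) > np.mean(cross)


class TestPhaseDiploid:
    def test_block_diagonal_matrix_recovers_blocks(self):
        entries = [(f"c{i}", "chr1", i * 2 * 10**6, (i * 2 + 1) * 10**6, 1, (1,)) for i in range(10)]
        cs = _contigs(entries)
        counts = np.zeros((10, 10))
        for i in range(5):
            for j in range(5):
                if i != j:
                    counts[i, j] = counts[i + 5, j + 5] = 10.0
        mat = HiCMatrix([f"c{i}" for i in range(10)], counts)
        asn = hic.phase_diploid(mat, cs)
        groups = {}
        for c, row in asn.assigned.iterrows():
            groups.setdefault(row["haps"], []).append(c)
        parts = sorted(sorted(v) for v in groups.values())
        assert parts == [[f"c{i}" for i in range(5)], sorted(f"c{i}" for i in range(5, 10))]

    def test_synthetic_diploid_fully_recovered(self, diploid_setup):
        cs, mat, norm, _ = diploid_setup
        asn = hic.rescue_unphased(hic.phase_diploid(norm, cs), mat, cs)
        assert hic.assignment_accuracy(asn, cs) == 1.0

    def test_short_contig_left_for_rescue(self):
        entries = [(f"c{i}", "chr1", i * 2 * 10**6, (i * 2 + 1) * 10**6, 1, (1 + i % 2,)) for i in range(8)]
        entries.append(("tiny", "chr1", 90_000_000, 90_800_000, 1, (1,)))
        cs = _contigs(entries)
        mat = sim.make_hic(cs, intra_boost=5.0, seed=1)
        norm, _ = hic.rabl_normalize(mat, cs)
        asn = hic.phase_diploid(norm, cs)
        assert "tiny" in asn.unassigned
        assert asn.df.loc["tiny", "flag"] == "short"

    def test_under_determined_chromosome_refused(self):
        entries = [(f"c{i}", "chr1", i * 2 * 10**6, (i * 2 + 1) * 10**6, 1, (1,)) for i in range(3)]
        cs = _contigs(entries)
        mat = HiCMatrix([f"c{i}" for i in range(3)], np.zeros((3, 3)))
        with pytest.raises(ValueError, match="under-determined"):
            hic.phase_diploid(mat, cs)

    def test_partition_attains_exhaustive_link_sum_optimum(self):
        """The PC1 split maximizes within-group link weight (10-contig oracle)."""
        cs = sim.make_assembly_sim(seed=41, ploidy=2, n_contigs=5, chrom_lengths={"chr1": 50_000_000})
        mat = sim.make_hic(cs, intra_boost=5.0, rabl_scale=50e6, mean_links=100.0, seed=42)
        norm, _ = hic.rabl_normalize(mat, cs)
        asn = hic.phase_diploid(norm, cs)
        ids = list(asn.assigned.index)
        idx = [mat.ids.index(c) for c in ids]
        sub = mat.counts[np.ix_(idx, idx)]

        def within_sum(labels):
            s = 0.0
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    if labels[a] == labels[b]:
                        s += sub[a, b]
            return s

        pred = [asn.assigned.loc[c, "haps"] for c in ids]
        # exhaustive search over balanced bipartitions (each haplotype tiles
        # the chromosome with the same number of contigs); the unconstrained
        # maximum is the degenerate single group
        half = len(ids) // 2
        best = max(
            within_sum(lab)
            for m in range(2 ** (len(ids) - 1))
            if sum(lab := [(m >> i) & 1 for i in range(len(ids))]) == half
        )
        assert within_sum(pred) == best

    def test_boost_monotonicity(self):
        means = []
        for boost in (1.5, 3, 5, 10):
            accs = []
            for seed in range(10):
                cs = sim.make_assembly_sim(
                    seed=seed, ploidy=2, n_contigs=20, chrom_lengths={"chr1": 80_000_000}
                )
                mat = sim.make_hic(cs, intra_boost=boost, seed=seed + 100)
                norm, _ = hic.rabl_normalize(mat, cs)
                asn = hic.rescue_unphased(hic.phase_diploid(norm, cs), mat, cs)
                accs.append(hic.assignment_accuracy(asn, cs))
            means.append(np.mean(accs))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestPhaseTetraploid:
    def test_recovers_truth_with_ibd_tract(self, tetraploid_setup):
        cs, mat, norm = tetraploid_setup
        asn = hic.rescue_unphased(hic.phase_tetraploid(norm, cs), mat, cs)
        assert hic.assignment_accuracy(asn, cs) >= 0.95
        assert not asn.diagnostics["inseparable_pairs"]

    def test_copy_two_contigs_get_two_haplotypes(self, tetraploid_setup):
        cs, mat, norm = tetraploid_setup
        asn = hic.phase_tetraploid(norm, cs)
        multi = asn.df[asn.df["method"] == "multicopy"]
        assert len(multi) > 0
        assert all(len(h) == 2 for h in multi["haps"])

    def test_copy_four_contig_gets_all_haplotypes(self):
        cs = sim.make_assembly_sim(
            seed=51, ploidy=4, n_contigs=30, chrom_lengths={"chr1": 100_000_000},
            ibd_tracts=[("chr1", 40_000_000, 50_000_000, (1, 2, 3, 4))],
        )
        mat = sim.make_hic(cs, intra_boost=5.0, seed=52)
        norm, _ = hic.rabl_normalize(mat, cs)
        asn = hic.phase_tetraploid(norm, cs)
        quad = asn.df[[len(h) == 4 for h in asn.df["haps"].map(lambda h: h or ())]]
        assert len(quad) > 0
        assert all(h == (1, 2, 3, 4) for h in quad["haps"])

    def test_ploidy_two_reduces_to_diploid_partition(self, diploid_setup):
        cs, _, norm, _ = diploid_setup
        di = hic.phase_diploid(norm, cs)
        tet = hic.phase_tetraploid(norm, cs, ploidy=2)
        for chrom in ("chr1", "chr2"):
            d_lab = {c: r["haps"] for c, r in di.assigned.iterrows() if r["chrom"] == chrom and r["method"] == "pca"}
            t_lab = {c: tet.df.loc[c, "haps"] for c in d_lab}
            # same bipartition up to label swap
            pairs = {(d_lab[c], t_lab[c]) for c in d_lab}
            assert len({a for a, _ in pairs}) == 2
            assert all(len({b for a2, b in pairs if a2 == a}) == 1 for a, _ in pairs)


class TestRescue:
    def _setup(self, tie=False, zero=False):
        entries = [(f"c{i}", "chr1", i * 2 * 10**6, (i * 2 + 1) * 10**6, 1, (1 + i % 2,)) for i in range(4)]
        entries.append(("small", "chr1", 50_000_000, 50_500_000, 1, (1,)))
        cs = _contigs(entries)
        ids = [s[0] for s in entries]
        counts = np.zeros((5, 5))
        counts[0, 2] = counts[2, 0] = counts[1, 3] = counts[3, 1] = 20.0
        if not zero:
            counts[4, 0] = counts[0, 4] = 5.0 if tie else 10.0
            counts[4, 1] = counts[1, 4] = 5.0 if tie else 2.0
        mat = HiCMatrix(ids, counts)
        rows = pd.DataFrame(
            [
                dict(contig=f"c{i}", chrom="chr1", haps=(1 + i % 2,), method="pca", flag="")
                for i in range(4)
            ]
            + [dict(contig="small", chrom="chr1", haps=None, method="", flag="short")]
        )
        return hic.HaplotypeAssignment(df=rows, ploidy=2), mat, cs

    def test_majority_assignment(self):
        asn, mat, cs = self._setup()
        out = hic.rescue_unphased(asn, mat, cs)
        assert out.df.loc["small", "haps"] == (1,)
        assert out.df.loc["small", "method"] == "majority"

    def test_tie_stays_unassigned(self):
        asn, mat, cs = self._setup(tie=True)
        out = hic.rescue_unphased(asn, mat, cs)
        assert out.df.loc["small", "haps"] is None
        assert out.df.loc["small", "flag"] == "tie"

    def test_zero_links_flagged(self):
        asn, mat, cs = self._setup(zero=True)
        out = hic.rescue_unphased(asn, mat, cs)
        assert out.df.loc["small", "haps"] is None
        assert out.df.loc["small", "flag"] == "no_links"
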