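"""Tests of k-mer masking, identity clustering and pangenome classification."""

import itertools
from collections import Counter

import numpy as np
import pytest

from bulbopan import pangenome as pg
from conftest import mutate, random_seq


def brute_force_unmasked(seq, k, max_occ):
    """Independent oracle: dictionary k-mer counts, per-base cover check."""
    cnt = Counter()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            cnt[min(km, pg.revcomp(km))] += 1
    masked = np.zeros(len(seq), bool)
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km or cnt[min(km, pg.revcomp(km))] > max_occ:
            masked[i : i + k] = True
    ivs, start = [], None
    for i, keep in enumerate(~masked):
        if keep and start is None:
            start = i
        elif not keep and start is not None:
            ivs.append((start, i))
            start = None
    if start is not None:
        ivs.append((start, len(seq)))
    return ivs


class TestMaskRepeatKmers:
    def test_all_distinct_kmers_fully_unmasked(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 500)
        reg = pg.mask_repeat_kmers(seq, k=31)
        if reg.regions["seq"] == [(0, 500)]:
            assert reg.total_length() == 500

    @pytest.mark.parametrize("k", [31, 34])
    def test_tandem_duplication_masked_matches_oracle(self, k):
        rng = np.random.default_rng(2)
        u, dup = random_seq(rng, 300), random_seq(rng, 100)
        seq = u[:100] + dup + u[100:200] + dup + u[200:]
        reg = pg.mask_repeat_kmers(seq, k=k)
        assert reg.regions["seq"] == brute_force_unmasked(seq, k, 1)

    def test_n_runs_masked(self):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 100) + "N" * 10 + random_seq(rng, 100)
        reg = pg.mask_repeat_kmers(seq, k=31)
        for s, e in reg.regions["seq"]:
            assert "N" not in seq[s:e]

    def test_sequence_shorter_than_k_empty(self):
        assert pg.mask_repeat_kmers("ACGTACGTACGT", k=31).regions["seq"] == []

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            pg.mask_repeat_kmers("A" * 100, k=7)


class TestProbeRegions:
    def test_strict_length_cutoff(self):
        reg = pg.SingleCopyRegions(regions={"chr1": [(0, 46), (100, 145), (200, 500)]})
        out = pg.probe_regions(reg, min_len=45)
        assert list(out["start"]) == [0, 200]  # 46 bp kept, 45 bp dropped

    def test_empty_input(self):
        assert pg.probe_regions(pg.SingleCopyRegions(regions={})).empty


class TestSingleCopyByOccurrence:
    def test_diploid_occurrence_rule(self):
        rng = np.random.default_rng(4)
        shared = random_seq(rng, 200)  # once per haplotype: 2 copies, retained
        tripled = random_seq(rng, 100)  # 3 copies in the genotype: excluded
        h1 = shared + random_seq(rng, 100) + tripled
        h2 = shared + tripled + random_seq(rng, 100) + tripled
        out = pg.single_copy_by_occurrence({"h1": h1, "h2": h2}, k=31, ploidy=2)
        h1_unmasked = set()
        for s, e in out["h1"].regions["seq"]:
            h1_unmasked.update(range(s, e))
        assert set(range(0, 170)) <= h1_unmasked  # shared block interior stays
        tri_start = len(h1) - 100
        assert not h1_unmasked & set(range(tri_start + 31, len(h1) - 31))

    def test_tetraploid_occurrence_rule(self):
        rng = np.random.default_rng(5)
        shared = random_seq(rng, 200)  # once per haplotype: 4 copies, retained
        seqs = {f"h{i}": shared + random_seq(rng, 60) for i in range(1, 5)}
        out = pg.single_copy_by_occurrence(seqs, k=31, ploidy=4)
        assert all(reg.total_length() > 0 for reg in out.values())
        # a 5th copy flips the shared block to excluded
        seqs["h1"] = shared + seqs["h1"]
        out5 = pg.single_copy_by_occurrence(seqs, k=31, ploidy=4)
        for s, e in out5["h2"].regions["seq"]:
            assert e <= 31 or s >= 200 - 31  # nothing inside the shared block

    def test_wrong_haplotype_count_rejected(self):
        with pytest.raises(ValueError):
            pg.single_copy_by_occurrence({"h1": "A" * 100}, ploidy=2)
        with pytest.raises(ValueError):
            pg.single_copy_by_occurrence({"h1": "A", "h2": "A", "h3": "A"}, ploidy=3)


class TestClusterSingleCopy:
    def test_identical_pair_one_cluster(self):
        rng = np.random.default_rng(6)
        s = random_seq(rng, 1000)
        cl = pg.cluster_single_copy([("a", "g1", s), ("b", "g2", s)])
        assert len(cl) == 1
        assert cl[0].representative_length == 1000

    def test_low_identity_pair_separate_clusters(self):
        rng = np.random.default_rng(7)
        s = random_seq(rng, 1000)
        cl = pg.cluster_single_copy([("a", "g1", s), ("b", "g2", mutate(rng, s, 0.10))])
        assert len(cl) == 2

    def test_short_fragments_dropped(self):
        rng = np.random.default_rng(8)
        cl = pg.cluster_single_copy([("a", "g1", random_seq(rng, 99))])
        assert cl == []

    def test_reverse_complement_members_cluster_together(self):
        rng = np.random.default_rng(9)
        s = random_seq(rng, 600)
        cl = pg.cluster_single_copy([("a", "g1", s), ("b", "g2", pg.revcomp(s))])
        assert len(cl) == 1

    def test_matches_single_linkage_oracle(self):
        """Greedy clustering equals brute-force single linkage at ~2% pairwise
        divergence (well inside the 95% threshold)."""
        rng = np.random.default_rng(10)
        bases = [random_seq(rng, 400) for _ in range(5)]
        frags = []
        for bi, base in enumerate(bases):
            for copy in range(4):
                frags.append((f"b{bi}c{copy}", f"g{copy}", mutate(rng, base, 0.01)))
        cl = pg.cluster_single_copy(frags)

        # oracle: union-find over all pairs at >= 95% identity
        names = [f[0] for f in frags]
        seqs = dict((f[0], f[2]) for f in frags)
        parent = {n: n for n in names}

        def find(n):
            while parent[n] != n:
                n = parent[n]
            return n

        for a, b in itertools.combinations(names, 2):
            sa, sb = seqs[a], seqs[b]
            q, t = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
            if pg._identity(q, t) >= 0.95:
                parent[find(a)] = find(b)
        oracle = {}
        for n in names:
            oracle.setdefault(find(n), set()).add(n)
        got = [frozenset(m for m, _, _ in c.members) for c in cl]
        assert sorted(map(sorted, got)) == sorted(map(sorted, oracle.values()))


def _toy_clusters():
    """4 genomes; cluster layout with known presence sets."""
    spec = [
        (1000, {"g1", "g2", "g3", "g4"}),  # core
        (800, {"g1", "g2"}),  # shell
        (600, {"g1"}),  # cloud
        (400, {"g3"}),  # cloud
    ]
    out = []
    for i, (length, units) in enumerate(spec):
        out.append(
            pg.PanCluster(
                cluster_id=i,
                members=[(f"c{i}_{u}", u, length) for u in sorted(units)],
                representative=f"c{i}",
                representative_length=length,
            )
        )
    return out


class TestGrowthCurve:
    def test_identical_genomes_flat_after_first(self):
        cl = [
            pg.PanCluster(0, [(f"x{u}", u, 500) for u in "abcd"], "x", 500),
        ]
        curve = pg.growth_curve(cl, list("abcd"), exhaustive=True)
        assert (curve["mean"] == 500).all()

    def test_disjoint_genomes_linear(self):
        cl = [
            pg.PanCluster(i, [(f"x{u}", u, 300)], f"x{u}", 300)
            for i, u in enumerate("abcd")
        ]
        curve = pg.growth_curve(cl, list("abcd"), exhaustive=True)
        assert list(curve["mean"]) == [300, 600, 900, 1200]

    def test_sampled_mean_matches_exhaustive_enumeration(self):
        clusters = _toy_clusters()
        units = ["g1", "g2", "g3", "g4"]
        # independent oracle: direct enumeration over all 4! orderings
        presence = [c.units for c in clusters]
        lengths = [c.representative_length for c in clusters]
        totals = np.zeros(4)
        orders = list(itertools.permutations(units))
        for order in orders:
            seen = set()
            for m, u in enumerate(order):
                seen.add(u)
                totals[m] += sum(
                    ln for p, ln in zip(presence, lengths) if p & seen
                )
        expected = totals / len(orders)
        got = pg.growth_curve(clusters, units, exhaustive=True)
        assert np.allclose(got["mean"], expected)

    def test_monotone_and_final_value_permutation_invariant(self):
        clusters = _toy_clusters()
        curve = pg.growth_curve(clusters, ["g1", "g2", "g3", "g4"], n_permutations=50, seed=1)
        assert (np.diff(curve["mean"]) >= 0).all()
        total = sum(c.representative_length for c in clusters)
        assert curve["mean"].iloc[-1] == total
        assert curve["q25"].iloc[-1] == curve["q75"].iloc[-1] == total


class TestClassifyPresence:
    def test_partition_and_hap_specific_core(self):
        geno_of_hap = {f"{g}_h{i}": g for g in ("g1", "g2") for i in (1, 2)}
        clusters = [
            # in every haplotype -> core at both levels
            pg.PanCluster(0, [(h, h, 500) for h in geno_of_hap], "r0", 500),
            # genotype-core but missing from g2_h2 -> haplotype-specific core
            pg.PanCluster(
                1,
                [(h, h, 400) for h in geno_of_hap if h != "g2_h2"],
                "r1", 400,
            ),
            # single genotype -> cloud at genotype level
            pg.PanCluster(2, [("g1_h1", "g1_h1", 300)], "r2", 300),
        ]
        pc = pg.classify_presence(clusters, geno_of_hap)
        t = pc.table.set_index("cluster_id")
        assert t.loc[0, "class_genotype"] == "core" and t.loc[0, "class_hap"] == "core"
        assert t.loc[1, "class_genotype"] == "core" and t.loc[1, "class_hap"] == "shell"
        assert t.loc[2, "class_genotype"] == "cloud"
        hs = pc.hap_specific_core
        assert list(hs["cluster_id"]) == [1]
        assert list(hs["missing_hap"]) == ["g2_h2"]
        counts = pc.class_counts("genotype")
        assert counts.sum() == len(clusters)

    def test_hap_core_subset_of_genotype_core(self):
        rng = np.random.default_rng(11)
        geno_of_hap = {f"g{j}_h{i}": f"g{j}" for j in range(3) for i in range(2)}
        haps = list(geno_of_hap)
        clusters = []
        for i in range(40):
            members = [
                (h, h, 200) for h in haps if rng.random() < 0.7
            ] or [(haps[0], haps[0], 200)]
            clusters.append(pg.PanCluster(i, members, f"r{i}", 200))
        pc = pg.classify_presence(clusters, geno_of_hap)
        hap_core = set(pc.table.loc[pc.table["class_hap"] == "core", "cluster_id"])
        geno_core = set(pc.table.loc[pc.table["class_genotype"] == "core", "cluster_id"])
        assert hap_core <= geno_core
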