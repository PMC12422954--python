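import numpy as np
import pytest

from bulbopan import hic, simulate as sim


@pytest.fixture(scope="session")
def diploid_setup():
    """Diploid assembly + Hi-C + Rabl-normalized matrix (known truth)."""
    cs = sim.make_assembly_sim(
        seed=11, ploidy=2, n_contigs=30,
        chrom_lengths={"chr1": 100_000_000, "chr2": 100_000_000},
    )
    mat = sim.make_hic(cs, intra_boost=5.0, rabl_scale=50e6, mean_links=100.0, seed=12)
    norm, diag = hic.rabl_normalize(mat, cs)
    return cs, mat, norm, diag


@pytest.fixture(scope="session")
def tetraploid_setup():
    """Autotetraploid assembly with one IBD tract shared by haplotypes 1+2."""
    cs = sim.make_assembly_sim(
        seed=21, ploidy=4, n_contigs=40, chrom_lengths={"chr1": 100_000_000},
        ibd_tracts=[("chr1", 40_000_000, 60_000_000, (1, 2))],
    )
    mat = sim.make_hic(cs, intra_boost=5.0, rabl_scale=50e6, mean_links=100.0, seed=22)
    norm, _ = hic.rabl_normalize(mat, cs)
    return cs, mat, norm


@pytest.fixture(scope="session")
def three_group_population():
    """12 haplotypes in 3 groups: within 9,500 / between 14,500 variants/Mb."""
    theta_within = 9_500 / 1e6
    split = 14_500 / 1e6 / (2 * sim.DEFAULT_MU) * sim.DEFAULT_GENERATION_TIME
    vm, truth = sim.make_population(
        seed=31, groups={"A": 4, "B": 4, "C": 4}, split_times=split,
        theta_within=theta_within, seq_length=100_000_000,
    )
    return vm, truth


@pytest.fixture(scope="session")
def three_group_tensor(three_group_population):
    from bulbopan import ahg

    vm, truth = three_group_population
    return ahg.window_distances(vm), vm, truth


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([c for c in "ACGT" if c != out[i]])
    return "".join(out)
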