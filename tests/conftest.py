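import numpy as np
import pytest

from chicsv import contact_map, hic_sim
from chicsv.cli_io import build_locus, default_config
from chicsv.locus_sv import GenomicInterval, digest


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def locus(cfg):
    """(annotation, restriction map) of the default model locus."""
    return build_locus(cfg)


@pytest.fixture(scope="session")
def wt_sim(cfg, locus):
    ann, rm = locus
    return hic_sim.simulate_dataset(ann, rm, cfg.model, None, "wildtype",
                                    cfg.sampling_bin)


@pytest.fixture(scope="session")
def dup_sim(cfg, locus):
    ann, rm = locus
    return hic_sim.simulate_dataset(ann, rm, cfg.model, cfg.sv_spec("dup"),
                                    "dup", cfg.sampling_bin)


@pytest.fixture(scope="session")
def inv1_sim(cfg, locus):
    ann, rm = locus
    return hic_sim.simulate_dataset(ann, rm, cfg.model, cfg.sv_spec("inv1"),
                                    "inv1", cfg.sampling_bin)


@pytest.fixture(scope="session")
def wt_map(cfg, wt_sim):
    return contact_map.bin_pairs(wt_sim["pairs"], cfg.region, cfg.bin_size,
                                 cfg.mapq_min)


@pytest.fixture(scope="session")
def dup_map(cfg, dup_sim):
    return contact_map.bin_pairs(dup_sim["pairs"], cfg.region, cfg.bin_size,
                                 cfg.mapq_min)


@pytest.fixture
def tiny_rm():
    """Four equal 1 kb fragments on a 4 kb region."""
    region = GenomicInterval("chrT", 0, 4000)
    return digest([1000, 2000, 3000], "GATC", region)


def random_symmetric(n, seed, low=0.5, high=2.0):
    rng = np.random.default_rng(seed)
    A = rng.uniform(low, high, (n, n))
    return 0.5 * (A + A.T)
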