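import logging

import numpy as np
import pytest

import crypterm as ct

# chromosome-end window clipping is expected on simulated genomes
logging.getLogger("crypterm.coverage").setLevel(logging.ERROR)
logging.getLogger("crypterm.readthrough").setLevel(logging.ERROR)


@pytest.fixture()
def toy_annot():
    """Five TUs: a convergent pair, a tandem pair, and an isolated gene."""
    sizes = {"chrI": 10_000, "chrII": 8_000}
    tus = [
        ct.TranscriptionUnit("g1", "chrI", 100, 600, "+"),
        ct.TranscriptionUnit("g2", "chrI", 700, 1200, "-"),
        ct.TranscriptionUnit("g3", "chrI", 3000, 5000, "+"),
        ct.TranscriptionUnit("g4", "chrI", 5400, 6900, "+"),
        ct.TranscriptionUnit("g5", "chrII", 2000, 4000, "-"),
    ]
    return ct.GenomeAnnotation(sizes, tus)


def build_coverage(sizes, fills, read_length=50, **meta):
    """Coverage with constant values painted over (chrom, strand, s, e, v)."""
    data = {}
    for chrom, strand, s, e, v in fills:
        key = (chrom, strand)
        if key not in data:
            data[key] = np.zeros(sizes[chrom])
        data[key][s:e] += v
    return ct.StrandedCoverage(sizes, data, read_length=read_length, **meta)


@pytest.fixture()
def make_cov():
    return build_coverage


@pytest.fixture(scope="session")
def sim_default():
    """Default simulated study: 200 TUs, 20 read-through, 15 antisense."""
    cfg = ct.SimulationConfig(seed=1)
    annot, truth = ct.simulate_dataset(cfg)
    covs = ct.simulate_all_replicates(annot, truth, cfg)
    return cfg, annot, truth, covs
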