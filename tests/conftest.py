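import numpy as np
import pytest

from cistromix.core import GenomicInterval, Peak, SignalTrack
from cistromix.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A compact simulated multi-assay dataset shared across tests."""
    config = SimConfig(
        seed=42,
        n_genes=400,
        n_peaks_tf_a=300,
        n_peaks_tf_b=300,
        n_indirect_up=60,
        n_chromosomes=4,
        chrom_length=1_200_000,
        n_open_regions=120,
        n_distal_open=60,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    """The same small dataset written out as a file bundle."""
    config = SimConfig(
        seed=42,
        n_genes=400,
        n_peaks_tf_a=300,
        n_peaks_tf_b=300,
        n_indirect_up=60,
        n_chromosomes=4,
        chrom_length=1_200_000,
        n_open_regions=120,
        n_distal_open=60,
    )
    out = tmp_path_factory.mktemp("bundle")
    simulate(config, out_dir=out)
    return out


def random_track(rng, chrom="chr1", length=5000):
    return SignalTrack(data={chrom: rng.uniform(0, 5, length)})


def random_peak(rng, chrom="chr1", max_pos=100_000, name="p"):
    start = int(rng.integers(0, max_pos))
    width = int(rng.integers(50, 800))
    summit = start + int(rng.integers(0, width))
    auc = float(rng.uniform(0, 500))
    bg = float(rng.uniform(0, 200))
    return Peak(GenomicInterval(chrom, start, start + width), summit=summit,
                auc=auc, background_auc=bg, name=name)
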