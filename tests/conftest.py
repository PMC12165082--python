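import numpy as np
import pytest

from lessel import pipeline, synthdata


@pytest.fixture(scope="session")
def small_bins():
    """Two 20 Mb synthetic chromosomes at 500 kb bins (80 bins)."""
    return synthdata.reference_bins(n_chroms=2, chrom_length=20_000_000, seed=7)


@pytest.fixture(scope="session")
def trained_models():
    """A small trained imaging cascade shared across imaging tests."""
    return pipeline.train_all_models(
        seed=0, n_detector_slides=4, cells_per_slide=10,
        n_qc_per_category=15, n_seg_crops=30, n_channel_cells=(60, 100))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
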