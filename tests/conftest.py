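import numpy as np
import pytest

from aggrescope import syndata


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_coloc_cell():
    """One noise-free perfectly colocalized two-channel cell with its ROI."""
    spec = syndata.CellSpec(coloc_fraction=1.0, noise=None)
    images, rois, gt = syndata.simulate_coloc_cells(1, spec, seed=7)
    return images[0], rois[0].rois[0], gt


@pytest.fixture(scope="session")
def blob_training_set():
    """Frames of annotated blobs shared by the segmentation tests."""
    frames, rois, gt = syndata.simulate_blob_fields(10, seed=5)
    return frames, rois, gt
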