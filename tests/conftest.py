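import numpy as np
import pytest

from fuseseg import PhantomSpec, generate_phantom
from fuseseg.volume_io import ImageVolume, Modality, SamplePair


def tiny_spec_2d(seed: int = 0, size: int = 32, **kw) -> PhantomSpec:
    """A 2-D spec scaled down so blobs fit on small grids used in fast tests."""
    defaults = dict(shape=(size, size), spacing=(1.0, 1.0),
                    tumor_radius_range=(2.5, 4.0), n_confounders=1,
                    n_ct_distractors=1, seed=seed)
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture
def sample_2d():
    return generate_phantom(tiny_spec_2d(seed=7, size=64))


@pytest.fixture
def tiny_dataset_2d():
    """Six 32x32 samples over two centers, for fast split/training tests."""
    samples = []
    for ci, center in enumerate(("A", "B")):
        for si in range(3):
            s = generate_phantom(tiny_spec_2d(seed=100 + 10 * ci + si, center=center))
            s.patient = f"{center}_{si}"
            samples.append(s)
    return samples


def make_volume(data, modality=Modality.PET, spacing=None):
    data = np.asarray(data)
    if spacing is None:
        spacing = (1.0,) * data.ndim
    return ImageVolume(data=data, spacing=spacing, modality=modality)


def random_blob_mask(rng, shape=(16, 16, 16)) -> np.ndarray:
    """Non-empty random blobby mask: smoothed noise thresholded at a random
    quantile."""
    from scipy import ndimage
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    thr = np.quantile(field, rng.uniform(0.75, 0.95))
    mask = field > thr
    if not mask.any():
        idx = tuple(rng.integers(0, s) for s in shape)
        mask[idx] = True
    return mask.astype(np.uint8)
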