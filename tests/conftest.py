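import numpy as np
import pytest

from turfhsi.cube import ReflectanceCube


@pytest.fixture
def band_cube():
    """3x3 cube with one band exactly at each wavelength the index formulas
    need, so formula spot checks are free of nearest-band ambiguity."""
    wavelengths = np.array(
        [445.0, 450.0, 500.0, 550.0, 650.0, 670.0, 675.0, 705.0, 720.0, 740.0, 750.0, 800.0]
    )
    data = np.full((3, 3, wavelengths.size), 0.2, dtype=np.float64)
    return ReflectanceCube(data, wavelengths, source_id="band-fixture")


def set_band(cube: ReflectanceCube, nm: float, value, pixel=None):
    """Set the reflectance of the band at `nm` (exact match) for one pixel or
    the whole frame."""
    idx = int(np.argmin(np.abs(cube.wavelengths - nm)))
    if pixel is None:
        cube.data[:, :, idx] = value
    else:
        cube.data[pixel[0], pixel[1], idx] = value


def pixel_f1(truth: np.ndarray, pred: np.ndarray) -> float:
    tp = np.sum(truth & pred)
    fp = np.sum(~truth & pred)
    fn = np.sum(truth & ~pred)
    return 2.0 * tp / (2.0 * tp + fp + fn) if tp + fp + fn else 1.0
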