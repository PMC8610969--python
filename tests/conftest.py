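import numpy as np
import pytest

from ivimroi import DWIStudy, LesionROISet, SliceROI, TissueIVIMParams, ivim_signal


def biexp_signal(s0, d, f, dstar, b):
    """Independent forward model used as the reference throughout the tests."""
    b = np.asarray(b, float)
    return s0 * ((1 - f) * np.exp(-b * d) + f * np.exp(-b * dstar))


@pytest.fixture
def worked_voxel():
    """The reference bi-exponential voxel used in several hand-checked cases."""
    return TissueIVIMParams(d=1.0e-3, f=0.2, dstar=20e-3, s0=1000.0)


@pytest.fixture
def uniform_study():
    """Factory: a small uniform study where every voxel has one tissue."""

    def make(tissue: TissueIVIMParams, shape=(3, 4, 4)) -> DWIStudy:
        b = np.array([0.0, 50.0, 250.0, 800.0])
        sig = np.empty(shape + (4,))
        for i, bv in enumerate(b):
            sig[..., i] = ivim_signal(tissue, bv)
        return DWIStudy(signal=sig)

    return make


def rect(rows, cols):
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


@pytest.fixture
def toy_lesion():
    """Three-slice lesion: bad(4) / good+ref(10) / bad(6) voxels, with an
    optional 3-voxel CDA on the reference slice."""

    def make(with_cda: bool = False) -> LesionROISet:
        slices = [
            SliceROI(1, rect(range(2), range(2)), quality="bad"),
            SliceROI(2, rect(range(2), range(5)), quality="good", reference=True),
            SliceROI(3, rect(range(2), range(3)), quality="bad"),
        ]
        cda = np.array([[2, 0, 0], [2, 0, 1], [2, 0, 2]]) if with_cda else None
        return LesionROISet("toy", "malignant", slices, cda_coords=cda)

    return make
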