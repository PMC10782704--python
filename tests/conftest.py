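import numpy as np
import pytest

from pctqa import Geometry, ImageVolume, PhantomConfig, StructureMask, generate_case, generate_cohort


@pytest.fixture(scope="session")
def default_case():
    """One default single-lesion case (3.4 cc, 1 x 21 Gy)."""
    return generate_case(PhantomConfig(seed=3), case_id="case_default")


@pytest.fixture(scope="session")
def cohort():
    """The 20-case default synthetic cohort used by the cohort-level checks."""
    return generate_cohort(20, seed=42)


@pytest.fixture
def unit_geometry():
    return Geometry((1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (10, 10, 10))


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), modality="CT"):
    values = np.asarray(values, dtype=float)
    geom = Geometry(spacing, origin, values.shape)
    return ImageVolume(geom, values, modality=modality)


def make_mask(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), role="PTV"):
    voxels = np.asarray(voxels, dtype=bool)
    geom = Geometry(spacing, origin, voxels.shape)
    return StructureMask(geom, voxels, role=role)
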