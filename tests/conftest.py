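import numpy as np
import pytest

from oligoccs import ccs_calibration as cal
from oligoccs import synthetic_data as syn
from oligoccs.structure_analysis import AtomRecord, StructureModel


@pytest.fixture(scope="session")
def calibration():
    """Noise-free calibration fitted from a synthetic calibrant ladder."""
    return cal.fit_calibration(syn.generate_calibrants(true_a=350.0, true_b=0.55, noise=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_sphere(radius=10.0, center=(0.0, 0.0, 0.0), element="X"):
    return AtomRecord(element, tuple(float(c) for c in center), radius, residue_name="SPH")


@pytest.fixture()
def single_sphere():
    return StructureModel([make_sphere()])


@pytest.fixture()
def sphere_pair():
    """Two identical spheres at centre distance 3r (partially overlapping shadows)."""
    return StructureModel([make_sphere(), make_sphere(center=(30.0, 0.0, 0.0))])
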