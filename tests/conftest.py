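"""Shared fixtures: phantom fields and small synthetic imaging artifacts.

Expensive objects (wave solves, RF frames) are session-scoped; everything
is generated programmatically with fixed seeds.
"""

import numpy as np
import pytest

from uswicrack import (
    DomainSpec,
    build_material_field,
    export_roi,
    make_psf,
    seed_scatterers,
    simulate,
    straight_crack,
    synthesize_frame,
)
from uswicrack.rf import ImagingSpec


@pytest.fixture(scope="session")
def domain():
    return DomainSpec()


@pytest.fixture(scope="session")
def homogeneous_roi(domain):
    """ROI displacement movie of the crack-free liver phantom."""
    material = build_material_field(domain, None)
    return export_roi(simulate(material), domain)


@pytest.fixture(scope="session")
def straight_crack_roi(domain):
    """ROI displacement movie with the 1.6 mm straight crack."""
    material = build_material_field(domain, straight_crack())
    return export_roi(simulate(material), domain)


@pytest.fixture(scope="session")
def imaging():
    return ImagingSpec()


@pytest.fixture(scope="session")
def psf(imaging):
    return make_psf(imaging.psf)


@pytest.fixture(scope="session")
def speckle_frame(imaging, psf):
    """One full-density RF frame of a static scatterer field (seed 7)."""
    sset = seed_scatterers(((0.0, 2.5), (0.0, 5.0)), 6.0, seed=7, psf=imaging.psf)
    return synthesize_frame(sset, psf, imaging)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
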