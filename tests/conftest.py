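"""Shared fixtures: small phantoms and their derived fields.

Everything is generated at session start from fixed seeds; the expensive
pieces (GVF fields, SVF response volumes) are session-scoped so the suite
computes each once.
"""

import numpy as np
import pytest

from svftrace import (
    PhantomSpec,
    SVFParams,
    gradient,
    gvf,
    make_phantom,
    normalize,
    normalize_field,
    svf_volume,
)


class Pack:
    """A phantom with its normalized volume, ground truth and fields."""

    def __init__(self, spec):
        self.spec = spec
        vol, self.truth = make_phantom(spec)
        self.volume = normalize(vol)
        self.grad = gradient(self.volume)
        self.gvf_norm = normalize_field(gvf(self.grad))


@pytest.fixture(scope="session")
def cylinder():
    return Pack(PhantomSpec(kind="cylinder", size=(40, 40, 60), radius=5.0, contrast=0.8))


@pytest.fixture(scope="session")
def cylinder_gauss():
    return Pack(
        PhantomSpec(kind="cylinder", size=(40, 40, 60), radius=5.0, contrast=0.8, profile="gaussian")
    )


@pytest.fixture(scope="session")
def helix():
    return Pack(
        PhantomSpec(
            kind="helix", size=(48, 64, 64), radius=3.0,
            coil_radius=16.0, pitch=16.0, turns=2.0, contrast=0.8,
        )
    )


@pytest.fixture(scope="session")
def helix_noisy():
    return Pack(
        PhantomSpec(
            kind="helix", size=(48, 64, 64), radius=3.0,
            coil_radius=16.0, pitch=16.0, turns=2.0, contrast=0.8,
            noise_sigma=0.1, seed=1,
        )
    )


@pytest.fixture(scope="session")
def blob():
    return Pack(PhantomSpec(kind="blob", size=(33, 33, 33), radius=8.0, profile="gaussian"))


#: SVF settings matched to the r=5 cylinder at desk scale
CYL_SVF = SVFParams(m_sections=16, pn_lines=16, vt=2, r_min=3.0, r_max=10.0)
#: SVF settings matched to the r=3 helix
HELIX_SVF = SVFParams(m_sections=16, pn_lines=16, vt=2, r_min=2.0, r_max=8.0)


@pytest.fixture(scope="session")
def cylinder_response(cylinder):
    return svf_volume(cylinder.volume, CYL_SVF, mask_threshold=0.05, gradient_field=cylinder.grad)


@pytest.fixture(scope="session")
def helix_response(helix):
    return svf_volume(helix.volume, HELIX_SVF, mask_threshold=0.05, gradient_field=helix.grad)


@pytest.fixture(scope="session")
def helix_noisy_response(helix_noisy):
    return svf_volume(
        helix_noisy.volume, HELIX_SVF, mask_threshold=0.2, gradient_field=helix_noisy.grad
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
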