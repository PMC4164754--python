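import numpy as np
import pytest

from elastrec.inversion import InversionDomain, ROISpec
from elastrec.mesh import PlaneStrainMaterial, solve_forward
from elastrec.phantom import compression_bc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_recovery_problem():
    """A 10x10-element ROI with its unit ring, a random modulus field and
    the exact forward solution on the same mesh — the setting in which the
    inversion must recover the truth to solver precision."""
    roi = ROISpec(top=0.48, left=0.48, height=4.8, width=4.8)
    domain = InversionDomain(roi)
    mesh = domain.full_mesh
    gen = np.random.default_rng(3)
    E = np.ones(mesh.n_elements)
    E[domain.roi_elements] = gen.uniform(0.5, 3.0, domain.roi_elements.size)
    material = PlaneStrainMaterial(E, 0.495)
    d = solve_forward(mesh, material, compression_bc(mesh, 0.02))
    return roi, domain, E, material, d
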