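import numpy as np
import pytest

import flexsas as fx
from flexsas.model import ParticleModel


def make_rod(length=200.0, spacing=2.5, offset=(0.0, 0.0, 0.0),
             axis=(0.0, 0.0, 1.0), start_res=1, chain="A", segment="tip"):
    """Straight bead rod along an arbitrary axis (unit scattering weights)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    n = int(round(length / spacing)) + 1
    pos = np.asarray(offset, float) + np.outer(np.arange(n) * spacing, axis)
    return ParticleModel(
        pos, np.ones(n), np.ones(n), np.zeros(n), np.zeros(n), np.zeros(n),
        np.array([segment] * n, dtype=object),
        np.arange(start_res, start_res + n),
        np.array([chain] * n, dtype=object))


def sphere_beads(radius=50.0, n_target=3000):
    """Beads on a cubic grid filling a sphere (≈ n_target beads)."""
    s = (4 / 3 * np.pi * radius ** 3 / n_target) ** (1 / 3)
    ax = np.arange(-radius, radius + s, s)
    X = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T
    X = X[(X ** 2).sum(axis=1) <= radius ** 2]
    n = len(X)
    return ParticleModel(
        X, np.ones(n), np.ones(n), np.zeros(n), np.zeros(n), np.zeros(n),
        np.array(["tip"] * n, dtype=object), np.arange(1, n + 1),
        np.array(["A"] * n, dtype=object))


def sphere_form_factor(q, radius):
    qR = np.asarray(q) * radius
    qR = np.where(qR == 0, 1e-12, qR)
    return (3 * (np.sin(qR) - qR * np.cos(qR)) / qR ** 3) ** 2


@pytest.fixture(scope="session")
def toy_dimer():
    return fx.make_toy_dimer()


@pytest.fixture(scope="session")
def saxs_q():
    return np.geomspace(0.006, 0.3, 121)


@pytest.fixture(scope="session")
def hinge_basis(toy_dimer, saxs_q):
    model, smap = toy_dimer
    return fx.build_hinge_basis(model, saxs_q, None, "xray",
                                segment_map=smap)


@pytest.fixture(scope="session")
def sans_setup(toy_dimer):
    """Dimer + tripod trimer with per-mass neutron component curves at
    4 M NaCl in D2O."""
    model, _ = toy_dimer
    solvent = fx.solvent_model(4.0, 1.0)
    q = np.geomspace(0.007, 0.25, 101)
    trimer = fx.assemble_c3(model, 52.0, "tripod")
    cd, ct = fx.component_curves(model, trimer, solvent, q, "neutron")
    return {"dimer": model, "trimer": trimer, "solvent": solvent,
            "q": q, "dimer_curve": cd, "trimer_curve": ct}
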