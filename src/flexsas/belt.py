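"""Detergent corona: a two-shell DDM belt around the transmembrane region.

The belt is modelled with two pseudo-atom species carrying fixed fractions of
the DDM molecule's scattering: a 9-electron CH3-like pseudo-atom standing in
for 9/97 of the C12H25 tail and a 10-electron NH3-like pseudo-atom standing
in for 10/181 of the C12H21O11 maltoside head (electron-proportional
fractions, so the X-ray picture is conserved by construction).  For neutrons
the same fractions of the moiety scattering-length sums are used, with the
head's seven hydroxyl hydrogens exchanged to deuterium according to the
solvent D2O fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import (B_C, B_D, B_H, DDM_HEAD_ELECTRONS,
                        DDM_HEAD_EXCHANGEABLE_H, DDM_HEAD_FORMULA,
                        DDM_HEAD_VOLUME, DDM_TAIL_ELECTRONS, DDM_TAIL_FORMULA,
                        DDM_TAIL_VOLUME, HEAD_PSEUDO_ELECTRONS,
                        TAIL_PSEUDO_ELECTRONS, formula_neutron_b)
from .model import ParticleModel


@dataclass
class BeltSpec:
    """Geometry of the elliptical two-shell belt.

    a, b : ellipse semi-axes of the hydrophobic shell in the membrane plane, Å
    half_thickness : hydrophobic half-thickness along z, Å
    head_thickness : thickness of the hydrophilic shell, Å
    density : pseudo-atoms per Å³ (0 -> empty belt)
    z_center : axial centre of the belt, Å
    clearance : minimum pseudo-atom / protein distance, Å
    seed : jitter seed for the packing lattice
    """

    a: float = 45.0
    b: float = 45.0
    half_thickness: float = 15.0
    head_thickness: float = 8.0
    density: float = 0.004
    z_center: float = 0.0
    clearance: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.half_thickness, self.head_thickness) <= 0:
            raise ValueError("belt dimensions must be positive")
        if self.density < 0:
            raise ValueError("density must be >= 0")


def tail_neutron_b() -> float:
    """Neutron scattering length of the tail pseudo-atom, fm (9/97 of C12H25)."""
    return TAIL_PSEUDO_ELECTRONS / DDM_TAIL_ELECTRONS \
        * formula_neutron_b(DDM_TAIL_FORMULA)


def head_neutron_b(d2o_fraction: float = 1.0) -> float:
    """Neutron scattering length of the head pseudo-atom, fm.

    10/181 of the maltoside head sum with the 7 exchangeable hydrogens
    replaced by D at the given solvent D2O fraction.
    """
    f = DDM_HEAD_FORMULA
    total = (formula_neutron_b(f)
             + DDM_HEAD_EXCHANGEABLE_H * d2o_fraction * (B_D - B_H))
    return HEAD_PSEUDO_ELECTRONS / DDM_HEAD_ELECTRONS * total


def _lattice_points(spec: BeltSpec) -> np.ndarray:
    """Jittered hexagonal-layered lattice filling the belt bounding box."""
    if spec.density == 0:
        return np.empty((0, 3))
    # hexagonal row spacing is s·√3/2, so scale s to hit the target density
    s = (2.0 / (np.sqrt(3.0) * spec.density)) ** (1.0 / 3.0)
    amax = spec.a + spec.head_thickness
    bmax = spec.b + spec.head_thickness
    zmax = spec.half_thickness + spec.head_thickness
    xs = np.arange(-amax, amax + s, s)
    ys = np.arange(-bmax, bmax + s, s * np.sqrt(3) / 2)
    zs = np.arange(-zmax, zmax + s, s)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    # offset alternate rows (hexagonal layering in the xy plane)
    X = X + (np.arange(len(ys)) % 2)[None, :, None] * (s / 2)
    pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    rng = np.random.default_rng(spec.seed)
    pts = pts + rng.uniform(-0.25 * s, 0.25 * s, pts.shape)
    pts[:, 2] += spec.z_center
    return pts


def build_belt(model: ParticleModel, spec: BeltSpec) -> ParticleModel:
    """Append the two-shell belt to an oriented model.

    The hydrophobic (tail) shell fills the elliptical annulus around the TM
    for |z − z_center| ≤ half_thickness; the hydrophilic (head) shell wraps
    it radially and axially.  Pseudo-atoms closer than ``spec.clearance`` to
    any protein scatterer are discarded.
    """
    tm = model.segment_mask("TM")
    if tm.any() and np.linalg.norm(model.positions[tm].mean(axis=0)) > 5.0:
        raise ValueError("model not oriented: TM centroid further than 5 Å "
                         "from the origin")
    pts = _lattice_points(spec)
    if len(pts) == 0:
        return model.copy()
    z = pts[:, 2] - spec.z_center
    e_in = (pts[:, 0] / spec.a) ** 2 + (pts[:, 1] / spec.b) ** 2
    e_out = ((pts[:, 0] / (spec.a + spec.head_thickness)) ** 2
             + (pts[:, 1] / (spec.b + spec.head_thickness)) ** 2)
    in_tail = (e_in <= 1.0) & (np.abs(z) <= spec.half_thickness)
    in_head = ((e_out <= 1.0)
               & (np.abs(z) <= spec.half_thickness + spec.head_thickness)
               & ~in_tail)
    keep = in_tail | in_head
    pts, in_tail = pts[keep], in_tail[keep]
    # exclude points overlapping the protein
    prot = model.positions[~model.is_belt]
    if len(prot):
        from scipy.spatial import cKDTree
        d, _ = cKDTree(prot).query(pts)
        ok = d >= spec.clearance
        pts, in_tail = pts[ok], in_tail[ok]
    nb = len(pts)
    seg = np.where(in_tail, "belt_tail", "belt_head").astype(object)
    belt = ParticleModel(
        pts,
        np.where(in_tail, float(TAIL_PSEUDO_ELECTRONS),
                 float(HEAD_PSEUDO_ELECTRONS)),
        np.where(in_tail, tail_neutron_b(), head_neutron_b(0.0)),
        np.where(in_tail,
                 TAIL_PSEUDO_ELECTRONS / DDM_TAIL_ELECTRONS * DDM_TAIL_VOLUME,
                 HEAD_PSEUDO_ELECTRONS / DDM_HEAD_ELECTRONS * DDM_HEAD_VOLUME),
        np.where(in_tail, 0.0,
                 HEAD_PSEUDO_ELECTRONS / DDM_HEAD_ELECTRONS
                 * DDM_HEAD_EXCHANGEABLE_H),
        np.zeros(nb), seg, np.full(nb, -1, int),
        np.full(nb, "X", dtype=object), {})
    out = ParticleModel.concat([model, belt])
    out.metadata["belt_spec"] = spec
    return out


def assign_belt_scattering(model: ParticleModel,
                           d2o_fraction: float) -> ParticleModel:
    """(Re)assign belt pseudo-atom scattering for a given solvent D2O level.

    Tail pseudo-atoms: 9 e, b = (9/97)·Σb(C12H25) (no exchange).
    Head pseudo-atoms: 10 e, b = (10/181)·Σb(head) with the 7 exchangeable
    hydrogens deuterated at ``d2o_fraction``; the exchange is baked into
    ``neutron_b`` and the labile-H count zeroed.
    """
    belt = model.is_belt
    if not belt.any():
        raise ValueError("no labelled belt pseudo-atoms "
                         "(segments belt_tail/belt_head) in model")
    out = model.copy()
    tail = out.segment_mask("belt_tail")
    head = out.segment_mask("belt_head")
    out.xray_electrons[tail] = TAIL_PSEUDO_ELECTRONS
    out.xray_electrons[head] = HEAD_PSEUDO_ELECTRONS
    out.neutron_b[tail] = tail_neutron_b()
    out.neutron_b[head] = head_neutron_b(d2o_fraction)
    out.n_exchangeable_h[belt] = 0.0
    return out


def equivalent_deuteration_fraction(target_b: float) -> float:
    """Deuteration fraction f of a CH3 pseudo-atom's hydrogens matching a
    target scattering length.

    Solves  b_C + 3·[(1 − f)·b_H + f·b_D] = target_b  for f.  This is the
    "perdeuteration parameter" one would give a neutron curve evaluator to
    make a renamed CH3 pseudo-atom scatter like a belt pseudo-atom.  Values
    outside [0, 1] are returned as-is with a warning.
    """
    f = (target_b - (B_C + 3 * B_H)) / (3 * (B_D - B_H))
    if not 0.0 <= f <= 1.0:
        import warnings
        warnings.warn(f"equivalent deuteration fraction {f:.4f} outside [0, 1]",
                      stacklevel=2)
    return float(f)


def belt_slds(d2o_fraction: float = 1.0,
              tail_volume: float = DDM_TAIL_VOLUME,
              head_volume: float = DDM_HEAD_VOLUME) -> tuple[float, float]:
    """Neutron SLDs (Å⁻²) of the hydrophobic and hydrophilic belt shells.

    SLD = Σb / V per DDM moiety (1 fm = 1e-5 Å).
    """
    if tail_volume <= 0 or head_volume <= 0:
        raise ValueError("molecular volumes must be positive")
    b_tail = formula_neutron_b(DDM_TAIL_FORMULA)
    b_head = (formula_neutron_b(DDM_HEAD_FORMULA)
              + DDM_HEAD_EXCHANGEABLE_H * d2o_fraction * (B_D - B_H))
    return (b_tail * 1e-5 / tail_volume, b_head * 1e-5 / head_volume)
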