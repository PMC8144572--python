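"""Rigid-body geometry: membrane-frame orientation, hinge bending, C3
assembly of trimers of dimers, and geometric descriptors.

All operations are rigid (rotation + translation) within each rigid block, so
intra-block pairwise distances are preserved to floating-point precision.
"""

from __future__ import annotations

import numpy as np

from .model import HingeBend, ParticleModel, SegmentMap


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue of the 2nd-moment tensor."""
    c = points - points.mean(axis=0)
    evals, evecs = np.linalg.eigh(c.T @ c)
    return evecs[:, -1]


def orient_membrane(model: ParticleModel,
                    tm_residues: range | None = None) -> ParticleModel:
    """Place the model in the membrane frame.

    The centroid of the transmembrane scatterers is moved to the origin and
    the principal axis of the whole assembly is aligned with z, with the
    cytoplasmic rod (the non-TM part) pointing toward +z.  Pure rigid
    transform.

    Parameters
    ----------
    tm_residues : residue range defining the TM selection; by default the
        scatterers labelled ``"TM"``.
    """
    if tm_residues is None:
        tm_mask = model.segment_mask("TM")
        sel_desc = "segment label 'TM'"
    else:
        tm_mask = np.isin(model.residue_index, np.asarray(list(tm_residues)))
        tm_mask &= ~model.is_belt
        sel_desc = f"residues {tm_residues.start}-{tm_residues.stop - 1}"
    if tm_mask.sum() < 3:
        raise ValueError(f"empty/too-small TM selection ({sel_desc}: "
                         f"{int(tm_mask.sum())} scatterers)")
    out = model.copy()
    out.positions = out.positions - out.positions[tm_mask].mean(axis=0)

    axis = _principal_axis(out.positions[~out.is_belt])
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s > 1e-12:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
        out.positions = out.positions @ R.T
    elif c < 0:
        out.positions[:, 1:] *= -1  # antiparallel: flip about x
    # cytoplasmic part points +z
    rod_mask = ~tm_mask & ~out.is_belt
    if rod_mask.any() and out.positions[rod_mask, 2].mean() < 0:
        out.positions[:, 1:] *= -1
    out.positions -= out.positions[tm_mask].mean(axis=0)
    return out


def _bend_axis(distal: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """Bend axis: ẑ × (distal rod axis), sign-normalised; x̂ fallback.

    The rod axis is oriented away from the pivot; the sign of the returned
    axis is fixed so its largest-magnitude component is positive, which makes
    bend(θ) followed by bend(−θ) an exact identity on straight rods.
    """
    u = _principal_axis(distal)
    if u @ (distal.mean(axis=0) - pivot) < 0:
        u = -u
    axis = np.cross([0.0, 0.0, 1.0], u)
    if np.linalg.norm(axis) < 1e-8:
        axis = np.array([1.0, 0.0, 0.0])
    axis = axis / np.linalg.norm(axis)
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def bend_at_hinge(model: ParticleModel, bend: HingeBend,
                  segment_map: SegmentMap | None = None) -> ParticleModel:
    """Bend the model at a hinge by ``bend.angle`` degrees.

    Scatterers distal to the hinge (residue index larger than the hinge
    pivot residue, i.e. toward the cytoplasmic tip) are rotated rigidly about
    an axis through the hinge pivot perpendicular to the distal rod axis;
    proximal scatterers and belt pseudo-atoms are untouched.
    """
    smap = segment_map or SegmentMap()
    hinge_res = smap.hinge_residues.get(bend.hinge_id)
    if hinge_res is None:
        raise ValueError(f"unknown hinge {bend.hinge_id!r}")
    at_hinge = (model.residue_index == hinge_res) & ~model.is_belt
    if not at_hinge.any():
        raise ValueError(f"hinge residue {hinge_res} absent from model")
    if bend.angle == 0.0:
        return model.copy()
    out = model.copy()
    pivot = out.positions[at_hinge].mean(axis=0)
    distal = (out.residue_index > hinge_res) & ~out.is_belt
    if not distal.any():
        return out
    axis = _bend_axis(out.positions[distal], pivot)
    R = _rotation_matrix(axis, bend.angle)
    out.positions[distal] = (out.positions[distal] - pivot) @ R.T + pivot
    return out


def _chain_suffixes(n_copies: int) -> list[str]:
    import string
    return list(string.ascii_uppercase)[:n_copies]


def assemble_c3(dimer: ParticleModel, radial_offset: float,
                mode: str = "tripod") -> ParticleModel:
    """Assemble three copies of a dimer into an exactly C3-symmetric trimer.

    mode="tripod": each copy's TM centroid is displaced radially outward by
    ``radial_offset`` (pairwise TM-centroid distances = radial_offset·√3) and
    the copy is tilted toward the symmetry axis so the cytoplasmic tips
    converge on it — only the tips touch, the TM parts stay apart.
    mode="tm_bound": copies are displaced radially without tilt, so the TM
    domains stay adjacent (coincident for radial_offset = 0).

    Chains of copy k are renamed ``<old>k`` so the three dimers remain
    distinguishable.
    """
    if radial_offset < 0:
        raise ValueError("radial_offset must be >= 0")
    if mode not in ("tripod", "tm_bound"):
        raise ValueError(f"unknown mode {mode!r}")
    base = dimer.copy()
    tm = base.segment_mask("TM")
    if not tm.any():
        raise ValueError("dimer has no TM scatterers")
    base.positions -= base.positions[tm].mean(axis=0)
    if mode == "tripod" and radial_offset > 0:
        tip_z = base.positions[~base.is_belt][:, 2].max()
        tilt = np.degrees(np.arctan2(radial_offset, max(tip_z, 1e-6)))
        # tilt about y toward -x so the +x displacement below lands the tip
        # back over the symmetry axis
        base.positions = base.positions @ _rotation_matrix(
            [0.0, 1.0, 0.0], -tilt).T
    base.positions[:, 0] += radial_offset

    copies = []
    for k in range(3):
        c = base.copy()
        Rk = _rotation_matrix([0.0, 0.0, 1.0], 120.0 * k)
        c.positions = c.positions @ Rk.T
        c.chain_id = np.array([f"{cid}{k}" for cid in c.chain_id],
                              dtype=object)
        copies.append(c)
    out = ParticleModel.concat(copies)
    out.metadata["c3_mode"] = mode
    out.metadata["radial_offset"] = radial_offset
    return out


def radius_of_gyration(model: ParticleModel, weighting: str = "uniform",
                       solvent=None, radiation: str = "xray") -> float:
    """Rg = sqrt(Σ wᵢ |rᵢ − r̄|² / Σ wᵢ).

    weighting="uniform" uses unit weights; "contrast" uses the scatterers'
    excess scattering amplitudes (solvent-corrected when a SolventModel is
    given, raw electron counts / b-values otherwise).
    """
    if model.n < 1:
        raise ValueError("empty model")
    if weighting == "uniform":
        w = np.ones(model.n)
    elif weighting == "contrast":
        from .scattering import excess_amplitudes
        w = excess_amplitudes(model, solvent, radiation)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    tot = w.sum()
    if tot == 0:
        raise ValueError("all weights zero")
    cen = (w[:, None] * model.positions).sum(axis=0) / tot
    return float(np.sqrt((w * ((model.positions - cen) ** 2).sum(axis=1)).sum()
                         / tot))


def inter_dimer_separations(trimer: ParticleModel,
                            residue_set: list[int]) -> list[float]:
    """Minimal cross-dimer distances between equivalent residue sites.

    The trimer's three dimers must be distinguishable by the chain-id suffix
    appended by :func:`assemble_c3`.  For each residue in ``residue_set`` the
    minimum distance between its copies in different dimers is returned,
    sorted by residue index.
    """
    suffixes = sorted({str(c)[-1] for c in trimer.chain_id})
    if len(suffixes) != 3:
        raise ValueError("trimer must contain exactly 3 chain-id groups, got "
                         f"{suffixes}")
    from scipy.spatial.distance import cdist
    missing = []
    seps = {}
    for res in sorted(residue_set):
        sites = []
        for sfx in suffixes:
            mask = ((trimer.residue_index == res) & ~trimer.is_belt
                    & np.array([str(c).endswith(sfx) for c in trimer.chain_id]))
            if not mask.any():
                missing.append(res)
                break
            sites.append(trimer.positions[mask])
        else:
            d = [cdist(sites[i], sites[j]).min()
                 for i in range(3) for j in range(i + 1, 3)]
            seps[res] = float(min(d))
    if missing:
        raise ValueError(f"residues missing in some dimer: {sorted(set(missing))}")
    return [seps[res] for res in sorted(seps)]


def c3_symmetry_rmsd(model: ParticleModel) -> float:
    """RMSD between the model and itself rotated by 120° about z (as a set,
    matched by nearest neighbour)."""
    rot = model.positions @ _rotation_matrix([0, 0, 1], 120.0).T
    from scipy.spatial import cKDTree
    d, _ = cKDTree(model.positions).query(rot)
    return float(np.sqrt((d ** 2).mean()))
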