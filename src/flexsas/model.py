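"""Particle models: coordinates plus per-scatterer scattering properties.

A :class:`ParticleModel` is the container every forward computation consumes.
It holds positions (Å), X-ray electron counts, neutron bound coherent
scattering lengths (fm, protonated state), displaced solvent volumes (Å³),
labile-hydrogen bookkeeping, and per-scatterer segment / residue / chain
labels.  Models may mix protein scatterers (atoms or one-bead-per-residue
beads) with detergent-belt pseudo-atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_NUMBER, NEUTRON_B

SEGMENT_LABELS = (
    "TM", "HAMP1", "interHAMP", "HAMP2", "adaptation", "tip",
    "belt_tail", "belt_head",
)

# CRYSOL-style per-element displaced volumes, Å³ (Fraser et al. convention)
ELEMENT_VOLUME = {
    "H": 5.15, "C": 16.44, "N": 2.49, "O": 9.13, "S": 19.86, "P": 5.73,
    "Se": 28.73, "Fe": 7.99, "Zn": 9.85, "Mg": 9.2, "Ca": 31.9,
    "Na": 4.45, "Cl": 24.84, "K": 11.01,
}


@dataclass
class ParticleModel:
    """Point-scatterer model of a (protein + detergent) particle.

    Attributes
    ----------
    positions : (N, 3) float array, Å
    xray_electrons : (N,) float array, e
    neutron_b : (N,) float array, fm — fully protonated scattering length
    excluded_volume : (N,) float array, Å³
    n_exchangeable_h : (N,) float array — labile hydrogens per scatterer
    deuteration_fraction : (N,) float array in [0, 1] — non-labile H already D
    segment : (N,) str array — one of SEGMENT_LABELS
    residue_index : (N,) int array, 1-based; -1 for belt pseudo-atoms
    chain_id : (N,) str array
    """

    positions: np.ndarray
    xray_electrons: np.ndarray
    neutron_b: np.ndarray
    excluded_volume: np.ndarray
    n_exchangeable_h: np.ndarray
    deuteration_fraction: np.ndarray
    segment: np.ndarray
    residue_index: np.ndarray
    chain_id: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        for name in ("xray_electrons", "neutron_b", "excluded_volume",
                     "n_exchangeable_h", "deuteration_fraction"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 0:
                arr = np.full(n, float(arr))
            setattr(self, name, arr)
        self.segment = np.asarray(self.segment, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.validate()

    # -- basic protocol ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.positions)

    def validate(self) -> None:
        n = self.n
        for name in ("xray_electrons", "neutron_b", "excluded_volume",
                     "n_exchangeable_h", "deuteration_fraction",
                     "segment", "residue_index", "chain_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if np.any(self.excluded_volume < 0):
            raise ValueError("excluded_volume must be >= 0")
        if np.any((self.deuteration_fraction < 0)
                  | (self.deuteration_fraction > 1)):
            raise ValueError("deuteration_fraction must lie in [0, 1]")
        bad = set(self.segment) - set(SEGMENT_LABELS)
        if bad:
            raise ValueError(f"unknown segment labels: {sorted(bad)}")

    def copy(self) -> "ParticleModel":
        return ParticleModel(
            self.positions.copy(), self.xray_electrons.copy(),
            self.neutron_b.copy(), self.excluded_volume.copy(),
            self.n_exchangeable_h.copy(), self.deuteration_fraction.copy(),
            self.segment.copy(), self.residue_index.copy(),
            self.chain_id.copy(), dict(self.metadata))

    def select(self, mask: np.ndarray) -> "ParticleModel":
        mask = np.asarray(mask)
        return ParticleModel(
            self.positions[mask], self.xray_electrons[mask],
            self.neutron_b[mask], self.excluded_volume[mask],
            self.n_exchangeable_h[mask], self.deuteration_fraction[mask],
            self.segment[mask], self.residue_index[mask],
            self.chain_id[mask], dict(self.metadata))

    @staticmethod
    def concat(models: list["ParticleModel"]) -> "ParticleModel":
        meta: dict = {}
        for m in models:
            meta.update(m.metadata)
        return ParticleModel(
            np.concatenate([m.positions for m in models]),
            np.concatenate([m.xray_electrons for m in models]),
            np.concatenate([m.neutron_b for m in models]),
            np.concatenate([m.excluded_volume for m in models]),
            np.concatenate([m.n_exchangeable_h for m in models]),
            np.concatenate([m.deuteration_fraction for m in models]),
            np.concatenate([m.segment for m in models]),
            np.concatenate([m.residue_index for m in models]),
            np.concatenate([m.chain_id for m in models]),
            meta)

    def segment_mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.segment, labels)

    @property
    def is_belt(self) -> np.ndarray:
        return self.segment_mask("belt_tail", "belt_head")


@dataclass
class SegmentMap:
    """Residue ranges of the transducer segments and the hinge pivots.

    Defaults follow the NpHtrII construct numbering: transmembrane region
    residues 1-83, HAMP1 84-136, inter-HAMP 137-156.  Hinge pivot residues are
    configurable; by default the HAMP1 hinge sits at the HAMP1/inter-HAMP
    boundary, the HAMP2 hinge at the HAMP2/adaptation boundary, and the Gly
    hinge at the centre of the glycine-hinge motif of the adaptation domain.
    """

    ranges: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "TM": (1, 83),
        "HAMP1": (84, 136),
        "interHAMP": (137, 156),
        "HAMP2": (157, 210),
        "adaptation": (211, 340),
        "tip": (341, 400),
    })
    hinge_residues: dict[str, int] = field(default_factory=lambda: {
        "HAMP1": 136, "HAMP2": 210, "Gly": 270,
    })

    def __post_init__(self) -> None:
        last = 0
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"segment {name}: range {lo}-{hi} not ascending")
            if lo <= last:
                raise ValueError(f"segment {name}: ranges overlap or out of order")
            last = hi

    def segment_of(self, residue: int) -> str:
        for name, (lo, hi) in self.ranges.items():
            if lo <= residue <= hi:
                return name
        return "tip"


@dataclass(frozen=True)
class HingeBend:
    """A single hinge bend: which hinge, by how many degrees.

    ``angle`` follows a right-hand-rule convention about the bend axis
    (ẑ × distal-rod-axis, sign-normalised); positive angles bend the
    cytoplasmic tip toward the -y half-space for a rod oriented on +z, which
    is the direction used to converge tips when building tripod trimers.
    """

    hinge_id: str
    angle: float  # degrees
    bend_plane: str = "auto"

    def __post_init__(self) -> None:
        if abs(self.angle) > 180.0:
            raise ValueError(f"|angle| > 180 deg: {self.angle}")


# -- PDB I/O ------------------------------------------------------------------

def model_from_pdb(path: str, segment_map: SegmentMap | None = None) -> ParticleModel:
    """Read a PDB file into a ParticleModel (all atoms, one scatterer each).

    HETATM records with residue names DTL/DHD are interpreted as belt tail /
    head pseudo-atoms.  Other atoms get element-wise electron counts, Sears
    scattering lengths and CRYSOL-style displaced volumes.
    """
    import gemmi

    smap = segment_map or SegmentMap()
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    pos, elec, nb, vol, nexh, segs, resi, chains = [], [], [], [], [], [], [], []
    from .constants import (DDM_HEAD_ELECTRONS, DDM_HEAD_EXCHANGEABLE_H,
                            DDM_HEAD_FORMULA, DDM_TAIL_ELECTRONS,
                            DDM_TAIL_FORMULA, HEAD_PSEUDO_ELECTRONS,
                            TAIL_PSEUDO_ELECTRONS, formula_neutron_b)
    b_tail = TAIL_PSEUDO_ELECTRONS / DDM_TAIL_ELECTRONS * formula_neutron_b(DDM_TAIL_FORMULA)
    b_head = HEAD_PSEUDO_ELECTRONS / DDM_HEAD_ELECTRONS * formula_neutron_b(DDM_HEAD_FORMULA)
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    p = atom.pos
                    pos.append((p.x, p.y, p.z))
                    chains.append(chain.name)
                    if res.name in ("DTL", "DHD"):
                        tail = res.name == "DTL"
                        elec.append(TAIL_PSEUDO_ELECTRONS if tail
                                    else HEAD_PSEUDO_ELECTRONS)
                        nb.append(b_tail if tail else b_head)
                        from .constants import DDM_HEAD_VOLUME, DDM_TAIL_VOLUME
                        vol.append(TAIL_PSEUDO_ELECTRONS / DDM_TAIL_ELECTRONS
                                   * DDM_TAIL_VOLUME if tail else
                                   HEAD_PSEUDO_ELECTRONS / DDM_HEAD_ELECTRONS
                                   * DDM_HEAD_VOLUME)
                        nexh.append(0.0 if tail else
                                    HEAD_PSEUDO_ELECTRONS / DDM_HEAD_ELECTRONS
                                    * DDM_HEAD_EXCHANGEABLE_H)
                        segs.append("belt_tail" if tail else "belt_head")
                        resi.append(-1)
                    else:
                        el = atom.element.name
                        el = {"D": "D"}.get(el, el)
                        elec.append(ATOMIC_NUMBER.get(el, atom.element.atomic_number))
                        nb.append(NEUTRON_B.get(el, 0.0))
                        vol.append(ELEMENT_VOLUME.get(el, 10.0))
                        # crude labile-H bookkeeping: N/O-bound H not resolved
                        # in heavy-atom files; count one per N
                        nexh.append(1.0 if el == "N" else 0.0)
                        segs.append(smap.segment_of(res.seqid.num))
                        resi.append(res.seqid.num)
        break  # first model only
    return ParticleModel(np.array(pos), np.array(elec, float),
                         np.array(nb, float), np.array(vol, float),
                         np.array(nexh, float), np.zeros(len(pos)),
                         np.array(segs, dtype=object),
                         np.array(resi, int), np.array(chains, dtype=object),
                         {"source": str(path)})


def model_to_pdb(model: ParticleModel, path: str) -> None:
    """Write a ParticleModel as fixed-column PDB.

    Protein scatterers become CA ATOM records (residue GLY placeholder); belt
    pseudo-atoms become HETATM records with residue names DTL/DHD, element C.
    Round-trippable by :func:`model_from_pdb` at bead granularity.
    """
    lines = []
    serial = 0
    # belt pseudo-atoms grouped by species so reads regroup identically
    order = np.concatenate([
        np.nonzero(~model.is_belt)[0],
        np.nonzero(model.segment_mask("belt_tail"))[0],
        np.nonzero(model.segment_mask("belt_head"))[0]])
    for i in order:
        serial += 1
        x, y, z = model.positions[i]
        seg = model.segment[i]
        if seg in ("belt_tail", "belt_head"):
            rec, name, resn = "HETATM", " C  ", "DTL" if seg == "belt_tail" else "DHD"
            resnum = 9000 + (0 if seg == "belt_tail" else 1)
        else:
            rec, name, resn = "ATOM  ", " CA ", "GLY"
            resnum = int(model.residue_index[i])
        ch = str(model.chain_id[i])[:1] or "A"
        lines.append(
            f"{rec}{serial % 100000:5d} {name} {resn} {ch}{resnum % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{'C':>2s}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
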