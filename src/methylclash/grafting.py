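"""In-silico methyl grafting onto DNA bases.

A methylated-base template (m5C, m6A or m4C) is superposed onto the target
base using the base ring atoms only (no sugar or phosphate atoms enter the
fit), and the template's methyl carbon is carried along by the fitted
rigid-body transform.  The methyl lies exactly in the plane of the idealized
template base.  N-linked methyls (m6A, m4C) default to the *trans* rotamer on
the Hoogsteen side of the base, as observed in duplex DNA; the *cis*
(Watson-Crick side) rotamer is available as an override for special cases
such as bases that pair through their Hoogsteen edge or are unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from ._basegeom import BASE_COORDS, PURINE_RING, PYRIMIDINE_RING
from .errors import GraftingError
from .radii import METHYL_RADIUS
from .structure import Residue

#: methyl carbon to attachment atom bond lengths, Angstrom
BOND_LENGTH_C_CH3 = 1.50   # aromatic C5-CH3 (m5C)
BOND_LENGTH_N_CH3 = 1.47   # exocyclic N-CH3 (m6A, m4C)
#: attachment bond angle at the exocyclic nitrogen / ring carbon, degrees
BOND_ANGLE = 120.0

_TEMPLATE_SPEC = {
    # methyl_type: (base, attachment atom, ring anchor, trans-side ref, cis-side ref)
    "m5C": ("DC", "C5", None, None, None),
    "m6A": ("DA", "N6", "C6", "N7", "N1"),
    "m4C": ("DC", "N4", "C4", "C5", "N3"),
}

METHYL_TYPES = tuple(_TEMPLATE_SPEC)


def _base3d(code: str) -> Dict[str, np.ndarray]:
    return {k: np.array([x, y, 0.0]) for k, (x, y) in BASE_COORDS[code].items()}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class RigidTransform:
    """Proper rotation + translation, x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    @property
    def is_proper(self) -> bool:
        return np.linalg.det(self.rotation) > 0


@dataclass
class MethylTemplate:
    """Reference methylated-base geometry: planar base + in-plane methyl carbon."""

    methyl_type: str
    base_atoms: Dict[str, np.ndarray]
    methyl_coord: np.ndarray
    bond_length: float
    bond_angle: float
    orientation: str = "trans"
    attachment_atom: str = ""
    ring_names: Tuple[str, ...] = ()


@dataclass
class GraftedMethyl:
    """A methyl pseudo-atom placed on a nucleotide."""

    parent: Residue
    methyl_type: str
    orientation: str
    coord: np.ndarray
    radius: float = METHYL_RADIUS
    superposition_rmsd: float = 0.0
    transform: Optional[RigidTransform] = field(default=None, repr=False)

    @property
    def attachment_atom(self) -> str:
        return _TEMPLATE_SPEC[self.methyl_type][1]


def build_template(methyl_type: str) -> MethylTemplate:
    """Idealized template for one methylation type.

    The m5C methyl extends the aromatic plane from C5 along the external
    bisector of C4-C5-C6.  The m6A and m4C methyls sit in the base plane at a
    120 degree angle to the exocyclic C-N bond, on the Hoogsteen (trans) side.
    """
    if methyl_type not in _TEMPLATE_SPEC:
        raise ValueError(f"unknown methylation type {methyl_type!r}; "
                         f"expected one of {METHYL_TYPES}")
    base, attach, anchor, trans_ref, _ = _TEMPLATE_SPEC[methyl_type]
    atoms = _base3d(base)
    p = atoms[attach]
    if methyl_type == "m5C":
        # unique in-plane direction: external bisector at the ring carbon
        direction = _unit(_unit(p - atoms["C4"]) + _unit(p - atoms["C6"]))
        methyl = p + BOND_LENGTH_C_CH3 * direction
        bond_length = BOND_LENGTH_C_CH3
    else:
        # two in-plane directions make the 120 deg angle with the N-C bond;
        # trans = the one on the Hoogsteen side of the base
        to_anchor = _unit(atoms[anchor] - p)
        normal = np.array([0.0, 0.0, 1.0])
        perp = _unit(np.cross(normal, to_anchor))
        cos_t = np.cos(np.radians(BOND_ANGLE))
        sin_t = np.sin(np.radians(BOND_ANGLE))
        candidates = [p + BOND_LENGTH_N_CH3 * (cos_t * to_anchor + s * sin_t * perp)
                      for s in (+1.0, -1.0)]
        ref = atoms[trans_ref]
        methyl = min(candidates, key=lambda c: np.linalg.norm(c - ref))
        bond_length = BOND_LENGTH_N_CH3
    ring = PURINE_RING if base in ("DA", "DG") else PYRIMIDINE_RING
    return MethylTemplate(
        methyl_type=methyl_type,
        base_atoms=atoms,
        methyl_coord=methyl,
        bond_length=bond_length,
        bond_angle=BOND_ANGLE,
        orientation="trans",
        attachment_atom=attach,
        ring_names=tuple(ring),
    )


def _mirror_in_plane(point: np.ndarray, line_a: np.ndarray, line_b: np.ndarray) -> np.ndarray:
    """Reflect a coplanar point across the line a-b (all points in one plane)."""
    axis = _unit(line_b - line_a)
    v = point - line_a
    return line_a + 2.0 * (v @ axis) * axis - v


def cis_methyl_coord(template: MethylTemplate) -> np.ndarray:
    """The template methyl mirrored to the Watson-Crick side of the base.

    The mirror line runs from the attachment atom to its ring anchor, within
    the base plane, so bond length and attachment angle are preserved.
    """
    _, attach, anchor, _, _ = _TEMPLATE_SPEC[template.methyl_type]
    if anchor is None:
        raise ValueError(f"{template.methyl_type}: the C-linked methyl has a unique "
                         "in-plane position; cis/trans applies to N-linked methyls only")
    return _mirror_in_plane(template.methyl_coord,
                            template.base_atoms[attach],
                            template.base_atoms[anchor])


def superpose_base(template: MethylTemplate, target: Residue) -> Tuple[RigidTransform, float]:
    """Least-squares rigid superposition of the template base onto the target.

    Only the base ring atoms enter the fit.  Returns the proper-rotation
    transform mapping template coordinates onto the target, and the RMSD of
    the fitted ring atoms.

    Raises
    ------
    GraftingError
        If the target lacks any of the matched base atoms.
    """
    names = template.ring_names
    missing = [n for n in names if target.get_atom(n) is None]
    if missing:
        raise GraftingError(
            f"{target.label}: cannot superpose {template.methyl_type} template; "
            f"missing base atoms: {', '.join(missing)}"
        )
    tmpl_pts = np.array([template.base_atoms[n] for n in names])
    targ_pts = np.array([target.get_atom(n).coord for n in names])
    tmpl_centroid = tmpl_pts.mean(axis=0)
    targ_centroid = targ_pts.mean(axis=0)
    rot, _ = Rotation.align_vectors(targ_pts - targ_centroid, tmpl_pts - tmpl_centroid)
    rotation = rot.as_matrix()
    translation = targ_centroid - rotation @ tmpl_centroid
    # recompute the RMSD from the moved coordinates; the solver's reported
    # residual loses precision to cancellation near an exact fit
    moved = tmpl_pts @ rotation.T + translation
    rmsd = np.sqrt(np.mean(np.sum((moved - targ_pts) ** 2, axis=1)))
    return RigidTransform(rotation, translation), float(rmsd)


def graft_methyl(target: Residue, methyl_type: str, orientation: str = "trans",
                 template: Optional[MethylTemplate] = None) -> GraftedMethyl:
    """Place a methyl pseudo-atom (radius 2.0 A) on a target base.

    The target base must be compatible with the methylation type: cytosine
    for m5C/m4C, adenine for m6A.  ``orientation="cis"`` mirrors the N-linked
    methyl to the Watson-Crick side within the base plane before transforming.
    """
    if orientation not in ("trans", "cis"):
        raise ValueError(f"orientation must be 'trans' or 'cis', got {orientation!r}")
    if template is None:
        template = build_template(methyl_type)
    base, _, _, _, _ = _TEMPLATE_SPEC[template.methyl_type]
    if target.canonical_base != base:
        raise ValueError(
            f"{target.label}: base {target.name!r} is incompatible with "
            f"{template.methyl_type} (requires {base})"
        )
    methyl_local = (template.methyl_coord if orientation == "trans"
                    else cis_methyl_coord(template))
    transform, rmsd = superpose_base(template, target)
    coord = transform.apply(methyl_local)
    return GraftedMethyl(
        parent=target,
        methyl_type=template.methyl_type,
        orientation=orientation,
        coord=coord,
        radius=METHYL_RADIUS,
        superposition_rmsd=rmsd,
        transform=transform,
    )


def base_plane_deviation(grafted: GraftedMethyl) -> float:
    """Unsigned distance of the methyl from the least-squares base-ring plane."""
    ring = grafted.parent.base_ring_atoms()
    if len(ring) < 3:
        raise GraftingError(f"{grafted.parent.label}: not enough base atoms for a plane")
    pts = np.array([a.coord for a in ring.values()])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    return float(abs((grafted.coord - centroid) @ normal))
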