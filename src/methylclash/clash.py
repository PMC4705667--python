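"""Distance- and volume-based steric clash scores for grafted methyl groups.

A clash is a pair of non-hydrogen atoms closer than the sum of their van der
Waals radii, after an allowance for coordinate uncertainty is added to the
measured distance.  With R the methyl radius (2.0 A), r the partner radius,
D the measured distance and d = D + epsilon:

    delta_d = R + r - d                      (linear overlap, A)
    delta_V = pi (R+r-d)^2 (d^2 + 2dr - 3r^2 + 2dR + 6rR - 3R^2) / (12 d)
                                             (lens overlap volume, A^3)

The lens formula applies in the partial-overlap regime |R-r| < d < R+r; for
d <= |R-r| one sphere is contained in the other and delta_V is the volume of
the smaller sphere (the lens expression reaches this value continuously at
d = |R-r|); for d >= R+r the overlap is zero.

Per-methyl scores aggregate the most severe and the cumulative clash in both
domains, plus contact and contacted-residue counts, partitioned by partner
category (protein main chain incl. C-beta, protein side chain, DNA of either
strand) and by partner element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .grafting import GraftedMethyl
from .radii import METHYL_RADIUS, RadiusTable, default_table
from .structure import (Atom, PartnerCategory, Residue, StructureComplex,
                        classify_partner)

#: parent-base atoms within three bonds of the methyl carbon, excluded from
#: the partner set (standard 1-2/1-3/1-4 steric exclusion); the rest of the
#: parent nucleotide remains eligible
BONDED_EXCLUSIONS = {
    "m5C": frozenset({"C5", "C4", "C6", "N1", "N3", "N4"}),
    "m6A": frozenset({"N6", "C6", "N1", "C5"}),
    "m4C": frozenset({"N4", "C4", "N3", "C5"}),
}


@dataclass
class ClashParams:
    """Scoring parameters.

    epsilon is the coordinate-uncertainty allowance added to every measured
    distance (0.1 A by default; the robustness sweep raises it to 0.4 A).
    neighbor_cutoff bounds the candidate search and must not be below the
    largest possible R + r = 4.0 A.
    """

    epsilon: float = 0.1
    neighbor_cutoff: float = 5.0
    include_protein: bool = True
    include_dna: bool = True
    include_excluded: bool = False  # waters, ions, non-nucleic ligands

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.neighbor_cutoff < 4.0:
            raise ValueError("neighbor_cutoff must be >= max possible R + r = 4.0 A")


def distance_clash(R: float, r: float, D: float, epsilon: float = 0.1) -> float:
    """Linear van der Waals overlap Delta-d = R + r - (D + epsilon), in A.

    A non-positive value means no clash; callers discard those pairs.
    """
    if R <= 0 or r <= 0:
        raise ValueError("radii must be positive")
    if D < 0:
        raise ValueError("interatomic distance D must be >= 0")
    return R + r - (D + epsilon)


def sphere_overlap_volume(R: float, r: float, d: float) -> float:
    """Intersection volume of spheres with radii R and r at center distance d."""
    if R <= 0 or r <= 0:
        raise ValueError("radii must be positive")
    if d < 0:
        raise ValueError("center distance must be >= 0")
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        rmin = min(R, r)
        return 4.0 / 3.0 * math.pi * rmin ** 3
    return (math.pi * (R + r - d) ** 2
            * (d * d + 2 * d * r - 3 * r * r + 2 * d * R + 6 * r * R - 3 * R * R)
            / (12.0 * d))


def volume_clash(R: float, r: float, D: float, epsilon: float = 0.1) -> float:
    """Overlap volume Delta-V in A^3 with d = D + epsilon."""
    if D < 0:
        raise ValueError("interatomic distance D must be >= 0")
    return sphere_overlap_volume(R, r, D + epsilon)


@dataclass
class Contact:
    """A candidate partner within the neighbor cutoff (clashing or not)."""

    partner: Atom
    D: float
    r: float
    category: PartnerCategory
    element: str
    is_methyl_methyl: bool = False


@dataclass
class ClashPair:
    """One methyl-vs-atom steric conflict (delta_d > 0 by construction)."""

    methyl_ref: GraftedMethyl
    partner: Atom
    D: float
    delta_d: float
    delta_V: float
    category: PartnerCategory
    partner_element: str
    is_methyl_methyl: bool = False


@dataclass
class MethylClashSummary:
    """Aggregated clash scores for one grafted methyl."""

    max_delta_d: float = 0.0
    sum_delta_d: float = 0.0
    max_delta_V: float = 0.0
    sum_delta_V: float = 0.0
    n_contacts: int = 0
    n_residues: int = 0
    by_category: Dict[str, dict] = field(default_factory=dict)
    by_element: Dict[str, dict] = field(default_factory=dict)

    MEASURES = ("max_delta_d", "sum_delta_d", "max_delta_V", "sum_delta_V",
                "n_contacts", "n_residues")

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in self.MEASURES}


def find_contacts(methyl: GraftedMethyl, complex_: StructureComplex,
                  params: Optional[ClashParams] = None,
                  other_methyls: Sequence[GraftedMethyl] = (),
                  table: Optional[RadiusTable] = None) -> List[Contact]:
    """All eligible partner atoms within the neighbor cutoff of the methyl.

    Candidate partners are the highest-occupancy conformers of all
    non-hydrogen atoms, minus atoms within three bonds of the methyl carbon
    in the parent base, filtered by the include flags.  Other grafted methyls
    (double-stranded methylation scenarios) may be passed explicitly.
    """
    params = params or ClashParams()
    table = table or default_table()
    excluded_names = BONDED_EXCLUSIONS[methyl.methyl_type]

    candidates: List[Contact] = []
    coords = []
    for atom in complex_.selected_atoms():
        residue = atom.residue
        if residue is methyl.parent and atom.name in excluded_names:
            continue
        category = classify_partner(atom, methyl.parent)
        if category is PartnerCategory.EXCLUDED and not params.include_excluded:
            continue
        if category in (PartnerCategory.PROTEIN_MAIN_CHAIN,
                        PartnerCategory.PROTEIN_SIDE_CHAIN) and not params.include_protein:
            continue
        if category in (PartnerCategory.DNA_SAME_STRAND,
                        PartnerCategory.DNA_OPPOSITE_STRAND) and not params.include_dna:
            continue
        candidates.append(Contact(
            partner=atom, D=0.0, r=table.assign_radius(atom),
            category=category, element=atom.element,
        ))
        coords.append(atom.coord)

    for other in other_methyls:
        if other is methyl:
            continue
        if not params.include_dna:
            continue
        same = other.parent.chain_id == methyl.parent.chain_id
        pseudo = Atom(name=f"CM({other.methyl_type})", element="C",
                      coord=other.coord, residue=other.parent)
        candidates.append(Contact(
            partner=pseudo, D=0.0, r=other.radius,
            category=(PartnerCategory.DNA_SAME_STRAND if same
                      else PartnerCategory.DNA_OPPOSITE_STRAND),
            element="C", is_methyl_methyl=True,
        ))
        coords.append(other.coord)

    if not candidates:
        return []
    coords = np.asarray(coords)
    dists = np.linalg.norm(coords - methyl.coord, axis=1)
    if math.isfinite(params.neighbor_cutoff) and len(coords) > 64:
        # KD-tree pruning; exact distances are still computed above
        tree = cKDTree(coords)
        keep = set(tree.query_ball_point(methyl.coord, params.neighbor_cutoff))
        selected = [(i, c) for i, c in enumerate(candidates) if i in keep]
    else:
        keep_mask = dists <= params.neighbor_cutoff
        selected = [(i, c) for i, c in enumerate(candidates) if keep_mask[i]]
    out = []
    for i, contact in selected:
        contact.D = float(dists[i])
        out.append(contact)
    out.sort(key=lambda c: c.D)
    return out


def clashes_from_contacts(methyl: GraftedMethyl, contacts: Iterable[Contact],
                          epsilon: float = 0.1) -> List[ClashPair]:
    """Convert near contacts to clash pairs at a given allowance (delta_d > 0)."""
    pairs = []
    for c in contacts:
        dd = distance_clash(methyl.radius, c.r, c.D, epsilon)
        if dd <= 0:
            continue
        pairs.append(ClashPair(
            methyl_ref=methyl, partner=c.partner, D=c.D,
            delta_d=dd, delta_V=volume_clash(methyl.radius, c.r, c.D, epsilon),
            category=c.category, partner_element=c.element,
            is_methyl_methyl=c.is_methyl_methyl,
        ))
    return pairs


def find_clashes(methyl: GraftedMethyl, complex_: StructureComplex,
                 params: Optional[ClashParams] = None,
                 other_methyls: Sequence[GraftedMethyl] = (),
                 table: Optional[RadiusTable] = None) -> List[ClashPair]:
    """All steric conflicts (delta_d > 0) of one grafted methyl."""
    params = params or ClashParams()
    contacts = find_contacts(methyl, complex_, params, other_methyls, table)
    return clashes_from_contacts(methyl, contacts, params.epsilon)


def _residue_key(atom: Atom) -> tuple:
    r = atom.residue
    return (r.chain_id, r.seq_id, r.icode, r.name) if r is not None else (atom.name,)


def summarize_methyl(clashes: Sequence[ClashPair],
                     categories: Optional[Iterable[PartnerCategory]] = None
                     ) -> MethylClashSummary:
    """Aggregate per-methyl scores; optionally restricted to partner categories.

    An empty clash list yields the all-zero summary.
    """
    if categories is not None:
        categories = set(categories)
        clashes = [c for c in clashes if c.category in categories]
    summary = MethylClashSummary()
    if not clashes:
        return summary
    dd = [c.delta_d for c in clashes]
    dv = [c.delta_V for c in clashes]
    summary.max_delta_d = max(dd)
    summary.sum_delta_d = float(sum(dd))
    summary.max_delta_V = max(dv)
    summary.sum_delta_V = float(sum(dv))
    summary.n_contacts = len(clashes)
    summary.n_residues = len({_residue_key(c.partner) for c in clashes})
    for c in clashes:
        for key, bucket in ((c.category.value, summary.by_category),
                            (c.partner_element, summary.by_element)):
            entry = bucket.setdefault(key, {
                "n_contacts": 0, "sum_delta_d": 0.0, "sum_delta_V": 0.0,
                "max_delta_d": 0.0, "max_delta_V": 0.0,
            })
            entry["n_contacts"] += 1
            entry["sum_delta_d"] += c.delta_d
            entry["sum_delta_V"] += c.delta_V
            entry["max_delta_d"] = max(entry["max_delta_d"], c.delta_d)
            entry["max_delta_V"] = max(entry["max_delta_V"], c.delta_V)
    return summary


PROTEIN_CATEGORIES = (PartnerCategory.PROTEIN_MAIN_CHAIN,
                      PartnerCategory.PROTEIN_SIDE_CHAIN)
DNA_CATEGORIES = (PartnerCategory.DNA_SAME_STRAND,
                  PartnerCategory.DNA_OPPOSITE_STRAND)
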