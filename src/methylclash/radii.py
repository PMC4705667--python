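"""Implicit-hydrogen van der Waals radii for protein and DNA heavy atoms.

Hydrogens are absorbed into their parent heavy atom, so e.g. an aliphatic
CH/CH2/CH3 carbon carries 2.0 A while a bare carbonyl carbon carries 1.7 A.
Aromatic rings are treated as balls of the smaller in-plane radius (1.7 A);
the carboxylate oxygen radius (1.5 A) is a compromise between carbonyl and
hydroxyl values, and amide O/N share an averaged 1.6 A.  DNA radii are set by
analogy to protein chemistry (base rings like aromatic side chains, exocyclic
amines like the arginine guanidino group, sugar/phosphate oxygens like the
main-chain carbonyl oxygen).  The grafted methyl group, like the thymine
methyl, is an aliphatic carbon of radius 2.0 A.

The table ships as ``data/vdw_radii.tsv`` (first matching rule wins) and may
be overridden by loading a user table with :meth:`RadiusTable.from_tsv`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .structure import Atom, Residue, ResidueKind, canonical_nucleotide

#: radius of the grafted methyl pseudo-atom (aliphatic CH3), symbol R
METHYL_RADIUS = 2.0

DEFAULT_RADIUS = 2.0


@dataclass(frozen=True)
class RadiusRule:
    kind: str            # "protein", "dna" or "any"
    residues: frozenset  # empty set = wildcard
    atoms: frozenset     # empty set = wildcard
    radius: float
    note: str = ""

    def matches(self, kind: str, residue_name: str, atom_name: str) -> bool:
        if self.kind != "any" and self.kind != kind:
            return False
        if self.residues and residue_name not in self.residues:
            return False
        if self.atoms and atom_name not in self.atoms:
            return False
        return True


class RadiusTable:
    """Ordered (residue, atom) -> radius lookup with an "all other" fallback."""

    def __init__(self, rules, default_radius: float = DEFAULT_RADIUS):
        self.rules = list(rules)
        self.default_radius = default_radius
        for rule in self.rules:
            if not 1.2 <= rule.radius <= 2.2:
                raise ValueError(
                    f"radius {rule.radius} out of the physical 1.2-2.2 A range: {rule}"
                )

    @classmethod
    def from_tsv(cls, source) -> "RadiusTable":
        """Load rules from a TSV with columns kind/residues/atoms/radius[/note]."""
        rules = []
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            with open(source) as fh:
                lines = fh.read().splitlines()
        reader = csv.DictReader(
            (ln for ln in lines if ln.strip() and not ln.startswith("#")),
            delimiter="\t",
        )
        for row in reader:
            rules.append(RadiusRule(
                kind=row["kind"].strip(),
                residues=frozenset() if row["residues"].strip() == "*"
                else frozenset(x.strip() for x in row["residues"].split(",")),
                atoms=frozenset() if row["atoms"].strip() == "*"
                else frozenset(x.strip() for x in row["atoms"].split(",")),
                radius=float(row["radius"]),
                note=row.get("note", "").strip(),
            ))
        return cls(rules)

    @classmethod
    def default(cls) -> "RadiusTable":
        ref = resources.files("methylclash").joinpath("data/vdw_radii.tsv")
        with ref.open() as fh:
            return cls.from_tsv(fh)

    def lookup(self, kind: str, residue_name: str, atom_name: str) -> tuple:
        """Return (radius, matched_rule or None)."""
        for rule in self.rules:
            if rule.matches(kind, residue_name, atom_name):
                return rule.radius, rule
        return self.default_radius, None

    def assign_radius(self, atom: Atom, context: Optional[Residue] = None) -> float:
        """Radius in Angstrom for a non-hydrogen atom in its residue context.

        Raises
        ------
        ValueError
            If the atom is a hydrogen/deuterium (contract violation: only
            heavy atoms carry implicit-hydrogen radii).
        """
        if atom.is_hydrogen:
            raise ValueError(f"hydrogen atom {atom.name} has no implicit-hydrogen radius")
        residue = context if context is not None else atom.residue
        if residue is None:
            return self.default_radius
        if residue.kind is ResidueKind.NUCLEOTIDE:
            name = canonical_nucleotide(residue.name) or residue.name
            radius, _ = self.lookup("dna", name, atom.name)
            return radius
        if residue.kind is ResidueKind.AMINO_ACID:
            radius, _ = self.lookup("protein", residue.name.upper(), atom.name)
            return radius
        # waters / ions / ligands are normally excluded from the partner set;
        # if scored anyway they fall back to the default
        return self.default_radius


_default_table: Optional[RadiusTable] = None


def default_table() -> RadiusTable:
    global _default_table
    if _default_table is None:
        _default_table = RadiusTable.default()
    return _default_table


def assign_radius(atom: Atom, context: Optional[Residue] = None) -> float:
    """Radius of ``atom`` under the package's default table."""
    return default_table().assign_radius(atom, context)
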