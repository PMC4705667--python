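"""Macromolecular structure model: atoms, residues, chains and partner categories.

Loads protein-DNA complexes from PDB/mmCIF (via gemmi) into a lightweight
object model suited to clash analysis: hydrogens are stripped on input,
alternate conformers are retained with their labels, and every atom can be
classified into the partner categories used by the clash partitioning
(protein main chain including C-beta, protein side chain, DNA of the
methylated strand, DNA of the opposite strand, or excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

from .errors import StructureContentError, StructureFormatError

logger = logging.getLogger(__name__)

PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

#: protein atoms counted as main chain; C-beta is positionally fixed by the
#: backbone and is therefore included, as is the terminal carboxylate oxygen
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "CB", "OXT"})

_DNA_ALIASES = {
    "A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DT",
    "DA": "DA", "DC": "DC", "DG": "DG", "DT": "DT", "DU": "DT",
    "ADE": "DA", "CYT": "DC", "GUA": "DG", "THY": "DT",
}


def canonical_nucleotide(name: str) -> Optional[str]:
    """Map a residue name to its canonical deoxynucleotide code, or None."""
    return _DNA_ALIASES.get(name.strip().upper())


class ResidueKind(Enum):
    AMINO_ACID = "amino_acid"
    NUCLEOTIDE = "nucleotide"
    WATER = "water"
    OTHER = "other"


class PartnerCategory(Enum):
    PROTEIN_MAIN_CHAIN = "protein_main_chain"
    PROTEIN_SIDE_CHAIN = "protein_side_chain"
    DNA_SAME_STRAND = "dna_same_strand"
    DNA_OPPOSITE_STRAND = "dna_opposite_strand"
    EXCLUDED = "excluded"


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    residue: "Residue" = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    seq_id: int
    chain_id: str
    kind: ResidueKind
    atoms: list = field(default_factory=list)
    icode: str = ""

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seq_id}{self.icode}"

    @property
    def canonical_base(self) -> Optional[str]:
        if self.kind is not ResidueKind.NUCLEOTIDE:
            return None
        return canonical_nucleotide(self.name)

    @property
    def is_purine(self) -> bool:
        return self.canonical_base in ("DA", "DG")

    def get_atom(self, name: str) -> Optional[Atom]:
        """Highest-occupancy conformer of the named atom (ties: altloc sort order)."""
        candidates = [a for a in self.atoms if a.name == name]
        if not candidates:
            return None
        return min(candidates, key=lambda a: (-a.occupancy, a.altloc))

    def base_ring_atoms(self) -> dict:
        """Canonical base ring atoms by name; requires kind=nucleotide."""
        ring = PURINE_RING if self.is_purine else PYRIMIDINE_RING
        out = {}
        for name in ring:
            atom = self.get_atom(name)
            if atom is not None:
                out[name] = atom
        return out


@dataclass
class Chain:
    chain_id: str
    residues: list = field(default_factory=list)

    def kinds(self) -> set:
        return {r.kind for r in self.residues}


@dataclass
class StructureComplex:
    """A protein-DNA complex: chains of residues with polymer classification.

    ``asu_copies`` groups chain ids into biological copies of the complex in
    the asymmetric unit; by default all chains form a single copy.
    """

    id: str
    chains: list = field(default_factory=list)
    resolution: Optional[float] = None
    asu_copies: Optional[list] = None

    def __post_init__(self):
        if self.asu_copies is None:
            self.asu_copies = [[c.chain_id for c in self.chains]]

    def get_chain(self, chain_id: str) -> Optional[Chain]:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        return None

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def atoms(self) -> Iterator[Atom]:
        for residue in self.residues():
            yield from residue.atoms

    def find_residue(self, chain_id: str, seq_id: int, icode: str = "") -> Optional[Residue]:
        chain = self.get_chain(chain_id)
        if chain is None:
            return None
        for residue in chain.residues:
            if residue.seq_id == seq_id and residue.icode == icode.strip():
                return residue
        return None

    def selected_atoms(self) -> list:
        """One atom per (residue, atom name): the highest-occupancy conformer."""
        out = []
        for residue in self.residues():
            seen = set()
            for atom in residue.atoms:
                if atom.name in seen:
                    continue
                seen.add(atom.name)
                out.append(residue.get_atom(atom.name))
        return out

    @property
    def has_protein(self) -> bool:
        return any(r.kind is ResidueKind.AMINO_ACID for r in self.residues())

    @property
    def has_dna(self) -> bool:
        return any(r.kind is ResidueKind.NUCLEOTIDE for r in self.residues())


def _classify_residue(name: str) -> ResidueKind:
    if canonical_nucleotide(name) is not None:
        return ResidueKind.NUCLEOTIDE
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_water():
            return ResidueKind.WATER
        if info.is_amino_acid():
            return ResidueKind.AMINO_ACID
        if info.is_nucleic_acid():
            return ResidueKind.NUCLEOTIDE
    return ResidueKind.OTHER


_ELEMENT_SYMBOLS = {"C", "N", "O", "P", "S", "F", "K", "I", "B", "SE", "CL",
                    "BR", "FE", "MG", "MN", "ZN", "CA", "NA", "CU", "NI", "CO"}


def _element_from_name(atom_name: str) -> str:
    """Infer the element when the file's element column is absent or blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("SE", "CL", "BR", "FE",
                                                       "MG", "MN", "ZN"):
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _convert(st: gemmi.Structure, structure_id: str) -> StructureComplex:
    if len(st) == 0:
        raise StructureContentError(f"{structure_id}: structure contains no model")
    model = st[0]  # first model only; NMR ensembles are out of scope
    chains = []
    n_hydrogens = 0
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            kind = _classify_residue(gres.name)
            residue = Residue(
                name=gres.name.strip(),
                seq_id=gres.seqid.num,
                chain_id=gchain.name,
                kind=kind,
                icode=gres.seqid.icode.strip(),
            )
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    n_hydrogens += 1
                    continue
                element = gatom.element.name if gatom.element.name not in ("X", "")  \
                    else _element_from_name(gatom.name)
                if element in ("H", "D"):
                    n_hydrogens += 1
                    continue
                altloc = gatom.altloc if gatom.altloc not in ("\0", "\x00") else ""
                atom = Atom(
                    name=gatom.name.strip(),
                    element=element,
                    coord=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=gatom.occ,
                    altloc=altloc,
                    residue=residue,
                )
                residue.atoms.append(atom)
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            chains.append(chain)
    if n_hydrogens:
        logger.debug("%s: stripped %d hydrogen/deuterium atoms", structure_id, n_hydrogens)
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureComplex(id=structure_id, chains=chains, resolution=resolution)


def load_complex(path, dialect: str = "auto", require_dna: bool = True) -> StructureComplex:
    """Read a PDB or mmCIF file into a :class:`StructureComplex`.

    Hydrogens are stripped; waters are retained but flagged; altloc conformers
    are retained with labels.  Only the first model is read.

    Parameters
    ----------
    path : str or Path
        Coordinate file.
    dialect : {"pdb", "mmcif", "auto"}
        File format; "auto" detects from content/extension.
    require_dna : bool
        Raise :class:`StructureContentError` when no nucleotide chain is found.
    """
    path = Path(path)
    if not path.exists():
        raise StructureFormatError(f"no such file: {path}")
    formats = {
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
        "auto": gemmi.CoorFormat.Detect,
    }
    if dialect not in formats:
        raise ValueError(f"unknown dialect {dialect!r}; expected pdb, mmcif or auto")
    try:
        st = gemmi.read_structure(str(path), format=formats[dialect])
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"could not parse {path} as {dialect}: {exc}") from exc
    structure_id = st.name.strip() or path.stem
    complex_ = _convert(st, structure_id)
    if not any(r.atoms for r in complex_.residues()):
        raise StructureFormatError(f"{path}: no atoms parsed")
    if require_dna and not complex_.has_dna:
        raise StructureContentError(f"{path}: structure contains no nucleotide chain")
    single_dna_chain = sum(
        1 for c in complex_.chains
        if any(r.kind is ResidueKind.NUCLEOTIDE for r in c.residues)
    ) == 1
    if require_dna and single_dna_chain:
        logger.info("%s: single DNA chain; opposite-strand partners will not occur "
                    "(hairpin constructs are treated as same-strand)", structure_id)
    return complex_


def classify_partner(atom: Atom, methyl_parent: Residue) -> PartnerCategory:
    """Partner category of ``atom`` relative to the methylated nucleotide.

    Protein N, CA, C, O and CB (and the terminal OXT) count as main chain;
    every other protein atom is side chain.  Nucleotide atoms are labelled by
    chain identity relative to the methylated base's chain.  Waters, ions and
    non-nucleic ligands are excluded.
    """
    residue = atom.residue
    if residue is None:
        raise ValueError("atom has no owning residue")
    if residue.kind is ResidueKind.AMINO_ACID:
        if atom.name in MAIN_CHAIN_ATOMS:
            return PartnerCategory.PROTEIN_MAIN_CHAIN
        return PartnerCategory.PROTEIN_SIDE_CHAIN
    if residue.kind is ResidueKind.NUCLEOTIDE:
        if residue.chain_id == methyl_parent.chain_id:
            return PartnerCategory.DNA_SAME_STRAND
        return PartnerCategory.DNA_OPPOSITE_STRAND
    return PartnerCategory.EXCLUDED


def to_gemmi(complex_: StructureComplex) -> gemmi.Structure:
    """Convert back to a gemmi Structure (for writing PDB/mmCIF)."""
    st = gemmi.Structure()
    st.name = complex_.id
    model = gemmi.Model("1")
    for chain in complex_.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for residue in chain.residues:
            gres = gemmi.Residue()
            gres.name = residue.name
            gres.seqid = gemmi.SeqId(residue.seq_id, residue.icode or " ")
            if residue.kind in (ResidueKind.WATER, ResidueKind.OTHER):
                gres.het_flag = "H"
            else:
                gres.het_flag = "A"
            for atom in residue.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coord)
                gatom.occ = atom.occupancy
                if atom.altloc:
                    gatom.altloc = atom.altloc
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(complex_: StructureComplex, path) -> None:
    """Write the complex as a PDB file."""
    to_gemmi(complex_).write_pdb(str(path))
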