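"""Structure input/output for two-partner complex ensembles.

Reads multi-model PDB/mmCIF files into a :class:`ComplexEnsemble` of heavy-atom
poses, restricted to the two named binding partners, and assigns the
physicochemical atom classes consumed by the interface detector and the
empirical energy function.

The representation is deliberately minimal: author residue numbering (so
results carry the labels practitioners use, e.g. R35, Y37, E103 of the anti-GFP
enhancer nanobody), heavy atoms only, waters/ions/ligands dropped.  gemmi does
the heavy lifting for parsing and writing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueId",
    "ComplexEnsemble",
    "read_structure_ensemble",
    "write_ensemble_pdb",
    "write_ensemble_mmcif",
    "assign_atom_classes",
    "atom_classes",
    "BACKBONE_ATOMS",
    "STANDARD_AA",
    "SIDECHAIN_ATOMS",
]

#: Backbone heavy-atom names; these (plus CB) survive alanine truncation.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Side-chain heavy atoms (including CB) per standard residue, PDB naming.
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

# Side-chain class membership tables (atom names per residue).
_DONOR_SC = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
_ACCEPTOR_SC = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}
_POSITIVE_SC = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_NEGATIVE_SC = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}


class ResidueId(NamedTuple):
    """Author-numbered residue identifier, unique within one model."""

    chain_id: str
    seq_num: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:37" or "A:37A"
        return f"{self.chain_id}:{self.seq_num}{self.icode}"


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.element.upper() in ("H", "D"):
            raise ValueError("hydrogens are not represented; drop them on read")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom]

    @property
    def rid(self) -> ResidueId:
        return ResidueId(self.chain_id, self.seq_num, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.rid} {self.res_name}: no atom {name!r}")


@dataclasses.dataclass
class ComplexEnsemble:
    """M structural poses of a receptor/ligand complex with a shared atom inventory."""

    models: list[list[Residue]]
    receptor_chains: frozenset[str]
    ligand_chains: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.receptor_chains = frozenset(self.receptor_chains)
        self.ligand_chains = frozenset(self.ligand_chains)
        validate_ensemble(self)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def side_of(self, residue: Residue) -> str:
        if residue.chain_id in self.receptor_chains:
            return "receptor"
        if residue.chain_id in self.ligand_chains:
            return "ligand"
        raise ValueError(f"chain {residue.chain_id!r} is neither receptor nor ligand")

    def residues(self, model_index: int, side: str | None = None) -> Iterator[Residue]:
        chains: frozenset[str] | None
        if side is None:
            chains = None
        elif side == "receptor":
            chains = self.receptor_chains
        elif side == "ligand":
            chains = self.ligand_chains
        else:
            raise ValueError(f"side must be 'receptor' or 'ligand', got {side!r}")
        for res in self.models[model_index]:
            if chains is None or res.chain_id in chains:
                yield res


def _inventory(model: Sequence[Residue]) -> set[tuple]:
    inv = set()
    for res in model:
        for atom in res.atoms:
            inv.add((res.chain_id, res.seq_num, res.icode, res.res_name, atom.name))
    return inv


def validate_ensemble(ens: ComplexEnsemble) -> None:
    if len(ens.models) < 1:
        raise ValueError("ensemble must contain at least one model")
    if not ens.receptor_chains or not ens.ligand_chains:
        raise ValueError("receptor and ligand chain sets must be non-empty")
    if ens.receptor_chains & ens.ligand_chains:
        raise ValueError("receptor and ligand chain sets must be disjoint")
    ref = _inventory(ens.models[0])
    if not ref:
        raise ValueError("ensemble contains zero protein atoms")
    for m, model in enumerate(ens.models[1:], start=1):
        inv = _inventory(model)
        if inv != ref:
            diff = sorted((inv ^ ref))[0]
            raise ValueError(
                f"atom inventory differs between model 0 and model {m}: "
                f"first mismatch {diff}"
            )
    for model in ens.models:
        seen: set[ResidueId] = set()
        for res in model:
            if res.rid in seen:
                raise ValueError(f"duplicate residue id {res.rid} within a model")
            seen.add(res.rid)


def atom_classes(res_name: str, atom_name: str, element: str) -> frozenset[str]:
    """Physicochemical classes for one heavy atom.

    Pure function of (residue name, atom name, element).  Standard residues use
    the fixed lookup tables; anything else falls back to element rules
    (C/S nonpolar, N donor, O acceptor).
    """
    element = element.upper()
    classes: set[str] = set()
    if res_name in STANDARD_AA:
        if element in ("C", "S"):
            classes.add("nonpolar")
        if atom_name == "N":
            classes.add("donor")
        if atom_name in ("O", "OXT"):
            classes.add("acceptor")
        if atom_name == "OXT":
            classes.add("negative")
        if atom_name in _DONOR_SC.get(res_name, ()):
            classes.add("donor")
        if atom_name in _ACCEPTOR_SC.get(res_name, ()):
            classes.add("acceptor")
        if atom_name in _POSITIVE_SC.get(res_name, ()):
            classes.add("positive")
        if atom_name in _NEGATIVE_SC.get(res_name, ()):
            classes.add("negative")
    else:
        if element in ("C", "S"):
            classes.add("nonpolar")
        elif element == "N":
            classes.add("donor")
        elif element == "O":
            classes.add("acceptor")
    return frozenset(classes)


def assign_atom_classes(ensemble: ComplexEnsemble) -> ComplexEnsemble:
    """Assign classes to every atom in place (idempotent); returns the ensemble."""
    for model in ensemble.models:
        for res in model:
            for atom in res.atoms:
                atom.classes = atom_classes(res.res_name, atom.name, atom.element)
    return ensemble


def _is_blank_altloc(alt: str) -> bool:
    return alt in ("", " ", "\0")


def _resolve_altlocs(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Per atom name keep the highest-occupancy location, ties by file order."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = a
            order.append(a.name)
        elif a.occ > by_name[a.name].occ:
            by_name[a.name] = a
    return [by_name[n] for n in order]


def read_structure_ensemble(
    path: str | Path,
    format: str = "auto",
    receptor_chains: Iterable[str] = (),
    ligand_chains: Iterable[str] = (),
) -> ComplexEnsemble:
    """Read a (possibly multi-model) PDB or mmCIF file into a ComplexEnsemble.

    Hydrogens, waters, ions and non-amino-acid heteroatoms are dropped; altloc
    duplicates are resolved to the highest-occupancy copy.  The model count
    equals the file's MODEL count (1 if none).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    receptor_chains = frozenset(receptor_chains)
    ligand_chains = frozenset(ligand_chains)
    wanted = receptor_chains | ligand_chains
    if not receptor_chains or not ligand_chains:
        raise ValueError("receptor_chains and ligand_chains must both be non-empty")

    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    st = gemmi.read_structure(str(path), format=fmt)

    models: list[list[Residue]] = []
    for model in st:
        chains_here = {ch.name for ch in model}
        missing = wanted - chains_here
        if missing:
            raise ValueError(
                f"chain(s) {sorted(missing)} not present in model "
                f"{model.num} of {path.name}"
            )
        residues: list[Residue] = []
        for chain in model:
            if chain.name not in wanted:
                continue
            for res in chain:
                if res.is_water():
                    continue
                info = gemmi.find_tabulated_residue(res.name)
                if info is None or not info.is_amino_acid():
                    continue
                kept = _resolve_altlocs(
                    [a for a in res if not a.is_hydrogen()]
                )
                atoms = [
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        altloc="" if _is_blank_altloc(a.altloc) else a.altloc,
                        occupancy=a.occ,
                    )
                    for a in kept
                ]
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_num=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        res_name=res.name,
                        atoms=atoms,
                    )
                )
        models.append(residues)

    return ComplexEnsemble(
        models=models,
        receptor_chains=receptor_chains,
        ligand_chains=ligand_chains,
        source=f"{path}::{format}",
    )


def _to_gemmi(ensemble: ComplexEnsemble, name: str = "capscan") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for m, model in enumerate(ensemble.models, start=1):
        gm = gemmi.Model(m)
        chains: dict[str, gemmi.Chain] = {}
        for res in model:
            ch = chains.get(res.chain_id)
            if ch is None:
                ch = gemmi.Chain(res.chain_id)
                chains[res.chain_id] = ch
            gr = gemmi.Residue()
            gr.name = res.res_name
            gr.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                if atom.altloc:
                    ga.altloc = atom.altloc
                gr.add_atom(ga)
            ch.add_residue(gr)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_ensemble_pdb(ensemble: ComplexEnsemble, path: str | Path) -> None:
    """Write all models as a MODEL/ENDMDL multi-model PDB file."""
    _to_gemmi(ensemble).write_pdb(str(path))


def write_ensemble_mmcif(ensemble: ComplexEnsemble, path: str | Path) -> None:
    st = _to_gemmi(ensemble)
    st.make_mmcif_document().write_file(str(path))
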