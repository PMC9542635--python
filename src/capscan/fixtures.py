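"""Synthetic complex ensembles and ELISA datasets with known answers.

Every designed fixture isolates one cross-chain atom-pair contact per residue
pair so that the empirical energy of the complex is an exact hand-computable
sum: the controlled atom pair sits at its designed distance, and every other
cross-chain atom pair is kept beyond the 8 Angstrom energy cutoff by
construction (receptor spectators pulled behind the contact, ligand spectators
pushed past it, one well-separated "lane" per contact).  Because a ContactSpec
places a chosen subset of a residue's heavy atoms, bonds to skipped atoms are
stretched; the fixtures trade local geometric realism for exact known-answer
energetics, which is what they exist for.

Gaussian coordinate jitter across models emulates the pose spread of an MD
ensemble (no claim of physical realism).  A second generator produces
saturation-binding response tables for the ELISA fitter.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import (
    Atom,
    ComplexEnsemble,
    Residue,
    SIDECHAIN_ATOMS,
    assign_atom_classes,
    write_ensemble_pdb,
)

__all__ = [
    "ResidueSpec",
    "ContactSpec",
    "generate_complex_ensemble",
    "preset_charge_hbond_np",
    "generate_elisa_dataset",
]

_BACKBONE_ORDER = ("N", "CA", "C", "O")


def _element_of(atom_name: str) -> str:
    return atom_name[0]  # PDB convention for standard amino-acid heavy atoms


@dataclasses.dataclass(frozen=True)
class ResidueSpec:
    """A residue and the subset of its heavy atoms to place."""

    res_name: str
    atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        valid = set(_BACKBONE_ORDER) | {"OXT"} | set(
            SIDECHAIN_ATOMS.get(self.res_name, ())
        )
        unknown = set(self.atoms) - valid
        if unknown:
            raise ValueError(f"{self.res_name}: unknown atoms {sorted(unknown)}")


@dataclasses.dataclass(frozen=True)
class ContactSpec:
    """One designed cross-chain contact: a residue pair plus one controlled
    atom-pair distance.

    ``pairs`` is a list of (receptor_atom, ligand_atom, distance) tuples; the
    same atom pair listed twice with different distances is a conflicting
    constraint, and more than one distinct controlled pair cannot be realised
    under the isolation-by-construction layout — both raise.
    """

    receptor: ResidueSpec
    ligand: ResidueSpec
    pairs: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], float] = {}
        for ra, la, d in self.pairs:
            if d <= 0:
                raise ValueError("designed distances must be positive")
            if ra not in self.receptor.atoms or la not in self.ligand.atoms:
                raise ValueError(f"contact atoms {(ra, la)} not among placed atoms")
            key = (ra, la)
            if key in seen and seen[key] != d:
                raise ValueError(
                    f"conflicting distance constraints on atom pair {key}: "
                    f"{seen[key]} vs {d}"
                )
            seen[key] = d
        if len(seen) != 1:
            raise ValueError(
                "exactly one controlled atom pair per contact is supported; "
                f"got {len(seen)}"
            )

    @property
    def pair(self) -> tuple[str, str, float]:
        ra, la, d = self.pairs[0]
        return ra, la, d


def _place_cluster(
    atom_names: list[str], start_x: float, step: float, y: float
) -> dict[str, np.ndarray]:
    """Compact zig-zag chain of spectator atoms along x."""
    coords = {}
    for i, name in enumerate(atom_names):
        coords[name] = np.array(
            [start_x + step * i, y + 0.5 * (i % 2), 0.6 * ((i // 2) % 2)]
        )
    return coords


def _build_base_model(
    specs: list[ContactSpec], receptor_chain: str, ligand_chain: str
) -> list[Residue]:
    lane_spacing = 40.0
    margin = 8.5  # keep spectators beyond the 8 A energy cutoff
    residues_r: list[Residue] = []
    residues_l: list[Residue] = []
    for i, spec in enumerate(specs):
        y = lane_spacing * i
        ratom, latom, dist = spec.pair

        # receptor contact atom at the lane origin, its partner at +dist along x;
        # spectators anchored at x <= -margin (receptor) and x >= +margin
        # (ligand) so every non-designed cross-chain pair stays out of range
        r_spect = [a for a in spec.receptor.atoms if a != ratom]
        r_coords = _place_cluster(r_spect, start_x=-margin - 1.4 * len(r_spect), step=1.4, y=y)
        r_coords[ratom] = np.array([0.0, y, 0.0])

        l_spect = [a for a in spec.ligand.atoms if a != latom]
        l_coords = _place_cluster(l_spect, start_x=max(dist, 0.0) + margin + 0.5, step=1.4, y=y)
        l_coords[latom] = np.array([dist, y, 0.0])

        residues_r.append(
            Residue(
                chain_id=receptor_chain,
                seq_num=i + 1,
                icode="",
                res_name=spec.receptor.res_name,
                atoms=[
                    Atom(name=n, element=_element_of(n), coords=r_coords[n])
                    for n in spec.receptor.atoms
                ],
            )
        )
        residues_l.append(
            Residue(
                chain_id=ligand_chain,
                seq_num=i + 1,
                icode="",
                res_name=spec.ligand.res_name,
                atoms=[
                    Atom(name=n, element=_element_of(n), coords=l_coords[n])
                    for n in spec.ligand.atoms
                ],
            )
        )
    return residues_r + residues_l


def generate_complex_ensemble(
    specs: list[ContactSpec],
    n_models: int = 20,
    jitter_sd: float = 0.0,
    seed: int = 0,
    receptor_chain: str = "A",
    ligand_chain: str = "B",
    path: str | Path | None = None,
) -> ComplexEnsemble:
    """Build a multi-model two-chain complex realising the designed contacts.

    The jitter-free base pose holds every designed distance exactly; each
    model applies isotropic Gaussian jitter of ``jitter_sd`` to all
    coordinates.  Classes are assigned; a multi-model PDB is written when
    ``path`` is given.  Seeded and reproducible.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not specs:
        raise ValueError("need at least one ContactSpec")
    base = _build_base_model(specs, receptor_chain, ligand_chain)
    rng = np.random.default_rng(seed)
    models: list[list[Residue]] = []
    for _ in range(n_models):
        model = []
        for res in base:
            atoms = []
            for atom in res.atoms:
                delta = (
                    rng.normal(0.0, jitter_sd, 3) if jitter_sd > 0 else np.zeros(3)
                )
                atoms.append(
                    Atom(name=atom.name, element=atom.element, coords=atom.coords + delta)
                )
            model.append(
                Residue(
                    chain_id=res.chain_id,
                    seq_num=res.seq_num,
                    icode=res.icode,
                    res_name=res.res_name,
                    atoms=atoms,
                )
            )
        models.append(model)
    ens = ComplexEnsemble(
        models=models,
        receptor_chains=frozenset({receptor_chain}),
        ligand_chains=frozenset({ligand_chain}),
        source="synthetic:generate_complex_ensemble",
    )
    assign_atom_classes(ens)
    if path is not None:
        write_ensemble_pdb(ens, path)
    return ens


def preset_charge_hbond_np() -> list[ContactSpec]:
    """Three contacts with a designed hot-spot ordering charge > hbond > nonpolar.

    LYS NZ vs ASP OD1 at 3.0 A (salt bridge: charge + donor/acceptor terms),
    SER OG vs ASN OD1 at 3.0 A (hydrogen bond only), LEU CD1 vs VAL CG1 at
    3.4 A (single nonpolar contact at full ramp strength).
    """
    bb = ("N", "CA", "C", "O", "CB")
    return [
        ContactSpec(
            receptor=ResidueSpec("LYS", bb + ("NZ",)),
            ligand=ResidueSpec("ASP", bb + ("OD1",)),
            pairs=(("NZ", "OD1", 3.0),),
        ),
        ContactSpec(
            receptor=ResidueSpec("SER", bb + ("OG",)),
            ligand=ResidueSpec("ASN", bb + ("OD1",)),
            pairs=(("OG", "OD1", 3.0),),
        ),
        ContactSpec(
            receptor=ResidueSpec("LEU", bb + ("CD1",)),
            ligand=ResidueSpec("VAL", bb + ("CG1",)),
            pairs=(("CD1", "CG1", 3.4),),
        ),
    ]


def generate_elisa_dataset(
    kd_nm: float,
    bmax: float = 1.0,
    concentrations_nm: np.ndarray | None = None,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Saturation-binding responses y = Bmax x/(Kd+x) + N(0, noise_sd), floored
    at 0; default 8 log-spaced concentrations spanning 0.01..100 x Kd.

    Returns a DataFrame with columns concentration_nM, response, replicate;
    written as CSV when ``path`` is given.
    """
    if kd_nm <= 0:
        raise ValueError("kd must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if concentrations_nm is None:
        concentrations_nm = np.logspace(
            np.log10(0.01 * kd_nm), np.log10(100 * kd_nm), 8
        )
    x = np.asarray(concentrations_nm, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        y = bmax * x / (kd_nm + x)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, x.shape)
        y = np.clip(y, 0.0, None)
        for xi, yi in zip(x, y):
            rows.append({"concentration_nM": xi, "response": yi, "replicate": rep})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
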