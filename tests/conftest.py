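"""Shared builders for small in-memory complexes used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from capscan.structio import Atom, ComplexEnsemble, Residue, assign_atom_classes


def make_atom(name: str, element: str, coords, classes=frozenset()) -> Atom:
    return Atom(name=name, element=element, coords=np.asarray(coords, float),
                classes=frozenset(classes))


def make_residue(chain: str, seq: int, res_name: str, atoms, icode: str = "") -> Residue:
    return Residue(chain_id=chain, seq_num=seq, icode=icode, res_name=res_name,
                   atoms=list(atoms))


def make_ensemble(models, receptor=("A",), ligand=("B",), classify=False) -> ComplexEnsemble:
    ens = ComplexEnsemble(
        models=[list(m) for m in models],
        receptor_chains=frozenset(receptor),
        ligand_chains=frozenset(ligand),
        source="test",
    )
    if classify:
        assign_atom_classes(ens)
    return ens


@pytest.fixture
def preset_ensemble():
    """Jitter-free charge > hbond > nonpolar designed fixture, one model."""
    from capscan.fixtures import generate_complex_ensemble, preset_charge_hbond_np

    return generate_complex_ensemble(preset_charge_hbond_np(), n_models=1)


@pytest.fixture
def jittered_ensemble():
    """The designed fixture across 20 Gaussian-jittered models."""
    from capscan.fixtures import generate_complex_ensemble, preset_charge_hbond_np

    return generate_complex_ensemble(
        preset_charge_hbond_np(), n_models=20, jitter_sd=0.2, seed=7
    )
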