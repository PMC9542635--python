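"""Empirical pair potential and ensemble alanine scanning."""

from __future__ import annotations

import copy
import math

import numpy as np
import pytest

from capscan.alascan import (
    DEFAULT_PARAMS,
    EnergyParams,
    alanine_scan_ensemble,
    alanine_scan_model,
    binding_free_energy,
    pair_energy,
)
from capscan.fixtures import generate_complex_ensemble, preset_charge_hbond_np
from capscan.structio import BACKBONE_ATOMS, ComplexEnsemble

from conftest import make_atom, make_ensemble, make_residue


def _atom_pair(d, ca, cb):
    return (
        make_atom("X", "C", [0.0, 0.0, 0.0], ca),
        make_atom("Y", "C", [d, 0.0, 0.0], cb),
    )


# ---------------------------------------------------------------- pair energy

@pytest.mark.parametrize(
    "d,ca,cb,expected",
    [
        (3.4, {"nonpolar"}, {"nonpolar"}, -0.4),  # ramp = 1 at onset
        (3.0, {"donor"}, {"acceptor"}, -2.4),  # ramp 0.6
        (2.0, {"nonpolar"}, {"nonpolar"}, 25 * 0.5 / 2.5 - 0.4),  # clash + np
        (3.0, {"positive"}, {"negative"}, -8 * 2 / 2.2),  # opposite charges
        (3.0, {"positive"}, {"positive"}, +8 * 2 / 2.2),  # like charges repel
        (3.0, {"donor", "positive"}, {"acceptor", "negative"}, -2.4 - 8 * 2 / 2.2),
        (8.0, {"nonpolar"}, {"nonpolar"}, 0.0),  # at/beyond global cutoff
        (6.0, {"nonpolar"}, {"nonpolar"}, 0.0),  # ramp off
    ],
)
def test_pair_energy_values(d, ca, cb, expected):
    a, b = _atom_pair(d, ca, cb)
    assert pair_energy(a, b) == pytest.approx(expected, abs=1e-12)


def test_pair_energy_zero_distance_rejected():
    a, b = _atom_pair(0.0, {"nonpolar"}, {"nonpolar"})
    with pytest.raises(ValueError):
        pair_energy(a, b)


# ------------------------------------------------------- binding free energy

def _lane_model(contacts):
    """contacts: list of (classes_a, classes_b, d); one residue pair per lane."""
    model = []
    for i, (ca, cb, d) in enumerate(contacts):
        y = 40.0 * i
        model.append(
            make_residue("A", i + 1, "LEU", [make_atom("CD1", "C", [0, y, 0], ca)])
        )
        model.append(
            make_residue("B", i + 1, "VAL", [make_atom("CG1", "C", [d, y, 0], cb)])
        )
    return model


def test_binding_free_energy_single_pair_equals_pair_energy():
    ens = make_ensemble([_lane_model([({"donor"}, {"acceptor"}, 3.0)])])
    assert binding_free_energy(ens, 0) == pytest.approx(-2.4)


def test_binding_free_energy_far_partners_warns_zero():
    ens = make_ensemble([_lane_model([({"nonpolar"}, {"nonpolar"}, 100.0)])])
    with pytest.warns(UserWarning, match="cutoff"):
        assert binding_free_energy(ens, 0) == 0.0


def test_binding_free_energy_three_contact_sum():
    # nonpolar 3.4, donor-acceptor 3.0, pure opposite-charge 3.0
    ens = make_ensemble(
        [
            _lane_model(
                [
                    ({"nonpolar"}, {"nonpolar"}, 3.4),
                    ({"donor"}, {"acceptor"}, 3.0),
                    ({"positive"}, {"negative"}, 3.0),
                ]
            )
        ]
    )
    expected = -0.4 - 2.4 - 8 * 2 / 2.2
    assert binding_free_energy(ens, 0) == pytest.approx(expected)
    assert expected == pytest.approx(-10.07, abs=0.005)


# -------------------------------------------------------------- alanine scan

def test_salt_bridge_truncation_ddg(preset_ensemble):
    ddg = alanine_scan_model(preset_ensemble, 0, side="receptor")
    lys = next(rid for rid in ddg if rid.seq_num == 1)
    assert ddg[lys] == pytest.approx(2.4 + 8 * 2 / 2.2, abs=1e-9)
    assert ddg[lys] == pytest.approx(9.67, abs=0.005)


def test_residue_without_contacts_scores_zero():
    specs = preset_charge_hbond_np()
    far = copy.deepcopy(specs[0])
    far = type(far)(receptor=far.receptor, ligand=far.ligand,
                    pairs=(("NZ", "OD1", 12.0),))
    ens = generate_complex_ensemble(specs + [far], n_models=1)
    ddg = alanine_scan_model(ens, 0, side="receptor")
    assert ddg[[r for r in ddg if r.seq_num == 4][0]] == 0.0


def test_gly_absent_from_scan_map():
    gly = make_residue("A", 1, "GLY", [make_atom("O", "O", [0, 0, 0], {"acceptor"})])
    donor = make_residue("B", 1, "SER", [make_atom("OG", "O", [3.0, 0, 0], {"donor"})])
    ens = make_ensemble([[gly, donor]])
    assert alanine_scan_model(ens, 0, side="receptor") == {}


def _two_model_hb_ensemble():
    """SER OG vs ASN OD1 at 3.1 A (model 1) and 2.6 A (model 2): DDG 2, 4."""
    def model(d):
        ser = make_residue("A", 1, "SER", [
            make_atom("CB", "C", [-9, 0, 0], {"nonpolar"}),
            make_atom("OG", "O", [0, 0, 0], {"donor", "acceptor"}),
        ])
        asn = make_residue("B", 1, "ASN", [make_atom("OD1", "O", [d, 0, 0], {"acceptor"})])
        return [ser, asn]

    return make_ensemble([model(3.1), model(2.6)])


def test_ensemble_mean_sd_aggregation():
    res = alanine_scan_ensemble(_two_model_hb_ensemble(), side="receptor")
    (ser,) = res
    assert ser.ddg_per_model == pytest.approx([2.0, 4.0])
    assert ser.ddg_mean == pytest.approx(3.0)
    assert ser.ddg_sd == pytest.approx(math.sqrt(2.0))


def test_single_model_sd_zero(preset_ensemble):
    for r in alanine_scan_ensemble(preset_ensemble, side="receptor"):
        assert r.ddg_sd == 0.0


def test_polar_downweighting_applied(preset_ensemble):
    params = EnergyParams(w_polar=0.5)
    res = {r.res_name: r for r in alanine_scan_ensemble(preset_ensemble,
                                                        side="receptor", params=params)}
    assert res["LYS"].ddg_weighted == pytest.approx(res["LYS"].ddg_mean * 0.5)
    assert res["SER"].ddg_weighted == pytest.approx(res["SER"].ddg_mean)


# ------------------------------------------------- independent scan oracle

def _naive_pair_e(d, ci, cj, p=DEFAULT_PARAMS):
    """Independent re-statement of the potential, plain python."""
    if d >= p.global_cutoff:
        return 0.0

    def ramp(on, off):
        if d <= on:
            return 1.0
        if d >= off:
            return 0.0
        return (off - d) / (off - on)

    e = 0.0
    if d < p.d_clash:
        e += p.k_clash * (p.d_clash - d) / p.d_clash
    if "nonpolar" in ci and "nonpolar" in cj:
        e -= p.k_np * ramp(p.np_on, p.np_off)
    if ("donor" in ci and "acceptor" in cj) or ("acceptor" in ci and "donor" in cj):
        e -= p.k_hb * ramp(p.hb_on, p.hb_off)
    if ("positive" in ci and "negative" in cj) or ("negative" in ci and "positive" in cj):
        e -= p.k_q * ramp(p.q_on, p.q_off)
    if ("positive" in ci and "positive" in cj) or ("negative" in ci and "negative" in cj):
        e += p.k_q * ramp(p.q_on, p.q_off)
    return e


def naive_dg(ensemble: ComplexEnsemble, m: int) -> float:
    total = 0.0
    for ra in ensemble.residues(m, "receptor"):
        for rb in ensemble.residues(m, "ligand"):
            for aa in ra.atoms:
                for ab in rb.atoms:
                    d = float(np.linalg.norm(aa.coords - ab.coords))
                    total += _naive_pair_e(d, aa.classes, ab.classes)
    return total


def _truncate(ensemble: ComplexEnsemble, rid) -> ComplexEnsemble:
    """Literal side-chain truncation beyond CB of one residue, all models."""
    ens = copy.deepcopy(ensemble)
    for model in ens.models:
        for res in model:
            if res.rid == rid:
                res.atoms = [
                    a for a in res.atoms if a.name in BACKBONE_ATOMS or a.name == "CB"
                ]
    return ens


def test_scan_equals_literal_truncation_oracle(jittered_ensemble):
    for m in range(jittered_ensemble.n_models):
        ddg = alanine_scan_model(jittered_ensemble, m, side="both")
        wt = naive_dg(jittered_ensemble, m)
        for rid, value in ddg.items():
            mutant = naive_dg(_truncate(jittered_ensemble, rid), m)
            assert value == pytest.approx(mutant - wt, abs=1e-9)


def test_ensemble_mean_is_mean_of_per_model_scans(jittered_ensemble):
    res = alanine_scan_ensemble(jittered_ensemble, side="receptor")
    for r in res:
        if r.rank is None:
            continue
        per_model = [
            alanine_scan_model(jittered_ensemble, m, side="receptor")[r.residue]
            for m in range(jittered_ensemble.n_models)
        ]
        assert r.ddg_mean == pytest.approx(float(np.mean(per_model)), abs=1e-12)


def test_rigid_translation_leaves_energies_unchanged(preset_ensemble):
    shifted = copy.deepcopy(preset_ensemble)
    shift = np.array([13.0, -7.0, 4.0])
    for res in shifted.models[0]:
        for atom in res.atoms:
            atom.coords = atom.coords + shift
    assert binding_free_energy(shifted, 0) == pytest.approx(
        binding_free_energy(preset_ensemble, 0), abs=1e-9
    )
    d1 = alanine_scan_model(preset_ensemble, 0, side="both")
    d2 = alanine_scan_model(shifted, 0, side="both")
    for rid in d1:
        assert d1[rid] == pytest.approx(d2[rid], abs=1e-9)


def test_disjoint_double_truncation_is_additive(preset_ensemble):
    """LYS and SER touch disjoint ligand atoms: double DDG = sum of singles."""
    ddg = alanine_scan_model(preset_ensemble, 0, side="receptor")
    lys = next(r for r in ddg if r.seq_num == 1)
    ser = next(r for r in ddg if r.seq_num == 2)
    wt = naive_dg(preset_ensemble, 0)
    double = naive_dg(_truncate(_truncate(preset_ensemble, lys), ser), 0)
    assert double - wt == pytest.approx(ddg[lys] + ddg[ser], abs=1e-9)
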