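"""Photocage switch planning: cage-site proposal, additivity, enumeration."""

from __future__ import annotations

import math
from itertools import combinations

import pytest
from scipy.optimize import brentq

from capscan.alascan import ScanResult, alanine_scan_ensemble
from capscan.fixtures import ContactSpec, ResidueSpec, generate_complex_ensemble
from capscan.occupancy import CellModel
from capscan.planner import (
    CageSpec,
    plan_switch,
    predict_variant_affinity,
    propose_cage_sites,
)
from capscan.structio import ResidueId


def _scan_entry(seq, res_name, ddg, rank=1):
    return ScanResult(
        residue=ResidueId("A", seq, ""),
        res_name=res_name,
        side="receptor",
        ddg_per_model=[ddg],
        ddg_mean=ddg,
        ddg_sd=0.0,
        ddg_weighted=ddg,
        rank=rank,
    )


CELL = CellModel(nb_total_um=1.0, antigen_nuclear_um=5.0, phi_nuc=0.15)


# --------------------------------------------------------------- cage sites

def _tyr_fixture():
    bb = ("N", "CA", "C", "O", "CB")
    specs = [
        ContactSpec(ResidueSpec("TYR", bb + ("OH",)),
                    ResidueSpec("GLN", bb + ("OE1",)), (("OH", "OE1", 3.0),)),
        ContactSpec(ResidueSpec("TYR", bb + ("OH",)),
                    ResidueSpec("GLN", bb + ("OE1",)), (("OH", "OE1", 3.5),)),
        ContactSpec(ResidueSpec("TYR", bb + ("OH",)),
                    ResidueSpec("GLN", bb + ("OE1",)), (("OH", "OE1", 20.0),)),
    ]
    return generate_complex_ensemble(specs, n_models=1)


def test_propose_cage_sites_filters_and_orders():
    ens = _tyr_fixture()
    scan = alanine_scan_ensemble(ens, side="receptor")
    sites = propose_cage_sites(scan, ens)
    # distant TYR (seq 3) has no interface contact and is excluded;
    # closer contact (higher DDG) ranks first
    assert sites == [ResidueId("A", 1, ""), ResidueId("A", 2, "")]


def test_propose_cage_sites_no_tyrosine(preset_ensemble):
    scan = alanine_scan_ensemble(preset_ensemble, side="receptor")
    assert propose_cage_sites(scan, preset_ensemble) == []


# ----------------------------------------------------------- Kd additivity

def test_variant_affinity_identity_and_known_values():
    assert predict_variant_affinity(0.76, []) == 0.76
    rt = 0.008314 * 298.15
    kd = predict_variant_affinity(0.76, [rt * math.log(726.4)])
    assert kd == pytest.approx(552.1, abs=0.1)
    kd2 = predict_variant_affinity(0.76, [rt * math.log(420), rt * math.log(726.4)])
    assert kd2 / 1e3 == pytest.approx(231.9, abs=0.1)  # nM -> uM


# ------------------------------------------------------------- plan_switch

def _scan_with_cage():
    return [
        _scan_entry(1, "TYR", 3.0, rank=3),  # cage site
        _scan_entry(2, "GLU", 8.0, rank=1),
        _scan_entry(3, "ARG", 5.0, rank=2),
        _scan_entry(4, "TRP", 2.0, rank=4),
    ]


def _oracle_plans(scan, kd_wt_nm, cage, cell, k_max, theta_off, theta_on):
    """Independent brute-force enumeration: re-derives Kd, occupancy, verdict."""
    rt = 0.008314 * 298.15
    by_id = {r.residue: r for r in scan}
    candidates = sorted(r.residue for r in scan if r.residue != cage.residue)

    def occupancy(kd_nm):
        kd = kd_nm * 1e-3
        f = lambda x: x + cell.phi_nuc * cell.antigen_nuclear_um * x / (kd + x) - cell.nb_total_um
        x = brentq(f, 0.0, cell.nb_total_um, xtol=1e-15, rtol=1e-14)
        bound = cell.antigen_nuclear_um * x / (kd + x)
        return bound / cell.antigen_nuclear_um

    plans = {}
    for k in range(k_max + 1):
        for subset in combinations(candidates, k):
            kd_on = kd_wt_nm * math.exp(
                sum(by_id[r].ddg_weighted for r in subset) / rt
            )
            kd_off = kd_on * cage.fold_caged
            occ_on, occ_off = occupancy(kd_on), occupancy(kd_off)
            if occ_off > theta_off:
                verdict = "fail_off"
            elif occ_on < theta_on:
                verdict = "fail_on"
            else:
                verdict = "pass"
            plans[subset] = (kd_on, kd_off, occ_on, occ_off, verdict)
    return plans


def test_plan_switch_matches_bruteforce_oracle():
    scan = _scan_with_cage()
    cage = CageSpec(ResidueId("A", 1, ""), fold_caged=420.0)
    plans = plan_switch(scan, 0.76, cage, CELL, k_max=2)
    assert len(plans) == 7  # 1 + 3 + 3 subsets of 3 candidates
    oracle = _oracle_plans(scan, 0.76, cage, CELL, 2, 0.05, 0.5)
    assert {p.secondary for p in plans} == set(oracle)
    for p in plans:
        kd_on, kd_off, occ_on, occ_off, verdict = oracle[p.secondary]
        assert p.kd_on_nm == pytest.approx(kd_on, rel=1e-12)
        assert p.kd_off_nm == pytest.approx(kd_off, rel=1e-12)
        assert p.occ_on == pytest.approx(occ_on, rel=1e-8)
        assert p.occ_off == pytest.approx(occ_off, rel=1e-8)
        assert p.verdict == verdict


def test_plan_switch_sorted_pass_first_by_occ_on():
    plans = plan_switch(_scan_with_cage(), 0.76,
                        CageSpec(ResidueId("A", 1, ""), 420.0), CELL, k_max=2)
    verdicts = [p.verdict for p in plans]
    first_fail = verdicts.index("fail_off") if "fail_off" in verdicts else len(plans)
    assert all(v == "pass" for v in verdicts[:first_fail]) or "pass" not in verdicts
    passes = [p for p in plans if p.verdict == "pass"]
    assert all(a.occ_on >= b.occ_on for a, b in zip(passes, passes[1:]))


def test_cage_only_npy_plan_fails_off():
    """With only the 420-fold cage, a sub-nM binder still occupies nuclear
    antigen — the caged form keeps binding in the cell scenario."""
    scan = [_scan_entry(1, "TYR", 3.0, rank=1)]
    plans = plan_switch(scan, 0.76, CageSpec(ResidueId("A", 1, ""), 420.0),
                        CELL, k_max=2)
    assert len(plans) == 1
    assert plans[0].secondary == ()
    assert plans[0].occ_off > 0.05
    assert plans[0].verdict == "fail_off"


def test_secondary_mutations_never_decrease_kd():
    plans = plan_switch(_scan_with_cage(), 0.76,
                        CageSpec(ResidueId("A", 1, ""), 420.0), CELL, k_max=2)
    by_subset = {p.secondary: p for p in plans}
    base = by_subset[()]
    for subset, p in by_subset.items():
        if subset:
            assert p.kd_on_nm >= base.kd_on_nm
            assert p.kd_off_nm >= base.kd_off_nm


def test_infinite_cage_fold_always_achieves_off():
    plans = plan_switch(_scan_with_cage(), 0.76,
                        CageSpec(ResidueId("A", 1, ""), 1e12), CELL, k_max=2)
    assert all(p.occ_off < 1e-6 for p in plans)


def test_plan_switch_invariant_to_candidate_order():
    scan = _scan_with_cage()
    cage = CageSpec(ResidueId("A", 1, ""), 420.0)
    cands = [ResidueId("A", 2, ""), ResidueId("A", 3, ""), ResidueId("A", 4, "")]
    p1 = plan_switch(scan, 0.76, cage, CELL, candidates=cands, k_max=2)
    p2 = plan_switch(scan, 0.76, cage, CELL, candidates=cands[::-1], k_max=2)
    assert [(p.secondary, p.verdict) for p in p1] == [(p.secondary, p.verdict) for p in p2]


def test_plan_switch_rejects_bad_cage_sites():
    scan = _scan_with_cage()
    with pytest.raises(ValueError, match="not a scannable"):
        plan_switch(scan, 0.76, CageSpec(ResidueId("A", 99, ""), 420.0), CELL)
    with pytest.raises(ValueError, match="not TYR"):
        plan_switch(scan, 0.76, CageSpec(ResidueId("A", 2, ""), 420.0), CELL)
    # force=True allows a non-tyrosine site through, flagged by the caller
    plans = plan_switch(scan, 0.76, CageSpec(ResidueId("A", 2, ""), 420.0),
                        CELL, force=True, k_max=0)
    assert len(plans) == 1
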