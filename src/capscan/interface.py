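"""Interface residue detection and contact geometry annotation.

Identifies residue pairs across the receptor/ligand boundary and annotates
two specific contact geometries that matter for paratope engineering:
donor-acceptor pairs as hydrogen-bond proxies (structures carry no hydrogens,
so a 3.5 Angstrom heavy-atom distance stands in for the usual distance+angle
criterion) and cation-pi packing between aromatic rings and cationic groups —
the geometry through which a photocaging group on a tyrosine can, perhaps
unexpectedly, keep gripping an interface arginine.

Annotations are aggregated over the ensemble: ``persistence`` is the fraction
of models in which the contact is present, ``distance`` the mean (over models
containing it) of the per-model minimum qualifying distance, ``model_index``
the first model containing it.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import product
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .structio import ComplexEnsemble, Residue, ResidueId

__all__ = [
    "ContactAnnotation",
    "find_interface_residues",
    "detect_polar_contacts",
    "detect_cation_pi",
    "AROMATIC_RINGS",
]

logger = logging.getLogger(__name__)

#: Ring atom names used for cation-pi detection.
AROMATIC_RINGS: dict[str, tuple[str, ...]] = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Planar cationic group of arginine (guanidinium); lysine NZ is point-like.
_ARG_PLANE = ("NE", "NH1", "NH2", "CZ")


@dataclasses.dataclass
class ContactAnnotation:
    kind: Literal["interface", "hbond", "cation_pi"]
    residue_a: ResidueId  # receptor side
    residue_b: ResidueId  # ligand side
    distance: float
    persistence: float
    model_index: int
    angle: float | None = None
    res_name_a: str = ""
    res_name_b: str = ""

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")


def _coords(res: Residue) -> np.ndarray:
    return np.array([a.coords for a in res.atoms])


def _aggregate(
    kind: str,
    per_model: list[dict[tuple[ResidueId, ResidueId], tuple[float, float | None]]],
    names: dict[tuple[ResidueId, ResidueId], tuple[str, str]],
    n_models: int,
) -> list[ContactAnnotation]:
    pairs = sorted({p for m in per_model for p in m})
    out = []
    for pair in pairs:
        hits = [(i, m[pair]) for i, m in enumerate(per_model) if pair in m]
        dists = [d for _, (d, _) in hits]
        angles = [a for _, (_, a) in hits if a is not None]
        na, nb = names[pair]
        out.append(
            ContactAnnotation(
                kind=kind,  # type: ignore[arg-type]
                residue_a=pair[0],
                residue_b=pair[1],
                distance=float(np.mean(dists)),
                persistence=len(hits) / n_models,
                model_index=hits[0][0],
                angle=float(np.mean(angles)) if angles else None,
                res_name_a=na,
                res_name_b=nb,
            )
        )
    return out


def find_interface_residues(
    ensemble: ComplexEnsemble, cutoff: float = 5.0
) -> list[ContactAnnotation]:
    """Residue pairs with any cross-partner heavy-atom distance <= cutoff.

    Returns one annotation per residue pair, sorted by (receptor residue,
    ligand residue), with persistence over the ensemble.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    per_model: list[dict] = []
    names: dict = {}
    for m in range(ensemble.n_models):
        rec = list(ensemble.residues(m, "receptor"))
        lig = list(ensemble.residues(m, "ligand"))
        if not rec or not lig:
            raise ValueError("empty receptor or ligand side")
        found: dict[tuple[ResidueId, ResidueId], tuple[float, None]] = {}
        for ra, rb in product(rec, lig):
            d = cdist(_coords(ra), _coords(rb)).min()
            if d <= cutoff:
                found[(ra.rid, rb.rid)] = (float(d), None)
                names[(ra.rid, rb.rid)] = (ra.res_name, rb.res_name)
        per_model.append(found)
    return _aggregate("interface", per_model, names, ensemble.n_models)


def detect_polar_contacts(
    ensemble: ComplexEnsemble, dmax: float = 3.5
) -> list[ContactAnnotation]:
    """Cross-partner donor<->acceptor heavy-atom pairs within dmax.

    A hydrogen-bond proxy: no angle criterion is applied because hydrogens are
    unavailable.  Symmetric in donor/acceptor role.
    """
    per_model: list[dict] = []
    names: dict = {}
    for m in range(ensemble.n_models):
        found: dict[tuple[ResidueId, ResidueId], tuple[float, None]] = {}
        for ra in ensemble.residues(m, "receptor"):
            for rb in ensemble.residues(m, "ligand"):
                best = np.inf
                for aa, ab in product(ra.atoms, rb.atoms):
                    pair_polar = ("donor" in aa.classes and "acceptor" in ab.classes) or (
                        "acceptor" in aa.classes and "donor" in ab.classes
                    )
                    if not pair_polar:
                        continue
                    d = float(np.linalg.norm(aa.coords - ab.coords))
                    if d <= dmax and d < best:
                        best = d
                if np.isfinite(best):
                    found[(ra.rid, rb.rid)] = (best, None)
                    names[(ra.rid, rb.rid)] = (ra.res_name, rb.res_name)
        per_model.append(found)
    return _aggregate("hbond", per_model, names, ensemble.n_models)


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centred = points - points.mean(axis=0)
    # smallest singular vector = best-fit plane normal
    _, _, vt = np.linalg.svd(centred)
    return vt[-1]


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosv = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(cosv, 0.0, 1.0))))


def _ring_groups(res: Residue) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centroid, normal) of the aromatic ring of res, or [] if not aromatic."""
    ring = AROMATIC_RINGS.get(res.res_name)
    if ring is None:
        return []
    try:
        pts = np.array([res.atom(n).coords for n in ring])
    except KeyError:
        logger.warning("skipping %s %s: ring atoms missing", res.res_name, res.rid)
        return []
    return [(pts.mean(axis=0), _plane_normal(pts))]


def _cation_groups(res: Residue) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """(centroid, normal-or-None) of cationic groups: ARG plane, LYS NZ point."""
    if res.res_name == "ARG":
        try:
            pts = np.array([res.atom(n).coords for n in _ARG_PLANE])
        except KeyError:
            logger.warning("skipping ARG %s: guanidinium atoms missing", res.rid)
            return []
        return [(pts.mean(axis=0), _plane_normal(pts))]
    if res.res_name == "LYS":
        try:
            return [(res.atom("NZ").coords, None)]
        except KeyError:
            logger.warning("skipping LYS %s: NZ missing", res.rid)
            return []
    return []


def detect_cation_pi(
    ensemble: ComplexEnsemble, dmax: float = 6.0, max_angle: float = 30.0
) -> list[ContactAnnotation]:
    """Cross-partner aromatic-ring / cation contacts.

    Reported iff ring-centroid to cation-centroid distance <= dmax and, for the
    planar arginine guanidinium, the interplanar angle <= max_angle (parallel
    packing).  Lysine NZ uses the distance criterion alone.
    """
    per_model: list[dict] = []
    names: dict = {}
    for m in range(ensemble.n_models):
        found: dict[tuple[ResidueId, ResidueId], tuple[float, float | None]] = {}
        rec = list(ensemble.residues(m, "receptor"))
        lig = list(ensemble.residues(m, "ligand"))
        for ra, rb in product(rec, lig):
            best: tuple[float, float | None] | None = None
            for res_ring, res_cat in ((ra, rb), (rb, ra)):
                for centroid_r, normal_r in _ring_groups(res_ring):
                    for centroid_c, normal_c in _cation_groups(res_cat):
                        d = float(np.linalg.norm(centroid_r - centroid_c))
                        if d > dmax:
                            continue
                        angle: float | None = None
                        if normal_c is not None:
                            angle = _interplanar_angle(normal_r, normal_c)
                            if angle > max_angle:
                                continue
                        if best is None or d < best[0]:
                            best = (d, angle)
            if best is not None:
                found[(ra.rid, rb.rid)] = best
                names[(ra.rid, rb.rid)] = (ra.res_name, rb.res_name)
        per_model.append(found)
    return _aggregate("cation_pi", per_model, names, ensemble.n_models)
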