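"""Affinity thermodynamics and intracellular occupancy predictions.

Bridges three descriptions of binding strength used when tuning a nanobody
paratope: equilibrium Kd, fold-change relative to wild type, and DDG via
DDG = RT ln(fold).  On top sits a two-compartment equilibrium model of the
in-vivo localisation read-out: an antigen anchored (immobile) in the nucleus,
a freely diffusing nanobody-fluorophore fusion, and the observable
nuclear/cytoplasmic signal ratio

    N/C = (nb_free + complex_nuclear + background) / (nb_free + background)

which is ~1 for a non-binder and rises as nuclear antigen captures the
nanobody.  Concentrations are in micromolar unless noted; Kd in AffinityRecord
follows the nanomolar convention of binding assays.
"""

from __future__ import annotations

import dataclasses
import math

from scipy.optimize import brentq

__all__ = [
    "R_KJ_PER_MOL_K",
    "AffinityRecord",
    "CellModel",
    "NCRatioPrediction",
    "rt_kj",
    "fold_change_ddg",
    "complex_concentration",
    "predict_nc_ratio",
    "parse_concentration_um",
]

#: Gas constant, kJ/mol/K.
R_KJ_PER_MOL_K = 0.008314


def rt_kj(temperature: float = 298.15) -> float:
    """RT in kJ/mol at the given absolute temperature."""
    return R_KJ_PER_MOL_K * temperature


@dataclasses.dataclass
class AffinityRecord:
    """Kd (nM), fold-change vs wild type, and the RT ln bridge between them."""

    kd_nm: float | None = None
    fold_vs_wt: float | None = None
    ddg_kj: float | None = None
    temperature: float = 298.15

    @property
    def rt(self) -> float:
        return rt_kj(self.temperature)

    def __post_init__(self) -> None:
        if self.kd_nm is not None and self.kd_nm <= 0:
            raise ValueError("kd must be positive")
        if self.fold_vs_wt is not None and self.fold_vs_wt < 0:
            raise ValueError("fold-change must be >= 0")


def fold_change_ddg(record: AffinityRecord, direction: str) -> AffinityRecord:
    """Convert fold-change <-> DDG on a record: ddg = RT ln(fold).

    ``direction`` is ``fold_to_ddg`` or ``ddg_to_fold``.  Round trips are
    exact to floating-point precision.
    """
    if direction == "fold_to_ddg":
        if record.fold_vs_wt is None or record.fold_vs_wt <= 0:
            raise ValueError("fold_vs_wt must be set and positive")
        return dataclasses.replace(
            record, ddg_kj=record.rt * math.log(record.fold_vs_wt)
        )
    if direction == "ddg_to_fold":
        if record.ddg_kj is None:
            raise ValueError("ddg_kj must be set")
        return dataclasses.replace(
            record, fold_vs_wt=math.exp(record.ddg_kj / record.rt)
        )
    raise ValueError("direction must be 'fold_to_ddg' or 'ddg_to_fold'")


def complex_concentration(a_total: float, b_total: float, kd: float) -> float:
    """Equilibrium complex concentration of A + B <-> AB in one compartment.

    Closed-form root of the mass-action quadratic; any consistent concentration
    unit.  kd = 0 is accepted as the stoichiometric limit min(A, B).
    """
    if a_total < 0 or b_total < 0 or kd < 0:
        raise ValueError("concentrations and kd must be non-negative")
    if a_total == 0 or b_total == 0:
        return 0.0
    s = a_total + b_total + kd
    disc = math.sqrt(max(s * s - 4 * a_total * b_total, 0.0))
    # numerically stable form of (s - sqrt(disc)) / 2
    c = 2 * a_total * b_total / (s + disc)
    return min(c, a_total, b_total)


@dataclasses.dataclass
class CellModel:
    """Whole-cell nanobody pool vs a nuclear-anchored antigen.

    nb_total_um: whole-cell nanobody concentration (per total cell volume).
    antigen_nuclear_um: antigen concentration within the nucleus (immobile).
    phi_nuc: nuclear volume fraction of the cell, in (0, 1).
    background: additive signal offset applied to both compartments (caps the
        observable ratio, as saturating measured ratios do).
    """

    nb_total_um: float
    antigen_nuclear_um: float
    phi_nuc: float
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.nb_total_um < 0 or self.antigen_nuclear_um < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0.0 < self.phi_nuc < 1.0:
            raise ValueError("phi_nuc must lie in (0, 1)")
        if self.background < 0:
            raise ValueError("background must be >= 0")


@dataclasses.dataclass
class NCRatioPrediction:
    nb_free_um: float
    complex_nuclear_um: float
    nc_ratio: float


def predict_nc_ratio(cell: CellModel, kd_um: float) -> NCRatioPrediction:
    """Solve the nuclear-capture equilibrium and predict the N/C signal ratio.

    The free nanobody concentration x satisfies mass conservation

        nb_total = x + phi_nuc * antigen_nuclear * x / (kd + x),

    a quadratic in x solved in closed form (bisection fallback); the bound
    complex is confined to the nucleus while free nanobody equilibrates across
    the nuclear envelope.
    """
    if kd_um <= 0:
        raise ValueError("kd must be positive")
    if cell.nb_total_um == 0:
        raise ValueError("nb_total is zero: N/C ratio undefined")
    nb, ag, phi = cell.nb_total_um, cell.antigen_nuclear_um, cell.phi_nuc
    # x^2 + (kd + phi*ag - nb) x - kd*nb = 0
    b = kd_um + phi * ag - nb
    disc = math.sqrt(b * b + 4 * kd_um * nb)
    x = (-b + disc) / 2 if b <= 0 else 2 * kd_um * nb / (b + disc)

    def residual(xv: float) -> float:
        return xv + phi * ag * xv / (kd_um + xv) - nb

    if abs(residual(x)) > 1e-10 * nb:  # pragma: no cover - closed form suffices
        x = brentq(residual, 0.0, nb, rtol=1e-12, maxiter=200)

    complex_nuc = ag * x / (kd_um + x)
    bg = cell.background
    nc = (x + complex_nuc + bg) / (x + bg)
    return NCRatioPrediction(nb_free_um=x, complex_nuclear_um=complex_nuc, nc_ratio=nc)


_UNIT_TO_UM = {"nm": 1e-3, "um": 1.0, "µm": 1.0, "μm": 1.0, "mm": 1e3, "m": 1e6}


def parse_concentration_um(text: str | float) -> float:
    """Parse '0.76nM' / '1uM' / '2mM' (default micromolar) into micromolar."""
    if isinstance(text, (int, float)):
        return float(text)
    t = text.strip().lower()
    for suffix, factor in sorted(_UNIT_TO_UM.items(), key=lambda kv: -len(kv[0])):
        if t.endswith(suffix):
            return float(t[: -len(suffix)]) * factor
    return float(t)
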