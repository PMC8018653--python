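"""Derived CNS pharmacokinetic metrics.

Accumulation ratios (observed ratio of steady-state to first-dose exposure,
and the predicted ratio 1/(1 - exp(-k10*tau)) for linear kinetics),
the Crone-Renkin permeability-surface area product, microdialysis recovery
correction, plasma protein-binding correction, the unbound brain-to-plasma
partition coefficient Kpuu, brain unbound-fraction estimation from paired
ECF/homogenate concentrations, and the fold-error classification of
predicted vs observed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "rac_predicted",
    "rac_observed",
    "crone_renkin_ps",
    "recovery_correct",
    "unbound_plasma",
    "kpuu",
    "KpuuResult",
    "AccumulationResult",
    "estimate_fu_brain",
    "classify_prediction",
    "fold_error",
]


@dataclass(frozen=True)
class AccumulationResult:
    rac_observed: float | None
    rac_predicted: float | None
    basis: str  # "cmax" or "auc_0_12"


@dataclass(frozen=True)
class KpuuResult:
    kpuu: float
    basis: str
    fu_plasma_used: float


def rac_predicted(k10: float, tau: float) -> float:
    """Predicted steady-state accumulation ratio 1/(1 - e^(-k10*tau)).

    Always > 1; k10 is the terminal elimination rate constant (1/h) and
    tau the dosing interval (h).
    """
    if k10 <= 0 or tau <= 0:
        raise ValueError("k10 and tau must be positive")
    return 1.0 / (1.0 - math.exp(-k10 * tau))


def rac_observed(ss_value: float, sd_value: float) -> float:
    """Observed accumulation ratio: steady-state / first-dose exposure
    (same basis — Cmax or AUC over the same window — and same matrix)."""
    if sd_value <= 0 or ss_value <= 0:
        raise ValueError("exposures must be positive")
    return ss_value / sd_value


def crone_renkin_ps(
    fpf_ml_min_g: float,
    kin_ml_min_g: float,
    brain_weight_g: float | None = None,
    fpf_in_ml_sec: bool = False,
) -> tuple[float, float | None]:
    """Crone-Renkin permeability-surface area product.

    PS = -Fpf * ln(1 - Kin/Fpf) with Fpf the cerebral perfusion flow and
    Kin the brain uptake clearance, both in mL/min/g after harmonization
    (``fpf_in_ml_sec=True`` converts an Fpf given in mL/sec/g).

    Returns ``(ps_per_g, ps_total)``; ``ps_total`` (mL/min) requires the
    brain weight in g, otherwise None.
    """
    fpf = fpf_ml_min_g * 60.0 if fpf_in_ml_sec else fpf_ml_min_g
    if fpf <= 0 or kin_ml_min_g <= 0:
        raise ValueError("Fpf and Kin must be positive")
    if kin_ml_min_g >= fpf:
        raise ValueError(
            "Kin >= Fpf: uptake is flow-limited and the Crone-Renkin "
            "logarithm is undefined"
        )
    ps_per_g = -fpf * math.log(1.0 - kin_ml_min_g / fpf)
    ps_total = ps_per_g * brain_weight_g if brain_weight_g is not None else None
    return ps_per_g, ps_total


def recovery_correct(dialysate_ng_ml, recovery: float):
    """Convert dialysate concentration to ECF: ECF = dialysate / recovery."""
    if not 0.0 < recovery <= 1.0:
        raise ValueError("recovery must be in (0, 1]")
    return np.asarray(dialysate_ng_ml, dtype=float) / recovery if np.ndim(
        dialysate_ng_ml
    ) else float(dialysate_ng_ml) / recovery


def unbound_plasma(total, fu_plasma: float):
    """Unbound plasma value (concentration or AUC) = total x fu_plasma."""
    if not 0.0 < fu_plasma <= 1.0:
        raise ValueError("fu_plasma must be in (0, 1]")
    return np.asarray(total, dtype=float) * fu_plasma if np.ndim(total) else (
        float(total) * fu_plasma
    )


def kpuu(
    brain_ecf_value: float,
    plasma_total_value: float,
    fu_plasma: float,
    basis: str = "auc_0_12",
) -> KpuuResult:
    """Unbound brain-to-plasma partition coefficient.

    Kpuu = ECF exposure / (plasma total exposure x fu_plasma), on a Cmax or
    AUC0-12 basis; ECF is taken as the unbound brain compartment.
    """
    if plasma_total_value <= 0:
        raise ValueError("plasma exposure must be positive")
    if brain_ecf_value <= 0:
        raise ValueError("brain ECF exposure must be positive")
    value = brain_ecf_value / unbound_plasma(plasma_total_value, fu_plasma)
    return KpuuResult(kpuu=float(value), basis=basis, fu_plasma_used=fu_plasma)


def estimate_fu_brain(ecf_concs, homogenate_concs) -> tuple[float, float, np.ndarray]:
    """Brain unbound fraction from paired ECF / whole-brain homogenate
    concentrations sampled at matched times.

    Returns (mean ratio, SD of per-animal ratios, per-animal ratios).
    """
    ecf = np.asarray(ecf_concs, dtype=float)
    hom = np.asarray(homogenate_concs, dtype=float)
    if ecf.shape != hom.shape or ecf.ndim != 1 or ecf.size == 0:
        raise ValueError("ECF and homogenate concentrations must be paired 1-D arrays")
    if np.any(ecf <= 0) or np.any(hom <= 0):
        raise ValueError("concentrations must be positive")
    ratios = ecf / hom
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return float(np.mean(ratios)), sd, ratios


def fold_error(predicted: float, observed: float) -> float:
    """Symmetric fold error max(p/o, o/p)."""
    if predicted <= 0 or observed <= 0:
        raise ValueError("predicted and observed must be positive")
    r = predicted / observed
    return max(r, 1.0 / r)


def classify_prediction(predicted: float, observed: float) -> str:
    """Classify a prediction: 'good' at or within 1.25-fold, 'reasonable' at
    or within 1.5-fold, otherwise 'outside'.

    The fold error is compared at each threshold's own printed precision
    (2 decimals against 1.25, 1 decimal against 1.5), a reporting convention
    under which a predicted/observed ratio of 0.66 (fold error 1.515, i.e.
    1.5 at the stated precision) still counts as reasonable.
    """
    fe = fold_error(predicted, observed)
    if round(fe, 2) <= 1.25:
        return "good"
    if round(fe, 1) <= 1.5:
        return "reasonable"
    return "outside"
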