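"""Mechanistic tissue-to-plasma partition coefficients and steady-state
volume of distribution.

Implements the tissue-composition (Rodgers-Rowland) approach: unbound
tissue-to-plasma ratios are assembled from partitioning into tissue water,
neutral lipid and neutral phospholipid, plus either binding-protein
(albumin/lipoprotein) interactions for neutral compounds and acids, or
acidic-phospholipid association for moderate-to-strong bases.  The neutral
and base branches are implemented; Kp values scale linearly with the
``kp_scalar`` of the drug.

The rat composition table ships as ``data/tissue_composition_rat.csv``
(transcribed from the published rodent composition tables of the method).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import DrugParameters, PhysiologySet, data_path

__all__ = [
    "load_composition",
    "predict_kp",
    "vss_from_kp",
    "erythrocyte_plasma_ratio",
]

# plasma neutral lipid / neutral phospholipid fractional volumes (rat)
F_NL_PLASMA = 0.0023
F_NP_PLASMA = 0.0013

# red blood cell composition (rat), used by the base branch
F_IW_BC = 0.603
F_NL_BC = 0.0017
F_NP_BC = 0.0029
AP_BC_MG_G = 0.5

PH_PLASMA = 7.4
PH_IW = 7.0
PH_BC = 7.22


class ConfigurationError(ValueError):
    """A parameter/physiology/Kp configuration is incomplete or inconsistent."""


def load_composition(path: str | Path | None = None) -> pd.DataFrame:
    """Load a tissue composition table (default: shipped rat table)."""
    if path is None:
        path = data_path("tissue_composition_rat.csv")
    df = pd.read_csv(path, comment="#")
    df = df.set_index("tissue")
    required = {"f_ew", "f_iw", "f_nl", "f_np", "ap_mg_g", "albumin_ratio", "lipoprotein_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"composition table lacks columns: {sorted(missing)}")
    return df


def erythrocyte_plasma_ratio(blood_plasma_ratio: float, hematocrit: float) -> float:
    """Blood cell-to-plasma concentration ratio implied by the blood:plasma ratio."""
    return (blood_plasma_ratio - (1.0 - hematocrit)) / hematocrit


def _octanol_p(logp: float) -> float:
    return 10.0 ** logp


def _vegetable_oil_d(logp: float) -> float:
    # olive-oil : water partition regression used for adipose
    return 10.0 ** (1.115 * logp - 1.35)


def predict_kp(
    drug: DrugParameters,
    composition: pd.DataFrame | None = None,
    kp_scalar: float | None = None,
    hematocrit: float = 0.45,
) -> dict[str, float]:
    """Predict tissue-to-plasma partition coefficients for every model tissue.

    Returns a map covering all composition-table tissues plus ``rest``
    (the lumped rest-of-body, treated as lean carcass and assigned the
    muscle Kp).

    Parameters
    ----------
    drug
        Needs ``logp``, ``fu_plasma``, ``blood_plasma_ratio`` and the
        ionization branch (``neutral`` or ``base`` with ``pka``).
    composition
        Tissue composition table; default is the shipped rat table.
    kp_scalar
        Empirical scalar applied to every Kp; defaults to ``drug.kp_scalar``.
    """
    if drug.fu_plasma <= 0:
        raise ConfigurationError("fu_plasma must be > 0 for partition prediction")
    if composition is None:
        composition = load_composition()
    scalar = drug.kp_scalar if kp_scalar is None else kp_scalar

    fu = drug.fu_plasma
    p = _octanol_p(drug.logp)
    d_adipose = _vegetable_oil_d(drug.logp)

    if drug.ionization == "base":
        if drug.pka is None:
            raise ConfigurationError("base branch requires pka")
        kp_map = _kp_base(drug, composition, p, d_adipose, hematocrit)
    elif drug.ionization == "neutral":
        kp_map = _kp_neutral(fu, composition, p, d_adipose)
    else:
        raise ConfigurationError(f"unsupported ionization branch {drug.ionization!r}")

    kp_map["rest"] = kp_map["muscle"]
    return {t: scalar * v for t, v in kp_map.items()}


def _lipid_term(p: float, f_nl: float, f_np: float) -> float:
    return p * f_nl + (0.3 * p + 0.7) * f_np


def _kp_neutral(fu: float, comp: pd.DataFrame, p: float, d_adipose: float) -> dict[str, float]:
    # residual plasma binding attributed to lipoproteins for neutral compounds
    plasma_lipid = _lipid_term(p, F_NL_PLASMA, F_NP_PLASMA)
    binding = 1.0 / fu - 1.0 - plasma_lipid
    kp = {}
    for tissue, row in comp.iterrows():
        p_t = d_adipose if tissue == "adipose" else p
        kpu = (
            row.f_ew
            + row.f_iw
            + _lipid_term(p_t, row.f_nl, row.f_np)
            + binding * row.lipoprotein_ratio
        )
        kp[tissue] = float(kpu * fu)
    return kp


def _kp_base(
    drug: DrugParameters,
    comp: pd.DataFrame,
    p: float,
    d_adipose: float,
    hematocrit: float,
) -> dict[str, float]:
    """Moderate-to-strong base branch: acidic-phospholipid association with the
    association constant back-calculated from blood-cell partitioning."""
    fu = drug.fu_plasma
    pka = float(drug.pka)
    ion_p = 10.0 ** (pka - PH_PLASMA)
    ion_iw = 10.0 ** (pka - PH_IW)
    ion_bc = 10.0 ** (pka - PH_BC)

    kpu_bc = erythrocyte_plasma_ratio(drug.blood_plasma_ratio, hematocrit) / fu
    ka_ap = (
        kpu_bc
        - (1.0 + ion_bc) / (1.0 + ion_p) * F_IW_BC
        - _lipid_term(p, F_NL_BC, F_NP_BC) / (1.0 + ion_p)
    ) * (1.0 + ion_p) / (AP_BC_MG_G * ion_bc)
    if ka_ap < 0:
        ka_ap = 0.0

    kp = {}
    for tissue, row in comp.iterrows():
        p_t = d_adipose if tissue == "adipose" else p
        kpu = (
            row.f_ew
            + (1.0 + ion_iw) / (1.0 + ion_p) * row.f_iw
            + ka_ap * row.ap_mg_g * ion_iw / (1.0 + ion_p)
            + _lipid_term(p_t, row.f_nl, row.f_np) / (1.0 + ion_p)
        )
        kp[tissue] = float(kpu * fu)
    return kp


def vss_from_kp(
    kp_map: dict[str, float],
    physiology: PhysiologySet,
    drug: DrugParameters,
) -> float:
    """Steady-state volume of distribution (plasma-referenced), L/kg.

    Vss = (V_plasma + V_rbc * E:P + sum_t V_t * Kp_t + V_brain * Kp_brain) / BW
    """
    v_blood = physiology.v_arterial + physiology.v_venous
    hct = physiology.hematocrit
    v_plasma = v_blood * (1.0 - hct)
    v_rbc = v_blood * hct
    e_p = erythrocyte_plasma_ratio(drug.blood_plasma_ratio, hct)

    total = v_plasma + v_rbc * max(e_p, 0.0)
    for tissue, v_t in physiology.volumes.items():
        if tissue not in kp_map:
            raise ConfigurationError(f"kp_map lacks tissue {tissue!r}")
        total += v_t * kp_map[tissue]
    if "brain" not in kp_map:
        raise ConfigurationError("kp_map lacks tissue 'brain'")
    total += physiology.v_brain_mass * kp_map["brain"]
    return total / physiology.body_weight_kg
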