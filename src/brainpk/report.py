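"""Scenario runner: simulate, analyse and tabulate one study arm.

``run_scenario`` reproduces the reporting layout of the study: a
derived-metrics table from the observed group means (unbound plasma values,
Kpuu, accumulation ratios) and a predicted-vs-observed table from the PBPK
simulation with fold-error classification.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .metrics import (
    classify_prediction,
    kpuu,
    rac_observed,
    rac_predicted,
    unbound_plasma,
)
from .nca import NCA
from .parameters import DoseRegimen, data_path, load_drug, load_physiology
from .partition import predict_kp, vss_from_kp
from .pbpk import PBPKModel

__all__ = ["RunConfig", "run_scenario", "load_observed_tables", "REGIMENS"]

#: once-daily 4 mg/kg regimens: 1 dose (single) or 5/11 doses (steady state)
REGIMENS = {
    ("single_dose", "male"): dict(n_doses=1, simulation_end_h=72.0),
    ("single_dose", "female"): dict(n_doses=1, simulation_end_h=72.0),
    ("steady_state", "male"): dict(n_doses=5, simulation_end_h=5 * 24.0),
    ("steady_state", "female"): dict(n_doses=11, simulation_end_h=11 * 24.0),
}


class RunConfig(BaseModel):
    scenario: str = Field(pattern="^(single_dose|steady_state)$")
    sex: str = Field(pattern="^(male|female)$")
    drug_file: str | None = None
    physiology_file: str | None = None
    out_dir: str = "brainpk_out"
    seed: int = 0
    dose_mg_per_kg: float = 4.0
    fu_plasma_observed: float = 0.38


def load_observed_tables() -> dict:
    with open(data_path("observed_tables.yaml")) as fh:
        return yaml.safe_load(fh)


def _regimen(config: RunConfig) -> DoseRegimen:
    spec = REGIMENS[(config.scenario, config.sex)]
    return DoseRegimen(dose_mg_per_kg=config.dose_mg_per_kg, interval_tau_h=24.0, **spec)


def observed_metrics_table(config: RunConfig) -> pd.DataFrame:
    """Tables 2/3-shaped derived metrics from the observed group means."""
    obs = load_observed_tables()
    fu = obs.get("fu_plasma", config.fu_plasma_observed)
    sd = obs["single_dose"][config.sex]
    arm = obs[config.scenario][config.sex]
    rows = []

    def row(basis, ecf_key, plasma_key):
        plasma = arm[plasma_key]
        ecf = arm[ecf_key]
        ub = unbound_plasma(plasma, fu)
        kp = kpuu(ecf, plasma, fu, basis=basis).kpuu
        entry = dict(
            basis=basis,
            brain_ecf=ecf,
            plasma_total=plasma,
            plasma_unbound=round(ub, 0),
            kpuu=round(kp, 1),
        )
        if config.scenario == "steady_state":
            entry["rac_brain"] = round(rac_observed(ecf, sd[ecf_key]), 1)
            entry["rac_plasma"] = round(rac_observed(plasma, sd[plasma_key]), 1)
            k10 = math.log(2.0) / sd["t_half_plasma"]
            entry["rac_predicted"] = round(rac_predicted(k10, 24.0), 1)
        rows.append(entry)

    row("cmax", "cmax_ecf", "cmax_plasma")
    row("auc_0_12", "auc12_ecf", "auc12_plasma")
    return pd.DataFrame(rows)


def _simulated_summary(config: RunConfig, results) -> dict:
    """NCA-style summary of the simulated profiles over the evaluation
    window (whole curve for single dose, last dosing interval at steady
    state)."""
    reg = results.model.regimen
    t_last = (reg.n_doses - 1) * reg.interval_tau_h
    plasma = results.profiles["plasma_total"]
    ecf = results.profiles["brain_ecf"]

    def window_slice(profile, start, end):
        mask = (profile.times_h >= start - 1e-9) & (profile.times_h <= end + 1e-9)
        return profile.times_h[mask] - start, profile.conc_ng_ml[mask]

    out = {}
    if config.scenario == "single_dose":
        t_p, c_p = plasma.times_h, plasma.conc_ng_ml
        t_e, c_e = ecf.times_h, ecf.conc_ng_ml
        res = NCA(plasma, dose_mg_per_kg=config.dose_mg_per_kg).fit()
        out["t_half_plasma"] = res.t_half
        out["auc72_plasma"] = float(np.trapezoid(c_p[t_p <= 72 + 1e-9], t_p[t_p <= 72 + 1e-9]))
    else:
        t_p, c_p = window_slice(plasma, t_last, t_last + 24.0)
        t_e, c_e = window_slice(ecf, t_last, t_last + 12.0)
        out["auc24_plasma"] = float(np.trapezoid(c_p, t_p))
    out["cmax_plasma"] = float(c_p[t_p <= 24 + 1e-9].max() if config.scenario == "single_dose" else c_p.max())
    out["cmax_ecf"] = float(c_e[t_e <= 12 + 1e-9].max())
    mask12 = t_e <= 12 + 1e-9
    out["auc12_ecf"] = float(np.trapezoid(c_e[mask12], t_e[mask12]))
    return out


_COMPARISON_ROWS = {
    "single_dose": [
        ("t1/2 plasma (h)", "t_half_plasma", "t_half_plasma"),
        ("Cmax plasma (ng/mL)", "cmax_plasma", "cmax_plasma"),
        ("AUC0-72 plasma (h.ng/mL)", "auc72_plasma", "auc72_plasma"),
        ("Cmax brain ECF (ng/mL)", "cmax_ecf", "cmax_ecf"),
        ("AUC0-12 brain ECF (h.ng/mL)", "auc12_ecf", "auc12_ecf"),
    ],
    "steady_state": [
        ("Cmax plasma (ng/mL)", "cmax_plasma", "cmax_plasma"),
        ("AUC0-24 plasma (h.ng/mL)", "auc24_plasma", "auc24_plasma"),
        ("Cmax brain ECF (ng/mL)", "cmax_ecf", "cmax_ecf"),
        ("AUC0-12 brain ECF (h.ng/mL)", "auc12_ecf", "auc12_ecf"),
    ],
}


def prediction_table(config: RunConfig, simulated: dict) -> pd.DataFrame:
    """Tables 4/5-shaped predicted-vs-observed comparison."""
    obs = load_observed_tables()[config.scenario][config.sex]
    rows = []
    for label, sim_key, obs_key in _COMPARISON_ROWS[config.scenario]:
        pred = simulated.get(sim_key)
        o = obs.get(obs_key)
        if pred is None or o is None:
            continue
        ratio = pred / o
        rows.append(
            dict(
                parameter=label,
                observed=o,
                predicted=round(pred, 2),
                ratio=round(ratio, 2),
                classification=classify_prediction(pred, o),
            )
        )
    return pd.DataFrame(rows)


def run_scenario(config: RunConfig) -> dict:
    """Run one scenario end to end and write the report bundle.

    Writes profiles CSV, NCA-style simulated summary JSON, the derived
    observed-metrics table and the predicted/observed classification table
    into ``config.out_dir``; returns the bundle as a dict.  Deterministic
    for a given config and seed.
    """
    drug_path = config.drug_file or data_path(f"letrozole_{config.sex}.yaml")
    phys_path = config.physiology_file or data_path("rat_250g.yaml")
    try:
        drug = load_drug(drug_path)
        physiology = load_physiology(phys_path)
    except FileNotFoundError as err:
        raise FileNotFoundError(f"configuration error: {err}") from err

    regimen = _regimen(config)
    kp_set = predict_kp(drug)
    vss = vss_from_kp(kp_set, physiology, drug)
    model = PBPKModel(drug, physiology, regimen, kp_set)
    results = model.simulate()

    simulated = _simulated_summary(config, results)
    simulated["vss_L_kg"] = vss
    pred_table = prediction_table(config, simulated)
    obs_table = observed_metrics_table(config)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{config.scenario}_{config.sex}"
    results.to_csv(out_dir / f"{stem}_profiles.csv")
    obs_table.to_csv(out_dir / f"{stem}_observed_metrics.csv", index=False)
    pred_table.to_csv(out_dir / f"{stem}_predicted_vs_observed.csv", index=False)
    with open(out_dir / f"{stem}_summary.json", "w") as fh:
        json.dump(
            {
                "config": config.model_dump(),
                "simulated": {k: v for k, v in simulated.items() if v is not None},
                "kp_set": kp_set,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return {
        "config": config,
        "results": results,
        "simulated": simulated,
        "observed_metrics": obs_table,
        "prediction_table": pred_table,
        "vss_L_kg": vss,
    }
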