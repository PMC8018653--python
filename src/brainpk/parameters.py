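"""Domain parameter objects: drug, physiology, dose regimen and profiles.

All quantities carry explicit units in their field names or docstrings.
Internally the simulator works in ng (amount), L (volume) and h (time);
concentrations cross the I/O boundary as ng/mL.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "DrugParameters",
    "PhysiologySet",
    "DoseRegimen",
    "ConcentrationTimeProfile",
    "MATRICES",
    "PERFUSION_TISSUES",
    "load_drug",
    "load_physiology",
    "data_path",
]

#: tissues of the whole-body model handled as perfusion (flow) limited;
#: brain is excluded because it is replaced by the three-compartment submodel
PERFUSION_TISSUES = (
    "lung",
    "adipose",
    "bone",
    "gut",
    "heart",
    "kidney",
    "liver",
    "muscle",
    "skin",
    "spleen",
    "rest",
)

#: output matrices produced by the simulator
MATRICES = (
    "plasma_total",
    "plasma_unbound",
    "brain_blood",
    "brain_mass",
    "brain_ecf",
    "csf",
    "dialysate",
)

MIN_PER_H = 60.0
ML_PER_L = 1000.0


class DrugParameters(BaseModel):
    """Physicochemical, binding, absorption, clearance and brain-barrier
    parameters of one compound.

    Clearance ``cl_systemic_ml_min`` is the in-vivo oral (dose/AUC) clearance
    at the reference body weight; the simulator converts it to a systemic
    plasma clearance as ``CLpo * fa``.
    """

    model_config = ConfigDict(frozen=True)

    name: str = "compound"
    molecular_weight: float = Field(gt=0, description="g/mol")
    logp: float
    blood_plasma_ratio: float = Field(gt=0)
    fu_plasma: float = Field(gt=0, le=1)
    intrinsic_solubility: float = Field(gt=0, description="ug/mL")
    fa: float = Field(gt=0, le=1, description="fraction absorbed")
    ka: float = Field(ge=0, description="1/h first-order absorption")
    cl_systemic_ml_min: float = Field(ge=0, description="oral clearance, mL/min")
    fu_brain: float = Field(gt=0, le=1)
    psb_ml_min: float = Field(ge=0, description="BBB passive PS product, mL/min")
    psc_ml_min: float = Field(ge=0, description="BCSFB passive PS product, mL/min")
    pse_ml_min: float = Field(ge=0, description="CSFBB passive PS product, mL/min")
    cl_b_in: float = Field(default=0.0, ge=0, description="BBB uptake transporter CL, L/h")
    cl_b_out: float = Field(default=0.0, ge=0, description="BBB efflux transporter CL, L/h")
    cl_c_in: float = Field(default=0.0, ge=0, description="BCSFB uptake transporter CL, L/h")
    cl_c_out: float = Field(default=0.0, ge=0, description="BCSFB efflux transporter CL, L/h")
    cl_met_brain: float = Field(default=0.0, ge=0, description="brain metabolic CL, L/h")
    kp_scalar: float = Field(default=1.0, gt=0)
    ionization: str = Field(
        default="neutral",
        description="'neutral' or 'base' branch for tissue partitioning; "
        "the letrozole fixture records neutral-at-pH-7.4 as an assumption, not fact",
    )
    pka: float | None = Field(default=None, description="basic pKa when ionization='base'")

    @property
    def cl_plasma_L_h(self) -> float:
        """Systemic plasma clearance (L/h) = CLpo * Fa."""
        return self.cl_systemic_ml_min * MIN_PER_H / ML_PER_L * self.fa

    @property
    def psb_L_h(self) -> float:
        return self.psb_ml_min * MIN_PER_H / ML_PER_L

    @property
    def psc_L_h(self) -> float:
        return self.psc_ml_min * MIN_PER_H / ML_PER_L

    @property
    def pse_L_h(self) -> float:
        return self.pse_ml_min * MIN_PER_H / ML_PER_L


class PhysiologySet(BaseModel):
    """Rat anatomy/physiology for one sex/body weight.

    Volumes in L, flows in L/h.  ``volumes`` and ``flows`` are keyed by the
    perfusion-tissue names; the brain is carried separately as the
    three-compartment submodel (blood, mass, CSF).  The brain-blood volume is
    additional to the systemic arterial/venous pools.
    """

    model_config = ConfigDict(frozen=True)

    name: str = "rat"
    body_weight_kg: float = Field(gt=0)
    volumes: dict[str, float]
    flows: dict[str, float]
    v_arterial: float = Field(gt=0)
    v_venous: float = Field(gt=0)
    brain_weight_g: float = Field(gt=0)
    v_brain_blood: float = Field(gt=0)
    v_brain_mass: float = Field(gt=0)
    v_csf: float = Field(gt=0)
    q_brain: float = Field(gt=0, description="cerebral blood flow, L/h")
    q_bulk: float = Field(ge=0, description="brain mass -> CSF bulk flow, L/h")
    q_sink: float = Field(ge=0, description="CSF -> brain blood sink flow, L/h")
    hematocrit: float = Field(default=0.45, gt=0, lt=1)

    @model_validator(mode="after")
    def _check_balance(self) -> "PhysiologySet":
        missing = set(PERFUSION_TISSUES) - set(self.volumes)
        if missing:
            raise ValueError(f"missing tissue volumes: {sorted(missing)}")
        if any(v <= 0 for v in self.volumes.values()):
            raise ValueError("all tissue volumes must be positive")
        tissue_flows = [k for k in PERFUSION_TISSUES if k != "lung"]
        missing_f = set(tissue_flows) - set(self.flows)
        if missing_f:
            raise ValueError(f"missing tissue flows: {sorted(missing_f)}")
        co = self.cardiac_output
        total = sum(self.flows[k] for k in tissue_flows) + self.q_brain
        if abs(total - co) / co > 1e-6:
            raise ValueError(
                f"organ flows ({total:.6g} L/h) do not sum to cardiac output ({co:.6g} L/h)"
            )
        return self

    @property
    def cardiac_output(self) -> float:
        """Total flow through the lung, L/h."""
        return self.flows["cardiac_output"]


class DoseRegimen(BaseModel):
    """Extravascular first-order dosing schedule."""

    model_config = ConfigDict(frozen=True)

    dose_mg_per_kg: float = Field(ge=0)
    interval_tau_h: float = Field(default=24.0, gt=0)
    n_doses: int = Field(default=1, ge=1)
    simulation_end_h: float = Field(gt=0)

    @model_validator(mode="after")
    def _check_window(self) -> "DoseRegimen":
        if self.simulation_end_h < (self.n_doses - 1) * self.interval_tau_h:
            raise ValueError("simulation_end must cover all dose times")
        return self

    def dose_times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval_tau_h

    def dose_amount_ng(self, body_weight_kg: float) -> float:
        """Amount per administration in ng."""
        return self.dose_mg_per_kg * body_weight_kg * 1e6


class ConcentrationTimeProfile:
    """One matrix concentration-time series (ng/mL, h)."""

    def __init__(self, matrix: str, times_h, conc_ng_ml):
        times = np.asarray(times_h, dtype=float)
        conc = np.asarray(conc_ng_ml, dtype=float)
        if times.shape != conc.shape or times.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(conc < 0):
            raise ValueError("negative concentrations are not allowed")
        self.matrix = str(matrix)
        self.times_h = times
        self.conc_ng_ml = conc

    def __len__(self) -> int:
        return self.times_h.size

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.times_h, self.conc_ng_ml))

    def scaled(self, factor: float) -> "ConcentrationTimeProfile":
        return ConcentrationTimeProfile(self.matrix, self.times_h, self.conc_ng_ml * factor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"matrix": self.matrix, "time_h": self.times_h, "conc_ng_per_ml": self.conc_ng_ml}
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ConcentrationTimeProfile({self.matrix!r}, n={len(self)}, "
            f"t=[{self.times_h[0]:g}, {self.times_h[-1]:g}] h)"
        )


# ---------------------------------------------------------------------------
# fixture I/O

_DATA_DIR = Path(__file__).parent / "data"


def data_path(name: str) -> Path:
    """Path to a shipped data file (drug/physiology fixtures, composition table)."""
    p = _DATA_DIR / name
    if not p.exists():
        raise FileNotFoundError(f"no shipped data file named {name!r}")
    return p


def _load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")
    return dict(doc)


def load_drug(path: str | Path) -> DrugParameters:
    """Read a drug parameter YAML file (explicit unit-suffixed keys)."""
    doc = _load_yaml(path)
    doc.pop("units", None)
    doc.pop("assumptions", None)
    return DrugParameters(**doc)


def load_physiology(path: str | Path) -> PhysiologySet:
    """Read a physiology YAML file."""
    doc = _load_yaml(path)
    doc.pop("units", None)
    doc.pop("source", None)
    return PhysiologySet(**doc)
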