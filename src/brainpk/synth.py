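"""Synthetic rat PK study generator.

Emulates the animal study design the analysis layer expects: 4 mg/kg i.p.
dosing once daily, plasma sampling at fixed nominal times (0-72 h after a
single dose, 0-24 h at steady state), microdialysis dialysate collected as
time-averaged windows over 0-12 h with a finite probe recovery, an assay
LLOQ below which values are censored, and a handful of animals per group.

Truth models
------------
* :class:`MonoExponentialTruth` — one-compartment kinetics, either bolus-like
  (pure mono-exponential, exactly linear so accumulation follows
  1/(1-e^(-k*tau))) or with first-order absorption.  Brain ECF truth is
  proportional to plasma through Kpuu x fu_plasma.
* :class:`PBPKTruth` — wraps a :class:`~brainpk.pbpk.PBPKModel` simulation.

Between-animal variability is lognormal on clearance and Ka (default CV
25 %); assay error is multiplicative lognormal (default CV 5 %, matching a
low-RSD HPLC assay).  All randomness flows from the design seed, so a given
design reproduces byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .nca import NCA
from .metrics import kpuu as kpuu_metric
from .metrics import rac_observed, rac_predicted, recovery_correct
from .parameters import ConcentrationTimeProfile, DoseRegimen

__all__ = [
    "StudyDesign",
    "StudyDataset",
    "MonoExponentialTruth",
    "PBPKTruth",
    "generate_study",
    "pipeline_roundtrip",
    "FEMALE_TRUTH",
    "MALE_TRUTH",
    "SINGLE_DOSE_TIMES",
    "STEADY_STATE_TIMES",
    "DIALYSATE_WINDOWS",
    "window_average",
]

#: nominal plasma sampling schedules (h)
SINGLE_DOSE_TIMES = (0.0, 1, 2, 4, 6, 8, 12, 14, 20, 24, 36, 48, 72)
STEADY_STATE_TIMES = (0.0, 1, 2, 4, 6, 8, 12, 24)
#: dialysate collection windows over the 0-12 h probe-patency span (h)
DIALYSATE_WINDOWS = ((0, 1), (1, 2), (2, 4), (4, 6), (6, 8), (8, 12))


@dataclass(frozen=True)
class StudyDesign:
    """One study arm: animals, regimen, schedules, assay characteristics."""

    group_label: str
    n_animals: int
    sex: str
    regimen: DoseRegimen
    plasma_times: tuple[float, ...] = SINGLE_DOSE_TIMES
    dialysate_windows: tuple[tuple[float, float], ...] = DIALYSATE_WINDOWS
    probe_recovery: float = 0.072
    lloq: float = 5.0
    noise_cv: float = 0.05
    bsv_cv: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if len(self.plasma_times) == 0:
            raise ValueError("empty plasma sampling schedule")
        w = sorted(self.dialysate_windows)
        for (a0, a1), (b0, b1) in zip(w, w[1:]):
            if b0 < a1:
                raise ValueError("dialysate windows must not overlap")
        for a0, a1 in w:
            if a0 < 0 or a1 > 12 + 1e-9 or a1 <= a0:
                raise ValueError("dialysate windows must lie within 0-12 h")


class MonoExponentialTruth:
    """One-compartment truth for the generator.

    Parameters
    ----------
    k10 : 1/h terminal elimination rate constant.
    v_ml_per_kg : apparent volume of distribution per kg (so that
        C0 = dose / V for a bolus-like dose).
    ka : first-order absorption rate (1/h) or None for bolus kinetics.
    kpuu_true : unbound brain-to-plasma ratio driving the ECF truth.
    fu_plasma : plasma unbound fraction used in the ECF truth.
    """

    def __init__(
        self,
        k10: float,
        v_ml_per_kg: float,
        ka: float | None = None,
        kpuu_true: float = 1.0,
        fu_plasma: float = 0.38,
    ):
        if k10 <= 0 or v_ml_per_kg <= 0:
            raise ValueError("k10 and volume must be positive")
        if ka is not None and ka <= k10:
            raise ValueError("ka must exceed k10 (no flip-flop truth supported)")
        self.k10 = k10
        self.v_ml_per_kg = v_ml_per_kg
        self.ka = ka
        self.kpuu_true = kpuu_true
        self.fu_plasma = fu_plasma

    def with_params(self, **kw) -> "MonoExponentialTruth":
        cur = dict(
            k10=self.k10,
            v_ml_per_kg=self.v_ml_per_kg,
            ka=self.ka,
            kpuu_true=self.kpuu_true,
            fu_plasma=self.fu_plasma,
        )
        cur.update(kw)
        return MonoExponentialTruth(**cur)

    def plasma(self, t, regimen: DoseRegimen):
        """True total plasma concentration (ng/mL) at time(s) t under the
        regimen (superposition of identical doses)."""
        t = np.asarray(t, dtype=float)
        dose_ng_per_kg = regimen.dose_mg_per_kg * 1e6
        c0 = dose_ng_per_kg / self.v_ml_per_kg
        out = np.zeros_like(t)
        for td in regimen.dose_times():
            dt = t - td
            live = dt >= 0
            if self.ka is None:
                out[live] += c0 * np.exp(-self.k10 * dt[live])
            else:
                scale = c0 * self.ka / (self.ka - self.k10)
                out[live] += scale * (
                    np.exp(-self.k10 * dt[live]) - np.exp(-self.ka * dt[live])
                )
        return out

    def ecf(self, t, regimen: DoseRegimen):
        """True brain ECF concentration: Kpuu x fu_plasma x plasma."""
        return self.kpuu_true * self.fu_plasma * self.plasma(t, regimen)

    @property
    def cl_ml_h_kg(self) -> float:
        return self.k10 * self.v_ml_per_kg


class PBPKTruth:
    """Truth backed by a PBPK simulation (dense grid, linear interpolation)."""

    def __init__(self, drug, physiology, kp_set=None, grid_step_h: float = 0.05):
        self.drug = drug
        self.physiology = physiology
        self.kp_set = kp_set
        self.grid_step_h = grid_step_h
        self._cache: dict = {}

    def with_params(self, cl_scale: float = 1.0, ka_scale: float = 1.0) -> "PBPKTruth":
        drug = self.drug.model_copy(
            update={
                "cl_systemic_ml_min": self.drug.cl_systemic_ml_min * cl_scale,
                "ka": self.drug.ka * ka_scale,
            }
        )
        return PBPKTruth(drug, self.physiology, self.kp_set, self.grid_step_h)

    def _profiles(self, regimen: DoseRegimen):
        key = (regimen.dose_mg_per_kg, regimen.n_doses, regimen.interval_tau_h,
               regimen.simulation_end_h)
        if key not in self._cache:
            from .pbpk import PBPKModel

            model = PBPKModel(self.drug, self.physiology, regimen, self.kp_set)
            self._cache[key] = model.simulate().profiles
        return self._cache[key]

    def _interp(self, matrix: str, t, regimen):
        prof = self._profiles(regimen)[matrix]
        return np.interp(np.asarray(t, dtype=float), prof.times_h, prof.conc_ng_ml)

    def plasma(self, t, regimen):
        return self._interp("plasma_total", t, regimen)

    def ecf(self, t, regimen):
        return self._interp("brain_ecf", t, regimen)


def window_average(fn: Callable[[np.ndarray], np.ndarray], t0: float, t1: float) -> float:
    """Time-average of a concentration curve over [t0, t1] by adaptive
    quadrature."""
    val, _ = quad(lambda x: float(fn(np.atleast_1d(x))[0]), t0, t1, limit=200)
    return val / (t1 - t0)


@dataclass
class StudyDataset:
    """Generated multi-animal dataset plus the truth that produced it."""

    design: StudyDesign
    records: pd.DataFrame
    animal_params: pd.DataFrame = field(repr=False, default=None)

    def observed(self, matrix: str, animal_id: int) -> pd.DataFrame:
        m = self.records
        sub = m[(m.matrix == matrix) & (m.animal_id == animal_id) & (~m.censored)]
        return sub.sort_values("time_h")

    def profile(self, matrix: str, animal_id: int) -> ConcentrationTimeProfile:
        """Analysis profile for one animal/matrix.

        BLQ (censored) samples before the observed peak are imputed as zero
        (rising limb); BLQ samples after the peak are dropped.
        """
        m = self.records
        sub = m[(m.matrix == matrix) & (m.animal_id == animal_id)].sort_values("time_h")
        quant = sub[~sub.censored]
        if quant.empty:
            raise ValueError(f"animal {animal_id} has no quantifiable {matrix} samples")
        t_peak = quant.loc[quant["conc_ng_per_ml"].idxmax(), "time_h"]
        keep = sub[(~sub.censored) | (sub.time_h < t_peak)]
        conc = keep["conc_ng_per_ml"].fillna(0.0).to_numpy()
        return ConcentrationTimeProfile(matrix, keep["time_h"].to_numpy(), conc)

    def ecf_profile(self, animal_id: int) -> ConcentrationTimeProfile:
        """Recovery-corrected ECF profile at window midpoints."""
        prof = self.profile("dialysate", animal_id)
        ecf = recovery_correct(prof.conc_ng_ml, self.design.probe_recovery)
        return ConcentrationTimeProfile("brain_ecf", prof.times_h, ecf)

    @property
    def n_censored(self) -> int:
        return int(self.records.censored.sum())

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def generate_study(design: StudyDesign, truth) -> StudyDataset:
    """Generate one study arm from a truth model.

    Per-animal parameters are lognormal around the truth (CV
    ``design.bsv_cv`` on clearance and absorption rate); plasma samples get
    multiplicative lognormal assay noise (CV ``design.noise_cv``);
    dialysate records are the exact time-average of the true ECF curve over
    each window, times probe recovery, times assay noise.  Values below the
    LLOQ are censored (flag set, no numeric value).
    """
    rng = np.random.default_rng(design.seed)
    reg = design.regimen
    rows = []
    params = []
    sigma_bsv = math.sqrt(math.log(1.0 + design.bsv_cv**2))
    sigma_noise = math.sqrt(math.log(1.0 + design.noise_cv**2))

    def noise(size=None):
        if design.noise_cv == 0:
            return 1.0 if size is None else np.ones(size)
        return rng.lognormal(-0.5 * sigma_noise**2, sigma_noise, size)

    for animal in range(1, design.n_animals + 1):
        if design.bsv_cv > 0:
            cl_scale = rng.lognormal(-0.5 * sigma_bsv**2, sigma_bsv)
            ka_scale = rng.lognormal(-0.5 * sigma_bsv**2, sigma_bsv)
        else:
            cl_scale, ka_scale = 1.0, 1.0
        truth_i = _scaled_truth(truth, cl_scale, ka_scale)
        params.append({"animal_id": animal, "cl_scale": cl_scale, "ka_scale": ka_scale})

        # sampling happens on the last dosing day: nominal times are
        # post-administration offsets from the final dose
        t_offset = (reg.n_doses - 1) * reg.interval_tau_h
        t = np.asarray(design.plasma_times, dtype=float)
        c_true = truth_i.plasma(t_offset + t, reg)
        c_obs = c_true * noise(t.size)
        for tj, cj in zip(t, c_obs):
            censored = bool(cj < design.lloq)
            rows.append(
                dict(
                    animal_id=animal,
                    matrix="plasma_total",
                    time_h=tj,
                    window_start_h=np.nan,
                    window_end_h=np.nan,
                    conc_ng_per_ml=np.nan if censored else cj,
                    censored=censored,
                )
            )

        for w0, w1 in design.dialysate_windows:
            avg = window_average(
                lambda x: truth_i.ecf(t_offset + x, reg), w0, w1
            )
            dial = avg * design.probe_recovery * float(noise())
            censored = bool(dial < design.lloq)
            rows.append(
                dict(
                    animal_id=animal,
                    matrix="dialysate",
                    time_h=0.5 * (w0 + w1),
                    window_start_h=w0,
                    window_end_h=w1,
                    conc_ng_per_ml=np.nan if censored else dial,
                    censored=censored,
                )
            )

    return StudyDataset(
        design=design,
        records=pd.DataFrame(rows),
        animal_params=pd.DataFrame(params),
    )


def _scaled_truth(truth, cl_scale: float, ka_scale: float):
    if isinstance(truth, MonoExponentialTruth):
        # clearance scales k10 at constant volume; ka scales directly
        kw = {"k10": truth.k10 * cl_scale}
        if truth.ka is not None:
            kw["ka"] = truth.ka * ka_scale
        return truth.with_params(**kw)
    return truth.with_params(cl_scale=cl_scale, ka_scale=ka_scale)


# truth defaults reproducing the observed study conditions: slow female
# clearance (t1/2 34 h) vs fast male clearance (t1/2 9.2 h)
FEMALE_TRUTH = MonoExponentialTruth(
    k10=math.log(2) / 34.0, v_ml_per_kg=57.4 / (math.log(2) / 34.0),
    kpuu_true=1.3, fu_plasma=0.38,
)
MALE_TRUTH = MonoExponentialTruth(
    k10=math.log(2) / 9.2, v_ml_per_kg=145.9 / (math.log(2) / 9.2),
    kpuu_true=0.6, fu_plasma=0.38,
)


def pipeline_roundtrip(
    design_sd: StudyDesign,
    design_ss: StudyDesign,
    truth: MonoExponentialTruth,
) -> dict:
    """Generate single-dose and steady-state arms, run NCA and the derived
    metrics, and report recovery bias against the truth.

    Returns a dict with group-mean estimates (t1/2, AUC0-12 for plasma and
    ECF, Kpuu, observed and predicted accumulation ratios) and their
    relative bias vs the truth-implied values.
    """
    ds_sd = generate_study(design_sd, truth)
    ds_ss = generate_study(design_ss, truth)

    t_half, k10s = [], []
    auc12_plasma_sd, auc12_plasma_ss = [], []
    auc12_ecf_sd, auc12_ecf_ss = [], []
    kpuu_vals = []
    for animal in range(1, design_sd.n_animals + 1):
        prof = ds_sd.profile("plasma_total", animal)
        res = NCA(prof, dose_mg_per_kg=design_sd.regimen.dose_mg_per_kg,
                  lloq=design_sd.lloq, windows=((0, 12),)).fit()
        if res.t_half is not None:
            t_half.append(res.t_half)
            k10s.append(res.k10)
        auc12_plasma_sd.append(res.auc_windows["0-12"])
        ecf = ds_sd.ecf_profile(animal)
        auc12_ecf_sd.append(np.trapezoid(ecf.conc_ng_ml, ecf.times_h))
    for animal in range(1, design_ss.n_animals + 1):
        prof = ds_ss.profile("plasma_total", animal)
        auc12_plasma_ss.append(
            NCA(prof, windows=((0, 12),)).fit(min_terminal_points=3).auc_windows["0-12"]
        )
        ecf = ds_ss.ecf_profile(animal)
        ecf_auc = np.trapezoid(ecf.conc_ng_ml, ecf.times_h)
        auc12_ecf_ss.append(ecf_auc)
        # plasma interpolated onto the ECF (window-midpoint) grid for Kpuu
        p = ds_ss.profile("plasma_total", animal)
        p_mid = np.interp(ecf.times_h, p.times_h, p.conc_ng_ml)
        p_auc = np.trapezoid(p_mid, ecf.times_h)
        kpuu_vals.append(
            kpuu_metric(ecf_auc, p_auc, truth.fu_plasma, basis="auc_0_12").kpuu
        )

    k10_mean = float(np.mean(k10s))
    rac_obs = rac_observed(float(np.mean(auc12_plasma_ss)), float(np.mean(auc12_plasma_sd)))
    rac_pred = rac_predicted(k10_mean, design_ss.regimen.interval_tau_h)
    t_half_mean = float(np.mean(t_half))
    kpuu_mean = float(np.mean(kpuu_vals))
    truth_t_half = math.log(2) / truth.k10
    return {
        "t_half_mean_h": t_half_mean,
        "t_half_bias": t_half_mean / truth_t_half - 1.0,
        "auc12_plasma_sd": float(np.mean(auc12_plasma_sd)),
        "auc12_ecf_sd": float(np.mean(auc12_ecf_sd)),
        "rac_observed": rac_obs,
        "rac_predicted": rac_pred,
        "rac_consistency": rac_obs / rac_pred - 1.0,
        "kpuu_mean": kpuu_mean,
        "kpuu_bias": kpuu_mean / truth.kpuu_true - 1.0,
        "n_censored_sd": ds_sd.n_censored,
        "n_censored_ss": ds_ss.n_censored,
    }
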