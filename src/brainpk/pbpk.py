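"""Whole-body rat PBPK simulator with a three-compartment brain.

The body is described by flow-limited (venous-equilibrium) tissues —
lung, adipose, bone, gut, heart, kidney, liver, muscle, skin, spleen and a
lumped rest-of-body — connected by arterial and venous blood pools, with the
brain replaced by a three-compartment submodel (brain blood, brain mass,
CSF).  Gut and spleen drain through the liver (portal inflow).  Dosing is
extravascular first-order absorption into venous blood; systemic clearance
is applied to the venous plasma concentration as CLpo x Fa so that the
steady-state plasma AUC over a dosing interval equals Dose/CLpo, the
defining property of an in-vivo oral clearance.

Brain exchange across the three barriers (BBB, BCSFB, CSFBB) is passive and
driven by unbound concentrations:

* brain blood unbound  = C_blood * fu_plasma / BP
* brain mass unbound   = fu_brain * C_brain_mass
* CSF                  = treated as fully unbound

with bulk flow Q_bulk carrying unbound brain-mass drug into CSF and
Q_sink returning CSF to brain blood.  Transporter clearances (CLBin,
CLBout, CLCin, CLCout) and brain metabolic clearance are carried in the
equations but are zero for the letrozole parameter set.

The full system is linear, so repeat doses superpose; the integrator
restarts at each dose time and re-adds the depot amount.

Internal units: amounts ng, volumes L, time h, concentrations ng/L
(converted to ng/mL at the output boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import (
    MATRICES,
    PERFUSION_TISSUES,
    ConcentrationTimeProfile,
    DoseRegimen,
    DrugParameters,
    PhysiologySet,
)
from .partition import ConfigurationError, predict_kp

__all__ = ["PBPKModel", "PBPKResults", "brain_fluxes", "IntegrationError"]

NG_L_PER_NG_ML = 1000.0


class IntegrationError(RuntimeError):
    """The ODE integration produced a non-finite state."""


def brain_fluxes(
    amounts: tuple[float, float, float],
    drug: DrugParameters,
    physiology: PhysiologySet,
) -> tuple[float, float, float]:
    """Exchange rates of change (ng/h) for (brain blood, brain mass, CSF).

    Pure function over the three brain compartment amounts (ng).  Covers the
    passive PS fluxes across BBB/BCSFB/CSFBB, bulk and sink flows, transporter
    clearances and brain metabolism — everything except cerebral perfusion,
    which couples brain blood to the systemic circulation and is handled by
    the whole-body right-hand side.
    """
    a_bb, a_bm, a_csf = amounts
    c_bb = a_bb / physiology.v_brain_blood          # blood-referenced, ng/L
    c_bm = a_bm / physiology.v_brain_mass
    c_csf = a_csf / physiology.v_csf

    cu_bb = c_bb * drug.fu_plasma / drug.blood_plasma_ratio
    cu_bm = drug.fu_brain * c_bm
    cu_csf = c_csf                                   # CSF taken as fully unbound

    j_bbb = drug.psb_L_h * (cu_bb - cu_bm)
    j_bcsfb = drug.psc_L_h * (cu_bb - cu_csf)
    j_csfbb = drug.pse_L_h * (cu_bm - cu_csf)
    t_bbb = drug.cl_b_in * cu_bb - drug.cl_b_out * cu_bm
    t_bcsfb = drug.cl_c_in * cu_bb - drug.cl_c_out * cu_csf
    bulk = physiology.q_bulk * cu_bm
    sink = physiology.q_sink * c_csf
    met = drug.cl_met_brain * cu_bm

    d_bb = -j_bbb - j_bcsfb - t_bbb - t_bcsfb + sink
    d_bm = j_bbb + t_bbb - j_csfbb - bulk - met
    d_csf = j_bcsfb + t_bcsfb + j_csfbb + bulk - sink
    return d_bb, d_bm, d_csf


@dataclass
class PBPKResults:
    """Simulation output: concentration profiles, state trajectories and
    mass-balance accounting."""

    model: "PBPKModel"
    times_h: np.ndarray
    states: pd.DataFrame                  # amounts (ng) per compartment
    profiles: dict[str, ConcentrationTimeProfile]
    absorbed_ng: np.ndarray = field(repr=False, default=None)
    eliminated_ng: np.ndarray = field(repr=False, default=None)

    def mass_balance(self, rtol: float = 1e-6) -> pd.DataFrame:
        """Absorbed / in-body / eliminated amounts vs time.

        Checks absorbed = in-body + eliminated at every output time;
        raises ``IntegrationError`` with the max relative error if the
        closure is worse than ``rtol``.
        """
        body_cols = [c for c in self.states.columns if c not in ("depot",)]
        in_body = self.states[body_cols].sum(axis=1).to_numpy()
        df = pd.DataFrame(
            {
                "time_h": self.times_h,
                "absorbed_ng": self.absorbed_ng,
                "in_body_ng": in_body,
                "eliminated_ng": self.eliminated_ng,
            }
        )
        df["closure_ng"] = df.absorbed_ng - df.in_body_ng - df.eliminated_ng
        scale = np.maximum(df.absorbed_ng.to_numpy(), 1e-12)
        rel = np.abs(df.closure_ng.to_numpy()) / scale
        df["rel_error"] = rel
        mask = df.absorbed_ng > 0
        if mask.any() and rel[mask.to_numpy()].max() > rtol:
            raise IntegrationError(
                f"mass balance violated: max relative error {rel[mask.to_numpy()].max():.3e}"
            )
        return df

    def to_csv(self, path) -> None:
        """Write tidy profile CSV (matrix, time_h, conc_ng_per_ml)."""
        pd.concat([p.to_frame() for p in self.profiles.values()]).to_csv(path, index=False)

    def plot(self, matrices=("plasma_total", "brain_ecf"), ax=None, logy=True):
        """Quick concentration-time plot for the chosen matrices."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for m in matrices:
            prof = self.profiles[m]
            ax.plot(prof.times_h, prof.conc_ng_ml, label=m)
        if logy:
            ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (ng/mL)")
        ax.legend()
        return ax


class PBPKModel:
    """Whole-body PBPK model for one drug/physiology/regimen.

    Parameters
    ----------
    drug, physiology, regimen
        Parameter objects; see :mod:`brainpk.parameters`.
    kp_set
        Tissue-to-plasma partition coefficients for every perfusion-limited
        tissue.  Default: predicted mechanistically from the shipped rat
        composition table.
    probe_recovery
        Microdialysis recovery used to derive the ``dialysate`` output matrix
        from brain ECF (default 0.072, the in-vitro letrozole recovery).
    """

    def __init__(
        self,
        drug: DrugParameters,
        physiology: PhysiologySet,
        regimen: DoseRegimen,
        kp_set: dict[str, float] | None = None,
        probe_recovery: float = 0.072,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ):
        self.drug = drug
        self.physiology = physiology
        self.regimen = regimen
        if kp_set is None:
            kp_set = predict_kp(drug)
        missing = [t for t in PERFUSION_TISSUES if t not in kp_set]
        if missing:
            raise ConfigurationError(f"kp_set lacks tissues: {missing}")
        self.kp_set = dict(kp_set)
        self.probe_recovery = probe_recovery
        self.rtol = rtol
        self.atol = atol
        self._index = self._build_index()
        self._matrix = self._build_matrix()

    # -- state layout -------------------------------------------------------
    def _build_index(self) -> dict[str, int]:
        names = (
            ["depot"]
            + list(PERFUSION_TISSUES)
            + ["arterial", "venous", "brain_blood", "brain_mass", "csf", "eliminated"]
        )
        return {n: i for i, n in enumerate(names)}

    @property
    def compartments(self) -> list[str]:
        return list(self._index)

    # -- linear system ------------------------------------------------------
    def _build_matrix(self) -> np.ndarray:
        """Constant coefficient matrix M with dA/dt = M A (linear kinetics)."""
        d, phys, kp = self.drug, self.physiology, self.kp_set
        ix = self._index
        n = len(ix)
        m = np.zeros((n, n))
        bp = d.blood_plasma_ratio
        co = phys.cardiac_output

        def vol(t):
            return phys.volumes[t]

        # tissue outflow concentration per unit amount: BP / (Kp * V)
        def out_coef(t):
            return bp / (kp[t] * vol(t))

        # depot -> venous absorption
        m[ix["depot"], ix["depot"]] -= d.ka
        m[ix["venous"], ix["depot"]] += d.ka

        # lung: venous -> lung -> arterial
        m[ix["lung"], ix["venous"]] += co / phys.v_venous
        m[ix["lung"], ix["lung"]] -= co * out_coef("lung")
        m[ix["arterial"], ix["lung"]] += co * out_coef("lung")

        # arterial supplies all tissues + brain; total = CO
        m[ix["arterial"], ix["arterial"]] -= co / phys.v_arterial

        portal = ("gut", "spleen")
        q_liver_total = phys.flows["liver"] + sum(phys.flows[t] for t in portal)
        for t in PERFUSION_TISSUES:
            if t == "lung":
                continue
            q = phys.flows[t]
            m[ix[t], ix["arterial"]] += q / phys.v_arterial
            if t in portal:
                m[ix[t], ix[t]] -= q * out_coef(t)
                m[ix["liver"], ix[t]] += q * out_coef(t)
            elif t == "liver":
                m[ix[t], ix[t]] -= q_liver_total * out_coef(t)
                m[ix["venous"], ix[t]] += q_liver_total * out_coef(t)
            else:
                m[ix[t], ix[t]] -= q * out_coef(t)
                m[ix["venous"], ix[t]] += q * out_coef(t)

        # venous pool: collect, send to lung, eliminate on plasma concentration
        m[ix["venous"], ix["venous"]] -= co / phys.v_venous
        cl_term = d.cl_plasma_L_h / bp / phys.v_venous
        m[ix["venous"], ix["venous"]] -= cl_term
        m[ix["eliminated"], ix["venous"]] += cl_term

        # brain perfusion
        m[ix["brain_blood"], ix["arterial"]] += phys.q_brain / phys.v_arterial
        m[ix["brain_blood"], ix["brain_blood"]] -= phys.q_brain / phys.v_brain_blood
        m[ix["venous"], ix["brain_blood"]] += phys.q_brain / phys.v_brain_blood

        # brain exchange: unbound-concentration coefficients per unit amount
        u_bb = d.fu_plasma / bp / phys.v_brain_blood
        u_bm = d.fu_brain / phys.v_brain_mass
        u_csf = 1.0 / phys.v_csf
        psb, psc, pse = d.psb_L_h, d.psc_L_h, d.pse_L_h

        def add(dst, src, coef):
            m[ix[dst], ix[src]] += coef

        # BBB: blood <-> mass (passive + transporters)
        add("brain_blood", "brain_blood", -(psb + d.cl_b_in) * u_bb)
        add("brain_mass", "brain_blood", (psb + d.cl_b_in) * u_bb)
        add("brain_mass", "brain_mass", -(psb + d.cl_b_out) * u_bm)
        add("brain_blood", "brain_mass", (psb + d.cl_b_out) * u_bm)
        # BCSFB: blood <-> CSF
        add("brain_blood", "brain_blood", -(psc + d.cl_c_in) * u_bb)
        add("csf", "brain_blood", (psc + d.cl_c_in) * u_bb)
        add("csf", "csf", -(psc + d.cl_c_out) * u_csf)
        add("brain_blood", "csf", (psc + d.cl_c_out) * u_csf)
        # CSFBB: mass <-> CSF
        add("brain_mass", "brain_mass", -pse * u_bm)
        add("csf", "brain_mass", pse * u_bm)
        add("csf", "csf", -pse * u_csf)
        add("brain_mass", "csf", pse * u_csf)
        # bulk flow mass -> CSF (unbound), sink flow CSF -> brain blood (total)
        add("brain_mass", "brain_mass", -phys.q_bulk * u_bm)
        add("csf", "brain_mass", phys.q_bulk * u_bm)
        add("csf", "csf", -phys.q_sink / phys.v_csf)
        add("brain_blood", "csf", phys.q_sink / phys.v_csf)
        # brain metabolism on unbound brain mass
        add("brain_mass", "brain_mass", -d.cl_met_brain * u_bm)
        add("eliminated", "brain_mass", d.cl_met_brain * u_bm)
        return m

    # -- integration --------------------------------------------------------
    def simulate(self, output_times=None) -> PBPKResults:
        """Integrate the model and return concentration-time profiles.

        ``output_times`` (h) defaults to a 0.05 h grid over the regimen.
        Dose events restart the integrator with the depot re-incremented by
        Fa x dose.
        """
        reg = self.regimen
        if output_times is None:
            output_times = np.arange(0.0, reg.simulation_end_h + 1e-9, 0.05)
        t_out = np.asarray(output_times, dtype=float)
        if t_out.ndim != 1 or np.any(np.diff(t_out) <= 0):
            raise ValueError("output_times must be strictly increasing 1-D")
        if t_out[0] < 0 or t_out[-1] > reg.simulation_end_h + 1e-9:
            raise ValueError("output_times must lie within [0, simulation_end]")

        ix = self._index
        n = len(ix)
        dose_ng = reg.dose_amount_ng(self.physiology.body_weight_kg) * self.drug.fa
        dose_times = reg.dose_times()

        # integration segments between dose events
        bounds = np.unique(np.concatenate([dose_times, [t_out[-1]]]))
        bounds = bounds[bounds <= t_out[-1] + 1e-12]
        state = np.zeros(n)
        absorbed_offset = 0.0  # total Fa*dose administered so far

        out_states = np.empty((t_out.size, n))
        out_absorbed = np.empty(t_out.size)
        filled = np.zeros(t_out.size, dtype=bool)

        def rhs(t, y):
            return self._matrix @ y

        def jac(t, y):
            return self._matrix

        for k, t0 in enumerate(bounds):
            if np.any(np.isclose(t0, dose_times, atol=1e-9)):
                state[ix["depot"]] += dose_ng
                absorbed_offset += dose_ng
            t1 = bounds[k + 1] if k + 1 < bounds.size else t_out[-1]
            if t1 <= t0:
                # dose exactly at final time; record below
                sel = np.isclose(t_out, t0, atol=1e-9) & ~filled
                out_states[sel] = state
                out_absorbed[sel] = absorbed_offset - state[ix["depot"]]
                filled |= sel
                continue
            sel = (t_out >= t0 - 1e-12) & (t_out <= t1 + 1e-12) & ~filled
            t_eval = t_out[sel]
            # always evaluate segment ends so the state can propagate
            sol = solve_ivp(
                rhs,
                (t0, t1),
                state,
                method="LSODA",
                jac=jac,
                rtol=self.rtol,
                atol=self.atol,
                t_eval=np.unique(np.concatenate([t_eval, [t1]])),
                dense_output=False,
            )
            if not sol.success or not np.all(np.isfinite(sol.y)):
                bad = sol.t[np.argmax(~np.isfinite(sol.y).all(axis=0))] if sol.t.size else t0
                raise IntegrationError(f"integration failed near t = {bad:g} h")
            # map solved columns onto requested output times
            for j, tv in enumerate(sol.t):
                hit = np.isclose(t_out, tv, atol=1e-9) & ~filled
                out_states[hit] = sol.y[:, j]
                out_absorbed[hit] = absorbed_offset - sol.y[ix["depot"], j]
                filled[hit] = True
            state = sol.y[:, -1]

        if not filled.all():  # pragma: no cover - defensive
            raise IntegrationError("some output times were not reached")

        states = pd.DataFrame(out_states, columns=self.compartments)
        profiles = self._profiles(t_out, states)
        eliminated = states["eliminated"].to_numpy()
        res_states = states.drop(columns=["eliminated"])
        res = PBPKResults(
            model=self,
            times_h=t_out,
            states=res_states,
            profiles=profiles,
            absorbed_ng=out_absorbed,
            eliminated_ng=eliminated,
        )
        return res

    def _profiles(self, t_out, states) -> dict[str, ConcentrationTimeProfile]:
        d, phys = self.drug, self.physiology
        c_ven_blood = states["venous"].to_numpy() / phys.v_venous / NG_L_PER_NG_ML
        plasma_total = c_ven_blood / d.blood_plasma_ratio
        c_bb = states["brain_blood"].to_numpy() / phys.v_brain_blood / NG_L_PER_NG_ML
        c_bm = states["brain_mass"].to_numpy() / phys.v_brain_mass / NG_L_PER_NG_ML
        c_csf = states["csf"].to_numpy() / phys.v_csf / NG_L_PER_NG_ML
        ecf = d.fu_brain * c_bm
        values = {
            "plasma_total": plasma_total,
            "plasma_unbound": d.fu_plasma * plasma_total,
            "brain_blood": c_bb,
            "brain_mass": c_bm,
            "brain_ecf": ecf,
            "csf": c_csf,
            "dialysate": self.probe_recovery * ecf,
        }
        return {
            m: ConcentrationTimeProfile(m, t_out, np.clip(values[m], 0.0, None))
            for m in MATRICES
        }
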