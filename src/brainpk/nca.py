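"""Non-compartmental analysis of concentration-time profiles.

Cmax/Tmax read directly off the data, AUC by the linear trapezoidal method
over observed sample times, terminal elimination rate constant (k10) by
log-linear regression over the best-fitting contiguous terminal window,
t1/2 = ln2/k10 and clearance = dose / AUC0-inf.

The estimator follows the usual model/results split: build an :class:`NCA`
from a profile, call :meth:`NCA.fit`, inspect the returned
:class:`NCAResults` (``summary()`` prints a one-profile table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ConcentrationTimeProfile

__all__ = [
    "auc_trapezoid",
    "terminal_slope",
    "NCA",
    "NCAResults",
    "TerminalFitError",
]

LN2 = math.log(2.0)


class TerminalFitError(RuntimeError):
    """No acceptable terminal log-linear fit could be found."""


def auc_trapezoid(
    profile: ConcentrationTimeProfile,
    window: tuple[float, float] | None = None,
) -> float:
    """Linear-trapezoid AUC (h*ng/mL) over ``window`` = (t_start, t_end).

    Window endpoints must coincide with observed sample times — the method
    never interpolates or extrapolates beyond the observed grid.
    """
    t = profile.times_h
    c = profile.conc_ng_ml
    if window is None:
        window = (t[0], t[-1])
    t0, t1 = window
    i0 = np.flatnonzero(np.isclose(t, t0, atol=1e-9))
    i1 = np.flatnonzero(np.isclose(t, t1, atol=1e-9))
    if i0.size == 0 or i1.size == 0:
        raise ValueError(
            f"window endpoints ({t0}, {t1}) must be observed sample times"
        )
    i0, i1 = int(i0[0]), int(i1[0])
    if i1 - i0 < 1:
        raise ValueError("window must contain at least two samples")
    tt, cc = t[i0 : i1 + 1], c[i0 : i1 + 1]
    return float(np.trapezoid(cc, tt))


def terminal_slope(
    profile: ConcentrationTimeProfile,
    min_points: int = 3,
    lloq: float = 0.0,
    start_after_tmax: bool = True,
) -> tuple[float, float, dict]:
    """Terminal k10 (1/h) and t1/2 (h) by log-linear regression.

    Candidate windows are all contiguous runs of >= ``min_points`` positive
    (> lloq) concentrations ending at the last quantifiable sample and
    starting after Tmax; the window with the best adjusted R-squared wins,
    ties broken toward more points.

    Returns ``(k10, t_half, diagnostics)``; raises :class:`TerminalFitError`
    when no window yields a positive, acceptable slope.
    """
    t = profile.times_h
    c = profile.conc_ng_ml
    ok = c > max(lloq, 0.0)
    i_tmax = int(np.argmax(c))
    idx = np.flatnonzero(ok & (np.arange(t.size) > i_tmax))
    if start_after_tmax and idx.size < min_points:
        # fall back to including Tmax itself (mono-exponential decline)
        idx = np.flatnonzero(ok & (np.arange(t.size) >= i_tmax))
    if idx.size < min_points:
        raise TerminalFitError(
            f"need >= {min_points} positive post-Tmax concentrations, have {idx.size}"
        )
    # contiguity in the quantifiable subsequence
    last = idx[-1]
    best = None
    for start_pos in range(idx.size - min_points + 1):
        win = idx[start_pos:]
        if win[-1] != last:
            continue
        x, y = t[win], np.log(c[win])
        n = win.size
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * x + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        cand = (round(adj, 10), n, -slope, r2, win)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        raise TerminalFitError("no terminal window with a declining log-linear fit")
    _, n_used, k10, r2, win = best
    diagnostics = {
        "n_terminal_points": int(n_used),
        "r_squared_terminal": float(r2),
        "adj_r_squared_terminal": float(best[0]),
        "times_used_h": t[win].tolist(),
        "span_half_lives": float((t[win][-1] - t[win][0]) * k10 / LN2),
    }
    return float(k10), float(LN2 / k10), diagnostics


@dataclass
class NCAResults:
    """Non-compartmental parameter estimates for one profile."""

    matrix: str
    cmax: float
    tmax: float
    auc_windows: dict[str, float]
    auc_0_last: float
    k10: float | None = None
    t_half: float | None = None
    auc_0_inf: float | None = None
    cl_per_kg: float | None = None
    dose_mg_per_kg: float | None = None
    diagnostics: dict = field(default_factory=dict)
    terminal_fit_failed: bool = False

    def summary(self) -> pd.DataFrame:
        rows = {
            "Cmax (ng/mL)": self.cmax,
            "Tmax (h)": self.tmax,
            "AUC0-last (h.ng/mL)": self.auc_0_last,
        }
        for k, v in self.auc_windows.items():
            rows[f"AUC{k} (h.ng/mL)"] = v
        rows["k10 (1/h)"] = self.k10
        rows["t1/2 (h)"] = self.t_half
        rows["AUC0-inf (h.ng/mL)"] = self.auc_0_inf
        rows["CL (mL/h/kg)"] = self.cl_per_kg
        return pd.DataFrame({"estimate": rows})

    def __repr__(self) -> str:  # pragma: no cover
        th = f"{self.t_half:.3g}" if self.t_half else "n/a"
        return f"NCAResults({self.matrix}, Cmax={self.cmax:.4g}, t1/2={th} h)"


class NCA:
    """Non-compartmental analysis of one concentration-time profile.

    Parameters
    ----------
    profile
        Observed or simulated profile; the pre-dose time is fixed to zero.
    dose_mg_per_kg
        Nominal dose per kg; enables the per-kg clearance estimate
        (CL = dose / AUC0-inf).
    lloq
        Values at or below this are excluded from the terminal fit.
    windows
        AUC windows as (start, end) pairs; endpoints must be sampled times.
    """

    def __init__(
        self,
        profile: ConcentrationTimeProfile,
        dose_mg_per_kg: float | None = None,
        lloq: float = 0.0,
        windows: tuple[tuple[float, float], ...] = (),
    ):
        if np.all(profile.conc_ng_ml == 0):
            raise ValueError("profile has no measurable exposure (all zero)")
        self.profile = profile
        self.dose_mg_per_kg = dose_mg_per_kg
        self.lloq = lloq
        self.windows = tuple(windows)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, matrix: str = "plasma_total", **kwargs
    ) -> "NCA":
        """Build from a tidy frame with columns matrix, time_h, conc_ng_per_ml.

        Censored (BLQ) records — flagged by a ``censored`` column or carrying
        a missing concentration — are dropped.
        """
        sub = df[df["matrix"] == matrix]
        if "censored" in sub.columns:
            sub = sub[~sub["censored"].astype(bool)]
        sub = sub.dropna(subset=["conc_ng_per_ml"]).sort_values("time_h")
        if sub.empty:
            raise ValueError(f"no quantifiable rows for matrix {matrix!r}")
        prof = ConcentrationTimeProfile(
            matrix, sub["time_h"].to_numpy(), sub["conc_ng_per_ml"].to_numpy()
        )
        return cls(prof, **kwargs)

    def fit(self, min_terminal_points: int = 3) -> NCAResults:
        p = self.profile
        i_max = int(np.argmax(p.conc_ng_ml))
        cmax = float(p.conc_ng_ml[i_max])
        tmax = float(p.times_h[i_max])
        auc_last = auc_trapezoid(p)
        aucs = {
            f"{int(a)}-{int(b)}" if float(a).is_integer() and float(b).is_integer()
            else f"{a}-{b}": auc_trapezoid(p, (a, b))
            for a, b in self.windows
        }
        res = NCAResults(
            matrix=p.matrix,
            cmax=cmax,
            tmax=tmax,
            auc_windows=aucs,
            auc_0_last=auc_last,
            dose_mg_per_kg=self.dose_mg_per_kg,
        )
        try:
            k10, t_half, diag = terminal_slope(p, min_terminal_points, self.lloq)
        except TerminalFitError as err:
            res.terminal_fit_failed = True
            res.diagnostics["terminal_fit_error"] = str(err)
            return res
        res.k10, res.t_half, res.diagnostics = k10, t_half, diag
        c_last = p.conc_ng_ml[p.conc_ng_ml > max(self.lloq, 0.0)][-1]
        res.auc_0_inf = auc_last + float(c_last) / k10
        res.diagnostics["auc_0_last"] = auc_last
        if self.dose_mg_per_kg:
            # dose in ng/kg over AUC in h*ng/mL -> mL/h/kg
            res.cl_per_kg = self.dose_mg_per_kg * 1e6 / res.auc_0_inf
        return res
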