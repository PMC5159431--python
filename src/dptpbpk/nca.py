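"""Non-compartmental analysis (NCA) of concentration–time profiles.

Implements the standard i.v.-bolus NCA estimands: the trapezoidal
``AUC_0-tn``, the terminal slope ``lambda_z`` chosen by best adjusted R^2
over trailing log-linear windows, the extrapolated ``AUC_0-inf``,
``MRT = AUMC/AUC`` with the usual tail corrections, and the derived
``CL = dose/AUC_0-inf``, ``Vss = CL * MRT`` and ``t_1/2 = ln2/lambda_z``.

Also provides the fold-error accuracy metric used to judge model
predictions: ``max(obs/pred, pred/obs)``, with < 2 the conventional
success threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConcentrationProfile

__all__ = ["NcaResult", "auc_trapezoid", "lambda_z", "nca", "fold_error"]


@dataclass(frozen=True)
class NcaResult:
    """Bundle of non-compartmental parameters for one profile.

    Areas are ug*min/mL; ``cl`` is mL/min (``cl_per_kg`` mL/min/kg);
    ``vss`` is L (``vss_per_kg`` L/kg); times are minutes.
    """

    auc_0_tn: float
    auc_0_inf: float
    cl: float
    cl_per_kg: float
    vss: float
    vss_per_kg: float
    mrt: float
    t_half: float
    lambda_z: float
    n_lambda_points: int
    adj_r2: float
    dose: float
    weight: float
    flags: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        rows = [
            ("AUC_0-tn", self.auc_0_tn, "ug*min/mL"),
            ("AUC_0-inf", self.auc_0_inf, "ug*min/mL"),
            ("CL", self.cl, "mL/min"),
            ("CL/kg", self.cl_per_kg, "mL/min/kg"),
            ("Vss", self.vss, "L"),
            ("Vss/kg", self.vss_per_kg, "L/kg"),
            ("MRT", self.mrt, "min"),
            ("t_1/2", self.t_half, "min"),
            ("lambda_z", self.lambda_z, "1/min"),
            ("n_lambda_points", self.n_lambda_points, ""),
            ("adj_r2", self.adj_r2, ""),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value", "units"])


def auc_trapezoid(profile: ConcentrationProfile, t_end: float | None = None) -> float:
    """Linear-trapezoid area from the first observation to ``t_end``."""

    if len(profile) < 2:
        raise ValueError("at least two points are required for an AUC")
    t_end = profile.times[-1] if t_end is None else t_end
    if t_end > profile.times[-1]:
        raise ValueError("t_end beyond the last observation")
    t, c = profile.times, profile.values
    mask = t <= t_end
    area = float(np.trapezoid(c[mask], t[mask]))
    # partial last interval if t_end falls between samples
    j = mask.sum()
    if j < t.size and t_end > t[j - 1]:
        c_end = np.interp(t_end, t, c)
        area += 0.5 * (c[j - 1] + c_end) * (t_end - t[j - 1])
    return area


def _loglinear_fit(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """OLS of log-concentration on time: (slope, intercept, adjusted R^2)."""
    n = t.size
    slope, intercept = np.polyfit(t, logc, 1)
    resid = logc - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, intercept, adj


def lambda_z(
    profile: ConcentrationProfile, min_points: int = 3
) -> tuple[float, int, float]:
    """Terminal elimination rate constant by best-fit window selection.

    Considers every trailing window of at least ``min_points`` positive
    concentrations that starts after the global maximum (C_max itself is
    excluded), fits log-linear OLS, and keeps the window with the highest
    adjusted R^2; near-ties (within 1e-4) are resolved toward more points.

    Returns ``(lambda_z, n_points, adj_r2)``; ``lambda_z`` is positive for
    a declining terminal phase.
    """

    t, c = profile.times, profile.values
    pos = c > 0
    if pos.sum() < min_points:
        raise ValueError("need at least three positive terminal concentrations")
    imax = int(np.argmax(c))
    first_start = imax + 1
    if first_start > t.size - min_points:
        # too few observations after C_max (e.g. exactly three declining
        # points): allow the window to include it
        first_start = imax
    best: tuple[float, int, float] | None = None
    for start in range(first_start, t.size - min_points + 1):
        sel = pos[start:]
        tt, cc = t[start:][sel], c[start:][sel]
        if tt.size < min_points:
            continue
        slope, _, adj = _loglinear_fit(tt, np.log(cc))
        if slope >= 0:
            continue
        if (
            best is None
            or adj > best[2] + 1e-4
            or (adj >= best[2] - 1e-4 and tt.size > best[1])
        ):
            best = (-slope, tt.size, adj)
    if best is None:
        raise ValueError("terminal phase not estimable (no declining window)")
    return best


def _with_bolus_c0(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Prepend a back-extrapolated time-zero concentration.

    The standard i.v.-bolus convention: C0 is the log-linear extrapolation
    of the first two positive observations back to the dose time; if the
    profile starts rising, the first observed value is carried back
    instead. A profile already starting at t = 0 is returned unchanged.
    """

    t, c = profile.times, profile.values
    if t[0] <= 0:
        return profile
    if c[0] > 0 and c[1] > 0 and c[1] < c[0]:
        slope = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
        c0 = math.exp(math.log(c[0]) - slope * t[0])
    else:
        c0 = c[0]
    return ConcentrationProfile(
        np.insert(t, 0, 0.0), np.insert(c, 0, c0), profile.matrix,
        profile.species, profile.dose, dict(profile.meta),
    )


def nca(
    profile: ConcentrationProfile,
    dose: float | None = None,
    weight: float = 1.0,
    *,
    min_points: int = 3,
    bolus_c0: bool = True,
) -> NcaResult:
    """Full non-compartmental analysis of an i.v.-bolus profile.

    ``dose`` is the absolute dose in ug (falls back to the profile's dose
    context); ``weight`` in kg yields the per-kg clearance and volume.
    With ``bolus_c0`` (the default, the usual i.v.-bolus convention) a
    profile starting after the dose time is extended back to t = 0 with a
    log-linearly extrapolated C0 before the areas are computed.
    If the terminal slope cannot be estimated the AUC_0-tn is still
    reported, with NaNs and an explanatory flag elsewhere.
    """

    dose = profile.dose if dose is None else dose
    if dose is None or dose <= 0:
        raise ValueError("a positive dose is required")
    if weight <= 0:
        raise ValueError("weight must be > 0")

    if bolus_c0:
        profile = _with_bolus_c0(profile)
    auc_tn = auc_trapezoid(profile)
    t, c = profile.times, profile.values
    pos = np.nonzero(c > 0)[0]
    flags: list[str] = []
    try:
        lz, n_pts, adj = lambda_z(profile, min_points=min_points)
    except ValueError as err:
        flags.append(str(err))
        nan = float("nan")
        return NcaResult(
            auc_tn, nan, nan, nan, nan, nan, nan, nan, nan, 0, nan,
            dose, weight, tuple(flags),
        )

    c_last, t_last = c[pos[-1]], t[pos[-1]]
    auc_inf = auc_tn + c_last / lz
    aumc_tn = float(np.trapezoid(t * c, t))
    aumc_inf = aumc_tn + c_last * t_last / lz + c_last / lz**2
    mrt = aumc_inf / auc_inf
    cl = dose / auc_inf  # mL/min
    vss = cl * mrt / 1000.0  # L
    return NcaResult(
        auc_0_tn=auc_tn,
        auc_0_inf=auc_inf,
        cl=cl,
        cl_per_kg=cl / weight,
        vss=vss,
        vss_per_kg=vss / weight,
        mrt=mrt,
        t_half=math.log(2) / lz,
        lambda_z=lz,
        n_lambda_points=n_pts,
        adj_r2=adj,
        dose=dose,
        weight=weight,
        flags=tuple(flags),
    )


def fold_error(observed: float, predicted: float) -> float:
    """Prediction accuracy: the larger of obs/pred and pred/obs (>= 1)."""

    if observed <= 0 or predicted <= 0:
        raise ValueError("fold-error requires positive values")
    return max(observed / predicted, predicted / observed)
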