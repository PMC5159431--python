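"""Interspecies allometric scaling and Dedrick species-invariant-time plots.

Clearance and steady-state volume scale across species as power laws of
body weight, ``CL = a2 * W**b2`` and ``Vss = a1 * W**b1``, fitted by
unweighted least squares after log10/log10 transformation. The Dedrick
construction superimposes the animal concentration–time curves by plotting
normalized concentration ``C' = C / (D / W**b1)`` against physiological
time ``t' = t / W**(b1 - b2)``; the pooled curve is fitted to a
two-compartment (biexponential) macro-model ``A'e^{-a't'} + B'e^{-b't'}``
and mapped back to a human curve by the inverse transformation. Closed
forms then give AUC, CL, MRT, Vss and the terminal half-life from the
macro-constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AllometricFit",
    "DedrickModel",
    "fit_power_law",
    "dedrick_transform",
    "fit_biexponential",
    "reverse_transform",
    "pk_from_biexponential",
]


@dataclass(frozen=True)
class AllometricFit:
    """Power-law fit value = alpha * W**beta on log10–log10 scale."""

    alpha: float
    beta: float
    r2: float
    points: tuple[tuple[float, float], ...]

    def predict(self, weight: float) -> float:
        return self.alpha * weight**self.beta


def fit_power_law(points: Sequence[tuple[float, float]]) -> AllometricFit:
    """Unweighted OLS of log10(value) on log10(weight).

    ``points`` are (body weight kg, parameter value) pairs; at least two,
    all positive.
    """

    pts = [(float(w), float(v)) for w, v in points]
    if len(pts) < 2:
        raise ValueError("at least two (weight, value) points are required")
    if any(w <= 0 or v <= 0 for w, v in pts):
        raise ValueError("weights and values must be > 0")
    lw = np.log10([w for w, _ in pts])
    lv = np.log10([v for _, v in pts])
    beta, intercept = np.polyfit(lw, lv, 1)
    pred = beta * lw + intercept
    ss_res = float(np.sum((lv - pred) ** 2))
    ss_tot = float(np.sum((lv - lv.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AllometricFit(10.0**intercept, float(beta), r2, tuple(pts))


@dataclass(frozen=True)
class DedrickModel:
    """Biexponential macro-constants on the Dedrick (t', C') scale.

    ``a_prime``/``b_prime`` are intercepts of the fast and slow phases in
    normalized-concentration units, ``alpha_prime > beta_prime`` the rate
    constants per unit physiological time, and ``beta1``/``beta2`` the
    allometric exponents (Vss and CL) that define the transformation.
    """

    a_prime: float
    alpha_prime: float
    b_prime: float
    beta_prime: float
    beta1: float
    beta2: float
    rss: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.a_prime <= 0 or self.b_prime < 0:
            raise ValueError("intercepts must be positive")
        if not self.degenerate and not self.alpha_prime > self.beta_prime > 0:
            raise ValueError("rate constants must satisfy alpha' > beta' > 0")

    def predict(self, t_prime) -> np.ndarray:
        t_prime = np.asarray(t_prime, dtype=float)
        return self.a_prime * np.exp(-self.alpha_prime * t_prime) + self.b_prime * np.exp(
            -self.beta_prime * t_prime
        )


def dedrick_transform(
    times,
    concentrations,
    weight: float,
    dose: float,
    beta1: float,
    beta2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a concentration–time curve onto the species-invariant scale.

    ``t' = t / W**(beta1-beta2)`` and ``C' = C / (D / W**beta1)`` with the
    absolute dose ``D`` in mg and ``W`` in kg.
    """

    if weight <= 0 or dose <= 0:
        raise ValueError("weight and dose must be > 0")
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    t_prime = t / weight ** (beta1 - beta2)
    c_prime = c / (dose / weight**beta1)
    return t_prime, c_prime


def fit_biexponential(
    t_prime,
    c_prime,
    beta1: float = float("nan"),
    beta2: float = float("nan"),
    n_starts: int = 8,
) -> DedrickModel:
    """Least-squares biexponential fit with curve-stripping multi-starts.

    Fits ``A'e^{-a't'} + B'e^{-b't'}`` on the untransformed concentrations,
    orders the phases so that ``alpha' > beta'``, and flags a degenerate
    fit (vanishing slow phase or indistinguishable rates) instead of
    failing on effectively mono-exponential input.
    """

    t = np.asarray(t_prime, dtype=float)
    c = np.asarray(c_prime, dtype=float)
    if t.size < 5:
        raise ValueError("at least five points spanning both phases are required")
    if np.any(c <= 0):
        keep = c > 0
        t, c = t[keep], c[keep]
        if t.size < 5:
            raise ValueError("too few positive concentrations")

    # curve stripping: terminal slope from the last third, fast phase from
    # the residual of the first third
    order = np.argsort(t)
    t, c = t[order], c[order]
    n = t.size
    tail = slice(max(n - max(3, n // 3), 2), n)
    slope_tail, icpt_tail = np.polyfit(t[tail], np.log(c[tail]), 1)
    b0 = max(-slope_tail, 1e-6)
    bcoef0 = math.exp(icpt_tail)
    resid0 = c - bcoef0 * np.exp(-b0 * t)
    head = resid0[: max(3, n // 3)] > 0
    if head.sum() >= 2:
        th = t[: max(3, n // 3)][head]
        ch = resid0[: max(3, n // 3)][head]
        slope_head, icpt_head = np.polyfit(th, np.log(ch), 1)
        a0, acoef0 = max(-slope_head, 10 * b0), math.exp(icpt_head)
    else:
        a0, acoef0 = 10 * b0, float(c.max())

    def residuals(log_theta: np.ndarray) -> np.ndarray:
        # clip optimizer excursions so exp stays finite
        a, al, b, be = np.exp(np.clip(log_theta, -600.0, 600.0))
        with np.errstate(over="ignore"):
            return a * np.exp(-al * t) + b * np.exp(-be * t) - c

    best = None
    for fac in np.geomspace(0.2, 5.0, n_starts):
        theta0 = np.log([acoef0, a0 * fac, bcoef0, b0])
        try:
            res = least_squares(residuals, theta0, method="lm", max_nfev=20000)
        except Exception:
            continue
        rss = float(res.fun @ res.fun)
        if res.success and (best is None or rss < best[0] - 1e-15):
            best = (rss, res)
    if best is None:
        raise RuntimeError("biexponential fit did not converge from any start")
    rss, res = best
    acoef, a, bcoef, b = np.exp(res.x)
    if a < b:
        acoef, a, bcoef, b = bcoef, b, acoef, a
    degenerate = min(acoef, bcoef) < 1e-6 * max(acoef, bcoef) or a / b < 1.05
    return DedrickModel(
        a_prime=float(acoef),
        alpha_prime=float(a),
        b_prime=float(bcoef),
        beta_prime=float(b),
        beta1=beta1,
        beta2=beta2,
        rss=rss,
        degenerate=degenerate,
    )


def reverse_transform(
    model: DedrickModel, weight: float, dose: float
) -> tuple[float, float, float, float]:
    """Back-transform Dedrick macro-constants to a real species curve.

    Returns ``(A, alpha, B, beta)`` of ``C = A e^{-alpha t} + B e^{-beta t}``
    with ``A = A' * dose / W**beta1`` and ``alpha = alpha' / W**(beta1-beta2)``
    (``dose`` in mg, ``W`` in kg, concentrations in ug/mL, rates 1/min).
    """

    if weight <= 0 or dose <= 0:
        raise ValueError("weight and dose must be > 0")
    scale_c = dose / weight**model.beta1
    scale_t = weight ** (model.beta1 - model.beta2)
    return (
        model.a_prime * scale_c,
        model.alpha_prime / scale_t,
        model.b_prime * scale_c,
        model.beta_prime / scale_t,
    )


def pk_from_biexponential(
    a: float, alpha: float, b: float, beta: float, dose: float
) -> dict[str, float]:
    """Closed-form PK parameters from biexponential macro-constants.

    ``dose`` in ug with ``a, b`` in ug/mL gives CL in mL/min and Vss in L:
    AUC = A/alpha + B/beta, MRT = (A/alpha^2 + B/beta^2)/AUC,
    CL = dose/AUC, Vss = CL*MRT, t_1/2 = ln2/beta. ``b = 0`` is accepted
    as the mono-exponential limit.
    """

    if a <= 0 or alpha <= 0 or b < 0 or (b > 0 and beta <= 0) or dose <= 0:
        raise ValueError("macro-constants and dose must be positive")
    if b > 0 and alpha <= beta:
        raise ValueError("macro-constants must satisfy alpha > beta")
    auc = a / alpha + (b / beta if b > 0 else 0.0)
    aumc = a / alpha**2 + (b / beta**2 if b > 0 else 0.0)
    mrt = aumc / auc
    cl = dose / auc
    terminal = beta if b > 0 else alpha
    return {
        "auc_0_inf": auc,
        "cl": cl,
        "mrt": mrt,
        "vss": cl * mrt / 1000.0,
        "t_half": math.log(2) / terminal,
    }
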