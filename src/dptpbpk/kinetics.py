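"""Microsomal enzyme-kinetic fitting and protein-binding arithmetic.

The M2 pathway follows classical Michaelis–Menten kinetics (one enzyme in
mouse, rat and human; two in monkey and dog), while M7 formation shows
auto-activation and is described by a Hill equation. The Eadie–Hofstee
transform (v against v/S) is the standard diagnostic: a straight line of
slope -Km for hyperbolic kinetics, a "hook" when the Hill coefficient
exceeds one.

Fitting is unweighted nonlinear least squares on the untransformed
velocities with a deterministic log-spaced multi-start, the convention of
mainstream enzyme-kinetics software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "RateDataset",
    "KineticModelFit",
    "MODEL_NAMES",
    "fit_kinetics",
    "eadie_hofstee",
    "unbound_fraction",
    "mm_velocity",
    "dual_mm_velocity",
    "hill_velocity",
]

MODEL_NAMES = ("mm", "dual_mm", "hill")


@dataclass(frozen=True)
class RateDataset:
    """Replicate-resolved rate-versus-substrate measurements.

    ``substrate`` in uM, ``velocity`` in the assay's rate unit
    (nmol/min/mg microsomal protein for M2, pmol/min/mg for M7).
    """

    substrate: np.ndarray
    velocity: np.ndarray
    protein_conc: float | None = None  # mg/mL
    incubation_time: float | None = None  # min
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("substrate and velocity must be equal-length 1-D")
        if np.any(s <= 0):
            raise ValueError("substrate concentrations must be > 0")
        object.__setattr__(self, "substrate", s)
        object.__setattr__(self, "velocity", v)

    def __len__(self) -> int:
        return self.substrate.size

    @property
    def n_levels(self) -> int:
        return np.unique(self.substrate).size


def mm_velocity(s, km, vmax):
    """Michaelis–Menten rate v = Vmax*S/(Km+S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def dual_mm_velocity(s, km1, vmax1, km2, vmax2):
    """Sum of two independent Michaelis–Menten enzymes."""
    return mm_velocity(s, km1, vmax1) + mm_velocity(s, km2, vmax2)


def hill_velocity(s, km, vmax, gamma):
    """Hill rate v = Vmax*S^g/(Km^g+S^g); reduces to MM at g = 1."""
    s = np.asarray(s, dtype=float)
    # evaluate as a logistic in log space: robust to extreme gamma during
    # optimizer excursions
    with np.errstate(over="ignore"):
        ratio = np.exp(np.clip(gamma * (np.log(km) - np.log(s)), -700, 700))
    return vmax / (1.0 + ratio)


_MODEL_FUNCS: dict[str, tuple[Callable, tuple[str, ...]]] = {
    "mm": (mm_velocity, ("km", "vmax")),
    "dual_mm": (dual_mm_velocity, ("km1", "vmax1", "km2", "vmax2")),
    "hill": (hill_velocity, ("km", "vmax", "gamma")),
}


@dataclass(frozen=True)
class KineticModelFit:
    """Fitted enzyme-kinetic parameters with standard errors and RSS."""

    model: str
    params: dict[str, float]
    bse: dict[str, float]
    rss: float
    n_obs: int
    data: RateDataset

    @property
    def aicc(self) -> float:
        """Corrected AIC from the Gaussian least-squares likelihood."""
        k = len(self.params) + 1  # + residual variance
        n = self.n_obs
        aic = n * math.log(self.rss / n) + 2 * k
        if n - k - 1 <= 0:
            return float("inf")
        return aic + 2 * k * (k + 1) / (n - k - 1)

    def predict(self, s) -> np.ndarray:
        func, names = _MODEL_FUNCS[self.model]
        return func(np.asarray(s, dtype=float), *(self.params[n] for n in names))

    def summary(self) -> pd.DataFrame:
        rows = [
            (name, self.params[name], self.bse.get(name, float("nan")))
            for name in self.params
        ]
        out = pd.DataFrame(rows, columns=["parameter", "estimate", "std_err"])
        out.attrs["model"] = self.model
        out.attrs["rss"] = self.rss
        out.attrs["aicc"] = self.aicc
        return out


def _multistart_grid(data: RateDataset, model: str, n_starts: int) -> list[np.ndarray]:
    s, v = data.substrate, data.velocity
    vmax0 = max(float(v.max()), 1e-9)
    km_lo, km_hi = float(s.min()) / 3.0, float(s.max()) * 3.0
    kms = np.geomspace(km_lo, km_hi, n_starts)
    starts = []
    for km in kms:
        if model == "mm":
            starts.append(np.array([km, vmax0]))
        elif model == "hill":
            starts.append(np.array([km, vmax0, 1.5]))
        else:
            starts.append(np.array([km, 0.7 * vmax0, km * 10.0, 0.3 * vmax0]))
    return starts


def fit_kinetics(
    data: RateDataset,
    model: str = "mm",
    starts: Sequence[Sequence[float]] | None = None,
    n_starts: int = 10,
) -> KineticModelFit:
    """Fit a velocity model by multi-start nonlinear least squares.

    Requires at least 5 distinct substrate levels (7 for the two-enzyme
    model). Parameters are optimized on a log scale to enforce positivity;
    the fit with the lowest residual sum of squares wins. Standard errors
    come from the Gauss–Newton approximation at the optimum.
    """

    if model not in MODEL_NAMES:
        raise ValueError(f"model must be one of {MODEL_NAMES}")
    min_levels = 7 if model == "dual_mm" else 5
    if data.n_levels < min_levels:
        raise ValueError(
            f"{model} fit needs >= {min_levels} distinct substrate levels"
        )
    func, names = _MODEL_FUNCS[model]
    s, v = data.substrate, data.velocity

    def residuals(log_theta: np.ndarray) -> np.ndarray:
        return func(s, *np.exp(np.clip(log_theta, -600.0, 600.0))) - v

    start_list = (
        [np.asarray(x, dtype=float) for x in starts]
        if starts is not None
        else _multistart_grid(data, model, n_starts)
    )
    best = None
    for theta0 in start_list:
        if np.any(theta0 <= 0):
            raise ValueError("start values must be positive")
        try:
            res = least_squares(
                residuals, np.log(theta0), method="lm", max_nfev=20000
            )
        except Exception:
            continue
        rss = float(res.fun @ res.fun)
        if res.success and (best is None or rss < best[0] - 1e-14):
            best = (rss, res)
    if best is None:
        raise RuntimeError(f"{model} fit did not converge from any start")
    rss, res = best
    theta = np.exp(res.x)
    if model == "dual_mm" and theta[0] > theta[2]:
        theta = theta[[2, 3, 0, 1]]  # order enzymes by ascending Km

    # delta-method SEs on the natural scale
    n, k = v.size, theta.size
    dof = max(n - k, 1)
    sigma2 = rss / dof
    jac = res.jac  # d r / d log theta
    try:
        cov_log = sigma2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov_log), 0, None)) * theta
    except np.linalg.LinAlgError:
        se = np.full(k, float("nan"))
    return KineticModelFit(
        model=model,
        params=dict(zip(names, map(float, theta))),
        bse=dict(zip(names, map(float, se))),
        rss=rss,
        n_obs=n,
        data=data,
    )


def eadie_hofstee(data: RateDataset) -> np.ndarray:
    """Eadie–Hofstee transform: array of (v, v/S) pairs.

    For Michaelis–Menten data the pairs fall on a line of slope -Km;
    sigmoidal (Hill, gamma > 1) kinetics bend into the diagnostic hook.
    """

    return np.column_stack([data.velocity, data.velocity / data.substrate])


def unbound_fraction(c_buffer: float, c_plasma: float) -> tuple[float, float]:
    """Equilibrium-dialysis unbound fraction and bound percentage.

    ``fu = C_buffer / C_plasma``; returns ``(fu, 100*(1-fu))``.
    """

    if c_buffer <= 0 or c_plasma <= 0:
        raise ValueError("concentrations must be > 0")
    if c_buffer > c_plasma:
        raise ValueError("buffer concentration exceeds plasma: non-physical equilibrium")
    fu = c_buffer / c_plasma
    return fu, 100.0 * (1.0 - fu)
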