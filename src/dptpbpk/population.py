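"""Population simulation and visual-predictive-check (VPC) percentiles.

Inter-individual variability enters through exponential random effects on
two physiological quantities — the total liver inflow (hepatic artery, gut
and spleen flows scaled jointly) and the metabolic maximum velocities
(all Vmax jointly) — so each virtual subject i has

    Q_liver,i = Q_liver * exp(eta_1i),   Vmax,i = Vmax * exp(eta_2i),

with eta ~ N(0, omega^2). Observations add a multiplicative residual,
C_obs = C_pred * (1 + eps), eps ~ N(0, sigma^2), truncated so that
concentrations stay non-negative. The VPC summarizes many such replicates
by the 5th/50th/95th percentiles at each scheduled sampling time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DoseEvent, PbpkModel, SimulationSettings
from .species import SpeciesProfile

__all__ = ["PopulationSpec", "VpcBands", "simulate_population", "vpc_bands"]


@dataclass(frozen=True)
class PopulationSpec:
    """Variability specification for a virtual population.

    ``omega_qhep``/``omega_vmax`` are standard deviations of the
    exponential-scale random effects; ``sigma`` is the residual SD.
    The defaults (0.2, 0.3 and 0.15) are package choices of a realistic
    pharmacokinetic spread, not estimated values.
    """

    omega_qhep: float = 0.2
    omega_vmax: float = 0.3
    sigma: float = 0.15
    n_subjects: int = 6
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.omega_qhep, self.omega_vmax, self.sigma) < 0:
            raise ValueError("variability SDs must be >= 0")
        if self.n_subjects < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")


def simulate_population(
    profile: SpeciesProfile,
    dose: DoseEvent,
    spec: PopulationSpec,
    schedule: np.ndarray,
    *,
    n_replicates: int | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> pd.DataFrame:
    """Simulate ``n_replicates`` virtual trials of ``n_subjects`` each.

    Returns a tidy table with columns replicate, subject, time_min,
    conc_pred_ug_ml (individual model prediction) and conc_ug_ml (with
    residual error). Reproducible for a given ``spec.seed``.
    """

    schedule = np.asarray(schedule, dtype=float)
    if schedule.ndim != 1 or np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be strictly increasing")
    n_rep = spec.n_replicates if n_replicates is None else n_replicates
    rng = np.random.default_rng(spec.seed)
    settings = SimulationSettings(
        t_end=float(schedule[-1]), grid=schedule, rtol=rtol, atol=atol
    )
    rows = []
    for rep in range(n_rep):
        for subj in range(spec.n_subjects):
            eta1 = rng.normal(0.0, spec.omega_qhep) if spec.omega_qhep else 0.0
            eta2 = rng.normal(0.0, spec.omega_vmax) if spec.omega_vmax else 0.0
            indiv = profile.with_scaled(
                liver_flow_factor=float(np.exp(eta1)),
                vmax_factor=float(np.exp(eta2)),
            )
            result = PbpkModel(indiv).simulate(dose, settings)
            pred = result.concentration("plasma")
            eps = rng.normal(0.0, spec.sigma, size=pred.size) if spec.sigma else 0.0
            obs = np.maximum(pred * (1.0 + eps), 0.0)
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "subject": subj,
                        "time_min": schedule,
                        "conc_pred_ug_ml": pred,
                        "conc_ug_ml": obs,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class VpcBands:
    """5th/50th/95th percentile bands of simulated concentrations."""

    times: np.ndarray
    p5: np.ndarray
    p50: np.ndarray
    p95: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "p5", "p50", "p95"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if not (self.times.size == self.p5.size == self.p50.size == self.p95.size):
            raise ValueError("band arrays must share the schedule length")
        if np.any(self.p5 > self.p50 + 1e-12) or np.any(self.p50 > self.p95 + 1e-12):
            raise ValueError("percentile bands must be ordered p5 <= p50 <= p95")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times, "p5": self.p5, "p50": self.p50, "p95": self.p95}
        )

    def plot(self, ax=None, observed: pd.DataFrame | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.p50, "-", label="median")
        ax.plot(self.times, self.p5, "--", label="5th/95th percentile")
        ax.plot(self.times, self.p95, "--", color=ax.lines[-1].get_color())
        if observed is not None:
            ax.plot(
                observed["time_min"], observed["conc_ug_ml"], "o", ms=3,
                label="observed",
            )
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (ug/mL)")
        ax.set_yscale("log")
        ax.legend()
        return ax


def vpc_bands(simulations: pd.DataFrame) -> VpcBands:
    """Empirical percentile bands across all simulated observations.

    ``simulations`` is the output of :func:`simulate_population`; every
    subject must share the same sampling schedule.
    """

    if simulations["replicate"].nunique() * simulations["subject"].nunique() < 2:
        raise ValueError("at least two simulated subjects are required")
    simulations = simulations.sort_values(["replicate", "subject", "time_min"])
    counts = simulations.groupby(["replicate", "subject"])["time_min"].apply(tuple)
    if counts.nunique() != 1:
        raise ValueError("mismatched sampling schedules across subjects")
    g = simulations.groupby("time_min")["conc_ug_ml"]
    q = g.quantile([0.05, 0.50, 0.95]).unstack()
    return VpcBands(q.index.values, q[0.05].values, q[0.50].values, q[0.95].values)
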