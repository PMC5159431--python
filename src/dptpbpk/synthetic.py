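"""Synthetic in vivo studies and microsomal datasets.

The raw animal concentration–time records behind the DPT studies are not
public; this module regenerates data with the same structure so the whole
pipeline can be exercised and validated end to end. Virtual studies come
from the population PBPK simulator (log-normal inter-individual
variability on liver blood flow and metabolic velocity, multiplicative
residual error); serial designs sample every animal at every time, while
destructive designs (the mouse study) sacrifice a cohort per time point.
Rate-versus-substrate tables add proportional Gaussian noise to an exact
kinetic model over the assayed substrate range (0.0785–3.77 uM).

``fit_ps`` re-enacts the estimation of the brain permeability–surface-area
product: with every other parameter fixed, PS is fitted by least squares
to whole-brain concentrations (the volume-weighted mix of the vascular and
extravascular sub-compartments, as tissue homogenates measure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .kinetics import RateDataset, dual_mm_velocity, hill_velocity, mm_velocity
from .model import DoseEvent, PbpkModel, SimulationSettings
from .population import PopulationSpec, simulate_population
from .species import SpeciesProfile

__all__ = ["StudyDesign", "generate_study", "generate_rate_data", "fit_ps"]

from .io import OBSERVED_SCHEDULES as STUDY_SCHEDULES

#: Substrate levels (uM) of the M7 microsomal assay.
M7_SUBSTRATE_LEVELS = (0.0785, 0.157, 0.314, 0.471, 0.943, 1.885, 2.828, 3.77)


@dataclass(frozen=True)
class StudyDesign:
    """A virtual single-dose i.v. study.

    ``design`` is "serial" (every animal sampled at every time) or
    "destructive" (``n_per_time`` animals sacrificed per time point, one
    observation each — the mouse design).
    """

    species: str
    dose_mg_per_kg: float
    schedule: tuple[float, ...] | None = None
    n_animals: int = 6
    n_per_time: int = 6
    design: str = "serial"
    omega_qhep: float = 0.2
    omega_vmax: float = 0.3
    sigma: float = 0.1
    seed: int = 0
    tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.design not in ("serial", "destructive"):
            raise ValueError("design must be 'serial' or 'destructive'")
        if self.dose_mg_per_kg <= 0:
            raise ValueError("dose must be > 0")
        if self.n_animals < 1 or self.n_per_time < 1:
            raise ValueError("animal counts must be >= 1")
        if self.schedule is None:
            object.__setattr__(
                self, "schedule", STUDY_SCHEDULES[self.species]
            )
        if np.any(np.diff(self.schedule) <= 0):
            raise ValueError("schedule must be strictly increasing")


def generate_study(design: StudyDesign, profile: SpeciesProfile | None = None) -> pd.DataFrame:
    """Simulate one virtual study; columns animal_id, time_min, matrix,
    conc_ug_ml (plus tissue rows when requested).

    Destructive designs emit one plasma row per animal (``n_per_time`` per
    scheduled time); serial designs emit the full grid per animal. Output
    carries the seed in ``DataFrame.attrs``.
    """

    from .species import load_builtin_profile

    profile = profile or load_builtin_profile(design.species)
    dose = DoseEvent.per_kg(design.dose_mg_per_kg, profile.body_weight)
    schedule = np.asarray(design.schedule, dtype=float)
    n_subjects = (
        design.n_per_time * len(schedule)
        if design.design == "destructive"
        else design.n_animals
    )
    spec = PopulationSpec(
        omega_qhep=design.omega_qhep,
        omega_vmax=design.omega_vmax,
        sigma=design.sigma,
        n_subjects=n_subjects,
        n_replicates=1,
        seed=design.seed,
    )
    sims = simulate_population(profile, dose, spec, schedule)

    if design.design == "destructive":
        # animal (i, j) is sacrificed at schedule[i]: keep one row each
        rows = []
        for i, t in enumerate(schedule):
            for j in range(design.n_per_time):
                subj = i * design.n_per_time + j
                row = sims[(sims["subject"] == subj) & (sims["time_min"] == t)]
                rows.append(row)
        out = pd.concat(rows, ignore_index=True)
    else:
        out = sims
    out = out.rename(columns={"subject": "animal_id"})[
        ["animal_id", "time_min", "conc_ug_ml"]
    ].assign(matrix="plasma")

    if design.tissues:
        # tissue concentrations from the typical-animal simulation with the
        # same residual error model (homogenized whole-tissue values)
        rng = np.random.default_rng(design.seed + 1)
        settings = SimulationSettings(t_end=float(schedule[-1]), grid=schedule)
        result = PbpkModel(profile).simulate(dose, settings)
        extra = []
        for tissue in design.tissues:
            pred = result.concentration(tissue)
            for j in range(design.n_per_time):
                eps = rng.normal(0.0, design.sigma, size=pred.size)
                extra.append(
                    pd.DataFrame(
                        {
                            "animal_id": j,
                            "time_min": schedule,
                            "conc_ug_ml": np.maximum(pred * (1 + eps), 0.0),
                            "matrix": tissue,
                        }
                    )
                )
        out = pd.concat([out, *extra], ignore_index=True)
    out.attrs["seed"] = design.seed
    out.attrs["species"] = profile.species
    out.attrs["dose_ug"] = dose.amount
    return out


def generate_rate_data(
    true_params: dict[str, float],
    model: str = "hill",
    substrate_levels=M7_SUBSTRATE_LEVELS,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> RateDataset:
    """Noisy microsomal rate data from an exact kinetic model.

    Velocities are ``model(S) * (1 + N(0, cv^2))`` floored at zero,
    ``n_replicates`` independent draws per substrate level.
    """

    if cv < 0:
        raise ValueError("cv must be >= 0")
    s_levels = np.asarray(substrate_levels, dtype=float)
    funcs = {
        "mm": (mm_velocity, ("km", "vmax")),
        "dual_mm": (dual_mm_velocity, ("km1", "vmax1", "km2", "vmax2")),
        "hill": (hill_velocity, ("km", "vmax", "gamma")),
    }
    func, names = funcs[model]
    exact = func(s_levels, *(true_params[n] for n in names))
    rng = np.random.default_rng(seed)
    s = np.repeat(s_levels, n_replicates)
    v_exact = np.repeat(exact, n_replicates)
    noise = rng.normal(0.0, cv, size=v_exact.size) if cv else np.zeros_like(v_exact)
    v = np.maximum(v_exact * (1.0 + noise), 0.0)
    return RateDataset(s, v, meta={"model": model, "seed": seed, "cv": cv})


def fit_ps(
    brain_observations: pd.DataFrame,
    profile: SpeciesProfile,
    dose: DoseEvent,
    *,
    ps_bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Estimate the brain PS product from whole-brain concentration data.

    ``brain_observations`` needs columns time_min and conc_ug_ml. All
    other model parameters stay fixed; PS is optimized on a log scale by
    least squares against the volume-weighted total brain concentration.
    Raises if the data carry no signal (flat zero).
    """

    obs = brain_observations.sort_values("time_min")
    times = obs["time_min"].to_numpy(dtype=float)
    conc = obs["conc_ug_ml"].to_numpy(dtype=float)
    if times.size < 3:
        raise ValueError("at least three brain time points are required")
    if not np.any(conc > 0):
        raise ValueError("flat-zero brain data: PS not identifiable")
    grid = np.unique(times)
    settings = SimulationSettings(t_end=float(grid[-1]), grid=grid, rtol=1e-7, atol=1e-9)

    def sse(log_ps: float) -> float:
        model = PbpkModel(profile, ps_brain=float(np.exp(log_ps)))
        result = model.simulate(dose, settings)
        pred = np.interp(times, grid, result.brain_total())
        return float(np.sum((pred - conc) ** 2))

    res = minimize_scalar(
        sse,
        bounds=(np.log(ps_bounds[0]), np.log(ps_bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError("PS estimation did not converge")
    return float(np.exp(res.x))
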