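"""Whole-body PBPK model of deoxypodophyllotoxin disposition.

The circulatory model has 13 anatomical compartments — adipose, liver,
muscle, lung, kidney, brain, heart, spleen, skin, gut, rest-of-body and the
arterial and venous blood pools — connected by regional blood flows. All
tissues are perfusion-rate limited except the brain, which is split into a
vascular and an extravascular sub-compartment exchanging through a
permeability–surface-area product ``PS`` (the perfusion-limited brain over-
predicted brain exposure).

Elimination is exclusively hepatic, via two microsomal pathways driven by
the unbound liver outflow concentration ``S = f_up * C_liv / K_liv:pl``
(converted to uM):

* demethylenation to M2 — one or two Michaelis–Menten enzymes,
  ``v_M2 = sum_i Vmax_i * S / (Km_i + S)``;
* hydroxylation to M7 — Hill kinetics,
  ``v_M7 = Vmax_M7 * S**g / (Km_M7**g + S**g)``.

The whole-liver elimination rate is ``PBSF * (v_M2 + v_M7)`` scaled from
nmol/min to ug/min with the molar mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .containers import ConcentrationProfile
from .species import SpeciesProfile

__all__ = [
    "DoseEvent",
    "SimulationSettings",
    "PbpkModel",
    "SimulationResult",
    "hepatic_elimination_velocity",
    "STATE_NAMES",
]

#: State-vector layout (concentrations in ug/mL).
STATE_NAMES = (
    "adipose",
    "liver",
    "muscle",
    "lung",
    "kidney",
    "heart",
    "spleen",
    "skin",
    "gut",
    "rest_of_body",
    "artery",
    "vein",
    "brain_vascular",
    "brain_extravascular",
)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}

#: Tissues whose outflow returns directly to the venous pool.
_DIRECT_RETURN = ("adipose", "muscle", "kidney", "heart", "skin", "rest_of_body")


@dataclass(frozen=True)
class DoseEvent:
    """An intravenous bolus into the venous blood pool.

    ``amount`` is in ug; ``per_kg`` constructs the absolute amount from a
    mg/kg dose and the profile body weight at simulation time.
    """

    amount: float
    time: float = 0.0
    route: str = "iv_bolus"
    compartment: str = "vein"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.route != "iv_bolus":
            raise ValueError("only intravenous bolus dosing is supported")
        if self.compartment != "vein":
            raise ValueError("bolus must be placed in the venous compartment")

    @classmethod
    def per_kg(cls, dose_mg_per_kg: float, body_weight_kg: float) -> "DoseEvent":
        return cls(amount=dose_mg_per_kg * body_weight_kg * 1000.0)


@dataclass(frozen=True)
class SimulationSettings:
    """Integration control: output grid, end time and solver tolerances."""

    t_end: float = 240.0
    grid: np.ndarray | None = None  # explicit output times (min)
    step: float | None = None  # dense grid spacing when ``grid`` is None
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("end time must be > 0")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be > 0")

    def output_times(self, t0: float = 0.0) -> np.ndarray:
        if self.grid is not None:
            grid = np.asarray(self.grid, dtype=float)
            if np.any(grid < t0) or np.any(grid > self.t_end):
                raise ValueError("grid times must lie within [dose time, t_end]")
            return grid
        step = self.step if self.step is not None else self.t_end / 1000.0
        return np.arange(t0, self.t_end + 0.5 * step, step)


def hepatic_elimination_velocity(
    c_liver: float, profile: SpeciesProfile
) -> tuple[float, float]:
    """Per-mg microsomal elimination velocities (v_M2, v_M7) in nmol/min/mg.

    ``c_liver`` is the total liver concentration in ug/mL; the driving
    substrate concentration is the unbound liver-outflow plasma
    concentration converted to uM.
    """

    if c_liver < 0:
        raise ValueError("liver concentration must be >= 0")
    met = profile.metabolic
    kliv = profile.tissues["liver"].ktpl / profile.rbp
    s_um = profile.fup * (c_liver / kliv) * 1000.0 / profile.mw
    v_m2 = sum(vmax * s_um / (km + s_um) for km, vmax in met.m2_enzymes)
    if s_um > 0:
        sg = s_um**met.m7_gamma
        v_m7 = (met.m7_vmax / 1000.0) * sg / (met.m7_km**met.m7_gamma + sg)
    else:
        v_m7 = 0.0
    return v_m2, v_m7


class PbpkModel:
    """The DPT whole-body PBPK model for one species.

    Parameters
    ----------
    profile : SpeciesProfile
        Physiological, partition and metabolic parameters.
    brain_vascular_fraction : float
        Fraction of the tabulated brain volume assigned to the vascular
        sub-compartment (default 0.03, a typical cerebral vascular space;
        plasma kinetics are insensitive to the split).
    perfusion_limited_brain : bool
        Treat the brain as an ordinary perfusion-limited tissue (the
        pre-refinement model); useful to verify the large-PS limit.
    ps_brain : float, optional
        Override the profile's permeability–surface-area product (mL/min).
    """

    def __init__(
        self,
        profile: SpeciesProfile,
        *,
        brain_vascular_fraction: float = 0.03,
        perfusion_limited_brain: bool = False,
        ps_brain: float | None = None,
    ) -> None:
        if not 0 < brain_vascular_fraction < 1:
            raise ValueError("brain vascular fraction must lie in (0, 1)")
        self.profile = profile
        self.perfusion_limited_brain = perfusion_limited_brain
        self.ps_brain = profile.ps_brain if ps_brain is None else ps_brain

        t = profile.tissues
        rbp = profile.rbp
        self._v = np.array(
            [t[n].volume for n in STATE_NAMES[:12]]
            + [
                t["brain"].volume * brain_vascular_fraction,
                t["brain"].volume * (1 - brain_vascular_fraction),
            ]
        )
        self._q = {n: t[n].blood_flow for n in t if t[n].blood_flow is not None}
        # effective partition K_t:pl / R_bp
        self._k = {n: t[n].ktpl / rbp for n in t if t[n].ktpl is not None}
        self._q_total = profile.cardiac_output
        self._q_hep = profile.hepatic_artery_flow
        self._q_liv_total = profile.liver_total_flow
        # Arterial drug leaves at the actual sum of tissue draws. For the
        # built-in flow-balanced tables this equals the cardiac output, but
        # writing it as the sum keeps mass conserved when individual flows
        # are perturbed without rebalancing cardiac output.
        self._q_arterial = (
            sum(self._q[n] for n in _DIRECT_RETURN)
            + self._q["gut"]
            + self._q["spleen"]
            + self._q["brain"]
            + self._q_hep
        )

    # ------------------------------------------------------------------
    @property
    def volumes(self) -> np.ndarray:
        """Compartment volumes (mL) in state order."""
        return self._v.copy()

    def total_amount(self, state: np.ndarray) -> float:
        """Drug amount in the body (ug) for a state vector."""
        return float(np.dot(self._v, np.asarray(state)))

    def elimination_rate(self, c_liver: float) -> float:
        """Whole-liver elimination rate in ug/min at liver conc ``c_liver``."""
        v_m2, v_m7 = hepatic_elimination_velocity(c_liver, self.profile)
        return self.profile.metabolic.pbsf * (v_m2 + v_m7) * self.profile.mw / 1000.0

    def derivatives(self, t: float, y: np.ndarray) -> np.ndarray:
        """Right-hand side dC/dt (ug/mL/min) of the circulatory ODE system."""
        p = self.profile
        q, k, v = self._q, self._k, self._v
        i = _IDX
        c_art = y[i["artery"]]
        c_ven = y[i["vein"]]
        dy = np.empty_like(y)

        # perfusion-limited tissues (venous or portal outflow alike)
        for name in (*_DIRECT_RETURN, "gut", "spleen"):
            j = i[name]
            dy[j] = q[name] * (c_art - y[j] / k[name]) / v[j]

        # lung: receives the entire venous return
        c_lun_out = y[i["lung"]] / k["lung"]
        dy[i["lung"]] = self._q_total * (c_ven - c_lun_out) / v[i["lung"]]
        dy[i["artery"]] = (
            self._q_total * c_lun_out - self._q_arterial * c_art
        ) / v[i["artery"]]

        # liver: hepatic artery + portal inflows, saturable elimination
        c_liv = y[i["liver"]]
        liv_in = (
            self._q_hep * c_art
            + q["gut"] * y[i["gut"]] / k["gut"]
            + q["spleen"] * y[i["spleen"]] / k["spleen"]
        )
        liv_out = self._q_liv_total * c_liv / k["liver"]
        dy[i["liver"]] = (liv_in - liv_out - self.elimination_rate(max(c_liv, 0.0))) / v[
            i["liver"]
        ]

        # brain
        q_bra, k_bra = q["brain"], k["brain"]
        c1 = y[i["brain_vascular"]]
        c2 = y[i["brain_extravascular"]]
        if self.perfusion_limited_brain:
            # single well-stirred compartment held in the vascular slot
            v_bra = v[i["brain_vascular"]] + v[i["brain_extravascular"]]
            dy[i["brain_vascular"]] = q_bra * (c_art - c1 / k_bra) / v_bra
            dy[i["brain_extravascular"]] = 0.0
            brain_return = q_bra * c1 / k_bra
        else:
            flux = self.ps_brain * (c1 - c2 / k_bra)
            dy[i["brain_vascular"]] = (q_bra * (c_art - c1) - flux) / v[
                i["brain_vascular"]
            ]
            dy[i["brain_extravascular"]] = flux / v[i["brain_extravascular"]]
            brain_return = q_bra * c1

        venous_in = (
            sum(q[n] * y[i[n]] / k[n] for n in _DIRECT_RETURN)
            + liv_out
            + brain_return
        )
        dy[i["vein"]] = (venous_in - self._q_total * c_ven) / v[i["vein"]]
        return dy

    # ------------------------------------------------------------------
    def simulate(
        self, dose: DoseEvent, settings: SimulationSettings | None = None
    ) -> "SimulationResult":
        """Integrate the model for an i.v. bolus and return all profiles."""

        settings = settings or SimulationSettings()
        y0 = np.zeros(len(STATE_NAMES))
        y0[_IDX["vein"]] = dose.amount / self._v[_IDX["vein"]]
        times = settings.output_times(dose.time)
        sol = solve_ivp(
            self.derivatives,
            (dose.time, settings.t_end),
            y0,
            method=settings.method,
            t_eval=times,
            rtol=settings.rtol,
            atol=settings.atol,
        )
        if not sol.success:
            last_t = sol.t[-1] if sol.t.size else dose.time
            raise RuntimeError(
                f"ODE integration failed ({sol.message}); last accepted time {last_t:g} min"
            )
        return SimulationResult(self, dose, sol.t, sol.y)


@dataclass(frozen=True)
class SimulationResult:
    """Concentration–time solution of a :class:`PbpkModel` simulation.

    Exposes per-compartment profiles, plasma (= venous blood for R_bp = 1)
    and the volume-weighted total brain concentration that tissue-sampling
    studies measure.
    """

    model: PbpkModel
    dose: DoseEvent
    times: np.ndarray
    states: np.ndarray  # shape (n_states, n_times)
    meta: dict = field(default_factory=dict)

    def concentration(self, compartment: str) -> np.ndarray:
        if compartment == "plasma":
            return self.states[_IDX["vein"]] / self.model.profile.rbp
        if compartment == "brain":
            return self.brain_total()
        return self.states[_IDX[compartment]]

    def brain_total(self) -> np.ndarray:
        """Volume-weighted whole-brain concentration (what homogenates see)."""
        v1 = self.model.volumes[_IDX["brain_vascular"]]
        v2 = self.model.volumes[_IDX["brain_extravascular"]]
        if self.model.perfusion_limited_brain:
            return self.states[_IDX["brain_vascular"]]
        c1 = self.states[_IDX["brain_vascular"]]
        c2 = self.states[_IDX["brain_extravascular"]]
        return (v1 * c1 + v2 * c2) / (v1 + v2)

    def total_amount(self) -> np.ndarray:
        """Amount of drug in the body (ug) along the solution."""
        return self.model.volumes @ self.states

    def profile(self, compartment: str = "plasma") -> ConcentrationProfile:
        return ConcentrationProfile(
            self.times,
            self.concentration(compartment),
            matrix=compartment,
            species=self.model.profile.species,
            dose=self.dose.amount,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_min, one column per compartment, plus plasma."""
        data = {"time_min": self.times}
        for name in STATE_NAMES:
            data[name] = self.states[_IDX[name]]
        data["brain"] = self.brain_total()
        data["plasma"] = self.concentration("plasma")
        return pd.DataFrame(data)

    def plot(self, compartments: Sequence[str] = ("plasma",), ax=None, logy=True):
        """Plot concentration–time curves for the selected compartments."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in compartments:
            ax.plot(self.times, self.concentration(name), label=name)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("concentration (ug/mL)")
        if logy:
            ax.set_yscale("log")
        ax.legend()
        return ax
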