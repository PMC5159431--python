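"""PBPK core: hepatic elimination, ODE structure, i.v. simulation."""

from dataclasses import replace

import numpy as np
import pytest

from dptpbpk import (
    DoseEvent,
    PbpkModel,
    SimulationSettings,
    hepatic_elimination_velocity,
    nca,
)
from dptpbpk.model import STATE_NAMES, _IDX


def _no_elimination(profile):
    met = replace(
        profile.metabolic,
        m2_enzymes=tuple((km, 1e-15) for km, _ in profile.metabolic.m2_enzymes),
        m7_vmax=1e-15,
    )
    return replace(profile, metabolic=met)


def _linear_kinetics(profile, factor=1e6):
    """Inflate every Km so elimination becomes first-order (v = Vmax/Km * S)."""
    met = replace(
        profile.metabolic,
        m2_enzymes=tuple(
            (km * factor, vmax * factor) for km, vmax in profile.metabolic.m2_enzymes
        ),
        m7_km=profile.metabolic.m7_km * factor,
        m7_vmax=profile.metabolic.m7_vmax * factor,
    )
    return replace(profile, metabolic=met)


class TestHepaticElimination:
    def test_zero_substrate(self, mouse):
        assert hepatic_elimination_velocity(0.0, mouse) == (0.0, 0.0)

    def test_hill_half_saturation(self, profiles):
        """At S = Km the M7 rate is half-maximal whatever the Hill exponent."""
        for profile in profiles.values():
            met = profile.metabolic
            kliv = profile.tissues["liver"].ktpl
            # choose C_liv so that S equals Km,M7 exactly
            c_liver = met.m7_km * profile.mw / 1000.0 * kliv / profile.fup
            _, v_m7 = hepatic_elimination_velocity(c_liver, profile)
            assert v_m7 == pytest.approx(met.m7_vmax / 1000.0 / 2.0, rel=1e-9)

    def test_saturation_approaches_total_vmax(self, mouse):
        c_huge = 1e9
        v_m2, v_m7 = hepatic_elimination_velocity(c_huge, mouse)
        assert v_m2 == pytest.approx(3.43, rel=1e-3)
        assert v_m7 == pytest.approx(42.76 / 1000.0, rel=1e-2)

    def test_negative_concentration_rejected(self, mouse):
        with pytest.raises(ValueError):
            hepatic_elimination_velocity(-1.0, mouse)


class TestDerivatives:
    def test_mass_conserved_without_elimination(self, rat):
        model = PbpkModel(_no_elimination(rat))
        rng = np.random.default_rng(0)
        y = rng.uniform(0.0, 5.0, len(STATE_NAMES))
        dy = model.derivatives(0.0, y)
        assert model.volumes @ dy == pytest.approx(0.0, abs=1e-9)

    def test_equilibrium_fixed_point(self, mouse):
        """Concentrations proportional to K_t:pl, unit blood: all rates zero
        (exact for the mouse, whose printed flows balance exactly)."""
        model = PbpkModel(_no_elimination(mouse))
        y = np.zeros(len(STATE_NAMES))
        for name in STATE_NAMES:
            if name in ("artery", "vein", "brain_vascular"):
                y[_IDX[name]] = 1.0
            elif name == "brain_extravascular":
                y[_IDX[name]] = mouse.tissues["brain"].ktpl
            else:
                y[_IDX[name]] = mouse.tissues[name].ktpl
        dy = model.derivatives(0.0, y)
        assert np.max(np.abs(dy)) == pytest.approx(0.0, abs=1e-9)

    def test_single_tissue_uptake_hand_value(self, rat):
        """dC_adipose/dt = Q*C_art/V with rat values 5.82/19.00."""
        model = PbpkModel(rat)
        y = np.zeros(len(STATE_NAMES))
        y[_IDX["artery"]] = 2.0
        dy = model.derivatives(0.0, y)
        assert dy[_IDX["adipose"]] == pytest.approx(5.82 * 2.0 / 19.00)


class TestSimulateIv:
    def test_dose_validation(self):
        with pytest.raises(ValueError):
            DoseEvent(-5.0)
        with pytest.raises(ValueError):
            DoseEvent(10.0, route="oral")

    def test_per_kg_constructor(self, rat):
        dose = DoseEvent.per_kg(2.0, rat.body_weight)
        assert dose.amount == pytest.approx(500.0)

    def test_total_amount_conserved_without_elimination(self, human):
        model = PbpkModel(_no_elimination(human))
        result = model.simulate(
            DoseEvent(16000.0), SimulationSettings(t_end=2000.0, step=2.0)
        )
        amount = result.total_amount()
        assert np.max(np.abs(amount - 16000.0)) / 16000.0 < 1e-3

    def test_dose_proportionality_in_linear_limit(self, rat):
        linear = _linear_kinetics(rat)
        settings = SimulationSettings(t_end=240.0, step=0.5)
        aucs = []
        for dose in (250.0, 2500.0):
            res = PbpkModel(linear).simulate(DoseEvent(dose), settings)
            aucs.append(np.trapezoid(res.concentration("plasma"), res.times))
        assert aucs[1] / aucs[0] == pytest.approx(10.0, rel=1e-3)

    def test_outputs_non_negative(self, mouse):
        res = PbpkModel(mouse).simulate(
            DoseEvent.per_kg(12.5, mouse.body_weight),
            SimulationSettings(t_end=240.0, step=0.5),
        )
        assert res.states.min() >= -1e-8

    def test_infinite_ps_matches_perfusion_limited_brain(self, mouse):
        """The permeability-limited brain collapses to the perfusion model."""
        dose = DoseEvent.per_kg(12.5, mouse.body_weight)
        settings = SimulationSettings(t_end=240.0, step=1.0)
        frac = 0.005  # small vascular slot: the limit is exact as frac -> 0
        fast = PbpkModel(mouse, ps_brain=1e5, brain_vascular_fraction=frac)
        perf = PbpkModel(mouse, perfusion_limited_brain=True,
                         brain_vascular_fraction=frac)
        b1 = fast.simulate(dose, settings).brain_total()
        b2 = perf.simulate(dose, settings).brain_total()
        sel = b2 > b2.max() * 1e-3
        assert np.max(np.abs(b1[sel] - b2[sel]) / b2[sel]) < 0.01

    def test_plasma_equals_venous_for_unit_rbp(self, human_16mg_result):
        np.testing.assert_allclose(
            human_16mg_result.concentration("plasma"),
            human_16mg_result.states[_IDX["vein"]],
        )

    def test_human_clearance_near_hepatic_blood_flow(self, human):
        """High-extraction sanity: dense-grid NCA CL in 80-100% of liver flow."""
        res = PbpkModel(human).simulate(
            DoseEvent(16000.0), SimulationSettings(t_end=2000.0, step=0.5)
        )
        r = nca(res.profile("plasma"), 16000.0, 70.0)
        assert 0.80 * 1480.0 < r.cl < 1.00 * 1480.0

    def test_frame_has_all_compartments(self, human_16mg_result):
        frame = human_16mg_result.to_frame()
        assert {"time_min", "plasma", "brain", "liver", "adipose"} <= set(frame)
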