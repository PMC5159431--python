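"""Species parameter registry, cross-species scaling rules, flow balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dptpbpk import (
    check_flow_balance,
    load_builtin_profile,
    read_profile,
    scale_ktpl_from_rat,
    scale_ps_allometric,
    write_profile,
)
from dptpbpk.species import PERFUSED_TISSUES, SPECIES_NAMES, TISSUE_NAMES


class TestRegistry:
    def test_unknown_species_names_valid_options(self):
        with pytest.raises(KeyError, match="mouse, rat, monkey, dog, human"):
            load_builtin_profile("hamster")

    def test_human_adipose_volume_in_ml(self, human):
        assert human.tissues["adipose"].volume == pytest.approx(10000.0)

    def test_dog_has_two_m2_enzymes(self, profiles):
        kms = [km for km, _ in profiles["dog"].metabolic.m2_enzymes]
        assert kms == pytest.approx([0.09, 9.47])

    def test_mouse_cardiac_output_is_lung_flow(self, mouse):
        assert mouse.cardiac_output == pytest.approx(8.00)
        assert mouse.tissues["lung"].blood_flow == pytest.approx(8.00)

    def test_unbound_fractions(self, profiles):
        expected = {"human": 0.0656, "rat": 0.0539, "mouse": 0.0283,
                    "monkey": 0.0081, "dog": 0.0016}
        for name, fup in expected.items():
            assert profiles[name].fup == pytest.approx(fup)
            assert profiles[name].rbp == 1.0

    def test_all_thirteen_tissues_present(self, profiles):
        for profile in profiles.values():
            assert set(profile.tissues) == set(TISSUE_NAMES)

    def test_hepatic_artery_flow_positive(self, profiles):
        for profile in profiles.values():
            assert profile.hepatic_artery_flow > 0


class TestKtplScaling:
    def test_rat_to_human_adipose(self):
        assert scale_ktpl_from_rat(21.63, 0.0656, 0.0539) == pytest.approx(
            26.33, abs=0.01
        )

    def test_identity_when_fractions_equal(self):
        assert scale_ktpl_from_rat(21.63, 0.0539, 0.0539) == pytest.approx(21.63)

    def test_rat_to_mouse_rest_of_body(self):
        assert scale_ktpl_from_rat(0.0100, 0.0283, 0.0539) == pytest.approx(
            0.0052, abs=0.0001
        )

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            scale_ktpl_from_rat(-1.0, 0.05, 0.05)
        with pytest.raises(ValueError):
            scale_ktpl_from_rat(1.0, 0.0, 0.05)

    @pytest.mark.parametrize("species", ["mouse", "monkey", "dog", "human"])
    def test_regenerates_every_tabulated_cell(self, profiles, species):
        """The unbound-ratio rule reproduces all non-rat partition values."""
        rat = profiles["rat"]
        target = profiles[species]
        for name in PERFUSED_TISSUES:
            scaled = scale_ktpl_from_rat(
                rat.tissues[name].ktpl, target.fup, rat.fup
            )
            tabulated = target.tissues[name].ktpl
            assert scaled == pytest.approx(tabulated, abs=0.01) or (
                scaled == pytest.approx(tabulated, rel=0.01)
            ), f"{species}/{name}: {scaled} vs {tabulated}"

    def test_unbound_ratio_invariant_across_species(self, profiles):
        rat = profiles["rat"]
        for name in PERFUSED_TISSUES:
            ref = rat.tissues[name].ktpl / rat.fup
            for species in ("mouse", "monkey", "dog", "human"):
                p = profiles[species]
                ktpl = p.tissues[name].ktpl
                ratio = ktpl / p.fup
                # partition values are tabulated to 2 decimals (4 for the
                # tiny rest-of-body entries): the ratio inherits that
                # half-ulp quantization on top of 1%
                half_ulp = 0.00005 if name == "rest_of_body" else 0.005
                tol = 0.01 + half_ulp / ktpl
                assert ratio == pytest.approx(ref, rel=tol), (species, name)


class TestPsScaling:
    def test_identity(self):
        assert scale_ps_allometric(0.0024, 0.02, 0.02) == pytest.approx(0.0024)

    @pytest.mark.parametrize(
        "weight, printed",
        [(0.25, 0.0133), (4.0, 0.0849), (8.5, 0.1407), (70.0, 0.5780)],
    )
    def test_consistent_with_tabulated_values(self, weight, printed):
        # the tabulated mouse PS has 2 significant figures; allow its rounding
        scaled = scale_ps_allometric(0.0024, weight, 0.02)
        assert scaled == pytest.approx(printed, rel=0.03)

    @settings(deadline=None, max_examples=50)
    @given(
        ps=st.floats(1e-4, 1.0),
        w1=st.floats(0.01, 100.0),
        w2=st.floats(0.01, 100.0),
        c=st.floats(0.1, 10.0),
    )
    def test_monotone_and_scale_free(self, ps, w1, w2, c):
        lo, hi = sorted((w1, w2))
        assert scale_ps_allometric(ps, hi, 0.02) >= scale_ps_allometric(ps, lo, 0.02)
        assert scale_ps_allometric(ps, c * w1, c * 0.02) == pytest.approx(
            scale_ps_allometric(ps, w1, 0.02), rel=1e-12
        )


class TestFlowBalance:
    @pytest.mark.parametrize("species", ["mouse", "dog", "monkey", "human"])
    def test_closed_circulation(self, profiles, species):
        assert check_flow_balance(profiles[species]).relative_error < 0.001

    def test_rat_table_rounding_flagged_not_fixed(self, rat):
        report = check_flow_balance(rat)
        assert 0.001 < report.relative_error < 0.01
        assert report.venous_return_total == pytest.approx(83.07, abs=0.01)


class TestParameterFiles:
    def test_round_trip(self, tmp_path, human):
        path = tmp_path / "human.params"
        write_profile(human, path)
        back = read_profile(path)
        assert back.fup == human.fup
        assert back.metabolic == human.metabolic
        for name in TISSUE_NAMES:
            assert back.tissues[name] == human.tissues[name]

    def test_unknown_key_rejected(self, tmp_path, human):
        path = tmp_path / "bad.params"
        write_profile(human, path)
        path.write_text(path.read_text() + "mystery_knob = 3\n")
        with pytest.raises(ValueError, match="mystery_knob"):
            read_profile(path)


class TestPerturbations:
    def test_fup_scaling_propagates_to_partitions(self, human):
        scaled = human.with_scaled(fup_factor=3.0)
        assert scaled.fup == pytest.approx(3 * human.fup)
        for name in PERFUSED_TISSUES:
            assert scaled.tissues[name].ktpl == pytest.approx(
                3 * human.tissues[name].ktpl
            )

    def test_liver_flow_scaling_is_joint(self, human):
        scaled = human.with_scaled(liver_flow_factor=2.0)
        for name in ("liver", "gut", "spleen"):
            assert scaled.tissues[name].blood_flow == pytest.approx(
                2 * human.tissues[name].blood_flow
            )
        assert scaled.cardiac_output == human.cardiac_output

    def test_adipose_resize_keeps_perfusion(self, human):
        scaled = human.with_scaled(adipose_volume_factor=3.0)
        a0, a1 = human.tissues["adipose"], scaled.tissues["adipose"]
        assert a1.volume == pytest.approx(3 * a0.volume)
        assert a1.blood_flow / a1.volume == pytest.approx(a0.blood_flow / a0.volume)

    def test_invalid_factor_rejected(self, human):
        with pytest.raises(ValueError):
            human.with_scaled(vmax_factor=0.0)
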