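"""Parameter arithmetic, dimensionless groups, fixtures and scenario I/O."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ohcamp
from ohcamp import params as pp
from ohcamp.params import (
    InvalidParameterError,
    MembraneCircuit,
    derive_groups,
    drag_from_subtectorial_geometry,
    export_json,
    guinea_pig_4khz,
    load_scenario,
    motor_count_from_capacitance,
    random_scenario,
    steady_state_current,
    stiffness_from_modulus,
)


class TestMeasurementDerivations:
    @pytest.mark.parametrize(
        "modulus, length, expected",
        [(510e-9, 30e-6, 17e-3), (510e-9, 40e-6, 12.75e-3), (0.0, 30e-6, 0.0)],
    )
    def test_stiffness_from_modulus(self, modulus, length, expected):
        assert stiffness_from_modulus(modulus, length) == pytest.approx(expected)

    def test_stiffness_zero_length_rejected(self):
        with pytest.raises(InvalidParameterError):
            stiffness_from_modulus(510e-9, 0.0)

    @pytest.mark.parametrize(
        "V0, expected",
        [(-50e-3, 0.3e-9), (-40e-3, 0.4e-9), (-80e-3, 0.0)],
    )
    def test_resting_potential_current(self, V0, expected):
        c = MembraneCircuit(C0=30e-12, sigma=10e-9, V0=V0, eK=-80e-3, Rm=100e6)
        assert steady_state_current(c) == pytest.approx(expected, abs=1e-15)

    def test_divider_mode_current(self):
        # endocochlear potential driving the series bundle + basolateral path
        c = MembraneCircuit(C0=30e-12, sigma=10e-9, eep=90e-3, eK=-80e-3,
                            R0=400e6, Rm=100e6)
        assert steady_state_current(c) == pytest.approx(170e-3 / 500e6)

    def test_current_missing_fields_rejected(self):
        with pytest.raises(InvalidParameterError):
            steady_state_current(MembraneCircuit(C0=30e-12, sigma=10e-9, i0=0.3e-9))

    def test_motor_count_from_capacitance(self):
        n = motor_count_from_capacitance(30e-12, 0.8 * pp.E_CHARGE, sig_figs=1)
        assert n == pytest.approx(3e7)
        # linearity in the peak capacitance
        n2 = motor_count_from_capacitance(60e-12, 0.8 * pp.E_CHARGE)
        assert n2 == pytest.approx(2 * motor_count_from_capacitance(30e-12, 0.8 * pp.E_CHARGE))

    def test_unit_displacement_from_total_motility(self):
        # 5% of a 40 um cell shared by 3e7 motors
        n = motor_count_from_capacitance(30e-12, 0.8 * pp.E_CHARGE, sig_figs=1)
        a = 0.05 * 40e-6 / n
        assert a == pytest.approx(0.67e-13, rel=0.01)

    def test_motor_count_capacitance_round_trip(self):
        q, kBT = 0.8 * pp.E_CHARGE, pp.KBT_300K
        n = motor_count_from_capacitance(30e-12, q, kBT)
        assert n * q**2 / (4 * kBT) == pytest.approx(30e-12)

    def test_motor_count_zero_charge_rejected(self):
        with pytest.raises(InvalidParameterError):
            motor_count_from_capacitance(30e-12, 0.0)

    @pytest.mark.parametrize(
        "area, height, visc, expected",
        [
            (10e-6 * 20e-6, 2e-6, 0.8e-3, 0.8e-7),
            (10e-6 * 20e-6, 2e-6, 0.4e-3, 0.4e-7),
            (0.0, 2e-6, 0.8e-3, 0.0),
        ],
    )
    def test_subtectorial_drag(self, area, height, visc, expected):
        assert drag_from_subtectorial_geometry(area, height, visc) == pytest.approx(expected)

    def test_drag_zero_gap_rejected(self):
        with pytest.raises(InvalidParameterError):
            drag_from_subtectorial_geometry(1e-10, 0.0, 1e-3)


class TestDerivedGroups:
    def test_reference_groups(self, gp_groups):
        gr = gp_groups
        assert gr.ua == pytest.approx(0.14, abs=0.005)
        assert gr.omega_bar_m == pytest.approx(0.013, abs=0.0005)
        assert gr.Kbar_e == pytest.approx(20 / 37)
        assert gr.alpha_c == 1.0  # series

    def test_no_external_spring(self, gp):
        for conn in ("series", "parallel"):
            p = dataclasses.replace(
                gp, mech=dataclasses.replace(gp.mech, Ke=0.0, connectivity=conn)
            )
            gr = derive_groups(p)
            assert gr.Kbar_e == 0.0
            assert gr.alpha_c == 1.0

    def test_parallel_alpha_c(self, gp):
        p = dataclasses.replace(gp, mech=dataclasses.replace(gp.mech, connectivity="parallel"))
        gr = derive_groups(p)
        assert gr.alpha_c == pytest.approx(1.0 - 20 / 37)

    def test_gain_sign_and_magnitude(self, gp, gp_groups):
        # amplifying configuration: g < 0, |g| = a N (1 - Kbar_e) gx
        assert gp.gain < 0
        expected = gp.motor.a * gp.motor.N * (1 - gp_groups.Kbar_e) * gp.bundle.gx
        assert abs(gp.gain) == pytest.approx(expected)
        flipped = dataclasses.replace(
            gp, bundle=dataclasses.replace(gp.bundle, amplifying=False))
        assert flipped.gain == pytest.approx(-gp.gain)

    @given(c=st.floats(0.1, 10.0))
    def test_stiffness_scaling(self, c):
        gp = guinea_pig_4khz()
        scaled = dataclasses.replace(
            gp, mech=dataclasses.replace(gp.mech, ko=c * gp.mech.ko, Ke=c * gp.mech.Ke)
        )
        g0, g1 = derive_groups(gp), derive_groups(scaled)
        assert g1.ua == pytest.approx(c * g0.ua)
        assert g1.Kbar_e == pytest.approx(g0.Kbar_e)

    @given(scale=st.floats(1e-3, 1.0))
    def test_ua_vanishes_with_motor_displacement(self, scale):
        gp = guinea_pig_4khz()
        small = dataclasses.replace(
            gp, motor=dataclasses.replace(gp.motor, a=scale * gp.motor.a))
        assert derive_groups(small).ua == pytest.approx(scale**2 * derive_groups(gp).ua)

    @given(ke=st.floats(1e-4, 10.0))
    def test_Kbar_e_monotone_in_Ke(self, ke):
        gp = guinea_pig_4khz()
        lo = dataclasses.replace(gp, mech=dataclasses.replace(gp.mech, Ke=ke))
        hi = dataclasses.replace(gp, mech=dataclasses.replace(gp.mech, Ke=2 * ke))
        assert derive_groups(hi).Kbar_e > derive_groups(lo).Kbar_e
        assert derive_groups(hi).Kbar_e < 1.0

    def test_mass_from_resonance(self, gp):
        wr = 2 * math.pi * gp.mech.fr
        assert (gp.mech.ko + gp.mech.Ke) / gp.mech.m == pytest.approx(wr**2)


class TestFixtures:
    def test_reference_fixture_values(self, gp):
        assert gp.circuit.i0 == pytest.approx(0.3e-9)
        assert gp.motor.q == pytest.approx(-1.28e-19)
        assert gp.motor.gamma == 1.0

    def test_fixture_deterministic(self):
        assert guinea_pig_4khz() == guinea_pig_4khz()

    def test_figure_mode_pins_roll_off(self, fm, gp_groups):
        assert fm.omega_bar_eta == 10.0
        assert fm.omega_bar_m == pytest.approx(gp_groups.omega_bar_m)
        assert fm.ah1 == pytest.approx(gp_groups.ah1)

    def test_random_scenario_reproducible(self):
        a, b = random_scenario(7), random_scenario(7)
        assert a == b
        assert random_scenario(8) != a

    def test_random_scenarios_valid_and_bounded(self):
        uas = []
        for seed in range(100):
            gr = derive_groups(random_scenario(seed))
            uas.append(gr.ua)
            assert gr.omega_bar_eta > 0 and gr.omega_bar_m > 0
            assert 0 <= gr.Kbar_e < 1
        uas = np.array(uas)
        assert np.all((uas > 0) & (uas < 14))


class TestScenarioIO:
    def test_yaml_physical_round_trip(self, tmp_path, gp, gp_groups):
        f = tmp_path / "s.yaml"
        f.write_text(
            "physical:\n"
            "  q: -1.28e-19\n  a: 6.7e-14\n  N: 3.0e+7\n  C0: 3.0e-11\n"
            "  sigma: 1.0e-8\n  i0: 3.0e-10\n  ko: 0.017\n  Ke: 0.020\n"
            "  gx: 4.0e+7\n  eta: 8.0e-8\n  fr: 4000.0\n"
            "  connectivity: series\n"
        )
        p = load_scenario(f)
        gr = derive_groups(p)
        assert gr.ua == pytest.approx(gp_groups.ua, rel=1e-3)
        assert gr.omega_bar_m == pytest.approx(gp_groups.omega_bar_m, rel=1e-6)

    def test_yaml_dimensionless_wins(self, tmp_path, caplog):
        f = tmp_path / "s.yaml"
        f.write_text(
            "physical:\n"
            "  q: -1.28e-19\n  a: 6.7e-14\n  N: 3.0e+7\n  C0: 3.0e-11\n"
            "  sigma: 1.0e-8\n  i0: 3.0e-10\n  ko: 0.017\n  Ke: 0.020\n"
            "  gx: 4.0e+7\n  eta: 8.0e-8\n  fr: 4000.0\n"
            "dimensionless:\n  omega_bar_eta: 10.0\n"
        )
        import logging
        with caplog.at_level(logging.WARNING):
            gr = load_scenario(f)
        assert isinstance(gr, ohcamp.DerivedGroups)
        assert gr.omega_bar_eta == 10.0
        assert gr.ua == pytest.approx(0.138, abs=0.001)  # kept from physical block
        assert any("precedence" in r.message for r in caplog.records)

    def test_yaml_pure_dimensionless(self, tmp_path):
        f = tmp_path / "s.yaml"
        f.write_text(
            "dimensionless:\n  ua: 0.14\n  Kbar_e: 0.54\n  omega_bar_eta: 10.0\n"
            "  omega_bar_m: 0.013\n  ah1: 0.11\n  bh2: 0.99\n"
        )
        gr = load_scenario(f)
        assert gr.alpha_c == 1.0
        assert gr.bh2 == 0.99

    def test_yaml_unknown_key_rejected(self, tmp_path):
        f = tmp_path / "s.yaml"
        f.write_text("physical:\n  bogus: 1\n")
        with pytest.raises(InvalidParameterError):
            load_scenario(f)

    def test_json_export(self, tmp_path, gp, gp_groups):
        import json
        out = tmp_path / "p.json"
        d = export_json(gp, gp_groups, out)
        loaded = json.loads(out.read_text())
        assert loaded["i0"] == pytest.approx(0.3e-9)
        assert loaded["groups"]["ua"] == pytest.approx(gp_groups.ua)
        assert loaded["units"]["ko"] == "N/m"
        assert d["m"] == pytest.approx(gp.mech.m)


class TestValidation:
    def test_positive_charge_rejected(self):
        with pytest.raises(InvalidParameterError):
            ohcamp.MotorElement(q=1e-19, a=1e-13, N=1e7)

    def test_gamma_from_operating_point(self):
        assert ohcamp.MotorElement(q=-1e-19, a=1e-13, N=1e7, P0=0.5).gamma == 1.0
        m = ohcamp.MotorElement(q=-1e-19, a=1e-13, N=1e7, P0=0.1)
        assert m.gamma == pytest.approx(0.36)

    def test_sigma_from_resistances(self):
        c = MembraneCircuit(C0=30e-12, R0=200e6, Rm=100e6, i0=0.0)
        assert c.sigma == pytest.approx(1 / 200e6 + 1 / 100e6)

    def test_zero_capacitance_needs_conductance(self):
        with pytest.raises(InvalidParameterError):
            MembraneCircuit(C0=0.0, sigma=0.0, i0=0.0)
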