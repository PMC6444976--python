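"""Migration-angle model: effective velocities, angles, regimes, sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gelstream as gs


def equal_mu_model(mu=2.75e-5):
    """Field- and length-independent mobility (beta = 0 parametric family)."""
    # mu0/(3N) = mu for the single fragment length used alongside this model
    return gs.MobilityModel("parametric", mu0=mu * 3.0, beta=0.0, gamma=0.0, kuhn_bp=300.0)


def frag_for_equal_mu(model):
    # N = 1 Kuhn segment makes mu = mu0/3 exactly
    return gs.FragmentSpec(300)


class TestEffectiveVelocity:
    def test_no_switching_loss_at_f_zero(self):
        frag = gs.FragmentSpec(2000)
        assert gs.effective_velocity(3e-5, 50.0, 0.0, frag) == 3e-5 * 50.0

    def test_zero_exactly_at_reorientation_frequency(self):
        frag = gs.FragmentSpec(2000)
        mu, E = 3e-5, 50.0
        f_or = mu * E / (2 * frag.contour_length_cm)
        assert gs.effective_velocity(mu, E, f_or, frag) == 0.0

    def test_worked_value(self):
        # mu=2.75e-5, E=22.4, L=3.4e-4 cm, f=0.5 Hz -> 6.16e-4 - 3.4e-4
        frag = gs.FragmentSpec(10000)
        v = gs.effective_velocity(2.75e-5, 22.4, 0.5, frag)
        assert v == pytest.approx(2.76e-4, rel=1e-10)


class TestMigrationAngle:
    def test_symmetric_orthogonal_fields_give_45deg(self):
        model = equal_mu_model()
        frag = frag_for_equal_mu(model)
        p = gs.FieldProtocol(10.0, 10.0, 0.0, 90.0, 0.0)
        assert gs.migration_angle(p, frag, model).phi_deg == pytest.approx(45.0, abs=1e-12)

    def test_weak_field_clamp_pins_angle_to_theta1(self, fixture_model):
        # 10 kbp at 2 Hz: weak-field f_or ~ 0.55 Hz < f < strong-field f_or
        p = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 2.0)
        res = gs.migration_angle(p, gs.FragmentSpec(10000), fixture_model)
        assert res.v_eff_2_cm_s == 0.0
        assert res.phi_deg == pytest.approx(25.0, abs=1e-9)
        assert res.regime == "switchback_window"

    def test_worked_equal_mobility_angle(self):
        # E1=59.5, E2=22.4, theta 25/115 deg, equal mu, f=0 -> 45.63 deg
        model = equal_mu_model()
        frag = frag_for_equal_mu(model)
        p = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.0)
        assert gs.migration_angle(p, frag, model).phi_deg == pytest.approx(45.6299, abs=1e-3)

    def test_no_net_motion_flagged_not_thrown(self, fixture_model):
        # far above the strong-field reorientation frequency
        p = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 1000.0)
        res = gs.migration_angle(p, gs.FragmentSpec(10000), fixture_model)
        assert res.no_net_motion
        assert res.regime == "no_reorientation"
        assert 25.0 <= res.phi_deg <= 115.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        E1=st.floats(1.0, 150.0),
        ratio=st.floats(0.05, 1.0),
        th1=st.floats(-80.0, 80.0),
        dth=st.floats(5.0, 120.0),
        duty=st.floats(0.1, 0.9),
    )
    def test_reduces_to_ion_angle_for_equal_mu_at_f_zero(self, E1, ratio, th1, dth, duty):
        model = equal_mu_model()
        frag = frag_for_equal_mu(model)
        p = gs.FieldProtocol(E1, E1 * ratio, th1, th1 + dth, 0.0, duty)
        assert gs.migration_angle(p, frag, model).phi_deg == pytest.approx(
            gs.ion_angle(p), abs=1e-9
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        f=st.floats(0.0, 20.0),
        length=st.sampled_from([500, 1000, 2000, 5000, 10000]),
    )
    def test_angle_bounded_by_field_angles(self, f, length):
        model = gs.synthetic_mobility_model()
        p = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, f)
        res = gs.migration_angle(p, gs.FragmentSpec(length), model)
        assert 25.0 - 1e-9 <= res.phi_deg <= 115.0 + 1e-9

    def test_angle_strictly_decreases_with_frequency(self, fixture_model):
        frag = gs.FragmentSpec(1000)
        f_or_weak = gs.reorientation_frequency(
            fixture_model.mobility(22.4, frag), 22.4, frag
        )
        fs = np.linspace(0.0, 0.9 * f_or_weak, 12)
        p0 = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.0)
        phis = [gs.migration_angle(p0.replace(f_Hz=f), frag, fixture_model).phi_deg for f in fs]
        assert all(a > b for a, b in zip(phis, phis[1:]))

    def test_as_printed_convention_available_and_distinct(self, fixture_model):
        p = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.5)
        frag = gs.FragmentSpec(2000)
        a = gs.migration_angle(p, frag, fixture_model).phi_deg
        b = gs.migration_angle(p, frag, fixture_model, convention="as_printed").phi_deg
        assert a != b  # published form has the inconsistent minus sign


class TestIonAngle:
    def test_equal_fields_bisect(self):
        p = gs.FieldProtocol(10.0, 10.0, 0.0, 90.0, 5.0)
        assert gs.ion_angle(p) == pytest.approx(45.0, abs=1e-12)

    def test_worked_value(self):
        p = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 2.0)
        assert gs.ion_angle(p) == pytest.approx(45.6299, abs=1e-3)

    def test_independent_of_frequency(self):
        a = gs.ion_angle(gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.0))
        b = gs.ion_angle(gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 33.0))
        assert a == b

    def test_dna_deflects_less_than_ions(self, fixture_model, paper_protocol, fragments5):
        phi0 = gs.ion_angle(paper_protocol)
        for frag in fragments5:
            assert gs.migration_angle(paper_protocol, frag, fixture_model).phi_deg < phi0


class TestRegimes:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (0.01, "field_dependent_mobility"),
            (10.0, "switchback_window"),
            (2.4, "switchback_window"),  # boundary inclusive upward
            (50.0, "switchback_window"),
            (50.1, "no_reorientation"),
        ],
    )
    def test_classification(self, f, expected):
        assert gs.classify_regime(f, 50.0, 2.4) == expected

    def test_inverted_ordering_rejected(self):
        with pytest.raises(ValueError):
            gs.classify_regime(1.0, 2.4, 50.0)


class TestFrequencySweep:
    def test_monotone_spectra_and_plateau(self, fixture_model):
        frag = gs.FragmentSpec(1000)
        p0 = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.0)
        f_grid = np.geomspace(0.016, 33.0, 25)
        table = gs.frequency_sweep(p0, [frag], f_grid, fixture_model)
        assert list(table.columns) == [
            "f_Hz", "length_bp", "phi_deg", "regime", "v_eff1_cm_s", "v_eff2_cm_s"
        ]
        moving = table[table.v_eff1_cm_s > 0]
        phis = moving.phi_deg.to_numpy()
        assert all(a >= b - 1e-12 for a, b in zip(phis, phis[1:]))
        # low-frequency plateau: the spectrum flattens toward the f=0 limit
        phi0 = gs.migration_angle(p0, frag, fixture_model).phi_deg
        assert abs(table.phi_deg.iloc[0] - phi0) < 0.05
        assert abs(table.phi_deg.iloc[1] - table.phi_deg.iloc[0]) < 0.05

    def test_low_f_separation_matches_quasistatic_difference(self, fixture_model):
        p0 = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.0)
        frags = [gs.FragmentSpec(500), gs.FragmentSpec(2000)]
        table = gs.frequency_sweep(p0, frags, [1e-12, 1e-11], fixture_model)
        lowest = table[table.f_Hz == 1e-12].set_index("length_bp").phi_deg
        sep = lowest[500] - lowest[2000]
        ana = (
            gs.migration_angle(p0, frags[0], fixture_model).phi_deg
            - gs.migration_angle(p0, frags[1], fixture_model).phi_deg
        )
        assert sep == pytest.approx(ana, abs=1e-9)

    def test_identical_fragments_identical_curves(self, fixture_model):
        p0 = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.0)
        frags = [gs.FragmentSpec(2000, "a"), gs.FragmentSpec(2000, "b")]
        table = gs.frequency_sweep(p0, frags, np.linspace(0.1, 5, 8), fixture_model)
        by_label = table.groupby("length_bp")
        # same length_bp collapses to one group; compare explicit per-fragment runs
        a = gs.frequency_sweep(p0, [frags[0]], np.linspace(0.1, 5, 8), fixture_model)
        b = gs.frequency_sweep(p0, [frags[1]], np.linspace(0.1, 5, 8), fixture_model)
        assert np.array_equal(a.phi_deg, b.phi_deg)

    def test_rejects_bad_grids(self, fixture_model):
        p0 = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.0)
        with pytest.raises(ValueError):
            gs.frequency_sweep(p0, [gs.FragmentSpec(500)], [1.0], fixture_model)
        with pytest.raises(ValueError):
            gs.frequency_sweep(p0, [], [1.0, 2.0], fixture_model)


class TestStreamCounts:
    def test_four_streams_quasistatic_five_at_2hz(self, fixture_model, fragments5):
        """Low f: 0.5-5 kbp resolve, 5/10 kbp co-migrate; at 2 Hz all five resolve."""
        p0 = gs.FieldProtocol(59.5, 22.4, 25.0, 115.0, 0.0)
        quasi = [gs.migration_angle(p0, f, fixture_model).phi_deg for f in fragments5]
        assert quasi[3] == pytest.approx(quasi[4], abs=1e-9)  # 5 and 10 kbp merged
        distinct = sorted(set(round(a, 6) for a in quasi), reverse=True)
        assert len(distinct) == 4
        assert quasi[:4] == sorted(quasi[:4], reverse=True)

        p2 = p0.replace(f_Hz=2.0)
        at2 = [gs.migration_angle(p2, f, fixture_model).phi_deg for f in fragments5]
        assert all(a > b for a, b in zip(at2, at2[1:]))  # five strictly ordered


class TestFieldProtocol:
    def test_strong_field_convention_enforced(self):
        with pytest.raises(ValueError, match="E1 >= E2"):
            gs.FieldProtocol(10.0, 20.0, 0.0, 90.0, 1.0)

    def test_duty_bounds(self):
        with pytest.raises(ValueError):
            gs.FieldProtocol(20.0, 10.0, 0.0, 90.0, 1.0, duty=1.0)
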