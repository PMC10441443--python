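"""Tensile machinery: grips, stress conversion, bond breaking, protocols."""

import math
import warnings

import numpy as np
import pytest

import fibrilmech as fm
from fibrilmech.forcefield import GLUCOSEPANE, System, _trilinear_tension
from fibrilmech.tensile import (
    PullProtocol,
    detect_broken_bonds,
    engineering_stress,
    run_tensile_test,
)
from fibrilmech import units


class TestEngineeringStress:
    def test_zero_force_zero_stress(self):
        assert engineering_stress(0.0, 202.0) == 0.0

    def test_undeformed_area_divisor(self):
        # d = 20.2 nm -> area π·101² Å² ≈ 3.2047e4
        area = math.pi * 101.0**2
        assert engineering_stress(1.0, 202.0) == pytest.approx(1.0 / area, rel=1e-12)
        assert area == pytest.approx(3.2047e4, rel=1e-4)

    def test_linearity(self):
        assert engineering_stress(4.0, 50.0) == 2 * engineering_stress(2.0, 50.0)

    def test_bad_diameter_rejected(self):
        with pytest.raises(ValueError):
            engineering_stress(1.0, 0.0)


class TestProtocolArithmetic:
    def test_reference_velocity_is_ten_meters_per_second(self):
        assert units.velocity_to_m_per_s(0.0001) == pytest.approx(10.0, rel=1e-12)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(ValueError):
            PullProtocol(mode="nonsense")
        with pytest.raises(ValueError):
            PullProtocol(strain_target=-0.1)
        with pytest.raises(ValueError):
            PullProtocol(mode="dynamic", velocity=0.0)


class TestRigidMotion:
    def test_rigid_translation_transmits_no_force(self):
        # moving the whole specimen (both grips identically) deforms nothing
        cfg, topo = fm.make_fixture("two-chain")
        ff = cfg.build_forcefield()
        sys_ = System(topo, ff)
        for shift in (0.0, 5.0, 37.0):
            pos = topo.positions.copy()
            pos[:, 2] += shift
            _, forces = sys_.evaluate(pos)
            left = forces[topo.left_grip, 2].sum()
            right = forces[topo.right_grip, 2].sum()
            base = sys_.evaluate(topo.positions)[1]
            assert right == pytest.approx(base[topo.right_grip, 2].sum(), abs=1e-9)
            assert left == pytest.approx(base[topo.left_grip, 2].sum(), abs=1e-9)


class TestSingleBondOracle:
    def test_force_extension_equals_trilinear_law(self, single_bond_traj):
        traj = single_bond_traj
        r = GLUCOSEPANE.r0 + traj.displacement
        expected = _trilinear_tension(GLUCOSEPANE, r)
        expected[r >= GLUCOSEPANE.rbreak + GLUCOSEPANE.a] = 0.0
        np.testing.assert_allclose(traj.force, expected, atol=1e-8)

    def test_peak_force_closed_form(self, single_bond_traj):
        assert single_bond_traj.force.max() == pytest.approx(
            GLUCOSEPANE.peak_force, rel=1e-9
        )

    def test_census_after_rupture(self, single_bond_traj):
        assert detect_broken_bonds(single_bond_traj) == {"age": 1, "collagen": 0}
        assert single_bond_traj.force[-1] == pytest.approx(0.0, abs=1e-12)

    def test_prepull_census_zero(self, single_bond_traj):
        assert detect_broken_bonds(single_bond_traj, frame=0) == {
            "age": 0, "collagen": 0,
        }

    def test_broken_counts_monotone(self, single_bond_traj):
        assert np.all(np.diff(single_bond_traj.broken_age) >= 0)

    def test_grip_work_equals_loading_energy_capacity(self, single_bond_traj):
        # ∫F dx from equilibrium to rupture = W (energy stored then lost)
        traj = single_bond_traj
        r = GLUCOSEPANE.r0 + traj.displacement
        upto = r <= GLUCOSEPANE.rbreak
        work = np.trapezoid(traj.force[upto], traj.displacement[upto])
        assert work == pytest.approx(328.66, rel=2e-3)


class TestPullOut:
    def test_uncrosslinked_pair_pulls_out_completely(self):
        cfg, topo = fm.make_fixture("two-chain")
        ff = cfg.build_forcefield()
        proto = PullProtocol(strain_target=0.9, stop_fraction=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = run_tensile_test(topo, ff, proto)
        raw = traj.force + traj.force_tare  # physical grip force
        peak = raw.max()
        assert peak > 0
        assert abs(raw[-1]) < 0.01 * peak
        assert traj.broken_collagen[-1] == 0  # molecules intact, just slid

    def test_mirror_symmetry(self):
        # reflecting the specimen axially gives the same curve
        cfg, topo = fm.make_fixture("two-chain")
        ff = cfg.build_forcefield()
        proto = PullProtocol(strain_target=0.25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fwd = run_tensile_test(topo, ff, proto)
            zmax = topo.positions[:, 2].max()
            topo.positions[:, 2] = zmax - topo.positions[:, 2]
            topo.left_grip, topo.right_grip = topo.right_grip, topo.left_grip
            rev = run_tensile_test(topo, ff, proto)
        n = min(fwd.n_frames, rev.n_frames)
        # agreement is limited by the minimizer force tolerance (~1e-3
        # kcal/mol/Å over a ~190 Å² section -> ~1e-5 stress units)
        np.testing.assert_allclose(
            fwd.stress[:n], rev.stress[:n], rtol=1e-4, atol=1e-5
        )


class TestDynamicMode:
    def test_dynamic_run_completes_and_frames_ordered(self):
        cfg, topo = fm.make_fixture("two-chain")
        ff = cfg.build_forcefield()
        proto = PullProtocol(
            mode="dynamic", velocity=0.01, strain_target=0.15,
            sample_interval=100, temperature=300.0,
        )
        traj = run_tensile_test(topo, ff, proto, seed=4)
        assert traj.n_frames > 3
        assert not traj.aborted
        assert np.all(np.diff(traj.displacement) > 0)
        assert np.isfinite(traj.force).all()

    def test_dynamic_deterministic_under_seed(self):
        cfg, topo = fm.make_fixture("two-chain")
        ff = cfg.build_forcefield()
        proto = PullProtocol(
            mode="dynamic", velocity=0.02, strain_target=0.05, sample_interval=50
        )
        a = run_tensile_test(topo, ff, proto, seed=11)
        cfg, topo = fm.make_fixture("two-chain")
        b = run_tensile_test(topo, ff, proto, seed=11)
        np.testing.assert_array_equal(a.force, b.force)

    def test_dynamic_matches_quasistatic_regime(self, mini7_factory, mini_sweep):
        # finite pulling speed does not change softening-vs-stiffening
        cfg, topo = mini7_factory(10.0)
        ff = cfg.build_forcefield()
        from fibrilmech.forcefield import age_spec

        ff.age = age_spec(k1=24.0, rbreak=50.0)
        proto = PullProtocol(
            mode="dynamic", velocity=0.01, strain_target=0.85, sample_interval=200
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = run_tensile_test(topo, ff, proto, seed=5)
        from fibrilmech.analysis import StressStrainCurve, classify_regime

        dynamic_label = classify_regime(StressStrainCurve.from_trajectory(traj))
        row = mini_sweep.table.query("k1 == 24 and rbreak == 50 and n_age == 10")
        assert dynamic_label == row["regime_observed"].iloc[0] == "stiffening"
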