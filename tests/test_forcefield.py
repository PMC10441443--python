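"""Trilinear bond law, pair/angle terms, energy assembly and its gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import fibrilmech as fm
from fibrilmech.forcefield import (
    BondState,
    COLLAGEN_BOND,
    ForceField,
    GLUCOSEPANE,
    PairSpec,
    Regime,
    System,
    TrilinearBondSpec,
    _trilinear_energy,
    _trilinear_tension,
    bond_energy,
    bond_force,
    loading_energy_capacity,
    pair_energy,
    pair_force,
    stiffening_criterion,
)


def random_specs():
    """Hypothesis strategy over valid trilinear bond specs."""
    return st.builds(
        TrilinearBondSpec,
        r0=st.floats(5.0, 20.0),
        r1=st.floats(21.0, 30.0),
        rbreak=st.floats(31.0, 60.0),
        k0=st.floats(0.05, 20.0),
        k1=st.floats(0.5, 100.0),
        z=st.floats(0.01, 0.5),
    )


class TestTrilinearLaw:
    def test_zero_force_at_equilibrium(self):
        f, state = bond_force(GLUCOSEPANE, GLUCOSEPANE.r0)
        assert f == 0.0
        assert state == BondState.INTACT

    def test_branch_one_endpoint(self):
        # k0·(r1-r0) = 0.1·4.2 at the hyperelastic threshold
        f, _ = bond_force(GLUCOSEPANE, 22.72)
        assert f == pytest.approx(0.42, abs=1e-12)

    def test_zero_and_broken_past_regularization(self):
        r_end = GLUCOSEPANE.rbreak + GLUCOSEPANE.a
        f, state = bond_force(GLUCOSEPANE, r_end + 0.01)
        assert f == 0.0
        assert state == BondState.BROKEN

    def test_broken_state_absorbing(self):
        _, state = bond_force(GLUCOSEPANE, GLUCOSEPANE.rbreak + GLUCOSEPANE.a + 1)
        f, state = bond_force(GLUCOSEPANE, GLUCOSEPANE.r0, state)
        assert f == 0.0 and state == BondState.BROKEN
        assert bond_energy(GLUCOSEPANE, GLUCOSEPANE.r0 + 1, state) == 0.0

    def test_compression_restores(self):
        f, _ = bond_force(GLUCOSEPANE, GLUCOSEPANE.r0 - 1.0)
        assert f < 0  # pushes back out

    @settings(max_examples=50, deadline=None)
    @given(random_specs())
    def test_continuity_at_branch_points(self, spec):
        eps = 1e-9
        for r in (spec.r1, spec.rbreak, spec.rbreak + spec.a):
            lo = _trilinear_tension(spec, np.array([r - eps]))[0]
            hi = _trilinear_tension(spec, np.array([r + eps]))[0]
            assert abs(hi - lo) < 1e-5 * max(1.0, spec.peak_force)

    @settings(max_examples=30, deadline=None)
    @given(random_specs(), st.integers(0, 2**31 - 1))
    def test_force_energy_consistency(self, spec, seed):
        # −dΦ/dr equals the tension everywhere off the breakpoints
        rng = np.random.default_rng(seed)
        r = rng.uniform(spec.r0 * 0.5, spec.rbreak + 2 * spec.a, 200)
        h = 1e-6
        num = -(_trilinear_energy(spec, r + h) - _trilinear_energy(spec, r - h)) / (2 * h)
        t = _trilinear_tension(spec, r)
        # exclude samples within h of a breakpoint
        ok = np.ones_like(r, dtype=bool)
        for rb in (spec.r1, spec.rbreak, spec.rbreak + spec.a):
            ok &= np.abs(r - rb) > 10 * h
        scale = max(1.0, spec.peak_force)
        assert np.max(np.abs(num[ok] + t[ok])) < 1e-6 * scale

    def test_thousand_point_consistency_reference_specs(self):
        rng = np.random.default_rng(0)
        for spec in (GLUCOSEPANE, COLLAGEN_BOND):
            r = rng.uniform(spec.r0 * 0.6, spec.rbreak + 2 * spec.a, 1000)
            h = 1e-7
            num = -(
                _trilinear_energy(spec, r + h) - _trilinear_energy(spec, r - h)
            ) / (2 * h)
            t = _trilinear_tension(spec, r)
            ok = np.ones_like(r, dtype=bool)
            for rb in (spec.r1, spec.rbreak, spec.rbreak + spec.a):
                ok &= np.abs(r - rb) > 10 * h
            assert np.max(np.abs(num[ok] + t[ok])) < 1e-6 * spec.peak_force


class TestLoadingEnergyCapacity:
    def test_glucosepane_reference_value(self):
        # quadrature oracle over the trilinear tension from r0 to rbreak
        w_quad, _ = quad(
            lambda r: _trilinear_tension(GLUCOSEPANE, np.array([r]))[0],
            GLUCOSEPANE.r0,
            GLUCOSEPANE.rbreak,
            points=[GLUCOSEPANE.r1],
        )
        w = loading_energy_capacity(GLUCOSEPANE)
        assert w == pytest.approx(w_quad, rel=1e-10)
        assert w == pytest.approx(328.66, abs=0.005)

    def test_equals_bond_energy_at_rbreak(self):
        for spec in (GLUCOSEPANE, COLLAGEN_BOND):
            assert loading_energy_capacity(spec) == pytest.approx(
                bond_energy(spec, spec.rbreak), rel=1e-12
            )

    def test_degenerate_zero_capacity(self):
        spec = TrilinearBondSpec(r0=10.0, r1=10.0, rbreak=10.0, k0=1.0, k1=1.0)
        assert loading_energy_capacity(spec) == 0.0

    def test_doubling_k1_adds_closed_form_increment(self):
        a = GLUCOSEPANE
        b = TrilinearBondSpec(a.r0, a.r1, a.rbreak, a.k0, 2 * a.k1, a.z)
        dw = loading_energy_capacity(b) - loading_energy_capacity(a)
        assert dw == pytest.approx(a.k1 / 2 * (a.rbreak - a.r1) ** 2, rel=1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            TrilinearBondSpec(r0=10, r1=30, rbreak=20, k0=1, k1=1)

    @settings(max_examples=40, deadline=None)
    @given(random_specs(), st.floats(1.01, 3.0))
    def test_monotone_in_stiffness_and_strength(self, spec, factor):
        w = loading_energy_capacity(spec)
        for field in ("k0", "k1", "rbreak"):
            kw = {
                "r0": spec.r0, "r1": spec.r1, "rbreak": spec.rbreak,
                "k0": spec.k0, "k1": spec.k1, "z": spec.z,
            }
            kw[field] = kw[field] * factor
            assert loading_energy_capacity(TrilinearBondSpec(**kw)) >= w


class TestStiffeningCriterion:
    def test_zero_density_is_sliding(self):
        assert stiffening_criterion(100.0, 1e9, 0.0) == Regime.SLIDING

    def test_boundary_is_sliding(self):
        # strict inequality: equality classifies as sliding-governed
        assert stiffening_criterion(120.0, 60.0, 2.0) == Regime.SLIDING

    def test_direct_inequality(self):
        assert stiffening_criterion(100.0, 60.0, 2.0) == Regime.TC_DEFORMATION

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            stiffening_criterion(-1.0, 1.0, 1.0)


class TestPairForce:
    def test_zero_at_potential_minimum(self):
        spec = PairSpec()
        assert pair_force(spec, 2 ** (1 / 6) * spec.sigma) == pytest.approx(0.0, abs=1e-12)

    def test_zero_at_cutoff(self):
        spec = PairSpec()
        assert pair_force(spec, spec.cutoff) == 0.0
        assert pair_energy(spec, spec.cutoff) == 0.0

    def test_repulsive_below_minimum(self):
        spec = PairSpec()
        assert pair_force(spec, 2 ** (1 / 6) * spec.sigma * 0.98) > 0

    def test_attractive_between_minimum_and_cutoff(self):
        spec = PairSpec()
        assert pair_force(spec, 20.0) < 0

    def test_overlap_guard_caps_force(self):
        spec = PairSpec(max_force=100.0)
        assert pair_force(spec, 1.0) == 100.0

    def test_continuous_through_switching_region(self):
        spec = PairSpec()
        r = np.linspace(spec.switch_on * spec.cutoff - 1, spec.cutoff + 1, 2000)
        f = pair_force(spec, r)
        assert np.max(np.abs(np.diff(f))) < 0.05  # no jumps


class TestAssembledSystem:
    def test_straight_rest_fibril_zero_energy_without_pair(self, mini7_factory):
        _, topo = mini7_factory(0.0)
        ff = ForceField(pair=None)
        comps = fm.total_energy(topo, topo.positions, ff)
        assert comps["total"] == pytest.approx(0.0, abs=1e-9)
        assert comps["angle"] == pytest.approx(0.0, abs=1e-9)

    def test_decomposition_sums_exactly(self, mini7_factory):
        cfg, topo = mini7_factory(2.0)
        ff = cfg.build_forcefield()
        rng = np.random.default_rng(0)
        pos = topo.positions + rng.normal(0, 0.2, topo.positions.shape)
        comps = fm.total_energy(topo, pos, ff)
        assert comps["total"] == pytest.approx(
            comps["bond"] + comps["angle"] + comps["inter"], rel=1e-12
        )
        assert comps["bond"] == pytest.approx(
            comps["bond_collagen"] + comps["bond_age"] + comps["bond_strengthened"],
            rel=1e-12,
        )

    def test_single_stretched_age_isolated(self):
        cfg, topo = fm.make_fixture("single-bond")
        ff = cfg.build_forcefield()
        pos = topo.positions.copy()
        pos[2:, 2] += 3.0  # stretch only the cross-link
        comps = fm.total_energy(topo, pos, ff)
        assert comps["total"] == pytest.approx(
            bond_energy(GLUCOSEPANE, GLUCOSEPANE.r0 + 3.0), rel=1e-12
        )

    def test_forces_match_numeric_gradient(self, mini7_factory):
        cfg, topo = mini7_factory(2.0)
        ff = cfg.build_forcefield()
        sys_ = System(topo, ff, use_numba=False)
        rng = np.random.default_rng(1)
        pos = topo.positions + rng.normal(0, 0.3, topo.positions.shape)
        _, forces = sys_.evaluate(pos)
        h = 1e-6
        for i, d in [(3, 0), (57, 2), (120, 1), (222, 2)]:
            p1, p2 = pos.copy(), pos.copy()
            p1[i, d] += h
            p2[i, d] -= h
            num = -(sys_.evaluate(p1)[0]["total"] - sys_.evaluate(p2)[0]["total"]) / (2 * h)
            assert num == pytest.approx(forces[i, d], rel=1e-5, abs=1e-5)

    def test_compiled_kernel_matches_reference(self, mini7_factory):
        cfg, topo = mini7_factory(10.0)
        ff = cfg.build_forcefield()
        s_fast = System(topo, ff, use_numba=True)
        s_ref = System(topo, ff, use_numba=False)
        rng = np.random.default_rng(2)
        pos = topo.positions + rng.normal(0, 0.4, topo.positions.shape)
        c1, f1 = s_fast.evaluate(pos)
        c2, f2 = s_ref.evaluate(pos)
        for key in c1:
            assert c1[key] == pytest.approx(c2[key], rel=1e-9, abs=1e-9)
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_broken_bonds_contribute_nothing(self, mini7_factory):
        cfg, topo = mini7_factory(5.0)
        ff = cfg.build_forcefield()
        sys_ = System(topo, ff)
        before, _ = sys_.evaluate(topo.positions)
        sys_.broken[:] = False
        rows = np.nonzero(sys_.bond_family == 1)[0]
        sys_.broken[rows] = True
        after, _ = sys_.evaluate(topo.positions)
        assert after["bond_age"] == 0.0
        assert after["bond_collagen"] == pytest.approx(before["bond_collagen"])
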