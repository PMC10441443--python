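"""Fibril construction: chains, D-banding, stagger classes, cross-links."""

import numpy as np
import pytest

import fibrilmech as fm
from fibrilmech.geometry import (
    CrossLinkSet,
    FibrilSpec,
    TCMoleculeSpec,
    build_chain,
    build_fibril,
    gap_overlap_map,
    insert_crosslinks,
)


class TestBuildChain:
    def test_full_scale_span(self):
        # 218 equidistant beads at 14 Å span (218-1)*14 = 3038 Å ≈ 304 nm
        spec = TCMoleculeSpec(n_particles=218, spacing=14.0)
        pos, bonds = build_chain(spec)
        assert len(pos) == 218
        assert len(bonds) == 217
        np.testing.assert_allclose(pos[-1, 2] - pos[0, 2], 3038.0)

    def test_minimal_chain_single_bond(self):
        pos, bonds = build_chain(TCMoleculeSpec(n_particles=2))
        assert bonds == [(0, 1)]
        np.testing.assert_allclose(np.linalg.norm(pos[1] - pos[0]), 14.0)

    def test_axis_and_origin(self):
        spec = TCMoleculeSpec(n_particles=218)
        pos, _ = build_chain(spec, origin=(0, 0, 0), axis=(0, 0, 1))
        np.testing.assert_allclose(pos[-1], [0.0, 0.0, 3038.0])

    def test_non_unit_axis_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            build_chain(TCMoleculeSpec(), axis=(0, 0, 2))

    @pytest.mark.parametrize(
        "kwargs", [{"n_particles": 1}, {"spacing": -1.0}, {"crimp_ratio": 0.9}]
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TCMoleculeSpec(**kwargs)


class TestBuildFibril:
    def test_all_five_stagger_classes_present(self):
        _, topo = fm.make_fixture("mini-7")
        assert set(topo.site_stagger_class) == {0, 1, 2, 3, 4}

    def test_stagger_histogram_uniform(self):
        _, topo = fm.make_fixture("mini-19")
        counts = np.bincount(topo.site_stagger_class, minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_banding_period_matches_configured_d(self):
        cfg, topo = fm.make_fixture("mini-7")
        gm = gap_overlap_map(topo)
        assert gm.banding_period == pytest.approx(
            cfg.geometry.fibril.d_period, abs=1e-9
        )

    def test_gap_fraction_exact(self):
        _, topo = fm.make_fixture("mini-7")
        gm = gap_overlap_map(topo)
        assert gm.gap_fraction == 0.6

    def test_mean_gap_is_point_six_d(self):
        cfg, topo = fm.make_fixture("mini-7")
        gm = gap_overlap_map(topo)
        assert gm.mean_gap_length == pytest.approx(
            0.6 * cfg.geometry.fibril.d_period, rel=1e-9
        )

    def test_bonds_connect_consecutive_beads_of_one_chain(self):
        _, topo = fm.make_fixture("mini-7")
        assert np.all(topo.chain_index[topo.bond_i] == topo.chain_index[topo.bond_j])
        # consecutive in axial order: bond length equals the bead spacing
        lengths = np.linalg.norm(
            topo.positions[topo.bond_j] - topo.positions[topo.bond_i], axis=1
        )
        np.testing.assert_allclose(lengths, topo.spacing, atol=1e-9)

    def test_grip_groups_disjoint_nonempty(self):
        _, topo = fm.make_fixture("mini-7")
        assert len(topo.left_grip) and len(topo.right_grip)
        assert not set(topo.left_grip) & set(topo.right_grip)
        assert topo.is_extension[topo.left_grip].all()
        assert topo.is_extension[topo.right_grip].all()

    def test_too_small_cross_section_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            build_fibril(
                FibrilSpec(d_period=105.0, fibril_diameter=20.0,
                           end_extension_particles=4),
                TCMoleculeSpec(n_particles=34),
            )

    def test_rebuild_bit_identical(self):
        _, t1 = fm.make_fixture("mini-7", seed=3)
        _, t2 = fm.make_fixture("mini-7", seed=3)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.bond_i, t2.bond_i)
        np.testing.assert_array_equal(t1.bond_family, t2.bond_family)


class TestCrossLinks:
    def test_zero_density_empty(self):
        _, topo = fm.make_fixture("mini-7")
        out = insert_crosslinks(topo, CrossLinkSet(n_age=0.0, rng_seed=0))
        assert len(out.crosslinks) == 0

    def test_count_matches_round_rule(self):
        # round(N_AGE · n_molecules) whenever supply suffices
        _, topo = fm.make_fixture("mini-7")
        for n_age in (0.5, 2, 10):
            out = insert_crosslinks(topo, CrossLinkSet(n_age=n_age, rng_seed=0))
            assert len(out.crosslinks) == round(n_age * topo.n_molecules)

    def test_full_scale_count_oracle(self):
        # N_AGE = 2 on a 155-molecule section would give 310; the rule is
        # the same round() on whatever the section holds
        _, topo = fm.make_fixture("mini-19")
        out = insert_crosslinks(topo, CrossLinkSet(n_age=2.0, rng_seed=0))
        assert len(out.crosslinks) == 2 * topo.n_molecules

    def test_endpoints_on_distinct_chains(self):
        _, topo = fm.make_fixture("mini-7")
        out = insert_crosslinks(topo, CrossLinkSet(n_age=10, rng_seed=1))
        ci = out.chain_index
        assert np.all(ci[out.crosslinks[:, 0]] != ci[out.crosslinks[:, 1]])

    def test_no_duplicate_pairs(self):
        _, topo = fm.make_fixture("mini-7")
        out = insert_crosslinks(topo, CrossLinkSet(n_age=10, rng_seed=1))
        pairs = {tuple(p) for p in out.crosslinks}
        assert len(pairs) == len(out.crosslinks)

    def test_endpoints_within_central_95_percent(self):
        # exact assertion: no endpoint in the outer 2.5% of its chain
        _, topo = fm.make_fixture("mini-7")
        out = insert_crosslinks(topo, CrossLinkSet(n_age=10, rng_seed=2))
        for p in out.crosslinks.ravel():
            chain = out.chain_particles(int(out.chain_index[p]))
            chain = chain[~out.is_extension[chain]]
            k = int(np.nonzero(chain == p)[0][0])
            n = len(chain)
            assert k >= 0.025 * (n - 1) - 1e-12
            assert k <= 0.975 * (n - 1) + 1e-12

    def test_same_seed_identical_different_seed_differs(self):
        _, topo = fm.make_fixture("mini-7")
        a = insert_crosslinks(topo, CrossLinkSet(n_age=5, rng_seed=7))
        b = insert_crosslinks(topo, CrossLinkSet(n_age=5, rng_seed=7))
        c = insert_crosslinks(topo, CrossLinkSet(n_age=5, rng_seed=8))
        np.testing.assert_array_equal(a.crosslinks, b.crosslinks)
        assert not np.array_equal(a.crosslinks, c.crosslinks)

    def test_shortfall_warns_and_caps(self):
        _, topo = fm.make_fixture("mini-7")
        with pytest.warns(UserWarning, match="admissible"):
            out = insert_crosslinks(
                topo, CrossLinkSet(n_age=500, rng_seed=0)
            )
        assert 0 < len(out.crosslinks) < 500 * topo.n_molecules


class TestGapOverlapMap:
    def test_deformed_topology_rejected(self):
        _, topo = fm.make_fixture("mini-7")
        topo.positions = topo.positions * 1.05
        with pytest.raises(ValueError, match="deformed"):
            gap_overlap_map(topo)

    def test_single_chain_has_no_gaps(self):
        _, topo = fm.make_fixture("two-chain")
        gm = gap_overlap_map(topo)
        assert gm.n_gaps == 0
        assert np.isnan(gm.mean_gap_length)

    def test_gap_fraction_recovered_within_bin(self):
        cfg, topo = fm.make_fixture("mini-19")
        gm = gap_overlap_map(topo)
        bin_frac = 1.0 / (gm.bin_edges.size - 1)
        assert abs(gm.gap_fraction - 0.6) <= bin_frac + 1e-12
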