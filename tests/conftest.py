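"""Shared fixtures: cached desk-scale tensile runs and the parameter sweep.

The destructive tests are the expensive part of the suite, so every
trajectory is computed once per session and shared between the unit,
property and acceptance layers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import fibrilmech as fm
from fibrilmech.analysis import run_sweep
from fibrilmech.forcefield import age_spec
from fibrilmech.tensile import PullProtocol, run_tensile_test

SEED = 1

#: grid of the desk-scale regime sweep
SWEEP_K1 = [6.0, 12.0, 24.0]
SWEEP_RBREAK = [25.0, 35.0, 50.0]
SWEEP_N_AGE = [2.0, 10.0]


def _quiet_run(topo, ff, protocol, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_tensile_test(topo, ff, protocol, **kw)


@pytest.fixture(scope="session")
def mini7_factory():
    """Builds a fresh mini-7 topology with a given cross-link density."""

    def build(n_age: float = 0.0, seed: int = SEED):
        cfg, topo = fm.make_fixture("mini-7", seed=seed)
        if n_age > 0:
            topo = fm.insert_crosslinks(
                topo, fm.CrossLinkSet(n_age=n_age, rng_seed=seed)
            )
        return cfg, topo

    return build


@pytest.fixture(scope="session")
def destructive_protocol():
    return PullProtocol(strain_target=0.85)


@pytest.fixture(scope="session")
def glucosepane_runs(mini7_factory, destructive_protocol):
    """Mini-7 tensile tests with the reference cross-link at N_AGE 0, 2, 10."""
    runs = {}
    for n_age in (0, 2, 10):
        cfg, topo = mini7_factory(n_age)
        ff = cfg.build_forcefield()
        runs[n_age] = _quiet_run(topo, ff, destructive_protocol, seed=SEED)
    return runs


@pytest.fixture(scope="session")
def mini_sweep(mini7_factory, destructive_protocol):
    """The 3×3×2 (k1, rbreak, N_AGE) regime sweep on the mini-7 fibril."""
    cfg, topo = mini7_factory(0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_sweep(
            topo,
            cfg.build_forcefield(),
            destructive_protocol,
            SWEEP_K1,
            SWEEP_RBREAK,
            SWEEP_N_AGE,
            seed=SEED,
        )


@pytest.fixture(scope="session")
def extreme_cell_run(mini7_factory, destructive_protocol):
    """Highest density, highest loading-energy-capacity cell (N=40, k1=24,
    rbreak=60): the massive-TC-rupture corner of the parameter space."""
    cfg, topo = mini7_factory(40)
    ff = cfg.build_forcefield()
    ff.age = age_spec(k1=24.0, rbreak=60.0)
    return _quiet_run(topo, ff, destructive_protocol, seed=SEED)


@pytest.fixture(scope="session")
def single_bond_traj():
    """Quasistatic pull of the one-AGE oracle system past rupture."""
    cfg, topo = fm.make_fixture("single-bond")
    ff = cfg.build_forcefield()
    proto = PullProtocol(
        strain_target=0.85, displacement_increment=0.1, stop_fraction=0.0
    )
    return _quiet_run(topo, ff, proto)


@pytest.fixture(scope="session")
def stretch_chain_system():
    """One straight chain gripped at both ends, no pair term: every interior
    collagen bond stretches uniformly (the backbone-stretching oracle)."""
    from fibrilmech.forcefield import ForceField
    from fibrilmech.geometry import FAMILY_COLLAGEN, FAMILY_STRENGTHENED, FibrilTopology

    n, n_ext = 8, 3
    total = n + 2 * n_ext
    z = np.arange(total) * 14.0
    positions = np.column_stack([np.zeros(total), np.zeros(total), z])
    is_ext = np.zeros(total, dtype=bool)
    is_ext[:n_ext] = True
    is_ext[-n_ext:] = True
    fam = np.where(
        is_ext[:-1] | is_ext[1:], FAMILY_STRENGTHENED, FAMILY_COLLAGEN
    )
    topo = FibrilTopology(
        positions=positions,
        chain_index=np.zeros(total, dtype=int),
        is_extension=is_ext,
        bond_i=np.arange(total - 1),
        bond_j=np.arange(1, total),
        bond_family=fam,
        crosslinks=np.empty((0, 2), dtype=int),
        stagger_class=np.array([0]),
        left_grip=np.arange(n_ext),
        right_grip=np.arange(total - n_ext, total),
        d_period=(n - 1) * 14.0 / 4.4,
        gap_fraction=0.6,
        window_length=z[-n_ext - 1] - z[n_ext],
        line_period=5 * (n - 1) * 14.0 / 4.4,
        molecule_span=(n - 1) * 14.0,
        spacing=14.0,
        fibril_diameter=14.72,
        n_cross_section=1,
        n_bonds_per_molecule=n - 1,
    )
    ff = ForceField(pair=None)
    return topo, ff


@pytest.fixture(scope="session")
def stretch_chain_traj(stretch_chain_system):
    topo, ff = stretch_chain_system
    proto = PullProtocol(
        strain_target=0.30, displacement_increment=0.2, stop_fraction=0.0
    )
    return _quiet_run(topo, ff, proto)
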