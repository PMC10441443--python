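"""Named fixture presets: desk-scale fibrils and oracle micro-systems.

All presets preserve the structural ratios of the full-scale fibril (gap
fraction 0.6, stagger D, line period 5·D, grip extensions) while shrinking
molecule length and chain count so that a quasistatic destructive test runs
in seconds to minutes on one CPU:

``single-bond``
    Two 2-bead chains joined by one AGE cross-link, both chains gripped
    rigidly — the recorded force–extension curve is exactly the trilinear
    bond law (the oracle for the tensile machinery).
``two-chain``
    Two staggered, overlapping chains with grips on opposite ends; the
    minimal sliding/pull-out system.
``mini-7``
    7 chains (hexagon), 37 beads/molecule (D = span/4.4 ≈ 114.5 Å); the
    standard desk-scale fibril for sweeps.  The bead count is chosen so
    the stagger offsets are incommensurate with the bead spacing, which
    decoheres the slip avalanches of the five stagger classes.
``mini-19``
    19 chains, 48 beads/molecule, D ≈ 149.5 Å.
``full-scale``
    Full-scale geometry: D ≈ 670 Å (67 nm), fibril diameter 202 Å, 40-bead
    grips, 212 beads/molecule (the span consistent with the 0.6·D / 5·D
    banding at 14 Å bead spacing).

The mini presets scale the pair adhesion by the bead-count ratio relative
to full scale so that the strain at slip onset — the end of the linear
elastic regime — is preserved under molecule shortening (see
:func:`_scaled_pair_epsilon`).
"""

from __future__ import annotations

import numpy as np

from fibrilmech.config import (
    CrosslinkConfig,
    FibrilConfig,
    ForceFieldConfig,
    GeometryConfig,
    MoleculeConfig,
    PairConfig,
    ProtocolConfig,
    RunConfig,
)
from fibrilmech.geometry import (
    FAMILY_STRENGTHENED,
    FibrilTopology,
    TCMoleculeSpec,
    consistent_d_period,
)

PRESETS = ("single-bond", "two-chain", "mini-7", "mini-19", "full-scale")

#: beads per molecule of the full-scale fibril (the mini presets scale the
#: pair adhesion by the bead-count ratio, see :func:`_scaled_pair_epsilon`)
FULL_SCALE_BEADS = 212


def _fibril_geometry(n_particles: int, diameter: float, n_ext: int) -> GeometryConfig:
    mol = MoleculeConfig(n_particles=n_particles)
    d = consistent_d_period(TCMoleculeSpec(**mol.model_dump()))
    return GeometryConfig(
        molecule=mol,
        fibril=FibrilConfig(d_period=d, fibril_diameter=diameter,
                            end_extension_particles=n_ext),
    )


def _scaled_pair_epsilon(n_particles: int) -> float:
    """Pair well depth for a mini preset.

    The strain at which inter-molecular slip starts goes as the total static
    friction a molecule can mobilize along its contacts divided by its
    backbone stiffness, i.e. ∝ (beads per molecule)·ε_pair/(k0·r0).
    Shortening the molecules by a factor s therefore multiplies the pair
    well depth by s so that the desk-scale fibril leaves the linear regime
    at the same strain as the full-scale one.
    """
    return 6.87 * (FULL_SCALE_BEADS - 1) / (n_particles - 1)


def _preset_config(name: str, seed: int, n_age: float) -> RunConfig:
    geometry = {
        "mini-7": lambda: _fibril_geometry(37, 48.0, 6),
        "mini-19": lambda: _fibril_geometry(48, 82.0, 8),
        "full-scale": lambda: _fibril_geometry(FULL_SCALE_BEADS, 202.0, 40),
    }.get(name, GeometryConfig)()
    # the single-bond oracle isolates the trilinear law: no pair, no bending
    if name == "single-bond":
        forcefield = ForceFieldConfig(pair=None, angle=None)
    elif name in ("mini-7", "mini-19"):
        forcefield = ForceFieldConfig(
            pair=PairConfig(epsilon=_scaled_pair_epsilon(geometry.molecule.n_particles))
        )
    else:
        forcefield = ForceFieldConfig()
    if name == "single-bond":
        # pull the lone cross-link all the way through rupture
        protocol = ProtocolConfig(
            strain_target=0.85, displacement_increment=0.1, stop_fraction=0.0
        )
    else:
        protocol = ProtocolConfig()
    return RunConfig(
        preset=name,
        geometry=geometry,
        forcefield=forcefield,
        crosslinks=CrosslinkConfig(n_age=n_age, seed=seed),
        protocol=protocol,
    )


def _single_bond_topology() -> FibrilTopology:
    """Two rigid 2-bead chains bridged by one AGE cross-link at rest."""
    r0_age = 18.52
    z = np.array([0.0, 14.0, 14.0 + r0_age, 28.0 + r0_age])
    positions = np.column_stack([np.zeros(4), np.zeros(4), z])
    return FibrilTopology(
        positions=positions,
        chain_index=np.array([0, 0, 1, 1]),
        is_extension=np.array([True, True, True, True]),
        bond_i=np.array([0, 2]),
        bond_j=np.array([1, 3]),
        bond_family=np.array([FAMILY_STRENGTHENED, FAMILY_STRENGTHENED]),
        crosslinks=np.array([[1, 2]]),
        stagger_class=np.array([0, 0]),
        left_grip=np.array([0, 1]),
        right_grip=np.array([2, 3]),
        d_period=r0_age,
        gap_fraction=0.6,
        window_length=r0_age,
        line_period=5 * r0_age,
        molecule_span=14.0,
        spacing=14.0,
        fibril_diameter=14.72,
        n_cross_section=2,
        n_bonds_per_molecule=1,
        requested_n_age=0.5,
    )


def _two_chain_topology(n_beads: int = 16, n_ext: int = 4) -> FibrilTopology:
    """Two staggered chains with ~50 % axial overlap, gripped on opposite
    ends; the sliding partner of the single-bond oracle."""
    dz = 14.0
    a = 2 ** (1 / 6) * 14.72
    span = (n_beads - 1) * dz
    zA = np.concatenate([-dz * np.arange(n_ext, 0, -1), np.arange(n_beads) * dz])
    z0B = span / 2.0
    zB = z0B + np.concatenate([np.arange(n_beads) * dz, span + dz * np.arange(1, n_ext + 1)])
    nA, nB = len(zA), len(zB)
    positions = np.vstack(
        [
            np.column_stack([np.zeros(nA), np.zeros(nA), zA]),
            np.column_stack([np.full(nB, a), np.zeros(nB), zB]),
        ]
    )
    is_ext = np.zeros(nA + nB, dtype=bool)
    is_ext[:n_ext] = True
    is_ext[-n_ext:] = True
    bond_i, bond_j, fam = [], [], []
    for base, n in ((0, nA), (nA, nB)):
        for b in range(n - 1):
            bond_i.append(base + b)
            bond_j.append(base + b + 1)
            fam.append(
                FAMILY_STRENGTHENED
                if is_ext[base + b] or is_ext[base + b + 1]
                else 0
            )
    return FibrilTopology(
        positions=positions,
        chain_index=np.concatenate([np.zeros(nA, int), np.ones(nB, int)]),
        is_extension=is_ext,
        bond_i=np.array(bond_i),
        bond_j=np.array(bond_j),
        bond_family=np.array(fam),
        crosslinks=np.empty((0, 2), dtype=int),
        stagger_class=np.array([0, 2]),
        left_grip=np.arange(n_ext),
        right_grip=np.arange(nA + nB - n_ext, nA + nB),
        d_period=span / 4.4,
        gap_fraction=0.6,
        window_length=z0B + span,
        line_period=5 * span / 4.4,
        molecule_span=span,
        spacing=dz,
        fibril_diameter=2 * a + 14.72,
        n_cross_section=2,
        n_bonds_per_molecule=n_beads - 1,
    )


def make_fixture(
    name: str, seed: int = 0, n_age: float = 0.0
) -> tuple[RunConfig, FibrilTopology]:
    """Build a named preset: returns (config, deterministic topology).

    ``n_age`` sets the cross-link density for the fibril presets (ignored by
    the micro-presets, which carry their links explicitly).
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    cfg = _preset_config(name, seed, n_age)
    if name == "single-bond":
        return cfg, _single_bond_topology()
    if name == "two-chain":
        return cfg, _two_chain_topology()
    return cfg, cfg.build_topology()
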