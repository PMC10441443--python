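"""Displacement-controlled destructive tensile tests.

The two grips (strengthened end extensions of the fibril) are moved apart
symmetrically along the fibril axis.  Two protocols are available:

* ``quasistatic`` — the reference desk-scale protocol: each grip-displacement
  increment is followed by energy minimization of the free beads (L-BFGS with
  analytic gradients); bond breaking is resolved by alternating minimization
  with absorbing-state updates until no further bond fails.  Fully
  deterministic.
* ``dynamic`` — steered Langevin dynamics at constant pull velocity
  (reference value 0.0001 Å/fs = 10 m/s, Δt = 1 fs), the protocol of the
  full-scale simulations this model emulates.

Each recorded frame carries the grip force (converted to engineering stress
via the undeformed cross-section), the mean length and tension of the intact
collagen backbone bonds, and per-family intact/broken bond counts — the raw
series the analysis layer integrates into stretching/sliding energies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from fibrilmech import units
from fibrilmech.forcefield import ForceField, System
from fibrilmech.geometry import FibrilTopology


@dataclass(frozen=True)
class PullProtocol:
    """Loading protocol for a destructive tensile test.

    ``strain_target`` is the grip displacement divided by the initial
    grip-to-grip gauge length at which pulling stops (earlier if the fibril
    has failed: stress below ``stop_fraction`` of the running peak).
    """

    mode: str = "quasistatic"  # or "dynamic"
    velocity: float = 1.0e-4  # Å/fs, dynamic mode (0.0001 Å/fs = 10 m/s)
    timestep: float = 1.0  # fs
    strain_target: float = 0.6
    sample_interval: int = 1  # increments (quasistatic) or steps (dynamic)
    displacement_increment: float | None = None  # Å; default gauge/400
    minimizer_gtol: float = 1.0e-3
    minimizer_maxiter: int = 2000
    stop_fraction: float = 0.05
    temperature: float = 300.0  # K, dynamic mode
    damping: float = 1000.0  # fs, Langevin relaxation time
    mass: float = 1360.0  # g/mol per bead

    def __post_init__(self) -> None:
        if self.mode not in ("quasistatic", "dynamic"):
            raise ValueError("mode must be 'quasistatic' or 'dynamic'")
        if self.mode == "dynamic" and self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.displacement_increment is not None and self.displacement_increment <= 0:
            raise ValueError("displacement_increment must be positive")
        if self.strain_target <= 0:
            raise ValueError("strain_target must be positive")


@dataclass
class Trajectory:
    """Scalar per-frame record of one tensile test (plus optional snapshots)."""

    gauge_length: float
    diameter: float
    n_cross_section: int
    n_bonds_per_molecule: int
    r0_collagen: float
    mean_gap_initial: float
    strain: np.ndarray = field(default_factory=lambda: np.empty(0))
    displacement: np.ndarray = field(default_factory=lambda: np.empty(0))
    force: np.ndarray = field(default_factory=lambda: np.empty(0))
    stress: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_rtc: np.ndarray = field(default_factory=lambda: np.empty(0))
    f_stretch: np.ndarray = field(default_factory=lambda: np.empty(0))
    intact_collagen: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    intact_age: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    broken_collagen: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    broken_age: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_age_total: int = 0
    n_collagen_total: int = 0
    positions: list[np.ndarray] | None = None
    aborted: bool = False
    #: residual grip tension of the relaxed initial state, subtracted from
    #: every recorded force (load-cell tare); raw force = force + force_tare
    force_tare: float = 0.0

    @property
    def n_frames(self) -> int:
        return len(self.strain)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-frame table (strain, stress, forces, bond censuses)."""
        return pd.DataFrame(
            {
                "strain": self.strain,
                "displacement": self.displacement,
                "force": self.force,
                "stress": self.stress,
                "stress_mpa": self.stress * units.KCAL_MOL_A3_IN_MPA,
                "mean_rtc": self.mean_rtc,
                "f_stretch": self.f_stretch,
                "intact_collagen": self.intact_collagen,
                "intact_age": self.intact_age,
                "broken_collagen": self.broken_collagen,
                "broken_age": self.broken_age,
            }
        )


def engineering_stress(force: float | np.ndarray, diameter: float) -> float | np.ndarray:
    """σ = F / (π·d²/4) with d the undeformed fibril diameter."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return force / (math.pi * diameter * diameter / 4.0)


def detect_broken_bonds(traj: Trajectory, frame: int = -1) -> dict[str, int]:
    """Broken-bond counts per family at one trajectory frame."""
    return {
        "age": int(traj.broken_age[frame]),
        "collagen": int(traj.broken_collagen[frame]),
    }


class _Recorder:
    def __init__(self, topo: FibrilTopology, sys_: System, protocol: PullProtocol,
                 gauge: float, mean_gap: float, record_positions: bool):
        self.sys = sys_
        self.gauge = gauge
        #: load-cell tare: residual grip tension of the relaxed initial state
        self.tare = 0.0
        self.traj = Trajectory(
            gauge_length=gauge,
            diameter=topo.fibril_diameter,
            n_cross_section=topo.n_cross_section,
            n_bonds_per_molecule=topo.n_bonds_per_molecule,
            r0_collagen=sys_.ff.collagen.r0,
            mean_gap_initial=mean_gap,
            positions=[] if record_positions else None,
        )
        self.traj.n_age_total = len(topo.crosslinks)
        self.traj.n_collagen_total = int(
            (topo.bond_family == 0).sum()
        )
        self._rows: list[tuple] = []

    def record(self, positions: np.ndarray, displacement: float, force: float) -> None:
        rtc, fstr = self.sys.mean_collagen_bond(positions)
        intact = self.sys.intact_counts()
        broken = self.sys.broken_counts()
        force = force - self.tare
        self._rows.append(
            (
                displacement / self.gauge,
                displacement,
                force,
                engineering_stress(force, self.traj.diameter),
                rtc,
                fstr,
                intact["collagen"],
                intact["age"],
                broken["collagen"],
                broken["age"],
            )
        )
        if self.traj.positions is not None:
            self.traj.positions.append(positions.copy())

    def finalize(self, aborted: bool = False) -> Trajectory:
        cols = list(zip(*self._rows)) if self._rows else [[]] * 10
        t = self.traj
        t.strain = np.asarray(cols[0], dtype=float)
        t.displacement = np.asarray(cols[1], dtype=float)
        t.force = np.asarray(cols[2], dtype=float)
        t.stress = np.asarray(cols[3], dtype=float)
        t.mean_rtc = np.asarray(cols[4], dtype=float)
        t.f_stretch = np.asarray(cols[5], dtype=float)
        t.intact_collagen = np.asarray(cols[6], dtype=int)
        t.intact_age = np.asarray(cols[7], dtype=int)
        t.broken_collagen = np.asarray(cols[8], dtype=int)
        t.broken_age = np.asarray(cols[9], dtype=int)
        t.aborted = aborted
        t.force_tare = self.tare
        return t


def _grip_tension(forces: np.ndarray, left: np.ndarray, right: np.ndarray) -> float:
    """Axial tension carried by the grips: mean of the external holding
    forces (+z on the right grip, −z on the left)."""
    f_right = -forces[right, 2].sum()
    f_left = forces[left, 2].sum()
    return 0.5 * (f_right + f_left)


def run_tensile_test(
    topo: FibrilTopology,
    ff: ForceField,
    protocol: PullProtocol,
    seed: int = 0,
    record_positions: bool = False,
    system: System | None = None,
) -> Trajectory:
    """Pull the fibril apart and record the force/extension history.

    Grips move symmetrically (±Δ/2 along z).  Returns a :class:`Trajectory`;
    quasistatic mode is fully deterministic, dynamic mode is deterministic
    under a fixed ``seed`` (Langevin noise).
    """
    if len(topo.left_grip) == 0 or len(topo.right_grip) == 0:
        raise ValueError("topology must have two non-empty grips")
    sys_ = system if system is not None else System(topo, ff)
    from fibrilmech.geometry import gap_overlap_map

    try:
        mean_gap = gap_overlap_map(topo).mean_gap_length
    except ValueError:
        mean_gap = float("nan")
    gauge = topo.window_length
    rec = _Recorder(topo, sys_, protocol, gauge, mean_gap, record_positions)
    if protocol.mode == "quasistatic":
        return _run_quasistatic(topo, sys_, protocol, rec)
    return _run_dynamic(topo, sys_, protocol, rec, seed)


def _run_quasistatic(
    topo: FibrilTopology, sys_: System, protocol: PullProtocol, rec: _Recorder
) -> Trajectory:
    gauge = rec.gauge
    dinc = protocol.displacement_increment or gauge / 400.0
    n_steps = int(math.ceil(protocol.strain_target * gauge / dinc))
    positions = topo.positions.copy()
    left, right = topo.left_grip, topo.right_grip
    grip_mask = np.zeros(len(positions), dtype=bool)
    grip_mask[left] = True
    grip_mask[right] = True
    free = np.nonzero(~grip_mask)[0]

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        positions[free] = x.reshape(-1, 3)
        comps, forces = sys_.evaluate(positions)
        return comps["total"], -forces[free].ravel()

    # relax the initial state once; tare the residual grip tension
    _minimize_with_breaks(sys_, positions, free, objective, protocol)
    comps, forces = sys_.evaluate(positions)
    rec.tare = _grip_tension(forces, left, right)
    rec.record(positions, 0.0, rec.tare)

    peak_stress = 0.0
    for step in range(1, n_steps + 1):
        positions[left, 2] -= dinc / 2.0
        positions[right, 2] += dinc / 2.0
        ok = _minimize_with_breaks(sys_, positions, free, objective, protocol)
        comps, forces = sys_.evaluate(positions)
        if not ok or not np.isfinite(forces).all():
            rec.record(positions, step * dinc, float("nan"))
            return rec.finalize(aborted=True)
        if step % protocol.sample_interval == 0 or step == n_steps:
            tension = _grip_tension(forces, left, right)
            rec.record(positions, step * dinc, tension)
            stress = engineering_stress(tension - rec.tare, topo.fibril_diameter)
            peak_stress = max(peak_stress, stress)
            if (protocol.stop_fraction > 0 and step * dinc / gauge > 0.02
                    and peak_stress > 0
                    and stress < protocol.stop_fraction * peak_stress):
                break
    return rec.finalize()


def _minimize_with_breaks(
    sys_: System,
    positions: np.ndarray,
    free: np.ndarray,
    objective,
    protocol: PullProtocol,
    max_cycles: int = 40,
) -> bool:
    """Minimize the free-bead energy, then absorb newly broken bonds and
    re-minimize until the broken set is stable."""
    if len(free) == 0:  # fully gripped system (oracle presets)
        for _ in range(max_cycles):
            if sys_.update_bond_states(positions) == 0:
                return True
        return True
    for _ in range(max_cycles):
        res = minimize(
            objective,
            positions[free].ravel(),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": protocol.minimizer_maxiter,
                "gtol": protocol.minimizer_gtol,
                "ftol": 1e-12,
            },
        )
        positions[free] = res.x.reshape(-1, 3)
        if not np.isfinite(res.fun):
            return False
        if sys_.update_bond_states(positions) == 0:
            if not res.success and res.status != 1:  # status 1 = maxiter
                warnings.warn(f"minimizer did not fully converge: {res.message}")
            return True
    warnings.warn("bond-breaking cascade did not settle within max_cycles")
    return True


def _run_dynamic(
    topo: FibrilTopology, sys_: System, protocol: PullProtocol, rec: _Recorder,
    seed: int,
) -> Trajectory:
    rng = np.random.default_rng(seed)
    gauge = rec.gauge
    positions = topo.positions.copy()
    left, right = topo.left_grip, topo.right_grip
    grip_mask = np.zeros(len(positions), dtype=bool)
    grip_mask[left] = True
    grip_mask[right] = True
    free = ~grip_mask

    n_steps = int(math.ceil(protocol.strain_target * gauge / (protocol.velocity * protocol.timestep)))
    dt = protocol.timestep
    m = protocol.mass
    kT = units.KB_KCAL_MOL_K * protocol.temperature
    gamma = 1.0 / protocol.damping
    c1 = math.exp(-gamma * dt)
    # velocities in Å/fs; thermal sigma = sqrt(kT/m · MVV2E)
    sigma_v = math.sqrt(units.FORCE_MASS_TO_ACCEL * kT / m) if protocol.temperature > 0 else 0.0
    c2 = sigma_v * math.sqrt(1.0 - c1 * c1)
    vel = np.zeros_like(positions)
    if protocol.temperature > 0:
        vel[free] = rng.normal(0.0, sigma_v, size=vel[free].shape)
    _, forces = sys_.evaluate(positions)
    acc = units.FORCE_MASS_TO_ACCEL * forces / m

    peak_stress = 0.0
    half = 0.5 * protocol.velocity
    for step in range(1, n_steps + 1):
        # BAOAB Langevin splitting for free beads; grips move at ±v/2
        vel[free] += 0.5 * dt * acc[free]
        positions[free] += 0.5 * dt * vel[free]
        if protocol.temperature > 0:
            vel[free] = c1 * vel[free] + c2 * rng.standard_normal(vel[free].shape)
        positions[free] += 0.5 * dt * vel[free]
        positions[left, 2] -= half * dt
        positions[right, 2] += half * dt
        sys_.update_bond_states(positions)
        _, forces = sys_.evaluate(positions)
        if not np.isfinite(forces).all():
            rec.record(positions, step * protocol.velocity * dt, float("nan"))
            return rec.finalize(aborted=True)
        acc = units.FORCE_MASS_TO_ACCEL * forces / m
        vel[free] += 0.5 * dt * acc[free]
        if step % protocol.sample_interval == 0 or step == n_steps:
            tension = _grip_tension(forces, left, right)
            rec.record(positions, step * protocol.velocity * dt, tension)
            stress = engineering_stress(tension, topo.fibril_diameter)
            peak_stress = max(peak_stress, stress)
            if protocol.stop_fraction > 0 and peak_stress > 0 \
                    and stress < protocol.stop_fraction * peak_stress \
                    and step * protocol.velocity * dt / gauge > 0.05:
                break
    return rec.finalize()
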