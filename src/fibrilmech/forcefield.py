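"""Trilinear breakable bonds, dispersive pair forces, bending, and energies.

The total potential energy of the model decomposes as

    E_total = E_bond + E_angle + E_inter,

with E_bond split by bond family into collagen backbone bonds, strengthened
grip bonds and AGE cross-links.  Every bond family obeys the same trilinear,
breakable force law: linear with stiffness k0 up to the critical hyperelastic
distance r1, then stiffness k1 up to the breaking distance rbreak, then a
regularized linear decay of the force to zero over a width a = z·(rbreak − r1).
Once a bond has been stretched past rbreak + a it is broken for good and never
transmits force again.

The energy a bond absorbs from equilibrium to its breaking point,

    W = k0/2·(r1 − r0)² + k0·(r1 − r0)·(rbreak − r1) + k1/2·(rbreak − r1)²,

is the loading energy capacity — the single descriptor that combines stiffness
and strength of a cross-link.  Balancing the capacity of a TC bond against the
total capacity of its attached cross-links yields the stiffening criterion:
the fibril switches from sliding-governed to TC-deformation-governed response
when W_TC < N_AGE · W_AGE.

Pair interactions are a 12-6 dispersive potential with CHARMM-style potential
switching so the force vanishes exactly at the minimum and goes continuously
to zero at the cutoff.  Bending is a cosine angle term, E = 2·k·(1 + cos θ),
which matches a harmonic k·(θ − π)² near the straight configuration of the
coarse-grained chains without the sin θ singularity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from fibrilmech.geometry import (
    FAMILY_AGE,
    FAMILY_COLLAGEN,
    FAMILY_STRENGTHENED,
    FibrilTopology,
)


class BondState(enum.IntEnum):
    """Life-cycle of a breakable bond. ``BROKEN`` is absorbing."""

    INTACT = 0
    SOFTENING = 1
    BROKEN = 2


class Regime(str, enum.Enum):
    SLIDING = "sliding-governed"
    TC_DEFORMATION = "TC-deformation-governed"


@dataclass(frozen=True)
class TrilinearBondSpec:
    """Parameters (r0, r1, rbreak, k0, k1, z) of one trilinear bond family.

    Lengths in Å, stiffnesses in kcal/mol/Å².  The regularization width is
    a = z·(rbreak − r1).
    """

    r0: float
    r1: float
    rbreak: float
    k0: float
    k1: float
    z: float = 0.1

    def __post_init__(self) -> None:
        if not (self.r0 <= self.r1 <= self.rbreak):
            raise ValueError("require r0 <= r1 <= rbreak")
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("stiffnesses must be positive")
        if self.z <= 0:
            raise ValueError("regularization factor z must be positive")

    @property
    def a(self) -> float:
        """Width of the post-rbreak force decay, Å."""
        return self.z * (self.rbreak - self.r1)

    @property
    def peak_force(self) -> float:
        """Force at rbreak: k0·(r1 − r0) + k1·(rbreak − r1)."""
        return self.k0 * (self.r1 - self.r0) + self.k1 * (self.rbreak - self.r1)


#: glucosepane reference cross-link (Table parameters of the AGE family)
GLUCOSEPANE = TrilinearBondSpec(r0=18.52, r1=22.72, rbreak=31.72, k0=0.1, k1=8.0, z=0.1)


def age_spec(k1: float = 8.0, rbreak: float = 31.72, z: float = 0.1) -> TrilinearBondSpec:
    """AGE cross-link spec with the standard r0/r1/k0 and variable k1, rbreak."""
    return TrilinearBondSpec(r0=18.52, r1=22.72, rbreak=rbreak, k0=0.1, k1=k1, z=z)


#: collagen backbone bond — literature coarse-grain values (config-overridable)
COLLAGEN_BOND = TrilinearBondSpec(r0=14.0, r1=18.2, rbreak=21.0, k0=17.13, k1=97.66, z=0.1)

#: strengthened grip bond: collagen stiffness, rupture pushed out of reach
STRENGTHENED_BOND = TrilinearBondSpec(r0=14.0, r1=1.0e5, rbreak=1.0e6, k0=17.13, k1=17.13, z=0.1)


@dataclass(frozen=True)
class PairSpec:
    """Dispersive 12-6 pair interaction with potential switching.

    σ in Å, ε in kcal/mol.  The potential is multiplied by a smoothstep that
    is 1 below ``switch_on``·cutoff and 0 at the cutoff, so force and energy
    vanish continuously there.  ``max_force`` caps the repulsion at extreme
    overlap.
    """

    sigma: float = 14.72
    epsilon: float = 6.87
    cutoff: float = 36.8
    switch_on: float = 0.9
    max_force: float = 1.0e4

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.cutoff < 2 ** (1 / 6) * self.sigma:
            raise ValueError("cutoff must be at least the potential minimum 2^(1/6)·sigma")
        if not (0.0 < self.switch_on < 1.0):
            raise ValueError("switch_on must be in (0, 1)")


@dataclass(frozen=True)
class AngleSpec:
    """Bending term with equilibrium angle ``theta0`` (rad).

    ``theta0=None`` (default) uses the *native* angles of the built topology
    as the per-triplet equilibria, so a crimped molecule is stress-free as
    constructed and resists straightening with stiffness ``k_bend``
    (kcal/mol/rad²).  Near-straight equilibria use the cosine form
    E = 2·k_bend·(1 + cos θ) — equal to the harmonic k_bend·(θ − π)² close
    to π but free of the sin θ singularity; kinked equilibria use the
    harmonic form E = k_bend·(θ − θ0)².
    """

    k_bend: float = 14.98
    theta0: float | None = None

    def __post_init__(self) -> None:
        if self.k_bend < 0:
            raise ValueError("k_bend must be >= 0")
        if self.theta0 is not None and not (0.0 < self.theta0 <= np.pi):
            raise ValueError("theta0 must be in (0, π]")


# ---------------------------------------------------------------------------
# trilinear bond law
# ---------------------------------------------------------------------------

def _trilinear_tension(spec: TrilinearBondSpec, r: np.ndarray) -> np.ndarray:
    """Tension magnitude of an intact trilinear bond (vectorized).

    Positive = restoring pull for r > r0 (negative below r0 = compression
    pushback via the first branch).
    """
    r = np.asarray(r, dtype=float)
    a = spec.a
    fpk = spec.peak_force
    t = np.empty_like(r)
    b1 = r < spec.r1
    b2 = (~b1) & (r < spec.rbreak)
    b3 = (~b1) & (~b2) & (r < spec.rbreak + a) if a > 0 else np.zeros_like(b1)
    t[b1] = spec.k0 * (r[b1] - spec.r0)
    t[b2] = spec.k0 * (spec.r1 - spec.r0) + spec.k1 * (r[b2] - spec.r1)
    if a > 0:
        t[b3] = fpk * (1.0 - (r[b3] - spec.rbreak) / a)
    t[r >= spec.rbreak + a] = 0.0
    return t


def _trilinear_energy(spec: TrilinearBondSpec, r: np.ndarray) -> np.ndarray:
    """Potential of an intact trilinear bond, zero at r0 (vectorized)."""
    r = np.asarray(r, dtype=float)
    a = spec.a
    f1 = spec.k0 * (spec.r1 - spec.r0)
    w = loading_energy_capacity(spec)
    fpk = spec.peak_force
    e = np.empty_like(r)
    b1 = r < spec.r1
    b2 = (~b1) & (r < spec.rbreak)
    b3 = (~b1) & (~b2) & (r < spec.rbreak + a) if a > 0 else np.zeros_like(b1)
    e[b1] = 0.5 * spec.k0 * (r[b1] - spec.r0) ** 2
    d2 = r[b2] - spec.r1
    e[b2] = 0.5 * spec.k0 * (spec.r1 - spec.r0) ** 2 + f1 * d2 + 0.5 * spec.k1 * d2**2
    if a > 0:
        d3 = r[b3] - spec.rbreak
        e[b3] = w + fpk * d3 - fpk * d3**2 / (2.0 * a)
    e[r >= spec.rbreak + a] = w + 0.5 * fpk * a
    return e


def bond_force(
    spec: TrilinearBondSpec, r: float, state: BondState = BondState.INTACT
) -> tuple[float, BondState]:
    """Signed tension of one bond at separation ``r`` plus its updated state.

    A broken bond stays broken and transmits nothing; reaching
    r ≥ rbreak + a breaks the bond irreversibly.
    """
    if r <= 0:
        raise ValueError("separation must be positive")
    if state == BondState.BROKEN:
        return 0.0, BondState.BROKEN
    if r >= spec.rbreak + spec.a:
        return 0.0, BondState.BROKEN
    new_state = BondState.SOFTENING if r >= spec.rbreak else state
    return float(_trilinear_tension(spec, np.array([r]))[0]), new_state


def bond_energy(spec: TrilinearBondSpec, r: float, state: BondState = BondState.INTACT) -> float:
    """Stored energy of one bond at separation ``r`` (0 if broken)."""
    if state == BondState.BROKEN:
        return 0.0
    return float(_trilinear_energy(spec, np.array([r]))[0])


def loading_energy_capacity(spec: TrilinearBondSpec) -> float:
    """Energy absorbed from equilibrium to the breaking point,
    W = k0/2(r1−r0)² + k0(r1−r0)(rbreak−r1) + k1/2(rbreak−r1)²."""
    d1 = spec.r1 - spec.r0
    d2 = spec.rbreak - spec.r1
    return 0.5 * spec.k0 * d1 * d1 + spec.k0 * d1 * d2 + 0.5 * spec.k1 * d2 * d2


def stiffening_criterion(w_tc: float, w_age: float, n_age: float) -> Regime:
    """Energy-capacity balance between a TC bond and its attached cross-links.

    TC-deformation-governed (stiffening) iff W_TC < N_AGE·W_AGE, strictly;
    the boundary case classifies as sliding-governed.
    """
    if min(w_tc, w_age, n_age) < 0:
        raise ValueError("inputs must be non-negative")
    return Regime.TC_DEFORMATION if w_tc < n_age * w_age else Regime.SLIDING


# ---------------------------------------------------------------------------
# pair interaction
# ---------------------------------------------------------------------------

def _switch(spec: PairSpec, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smoothstep S(r) and S'(r): 1 below r_on, 0 at the cutoff."""
    r_on = spec.switch_on * spec.cutoff
    width = spec.cutoff - r_on
    s = np.clip((r - r_on) / width, 0.0, 1.0)
    S = 1.0 - s * s * (3.0 - 2.0 * s)
    dS = -6.0 * s * (1.0 - s) / width
    return S, dS


def _lj(spec: PairSpec, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plain 12-6 potential and its tension −dΦ/dr... returns (Φ, F_mag)."""
    sr6 = (spec.sigma / r) ** 6
    phi = 4.0 * spec.epsilon * (sr6 * sr6 - sr6)
    fmag = 24.0 * spec.epsilon * (2.0 * sr6 * sr6 - sr6) / r  # −dΦ/dr
    return phi, fmag


def pair_energy(spec: PairSpec, r: float | np.ndarray) -> float | np.ndarray:
    """Switched pair potential; exactly zero at and beyond the cutoff."""
    scalar = np.isscalar(r)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    phi, _ = _lj(spec, r)
    S, _ = _switch(spec, r)
    out = np.where(r < spec.cutoff, phi * S, 0.0)
    return float(out[0]) if scalar else out


def pair_force(spec: PairSpec, r: float | np.ndarray) -> float | np.ndarray:
    """Signed pair force magnitude −dΦ_switched/dr (positive = repulsive is
    negative sign convention: this returns −dΦ/dr, i.e. > 0 means repulsion).

    Capped at ``max_force`` as an overlap guard; exactly zero at the
    potential minimum (inside the switching region start) and at the cutoff.
    """
    scalar = np.isscalar(r)
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    phi, fmag = _lj(spec, r)
    S, dS = _switch(spec, r)
    f = fmag * S - phi * dS  # −d(Φ·S)/dr
    f = np.where(r < spec.cutoff, f, 0.0)
    f = np.clip(f, -spec.max_force, spec.max_force)
    return float(f[0]) if scalar else f


# ---------------------------------------------------------------------------
# force field container and assembled energies/forces
# ---------------------------------------------------------------------------

@dataclass
class ForceField:
    """Bond-family parameters plus pair and angle terms for one model."""

    collagen: TrilinearBondSpec = field(default_factory=lambda: COLLAGEN_BOND)
    age: TrilinearBondSpec = field(default_factory=lambda: GLUCOSEPANE)
    strengthened: TrilinearBondSpec = field(default_factory=lambda: STRENGTHENED_BOND)
    pair: PairSpec | None = field(default_factory=PairSpec)
    angle: AngleSpec | None = field(default_factory=AngleSpec)

    def family_spec(self, family: int) -> TrilinearBondSpec:
        return {
            FAMILY_COLLAGEN: self.collagen,
            FAMILY_AGE: self.age,
            FAMILY_STRENGTHENED: self.strengthened,
        }[family]

    def tabulated_force_curve(
        self, family: int, n: int = 500, r_max: float | None = None
    ) -> np.ndarray:
        """Two-column (r, tension) table of the trilinear law, e.g. for
        external tabulated-bond interop."""
        spec = self.family_spec(family)
        if r_max is None:
            r_max = spec.rbreak + spec.a * 1.5
        r = np.linspace(max(1e-6, spec.r0 * 0.5), r_max, n)
        return np.column_stack([r, _trilinear_tension(spec, r)])


class System:
    """Precompiled interaction lists for a topology + force field.

    Holds the immutable index arrays (bonds incl. cross-links, angle
    triplets, pair exclusions) and the mutable broken-bond flags; evaluates
    total energy and forces for arbitrary positions.  A compiled kernel
    (:mod:`fibrilmech._kernels`) is used when available; the vectorized
    numpy path is the reference implementation (``use_numba=False``).
    """

    def __init__(self, topo: FibrilTopology, ff: ForceField, use_numba: bool = True):
        self.topo = topo
        self.ff = ff
        self.use_numba = use_numba
        if use_numba:
            try:
                from fibrilmech._kernels import evaluate_kernel

                self._kernel = evaluate_kernel
            except ImportError:  # pragma: no cover
                self.use_numba = False
                self._kernel = None
        else:
            self._kernel = None
        nb = len(topo.bond_i)
        ncl = len(topo.crosslinks)
        self.bond_i = np.concatenate([topo.bond_i, topo.crosslinks[:, 0]]).astype(int)
        self.bond_j = np.concatenate([topo.bond_j, topo.crosslinks[:, 1]]).astype(int)
        self.bond_family = np.concatenate(
            [topo.bond_family, np.full(ncl, FAMILY_AGE, dtype=int)]
        )
        self.n_bonds = nb + ncl
        self.broken = np.zeros(self.n_bonds, dtype=bool)
        self.softening = np.zeros(self.n_bonds, dtype=bool)
        self.max_extension = np.zeros(self.n_bonds)
        # per-family index groups (static)
        self._family_rows = {
            fam: np.nonzero(self.bond_family == fam)[0]
            for fam in (FAMILY_COLLAGEN, FAMILY_AGE, FAMILY_STRENGTHENED)
        }
        # angle triplets: consecutive beads of one chain
        trips = []
        for c in range(topo.n_chains):
            idx = topo.chain_particles(c)
            if len(idx) >= 3:
                trips.append(np.column_stack([idx[:-2], idx[1:-1], idx[2:]]))
        self.angles = np.vstack(trips) if trips else np.empty((0, 3), dtype=int)
        # pair exclusions: 1-2 (all bonds incl. cross-links) and 1-3 (angles)
        excl = set()
        for i, j in zip(self.bond_i, self.bond_j):
            excl.add((min(i, j), max(i, j)))
        for i, _, k in self.angles:
            excl.add((min(i, k), max(i, k)))
        self._excluded = excl
        self._pair_list: np.ndarray | None = None
        self._pair_ref_positions: np.ndarray | None = None
        self._skin = 4.0
        # per-family trilinear parameter tables for the compiled kernel
        fams = [self.ff.family_spec(f) for f in (FAMILY_COLLAGEN, FAMILY_AGE,
                                                 FAMILY_STRENGTHENED)]
        self._p_r0 = np.array([s.r0 for s in fams])
        self._p_r1 = np.array([s.r1 for s in fams])
        self._p_rbreak = np.array([s.rbreak for s in fams])
        self._p_k0 = np.array([s.k0 for s in fams])
        self._p_k1 = np.array([s.k1 for s in fams])
        self._p_a = np.array([s.a for s in fams])
        self._angle_i = self.angles[:, 0].astype(np.int64)
        self._angle_j = self.angles[:, 1].astype(np.int64)
        self._angle_k = self.angles[:, 2].astype(np.int64)
        # per-angle equilibrium: native (as-built) angles, or the scalar θ0
        if ff.angle is not None and len(self.angles):
            if ff.angle.theta0 is None:
                self._theta0 = self._measure_angles(topo.positions)
            else:
                self._theta0 = np.full(len(self.angles), float(ff.angle.theta0))
        else:
            self._theta0 = np.empty(0)

    def _measure_angles(self, positions: np.ndarray) -> np.ndarray:
        a = positions[self._angle_i] - positions[self._angle_j]
        b = positions[self._angle_k] - positions[self._angle_j]
        cos = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        return np.arccos(np.clip(cos, -1.0, 1.0))

    # -- neighbor list ------------------------------------------------------
    def _ensure_pairs(self, positions: np.ndarray) -> np.ndarray:
        if self.ff.pair is None:
            return np.empty((0, 2), dtype=int)
        rebuild = self._pair_list is None
        if not rebuild:
            disp = np.abs(positions - self._pair_ref_positions).max()
            rebuild = disp > 0.5 * self._skin
        if rebuild:
            from scipy.spatial import cKDTree

            tree = cKDTree(positions)
            pairs = tree.query_pairs(
                r=self.ff.pair.cutoff + self._skin, output_type="ndarray"
            )
            if len(pairs):
                keep = np.array(
                    [
                        (min(i, j), max(i, j)) not in self._excluded
                        for i, j in pairs
                    ]
                )
                pairs = pairs[keep]
            self._pair_list = pairs
            self._pair_ref_positions = positions.copy()
        return self._pair_list

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, positions: np.ndarray) -> tuple[dict[str, float], np.ndarray]:
        """Return (energy components, forces (N,3)) at ``positions``.

        Broken bonds contribute nothing.  Components: ``bond_collagen``,
        ``bond_age``, ``bond_strengthened``, ``angle``, ``inter``, ``total``.
        """
        if self.use_numba:
            return self._evaluate_compiled(positions)
        return self._evaluate_numpy(positions)

    def _evaluate_compiled(self, positions: np.ndarray) -> tuple[dict[str, float], np.ndarray]:
        pair = self.ff.pair
        pairs = self._ensure_pairs(positions)
        angle = self.ff.angle
        kb = angle.k_bend if angle is not None else 0.0
        ec, ea, es, e_angle, e_pair, forces = self._kernel(
            np.ascontiguousarray(positions),
            self.bond_i,
            self.bond_j,
            self.bond_family,
            self.broken,
            self._p_r0, self._p_r1, self._p_rbreak,
            self._p_k0, self._p_k1, self._p_a,
            self._angle_i, self._angle_j, self._angle_k,
            kb, self._theta0,
            pairs[:, 0].astype(np.int64) if len(pairs) else np.empty(0, np.int64),
            pairs[:, 1].astype(np.int64) if len(pairs) else np.empty(0, np.int64),
            pair.sigma if pair else 1.0,
            pair.epsilon if pair else 0.0,
            pair.cutoff if pair else 1.0,
            (pair.switch_on * pair.cutoff) if pair else 0.5,
            pair.max_force if pair else 1.0,
            pair is not None,
        )
        comps = {
            "bond_collagen": ec, "bond_age": ea, "bond_strengthened": es,
            "angle": e_angle, "inter": e_pair,
        }
        comps["bond"] = ec + ea + es
        comps["total"] = comps["bond"] + e_angle + e_pair
        return comps, forces

    def _evaluate_numpy(self, positions: np.ndarray) -> tuple[dict[str, float], np.ndarray]:
        forces = np.zeros_like(positions)
        comps = {"bond_collagen": 0.0, "bond_age": 0.0, "bond_strengthened": 0.0,
                 "angle": 0.0, "inter": 0.0}

        d = positions[self.bond_j] - positions[self.bond_i]
        r = np.linalg.norm(d, axis=1)
        for fam, key in ((FAMILY_COLLAGEN, "bond_collagen"),
                         (FAMILY_AGE, "bond_age"),
                         (FAMILY_STRENGTHENED, "bond_strengthened")):
            rows = self._family_rows[fam]
            if not len(rows):
                continue
            live = rows[~self.broken[rows]]
            if not len(live):
                continue
            spec = self.ff.family_spec(fam)
            rl = r[live]
            comps[key] += float(_trilinear_energy(spec, rl).sum())
            t = _trilinear_tension(spec, rl)
            u = d[live] / rl[:, None]
            fvec = t[:, None] * u  # force on i toward j
            np.add.at(forces, self.bond_i[live], fvec)
            np.add.at(forces, self.bond_j[live], -fvec)

        if self.ff.angle is not None and self.ff.angle.k_bend > 0 and len(self.angles):
            i, j, kk = self.angles.T
            a = positions[i] - positions[j]
            b = positions[kk] - positions[j]
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            cos = np.einsum("ij,ij->i", a, b) / (na * nb)
            cos = np.clip(cos, -1.0, 1.0)
            kb = self.ff.angle.k_bend
            theta0 = self._theta0
            near_pi = np.abs(theta0 - np.pi) < 1e-9
            theta = np.arccos(cos)
            sin = np.sqrt(np.maximum(1.0 - cos * cos, 1e-12))
            # cosine form at straight equilibria, harmonic at kinked ones
            e_ang = np.where(
                near_pi, 2.0 * kb * (1.0 + cos), kb * (theta - theta0) ** 2
            )
            comps["angle"] += float(e_ang.sum())
            decos = np.where(
                near_pi, 2.0 * kb, -2.0 * kb * (theta - theta0) / sin
            )
            # grad of cos wrt a: b/(na nb) − cos·a/na²
            ga = decos[:, None] * (
                b / (na * nb)[:, None] - cos[:, None] * a / (na * na)[:, None]
            )
            gb = decos[:, None] * (
                a / (na * nb)[:, None] - cos[:, None] * b / (nb * nb)[:, None]
            )
            np.add.at(forces, i, -ga)
            np.add.at(forces, kk, -gb)
            np.add.at(forces, j, ga + gb)

        if self.ff.pair is not None:
            pairs = self._ensure_pairs(positions)
            if len(pairs):
                dp = positions[pairs[:, 1]] - positions[pairs[:, 0]]
                rp = np.linalg.norm(dp, axis=1)
                within = rp < self.ff.pair.cutoff
                dp, rp = dp[within], rp[within]
                pi = pairs[within, 0]
                pj = pairs[within, 1]
                if len(rp):
                    comps["inter"] += float(np.sum(pair_energy(self.ff.pair, rp)))
                    f = pair_force(self.ff.pair, rp)  # −dΦ/dr; >0 repulsive
                    u = dp / rp[:, None]
                    fvec = f[:, None] * u  # force on j
                    np.add.at(forces, pj, fvec)
                    np.add.at(forces, pi, -fvec)

        comps["bond"] = comps["bond_collagen"] + comps["bond_age"] + comps["bond_strengthened"]
        comps["total"] = comps["bond"] + comps["angle"] + comps["inter"]
        return comps, forces

    def update_bond_states(self, positions: np.ndarray) -> int:
        """Mark bonds past rbreak + a as broken (absorbing); track softening
        and max extension.  Returns the number of newly broken bonds."""
        d = positions[self.bond_j] - positions[self.bond_i]
        r = np.linalg.norm(d, axis=1)
        self.max_extension = np.maximum(self.max_extension, r)
        newly = 0
        for fam, rows in self._family_rows.items():
            if not len(rows):
                continue
            spec = self.ff.family_spec(fam)
            rr = r[rows]
            soft = rr >= spec.rbreak
            self.softening[rows] |= soft & ~self.broken[rows]
            gone = (rr >= spec.rbreak + spec.a) & ~self.broken[rows]
            newly += int(gone.sum())
            self.broken[rows] |= gone
        return newly

    def broken_counts(self) -> dict[str, int]:
        return {
            FAMILY_NAMES_SHORT[fam]: int(self.broken[rows].sum())
            for fam, rows in self._family_rows.items()
        }

    def intact_counts(self) -> dict[str, int]:
        return {
            FAMILY_NAMES_SHORT[fam]: int((~self.broken[rows]).sum())
            for fam, rows in self._family_rows.items()
        }

    def mean_collagen_bond(self, positions: np.ndarray) -> tuple[float, float]:
        """(mean length, mean tension) over intact collagen backbone bonds."""
        rows = self._family_rows[FAMILY_COLLAGEN]
        live = rows[~self.broken[rows]]
        if not len(live):
            return float("nan"), 0.0
        d = positions[self.bond_j[live]] - positions[self.bond_i[live]]
        r = np.linalg.norm(d, axis=1)
        t = _trilinear_tension(self.ff.collagen, r)
        return float(r.mean()), float(t.mean())


FAMILY_NAMES_SHORT = {FAMILY_COLLAGEN: "collagen", FAMILY_AGE: "age",
                      FAMILY_STRENGTHENED: "strengthened"}


def total_energy(
    topo: FibrilTopology,
    positions: np.ndarray,
    ff: ForceField,
    system: System | None = None,
) -> dict[str, float]:
    """Energy decomposition E_total = E_bond + E_angle + E_inter at given
    positions (convenience wrapper around :class:`System`)."""
    sys_ = system if system is not None else System(topo, ff)
    comps, _ = sys_.evaluate(np.asarray(positions, dtype=float))
    return comps
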