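"""Construction of the D-banded collagen fibril and AGE cross-link insertion.

The fibril follows the Hodge–Petruska picture of collagen type I: tropocollagen
(TC) molecules, coarse-grained as straight bead chains with one bead every
``spacing`` Å, are packed on a transverse hexagonal lattice and staggered
axially by one D-period (67 nm at full scale) between the five stagger classes.
Successive molecules of one filament line tile with period 5·D, leaving an
inter-molecular gap of ≈0.6·D; the superposition of the five stagger classes
then produces the characteristic axial banding with period D, in which the gap
zones (reduced molecular occupancy) cover ≈0.6 of every period and the overlap
zones the remaining 0.4.

The modeled specimen is one 5·D super-period of that arrangement.  Chains that
reach the specimen ends are extended with additional beads connected by
"strengthened" (effectively unbreakable) bonds; those extension beads form the
two rigid grips through which a tensile test loads the fibril.

AGE cross-links are inserted as explicit bonds between beads of distinct
chains, uniformly at random over the admissible pairs: both endpoints must lie
within the central 95 % of their chain (glycation occurs in the helical region,
not at the telopeptide ends) and the pair separation must not exceed an
insertion cutoff, so that freshly inserted links start near their equilibrium
length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

#: bond family codes
FAMILY_COLLAGEN = 0
FAMILY_AGE = 1
FAMILY_STRENGTHENED = 2

FAMILY_NAMES = {FAMILY_COLLAGEN: "collagen", FAMILY_AGE: "age", FAMILY_STRENGTHENED: "strengthened"}


@dataclass(frozen=True)
class TCMoleculeSpec:
    """Coarse-grained tropocollagen molecule: a straight chain of beads.

    Parameters
    ----------
    n_particles:
        Beads per molecule (218 at full scale).
    spacing:
        Equilibrium bead spacing r0 in Å (14.0); also the collagen bond rest
        length.
    diameter_sigma:
        Dispersive diameter σ of the molecule in Å (14.72), used for the
        transverse lattice constant and the pair interaction.
    molecule_length:
        Nominal molecule length in Å; defaults to the chain span
        (n_particles − 1)·spacing and must agree with it within 5 %.
    crimp_ratio:
        Contour-to-axial-span ratio λ ≥ 1 of the molecular crimp.  1.0
        (default, used by the presets) gives straight chains; λ > 1 places
        the beads on a small-amplitude planar sine wave (identical phase for
        every chain so the transverse packing is preserved), giving the
        molecule an axial uncrimping reserve of ≈ (λ − 1) that is released
        against the bending stiffness before the backbone bonds load.
    """

    n_particles: int = 218
    spacing: float = 14.0
    diameter_sigma: float = 14.72
    molecule_length: float | None = None
    crimp_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("a molecule needs at least 2 particles")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.diameter_sigma <= 0:
            raise ValueError("diameter_sigma must be positive")
        if self.crimp_ratio < 1.0:
            raise ValueError("crimp_ratio must be >= 1")
        if self.molecule_length is not None:
            if abs(self.molecule_length - self.span) > 0.05 * self.span:
                raise ValueError(
                    f"molecule_length {self.molecule_length} inconsistent with "
                    f"(n_particles-1)*spacing = {self.span} (>5%)"
                )

    @property
    def span(self) -> float:
        """Axial extent of the chain in Å."""
        return (self.n_particles - 1) * self.spacing


@dataclass(frozen=True)
class FibrilSpec:
    """Geometry of the representative fibril specimen.

    ``d_period`` and ``gap_fraction`` define the banding; the filament-line
    tiling period is ``n_periods * d_period`` and the stagger offset between
    classes is exactly ``d_period``.  ``fibril_diameter`` bounds the
    transverse hexagonal lattice.  ``end_extension_particles`` beads with
    strengthened bonds are appended to every chain that reaches a specimen
    end; they constitute the grips.
    """

    d_period: float = 670.0
    gap_fraction: float = 0.6
    n_periods: int = 5
    fibril_diameter: float = 202.0
    end_extension_particles: int = 40
    lattice_spacing: float | None = None  # default: 2^(1/6)·σ

    def __post_init__(self) -> None:
        if not (0.0 < self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must be in (0, 1)")
        if self.d_period <= 0:
            raise ValueError("d_period must be positive")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.end_extension_particles < 1:
            raise ValueError("end_extension_particles must be >= 1")

    @property
    def overlap_fraction(self) -> float:
        return 1.0 - self.gap_fraction

    @property
    def line_period(self) -> float:
        """Axial tiling period of molecules within one filament line."""
        return self.n_periods * self.d_period

    @property
    def window_length(self) -> float:
        """Axial extent of the modeled specimen (one super-period)."""
        return self.n_periods * self.d_period


@dataclass(frozen=True)
class CrossLinkSet:
    """Prescription for random AGE cross-link insertion.

    ``n_age`` is the density in cross-links per TC molecule of the fibril
    cross-section; the realized count is ``round(n_age * n_molecules)``
    whenever enough admissible bead pairs exist.
    """

    n_age: float = 0.0
    rng_seed: int = 0
    insertion_cutoff: float = 20.62  # (r0+r1)/2: links start in the lower half of the harmonic branch

    def __post_init__(self) -> None:
        if self.n_age < 0:
            raise ValueError("n_age must be >= 0")
        if self.insertion_cutoff <= 0:
            raise ValueError("insertion_cutoff must be positive")


@dataclass
class FibrilTopology:
    """The full mechanical graph of one fibril specimen.

    Bead positions, chain membership, intra-chain bonds (collagen or
    strengthened family), AGE cross-links, stagger classes and the two grip
    groups, together with the construction metadata needed by the analysis
    layer (D-period, mean initial gap, cross-section molecule count, ...).
    """

    positions: np.ndarray  # (N, 3) float64, Å
    chain_index: np.ndarray  # (N,) int
    is_extension: np.ndarray  # (N,) bool — grip-extension beads
    bond_i: np.ndarray  # (B,) int
    bond_j: np.ndarray  # (B,) int
    bond_family: np.ndarray  # (B,) int — FAMILY_COLLAGEN / FAMILY_STRENGTHENED
    crosslinks: np.ndarray  # (M, 2) int — AGE bonds, i < j
    stagger_class: np.ndarray  # (n_chains,) int in 0..4
    left_grip: np.ndarray  # particle indices
    right_grip: np.ndarray
    d_period: float
    gap_fraction: float
    window_length: float
    line_period: float
    molecule_span: float
    spacing: float
    fibril_diameter: float
    n_cross_section: int  # molecules across the section (lattice sites)
    n_bonds_per_molecule: int  # bonds of one full TC molecule
    molecule_starts: list[list[float]] = field(default_factory=list)  # per line
    site_stagger_class: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )  # per cross-section lattice site
    crosslink_seed: int | None = None
    requested_n_age: float = 0.0

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_chains(self) -> int:
        return int(self.chain_index.max()) + 1 if len(self.chain_index) else 0

    @property
    def n_molecules(self) -> int:
        """Molecule count used for densities and censuses (cross-section)."""
        return self.n_cross_section

    @property
    def bond_list(self) -> list[tuple[int, int, int]]:
        return [
            (int(i), int(j), int(f))
            for i, j, f in zip(self.bond_i, self.bond_j, self.bond_family)
        ]

    @property
    def crosslink_list(self) -> list[tuple[int, int]]:
        return [(int(i), int(j)) for i, j in self.crosslinks]

    @property
    def realized_n_age(self) -> float:
        return len(self.crosslinks) / self.n_molecules if self.n_molecules else 0.0

    def chain_particles(self, c: int) -> np.ndarray:
        """Particle indices of chain ``c`` in axial order."""
        idx = np.nonzero(self.chain_index == c)[0]
        return idx[np.argsort(self.positions[idx, 2], kind="stable")]

    def admissible_crosslink_particles(self) -> np.ndarray:
        """Beads eligible as cross-link endpoints: central 95 % of each chain.

        Grip-extension beads are never admissible; within the molecular part
        of a chain of n beads, bead k (0-based axial order) is admissible iff
        0.025·(n−1) ≤ k ≤ 0.975·(n−1).
        """
        out = []
        for c in range(self.n_chains):
            idx = self.chain_particles(c)
            idx = idx[~self.is_extension[idx]]
            n = len(idx)
            if n < 2:
                continue
            lo = 0.025 * (n - 1)
            hi = 0.975 * (n - 1)
            ks = np.arange(n)
            out.append(idx[(ks >= lo) & (ks <= hi)])
        if not out:
            return np.empty(0, dtype=int)
        return np.concatenate(out)


def build_chain(
    spec: TCMoleculeSpec,
    origin: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    axis: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Place one straight TC chain and return (positions, consecutive bonds).

    ``axis`` must be a unit vector; beads sit at origin + k·spacing·axis.
    """
    origin = np.asarray(origin, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-8:
        raise ValueError("axis must be a unit vector")
    k = np.arange(spec.n_particles)[:, None]
    positions = origin[None, :] + k * spec.spacing * axis[None, :]
    bonds = [(i, i + 1) for i in range(spec.n_particles - 1)]
    return positions, bonds


#: nominal wavelength of the molecular crimp, Å
CRIMP_WAVELENGTH = 90.0


def crimp_wavelength(d_period: float) -> float:
    """Crimp wavelength: the closest integer fraction of the D-period to the
    ~90 Å nominal molecular crimp.  Because the crimp phase is a function of
    absolute z and molecule starts are multiples of D, every molecule starts
    at phase zero and all chains stay in register."""
    m = max(1, round(d_period / CRIMP_WAVELENGTH))
    return d_period / m


def _zigzag_z_grid(
    n: int, spacing: float, amplitude: float, wavelength: float, phase_index: int = 0
) -> np.ndarray:
    """Axial bead coordinates of a planar-sine crimped chain.

    Beads sit at (A·sin(2π·z/w), 0, z) with every chord exactly ``spacing``;
    the grid is solved sequentially (index ``phase_index`` pinned to z = 0).
    Straightening a planar zigzag must open the bead angles — unlike a
    helix, it has no torsional soft mode — so the crimp reserve is released
    against the bending stiffness, giving the fibril its toe regime.
    """
    if amplitude == 0.0:
        return (np.arange(n) - phase_index) * spacing
    om = 2.0 * math.pi / wavelength
    z = np.empty(n)
    z[phase_index] = 0.0
    for direction in (+1, -1):
        rng = (
            range(phase_index + 1, n)
            if direction > 0
            else range(phase_index - 1, -1, -1)
        )
        for k in rng:
            zp = z[k - direction]
            xp = amplitude * math.sin(om * zp)
            dz = spacing * 0.8  # initial guess
            for _ in range(80):
                zn = zp + direction * dz
                dx = amplitude * math.sin(om * zn) - xp
                new = math.sqrt(max(spacing**2 - dx * dx, 1e-12))
                if abs(new - dz) < 1e-13:
                    dz = new
                    break
                dz = 0.5 * (dz + new)
            z[k] = zp + direction * dz
    return z


def crimp_amplitude(spacing: float, crimp_ratio: float, wavelength: float) -> float:
    """Sine-crimp amplitude giving a contour/axial-span ratio of λ.

    Solved numerically on a long reference chain (bisection on A).
    """
    if crimp_ratio <= 1.0:
        return 0.0
    n_ref = max(64, int(round(8 * wavelength / spacing)))
    target = (n_ref - 1) * spacing / crimp_ratio

    def span(A: float) -> float:
        z = _zigzag_z_grid(n_ref, spacing, A, wavelength)
        return z[-1] - z[0]

    lo, hi = 0.0, 0.6 * wavelength
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        if span(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def consistent_d_period(
    mspec: TCMoleculeSpec, n_periods: int = 5, gap_fraction: float = 0.6
) -> float:
    """D-period that makes the molecule's axial span exactly
    (n_periods − gap_fraction)·D, accounting for the crimp."""
    factor = n_periods - gap_fraction
    D = (mspec.n_particles - 1) * mspec.spacing / factor
    for _ in range(60):
        w = crimp_wavelength(D)
        A = crimp_amplitude(mspec.spacing, mspec.crimp_ratio, w)
        z = _zigzag_z_grid(mspec.n_particles, mspec.spacing, A, w)
        new = (z[-1] - z[0]) / factor
        if abs(new - D) < 1e-10:
            return new
        D = new
    return D


def hexagonal_sites(radius: float, a: float) -> np.ndarray:
    """Hexagonal lattice sites (x, y) with |r| <= radius, lattice constant a."""
    nmax = int(math.ceil(radius / a)) + 2
    pts = []
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            x = a * (i + 0.5 * j)
            y = a * (math.sqrt(3) / 2) * j
            if x * x + y * y <= radius * radius + 1e-9:
                pts.append((x, y))
    pts.sort(key=lambda p: (round(p[1], 9), round(p[0], 9)))
    return np.array(pts) if pts else np.empty((0, 2))


def build_fibril(fspec: FibrilSpec, mspec: TCMoleculeSpec) -> FibrilTopology:
    """Assemble the staggered, D-banded fibril specimen with grip extensions.

    Raises ``ValueError`` if the cross-section cannot hold the five stagger
    classes or if molecules would overlap within a filament line.
    """
    a = fspec.lattice_spacing or 2 ** (1 / 6) * mspec.diameter_sigma
    radius = (fspec.fibril_diameter - mspec.diameter_sigma) / 2.0
    sites = hexagonal_sites(radius, a)
    if len(sites) < 5:
        raise ValueError(
            f"fibril_diameter {fspec.fibril_diameter} holds only {len(sites)} "
            "chains; at least 5 (one per stagger class) are required"
        )
    D = fspec.d_period
    P = fspec.line_period
    L = fspec.window_length
    wav = crimp_wavelength(D)
    amp = crimp_amplitude(mspec.spacing, mspec.crimp_ratio, wav)
    omega = 2.0 * math.pi / wav
    n_ext = fspec.end_extension_particles
    n_mol = mspec.n_particles
    # relative axial grid of one molecule plus its potential grip extensions;
    # molecule starts are multiples of the crimp wavelength, so one grid
    # (phase 0 at the first molecule bead) serves every instance
    grid = _zigzag_z_grid(n_mol + 2 * n_ext, mspec.spacing, amp, wav, phase_index=n_ext)
    span = grid[n_ext + n_mol - 1] - grid[n_ext]  # axial extent of one molecule
    if span >= P - 1e-9:
        raise ValueError("molecule span exceeds the filament-line period; molecules overlap")
    if D <= mspec.spacing:
        raise ValueError("d_period must exceed the bead spacing")

    positions: list[np.ndarray] = []
    chain_index: list[np.ndarray] = []
    is_ext: list[np.ndarray] = []
    bond_i: list[int] = []
    bond_j: list[int] = []
    bond_family: list[int] = []
    stagger_class: list[int] = []
    left_grip: list[int] = []
    right_grip: list[int] = []
    molecule_starts: list[list[float]] = []

    n_total = 0
    chain = 0
    for k, (x, y) in enumerate(sites):
        cls = k % 5
        z_off = cls * D
        starts = []
        m_lo = int(math.floor((-span - z_off) / P)) - 1
        m_hi = int(math.ceil((L - z_off) / P)) + 1
        for m in range(m_lo, m_hi + 1):
            start = z_off + m * P
            if start > L + 1e-9 or start + span < -1e-9:
                continue
            # bead indices of this molecule instance clipped to the window
            z_mol = start + grid[n_ext: n_ext + n_mol]
            kept = (z_mol >= -1e-9) & (z_mol <= L + 1e-9)
            if not kept.any():
                continue
            i_first = int(np.argmax(kept))
            i_last = n_mol - 1 - int(np.argmax(kept[::-1]))
            starts.append(start)
            z = z_mol[i_first: i_last + 1]
            grip_left = i_first > 0 or z[0] < 1e-9
            grip_right = i_last < n_mol - 1 or z[-1] > L - 1e-9
            zl = start + grid[i_first: n_ext + i_first] if grip_left else np.empty(0)
            zr = (
                start + grid[n_ext + i_last + 1: 2 * n_ext + i_last + 1]
                if grip_right
                else np.empty(0)
            )
            zc = np.concatenate([zl, z, zr])
            nc = len(zc)
            pos = np.column_stack([np.full(nc, x), np.full(nc, y), zc])
            if amp > 0:  # in-phase planar sine crimp
                pos[:, 0] += amp * np.sin(omega * zc)
            ext_mask = np.zeros(nc, dtype=bool)
            ext_mask[: len(zl)] = True
            if len(zr):
                ext_mask[-len(zr):] = True
            base = n_total
            # consecutive bonds; strengthened if either endpoint is extension
            for b in range(nc - 1):
                bond_i.append(base + b)
                bond_j.append(base + b + 1)
                strengthened = ext_mask[b] or ext_mask[b + 1]
                bond_family.append(FAMILY_STRENGTHENED if strengthened else FAMILY_COLLAGEN)
            if nc == 1 and not (grip_left or grip_right):
                continue  # isolated single interior bead: drop
            left_grip.extend(range(base, base + len(zl)))
            right_grip.extend(range(base + nc - len(zr), base + nc))
            positions.append(pos)
            chain_index.append(np.full(nc, chain))
            is_ext.append(ext_mask)
            stagger_class.append(cls)
            n_total += nc
            chain += 1
        molecule_starts.append(sorted(starts))

    topo = FibrilTopology(
        positions=np.vstack(positions),
        chain_index=np.concatenate(chain_index),
        is_extension=np.concatenate(is_ext),
        bond_i=np.array(bond_i, dtype=int),
        bond_j=np.array(bond_j, dtype=int),
        bond_family=np.array(bond_family, dtype=int),
        crosslinks=np.empty((0, 2), dtype=int),
        stagger_class=np.array(stagger_class, dtype=int),
        left_grip=np.array(sorted(left_grip), dtype=int),
        right_grip=np.array(sorted(right_grip), dtype=int),
        d_period=D,
        gap_fraction=fspec.gap_fraction,
        window_length=L,
        line_period=P,
        molecule_span=span,
        spacing=mspec.spacing,
        fibril_diameter=fspec.fibril_diameter,
        n_cross_section=len(sites),
        n_bonds_per_molecule=mspec.n_particles - 1,
        molecule_starts=molecule_starts,
        site_stagger_class=np.arange(len(sites)) % 5,
    )
    assert len(np.intersect1d(topo.left_grip, topo.right_grip)) == 0
    return topo


def insert_crosslinks(topo: FibrilTopology, cls: CrossLinkSet) -> FibrilTopology:
    """Insert ``round(n_age · n_molecules)`` AGE cross-links at random.

    Candidate pairs connect admissible beads (central 95 % of distinct
    chains) separated by at most ``insertion_cutoff``; sampling is uniform
    without replacement and deterministic under a fixed seed.  If the
    admissible supply is short, all candidates are used and a warning records
    the realized density.
    """
    target = int(round(cls.n_age * topo.n_molecules))
    if target == 0:
        return replace(topo, crosslinks=np.empty((0, 2), dtype=int),
                       crosslink_seed=cls.rng_seed, requested_n_age=cls.n_age)
    admissible = topo.admissible_crosslink_particles()
    tree = cKDTree(topo.positions[admissible])
    pairs = tree.query_pairs(r=cls.insertion_cutoff, output_type="ndarray")
    gi = admissible[pairs[:, 0]]
    gj = admissible[pairs[:, 1]]
    keep = topo.chain_index[gi] != topo.chain_index[gj]
    gi, gj = gi[keep], gj[keep]
    lo = np.minimum(gi, gj)
    hi = np.maximum(gi, gj)
    order = np.lexsort((hi, lo))
    cand = np.column_stack([lo[order], hi[order]])
    if len(cand) < target:
        warnings.warn(
            f"only {len(cand)} admissible pairs for {target} requested cross-links; "
            f"realized density {len(cand) / topo.n_molecules:.3f} per molecule"
        )
        chosen = cand
    else:
        rng = np.random.default_rng(cls.rng_seed)
        sel = rng.choice(len(cand), size=target, replace=False)
        chosen = cand[np.sort(sel)]
    return replace(topo, crosslinks=chosen, crosslink_seed=cls.rng_seed,
                   requested_n_age=cls.n_age)


@dataclass
class GapOverlapMap:
    """Binned axial occupancy classification of an undeformed fibril."""

    bin_edges: np.ndarray
    occupancy: np.ndarray  # molecule beads per bin
    is_gap: np.ndarray  # bool per bin
    banding_period: float  # dominant axial period, Å
    gap_fraction: float  # fraction of bins classified gap
    mean_gap_length: float  # ⟨g⟩, Å (nan if no gaps)
    n_gaps: int


def gap_overlap_map(topo: FibrilTopology, bin_width: float | None = None) -> GapOverlapMap:
    """Classify axial bins as gap/overlap and measure ⟨g⟩ and the banding period.

    Requires the undeformed topology (uniform collagen bond lengths); the
    banding period is located from the autocorrelation of the binned
    occupancy profile.
    """
    lengths = np.linalg.norm(
        topo.positions[topo.bond_j] - topo.positions[topo.bond_i], axis=1
    )
    if len(lengths) and np.max(np.abs(lengths - topo.spacing)) > 1e-3:
        raise ValueError("topology is deformed; the gap/overlap map is defined "
                         "for the initial configuration only")
    if bin_width is None:
        bin_width = topo.d_period / 10.0
    n_bins = max(1, int(round(topo.window_length / bin_width)))
    edges = np.linspace(0.0, topo.window_length, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # occupancy by molecular coverage: a chain occupies the axial interval
    # spanned by its molecule beads (bead-count histograms alias when the
    # bin width is incommensurate with the bead spacing)
    occ = np.zeros(n_bins)
    for c in range(topo.n_chains):
        idx = topo.chain_particles(c)  # grip extensions continue the chain
        zlo = topo.positions[idx, 2].min()  # beyond the window edge, so
        zhi = topo.positions[idx, 2].max()  # clipped chains stay covered
        occ += (centers >= zlo) & (centers <= zhi)
    # a bin belongs to a gap zone when any filament line is absent
    is_gap = occ < occ.max() if occ.max() > 0 else np.zeros(n_bins, dtype=bool)

    # dominant period from the power spectrum of the centered profile
    x = occ - occ.mean()
    if n_bins >= 4 and np.any(x != 0):
        power = np.abs(np.fft.rfft(x)) ** 2
        k = int(np.argmax(power[1:])) + 1  # skip the DC component
        period = topo.window_length / k
    else:
        period = float("nan")

    gaps = []
    for starts in topo.molecule_starts:
        for s0, s1 in zip(starts, starts[1:]):
            gaps.append(s1 - (s0 + topo.molecule_span))
    mean_gap = float(np.mean(gaps)) if gaps else float("nan")
    return GapOverlapMap(
        bin_edges=edges,
        occupancy=occ,
        is_gap=is_gap,
        banding_period=period,
        gap_fraction=float(np.mean(is_gap)),
        mean_gap_length=mean_gap,
        n_gaps=len(gaps),
    )
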