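"""Mechanical observables from tensile-test trajectories.

Stress–strain reduction
    The linear elastic limit ε0 is the largest strain up to which the curve
    stays within a relative tolerance of the least-squares line through the
    origin; σ0 = σ(ε0), and the elastic-to-peak stress difference
    Δσ = σpeak − σ0 quantifies stiffening (Δσ > 0) versus softening (Δσ ≈ 0).

Energy partition
    The energy absorbed by stretching of the TC molecules is the cumulative
    integral of the mean collagen-bond tension over the mean bond elongation,

        E_stretch(ε) = ∫ F_stretch dΔr_TC,

    started at ε*, the first strain where the mean molecular strain matches
    the fibrillar strain (the transition to stretching-governed deformation).
    The energy dissipated by inter-molecular sliding is estimated
    heuristically from the force balance: the part of the applied tensile
    force per molecule not carried by backbone stretching, integrated over
    the change in gap length,

        E_slide(ε) = ∫ F_slide dΔg,

    where Δg follows from the kinematic decomposition of the global strain
        ε = (Δg + n_TC·(r_TC − r0)) / (⟨g⟩ + n_TC·r0).

    Both energies are reported normalized by the values of a matched
    cross-link-free (N_AGE = 0) reference run, the most extreme sliding case.

Sweeps
    :func:`run_sweep` evaluates a (k1, rbreak, N_AGE) grid, classifies each
    cell as softening/stiffening, compares the observation against the
    energy-capacity criterion W_TC < N_AGE·W_AGE, and collects peak stress,
    normalized energies and the broken-bond census in a tidy table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fibrilmech.forcefield import (
    ForceField,
    Regime,
    age_spec,
    loading_energy_capacity,
    stiffening_criterion,
)
from fibrilmech.geometry import CrossLinkSet, FibrilTopology, insert_crosslinks
from fibrilmech.tensile import PullProtocol, Trajectory, run_tensile_test

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stress-strain curve
# ---------------------------------------------------------------------------

@dataclass
class StressStrainCurve:
    """(ε, σ) samples with the derived scalars ε0, σ0, σpeak, εpeak, Δσ."""

    strain: np.ndarray
    stress: np.ndarray
    eps0: float = float("nan")
    sigma0: float = float("nan")
    stiffness: float = float("nan")
    eps0_flagged: bool = False
    linear_tol: float = 0.05

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if np.isnan(self.eps0):
            self.eps0, self.sigma0, self.stiffness, self.eps0_flagged = fit_linear_limit(
                self.strain, self.stress, tol=self.linear_tol
            )

    @classmethod
    def from_trajectory(cls, traj: Trajectory, linear_tol: float = 0.05) -> "StressStrainCurve":
        return cls(traj.strain, traj.stress, linear_tol=linear_tol)

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.stress))

    @property
    def sigma_peak(self) -> float:
        return float(self.stress[self.peak_index])

    @property
    def eps_peak(self) -> float:
        return float(self.strain[self.peak_index])

    @property
    def delta_sigma(self) -> float:
        """Elastic-to-peak stress difference Δσ = σpeak − σ0."""
        return self.sigma_peak - self.sigma0


def fit_linear_limit(
    strain: np.ndarray,
    stress: np.ndarray,
    tol: float = 0.05,
    min_points: int = 10,
    smooth_window: int = 9,
) -> tuple[float, float, float, bool]:
    """Locate the limit of the initial linear regime.

    Scans growing windows [0, ε_i] of the rising branch; ε0 is the largest
    strain for which the stress deviates from the least-squares line through
    the origin by less than ``tol`` (relative to the window-end line value),
    contiguously from the start.  Returns (ε0, σ0, initial stiffness,
    flagged) where ``flagged`` means the window ran into the end of the
    rising branch (curve shorter than the search window).

    Quasistatic (athermal) loading produces sawtooth stick-slip
    fluctuations that finite-temperature dynamics would average out; the
    detector therefore operates on a centered moving average of the stress
    (``smooth_window`` frames, 1 disables).
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if smooth_window > 1 and len(stress) > smooth_window:
        from scipy.signal import savgol_filter

        # local linear regression: averages the stick-slip sawtooth while
        # reproducing a linear trend exactly, edges included
        stress = savgol_filter(stress, smooth_window | 1, 1, mode="interp")
    rising_end = int(np.argmax(stress))
    if rising_end + 1 < max(min_points, 3):
        raise ValueError("need at least 10 samples in the rising branch")
    best = min_points - 1
    for i in range(min_points - 1, rising_end + 1):
        e = strain[: i + 1]
        s = stress[: i + 1]
        denom = float(np.dot(e, e))
        if denom == 0.0:
            continue
        k = float(np.dot(e, s)) / denom
        scale = abs(k) * strain[i]
        if scale <= 0:
            continue
        dev = np.max(np.abs(s - k * e)) / scale
        if dev < tol:
            best = i  # largest window satisfying the tolerance
    e = strain[: best + 1]
    s = stress[: best + 1]
    k = float(np.dot(e, s) / np.dot(e, e))
    flagged = best == rising_end
    return float(strain[best]), float(stress[best]), k, flagged


def classify_regime(
    curve: StressStrainCurve,
    tol_fraction: float = 0.05,
    reference_delta_sigma: float | None = None,
) -> str:
    """'stiffening' if Δσ exceeds the softening baseline, else 'softening'.

    The baseline is ``tol_fraction``·σ0; when the matched cross-link-free
    reference run is available its own elastic-to-peak rise is used as the
    floor instead, because quasistatic stick-slip friction hardens the
    post-ε0 plateau even in a purely sliding-governed fibril (the
    uncross-linked specimen itself must classify as softening).
    """
    floor = tol_fraction * curve.sigma0
    if reference_delta_sigma is not None:
        floor = max(floor, reference_delta_sigma)
    return "stiffening" if curve.delta_sigma > floor else "softening"


# ---------------------------------------------------------------------------
# kinematics and energy partition
# ---------------------------------------------------------------------------

def gap_change(
    eps: float | np.ndarray,
    mean_gap: float,
    n_tc: int,
    r0: float,
    r_tc: float | np.ndarray,
) -> float | np.ndarray:
    """Gap-length change Δg from the strain decomposition
    ε = (Δg + n_TC·(r_TC − r0)) / (⟨g⟩ + n_TC·r0), solved for Δg."""
    denom = mean_gap + n_tc * r0
    if denom <= 0:
        raise ValueError("⟨g⟩ + n_TC·r0 must be positive")
    return eps * denom - n_tc * (np.asarray(r_tc) - r0)


def strain_from_gap_change(
    dg: float | np.ndarray,
    mean_gap: float,
    n_tc: int,
    r0: float,
    r_tc: float | np.ndarray,
) -> float | np.ndarray:
    """Inverse of :func:`gap_change` (the strain decomposition itself)."""
    denom = mean_gap + n_tc * r0
    if denom <= 0:
        raise ValueError("⟨g⟩ + n_TC·r0 must be positive")
    return (dg + n_tc * (np.asarray(r_tc) - r0)) / denom


def find_transition_strain(
    strain: np.ndarray, eps_tc: np.ndarray, rel_tol: float = 0.05
) -> tuple[int, bool]:
    """Index of ε*: first frame with |ε_TC − ε| ≤ rel_tol·ε (ε > 0).

    Falls back (flagged) to the frame minimizing the relative mismatch when
    the condition is never met.
    """
    strain = np.asarray(strain, dtype=float)
    eps_tc = np.asarray(eps_tc, dtype=float)
    pos = strain > 0
    rel = np.full(len(strain), np.inf)
    rel[pos] = np.abs(eps_tc[pos] - strain[pos]) / strain[pos]
    hits = np.nonzero(rel <= rel_tol)[0]
    if len(hits):
        return int(hits[0]), False
    if np.isfinite(rel).any():
        return int(np.argmin(rel)), True
    return 0, True


@dataclass
class EnergyLedger:
    """Cumulative stretching/sliding energies of one run, with context."""

    strain: np.ndarray
    e_stretch: np.ndarray  # cumulative, kcal/mol per TC bond
    e_slide: np.ndarray  # cumulative, kcal/mol per molecule
    f_stretch: np.ndarray
    f_slide: np.ndarray
    delta_rtc: np.ndarray
    delta_g: np.ndarray
    start_index: int
    start_flagged: bool
    e_stretch_ref: float = float("nan")  # N_AGE = 0 normalizers at their εpeak
    e_slide_ref: float = float("nan")

    def at_strain(self, eps: float) -> tuple[float, float]:
        """(E_stretch, E_slide) interpolated at strain ``eps``."""
        return (
            float(np.interp(eps, self.strain, self.e_stretch)),
            float(np.interp(eps, self.strain, self.e_slide)),
        )


def _cumulative_integral(y: np.ndarray, x: np.ndarray, start: int) -> np.ndarray:
    """Trapezoidal cumulative ∫ y dx from index ``start``; zero before."""
    out = np.zeros(len(x))
    if start < len(x) - 1:
        seg = np.concatenate(
            [[0.0], np.cumsum(0.5 * (y[start + 1:] + y[start:-1]) * np.diff(x[start:]))]
        )
        out[start:] = seg
    return out


def stretch_energy(traj: Trajectory, rel_tol: float = 0.05) -> tuple[np.ndarray, int, bool]:
    """Cumulative E_stretch(ε) series, the ε* index, and its fallback flag."""
    drtc = traj.mean_rtc - traj.r0_collagen
    eps_tc = drtc / traj.r0_collagen
    start, flagged = find_transition_strain(traj.strain, eps_tc, rel_tol)
    e = _cumulative_integral(traj.f_stretch, drtc, start)
    return e, start, flagged


def slide_energy(traj: Trajectory, rel_tol: float = 0.05) -> tuple[np.ndarray, int, bool]:
    """Cumulative E_slide(ε) series (heuristic force balance), ε* index, flag."""
    drtc = traj.mean_rtc - traj.r0_collagen
    eps_tc = drtc / traj.r0_collagen
    start, flagged = find_transition_strain(traj.strain, eps_tc, rel_tol)
    f_slide = traj.force / traj.n_cross_section - traj.f_stretch
    dg = gap_change(
        traj.strain, traj.mean_gap_initial, traj.n_bonds_per_molecule,
        traj.r0_collagen, traj.mean_rtc,
    )
    e = _cumulative_integral(f_slide, np.asarray(dg), start)
    return e, start, flagged


def energy_ledger(
    traj: Trajectory,
    reference: Trajectory | None = None,
    rel_tol: float = 0.05,
) -> EnergyLedger:
    """Full energy partition of one run, optionally normalized by a matched
    N_AGE = 0 reference (each evaluated at its own peak strain)."""
    drtc = traj.mean_rtc - traj.r0_collagen
    e_stretch, start, flagged = stretch_energy(traj, rel_tol)
    e_slide, _, _ = slide_energy(traj, rel_tol)
    dg = np.asarray(
        gap_change(traj.strain, traj.mean_gap_initial, traj.n_bonds_per_molecule,
                   traj.r0_collagen, traj.mean_rtc)
    )
    ledger = EnergyLedger(
        strain=traj.strain,
        e_stretch=e_stretch,
        e_slide=e_slide,
        f_stretch=traj.f_stretch,
        f_slide=traj.force / traj.n_cross_section - traj.f_stretch,
        delta_rtc=drtc,
        delta_g=dg,
        start_index=start,
        start_flagged=flagged,
    )
    if reference is not None:
        ref = energy_ledger(reference, None, rel_tol)
        curve = StressStrainCurve.from_trajectory(reference)
        ledger.e_stretch_ref, ledger.e_slide_ref = ref.at_strain(curve.eps_peak)
    return ledger


def failure_census(traj: Trajectory, frame: int = -1) -> dict[str, float]:
    """Broken-bond percentages at (after) failure.

    ``broken_age_pct`` is relative to the inserted cross-link count;
    ``broken_tc_pct`` counts broken collagen bonds relative to the number of
    TC molecules in the cross-section and may exceed 100 %.
    """
    n_age = traj.n_age_total
    return {
        "broken_age": int(traj.broken_age[frame]),
        "broken_collagen": int(traj.broken_collagen[frame]),
        "broken_age_pct": 100.0 * traj.broken_age[frame] / n_age if n_age else 0.0,
        "broken_tc_pct": 100.0 * traj.broken_collagen[frame] / traj.n_cross_section,
    }


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Tidy table over the (k1, rbreak, N_AGE) grid plus the per-cell runs."""

    table: pd.DataFrame
    trajectories: dict[tuple[float, float, float], Trajectory] = field(default_factory=dict)
    references: dict[int, Trajectory] = field(default_factory=dict)


def run_sweep(
    base_topology: FibrilTopology,
    ff: ForceField,
    protocol: PullProtocol,
    k1_values: list[float],
    rbreak_values: list[float],
    n_age_values: list[float],
    seed: int = 0,
    insertion_cutoff: float = 20.62,
    linear_tol: float = 0.05,
    regime_tol: float = 0.05,
    keep_trajectories: bool = False,
) -> SweepResult:
    """Destructive tensile tests over a cross-link parameter grid.

    One cross-link realization per (N_AGE) density (same seed protocol for
    every (k1, rbreak) cell so cells differ only in AGE mechanics); a matched
    N_AGE = 0 reference run provides the energy normalizers.
    """
    w_tc = loading_energy_capacity(ff.collagen)
    ref_ff = ForceField(collagen=ff.collagen, age=ff.age,
                        strengthened=ff.strengthened, pair=ff.pair, angle=ff.angle)
    ref_traj = run_tensile_test(base_topology, ref_ff, protocol, seed=seed)
    ref_ledger = energy_ledger(ref_traj)
    ref_curve = StressStrainCurve.from_trajectory(ref_traj, linear_tol)
    e_stretch_ref, e_slide_ref = ref_ledger.at_strain(ref_curve.eps_peak)

    rows = []
    result = SweepResult(table=pd.DataFrame())
    result.references[0] = ref_traj
    for n_age in n_age_values:
        topo = insert_crosslinks(
            base_topology,
            CrossLinkSet(n_age=n_age, rng_seed=seed, insertion_cutoff=insertion_cutoff),
        )
        for k1 in k1_values:
            for rbreak in rbreak_values:
                spec = age_spec(k1=k1, rbreak=rbreak)
                w_age = loading_energy_capacity(spec)
                cell_ff = ForceField(
                    collagen=ff.collagen, age=spec,
                    strengthened=ff.strengthened, pair=ff.pair, angle=ff.angle,
                )
                logger.info("sweep cell k1=%g rbreak=%g n_age=%g", k1, rbreak, n_age)
                traj = run_tensile_test(topo, cell_ff, protocol, seed=seed)
                curve = StressStrainCurve.from_trajectory(traj, linear_tol)
                ledger = energy_ledger(traj)
                e_stretch, e_slide = ledger.at_strain(curve.eps_peak)
                census = failure_census(traj)
                observed = classify_regime(
                    curve, regime_tol,
                    reference_delta_sigma=ref_curve.delta_sigma,
                )
                predicted = stiffening_criterion(w_tc, w_age, n_age)
                predicted_label = (
                    "stiffening" if predicted == Regime.TC_DEFORMATION else "softening"
                )
                rows.append(
                    {
                        "k1": k1,
                        "rbreak": rbreak,
                        "n_age": n_age,
                        "w_age": w_age,
                        "w_tc": w_tc,
                        "sigma_peak": curve.sigma_peak,
                        "eps_peak": curve.eps_peak,
                        "eps0": curve.eps0,
                        "sigma0": curve.sigma0,
                        "delta_sigma": curve.delta_sigma,
                        "regime_observed": observed,
                        "regime_predicted": predicted_label,
                        "criterion_agrees": observed == predicted_label,
                        "e_stretch": e_stretch,
                        "e_slide": e_slide,
                        "e_stretch_norm": e_stretch / e_stretch_ref
                        if e_stretch_ref else float("nan"),
                        "e_slide_norm": e_slide / e_slide_ref
                        if e_slide_ref else float("nan"),
                        "broken_age_pct": census["broken_age_pct"],
                        "broken_tc_pct": census["broken_tc_pct"],
                        "seed": seed,
                    }
                )
                if keep_trajectories:
                    result.trajectories[(k1, rbreak, n_age)] = traj
    result.table = pd.DataFrame(rows)
    return result
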