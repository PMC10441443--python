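# Methods

## Model

A collagen fibril is represented as a bundle of bead-spring tropocollagen
(TC) molecules. Beads sit every r₀ = 14.0 Å along straight chains; chains are
packed on a transverse hexagonal lattice with spacing 2^(1/6)·σ (σ = 14.72 Å,
the dispersive diameter of the molecule) and staggered axially in the
Hodge–Petruska pattern: the five stagger classes are offset by one D-period,
molecules of one filament line tile with period 5·D, and the inter-molecular
gap within a line is 0.6·D. The specimen is one 5·D super-period; the builder
derives D from the molecule span (D = span/4.4) so the banding — period D,
gap fraction 0.6 — is exact by construction. Chains that touch a specimen end
are extended by `end_extension_particles` beads joined by "strengthened"
bonds (trilinear parameters with the rupture threshold far out of reach);
the extension beads form the two rigid grips.

The total energy is E_bond + E_angle + E_inter. All bonds follow the
breakable trilinear law

    F(r) = k₀(r−r₀)                          r < r₁
         = k₀(r₁−r₀) + k₁(r−r₁)              r₁ ≤ r < r_break
         = F_peak(1 − (r−r_break)/a)         r_break ≤ r < r_break + a,  a = z(r_break−r₁)
         = 0 and permanently broken          r ≥ r_break + a

whose integral from r₀ to r_break is the loading energy capacity
W = k₀/2(r₁−r₀)² + k₀(r₁−r₀)(r_break−r₁) + k₁/2(r_break−r₁)². Note the second
branch is written so the force is continuous at r₁ and the integral is
exactly W; the post-rupture branch is a linear ramp to zero over the
regularization width a (z = 0.1 by default — any positive value preserves
the contracts; small z gives nearly brittle rupture). Broken is an absorbing
state, applied when a converged configuration (quasistatic) or an
integration step (dynamic) carries a bond past r_break + a.

Parameter families:

| family        | r₀ (Å) | r₁ (Å) | r_break (Å) | k₀ | k₁ (kcal/mol/Å²) |
|---------------|--------|--------|-------------|------|------|
| AGE (glucosepane reference) | 18.52 | 22.72 | 31.72 (grid: 25–60) | 0.1 | 8.0 (grid: 6–24) |
| collagen backbone | 14.0 | 18.2 | 21.0 | 17.13 | 97.66 |
| strengthened grip | 14.0 | 10⁵ | 10⁶ | 17.13 | 17.13 |

The collagen backbone, angle and pair parameters are defaults taken from the
established coarse-grained collagen force-field literature, not asserted as
ground truth of any particular study; all are configurable. The k₀ branch of
the backbone bond (up to 30 % bond strain) represents molecular
unfolding/uncoiling; the k₁ branch the stiff covalent backbone.

Pair interactions are 12-6 dispersive (ε = 6.87 kcal/mol at full scale,
cutoff 2.5·σ) with CHARMM-style potential switching over the outer 10 % of
the cutoff, so the pair force is exactly zero at the minimum and goes
continuously to zero at the cutoff; a configurable cap guards extreme
overlap. 1-2 and 1-3 intra-chain pairs are excluded. Bending is
E = 2·k_bend(1 + cos θ) with k_bend = 14.98 kcal/mol/rad² (the harmonic
equivalent near straight, without the sin θ singularity). An optional planar
sine "crimp" geometry (crimp_ratio > 1) with per-triplet native equilibrium
angles exists as a configuration choice but is not used by the presets: its
toe response is intrinsically concave-up, whereas in this force field the
soft k₀ bond branch itself supplies the linear toe.

AGE cross-links are inserted uniformly at random, without replacement, over
admissible bead pairs: endpoints on distinct chains, both within the central
95 % of their chain (glycation occurs in the helical region, not at the
telopeptides), separation at most the insertion cutoff. The cutoff default
is (r₀+r₁)/2 = 20.62 Å so every fresh link starts in the lower half of its
harmonic branch — near equilibrium, never at the brink of the hyperelastic
branch. The realized count is round(N_AGE · n_molecules) with n_molecules
the cross-section molecule count; a supply shortfall warns and records the
realized density. Insertion is deterministic under a fixed seed and
rebuilding a topology from its archived config is bit-identical.

## Tensile protocol

Quasistatic mode (the deterministic reference used by all tests): the grips
move apart symmetrically in displacement increments of gauge/400 (strain
2.5·10⁻³); after each increment the free beads are relaxed by L-BFGS with
analytic gradients (projected-gradient tolerance 10⁻³ kcal/mol/Å), and
minimization alternates with absorbing bond-state updates until the broken
set is stable. The residual grip tension of the relaxed initial state is
tared (stored on the trajectory); strain is grip displacement over the
initial 5·D gauge; engineering stress divides the grip tension by the
undeformed section π·d²/4. A run ends at the target strain or once the
stress falls below 5 % of the running peak (configurable;
`stop_fraction=0` disables early stopping).

Dynamic mode: BAOAB Langevin steered dynamics, grips at constant ±v/2
(reference v = 10⁻⁴ Å/fs = 10 m/s, Δt = 1 fs), default 300 K, damping
1000 fs, bead mass 1.36 kDa. The thermostat settings are modeling choices —
only qualitative agreement (e.g. the softening/stiffening classification,
which matches the quasistatic label on the desk-scale fibril) should be
read from dynamic runs.

The energy/force kernel is numba-compiled; the vectorized numpy
implementation is kept as the reference and the two are cross-checked to
10⁻⁹ in the suite.

## Observables

Stress–strain reduction: the linear limit ε₀ is the largest strain window
[0, ε] whose stress deviates from the least-squares line through the origin
by less than 5 % (relative to the window-end line value). Because athermal
quasistatic loading produces stick-slip sawteeth that thermal dynamics would
average out, the detector operates on a first-order Savitzky–Golay smoothing
(9 frames) of the stress; the window rule is "largest satisfying", so a
single slip avalanche does not void all larger windows. σ₀ = σ(ε₀),
Δσ = σ_peak − σ₀.

Regime classification: stiffening when Δσ exceeds the softening baseline.
The absolute default baseline is 5 %·σ₀; when the matched cross-link-free
reference run is available (always, in sweeps) its own Δσ is used as the
floor instead, because desk-scale stick-slip friction hardens the post-ε₀
plateau by ~30–40 % of σ₀ even in the purely sliding-governed fibril. The
observed label is compared against the capacity criterion
W_TC < N_AGE·W_AGE per cell.

Energy partition: E_stretch(ε) = ∫ F_stretch dΔr_TC with F_stretch the mean
tension and r_TC the mean length of intact collagen bonds, integrated
(trapezoid over frames) from ε*, the first frame where the mean molecular
strain is within 5 % of the fibril strain. E_slide(ε) = ∫ F_slide dΔg with
F_slide = F/n_molecules − F_stretch and Δg obtained by inverting
ε = (Δg + n_TC(r_TC−r₀))/(⟨g⟩ + n_TC·r₀), ⟨g⟩ being the mean initial gap.
Both are reported normalized by a matched N_AGE = 0 reference run (each
evaluated at its own peak strain). The sliding measure is a force-balance
heuristic, and at desk scale it breaks down quantitatively: the gap-end
dispersive interactions of short molecules carry a compressive axial flux,
so the mean bond tension exceeds F/n and F_slide is systematically negative;
normalized E_slide from the 7-chain fibril should therefore be read as
qualitative at best (see Limitations). Broken-bond censuses report broken
AGEs relative to the inserted count and broken collagen bonds relative to
the cross-section molecule count (which may exceed 100 %).

## Desk-scale presets and what they show

The `mini-7` preset (7 chains, 37 beads/molecule, D ≈ 114.5 Å, 6-bead grips)
preserves the structural ratios of the full fibril — gap fraction 0.6,
stagger D, line period 5·D — and two deliberate scalings:

* **Adhesion scaling.** The strain at slip onset (the end of the linear
  regime) scales as (contacts per molecule)·ε_pair/(k₀·r₀); shortening
  molecules from 212 to 37 beads without rescaling would shrink ε₀
  sixfold. The pair well depth is therefore multiplied by the bead-count
  ratio (ε = 6.87·211/36 ≈ 40 kcal/mol), which restores ε₀ ≈ 0.17 for the
  cross-link-free fibril.
* **Registry decoherence.** 37 beads/molecule makes the stagger offset
  incommensurate with the bead spacing, spreading the five stagger-class
  bead registries evenly so the stick-slip avalanches of different
  interfaces do not fire coherently.

Sweep and simulation sizes were chosen so a destructive test takes ~20–40 s
and the full 3×3×2 parameter sweep under ten minutes on one CPU.

What the desk-scale fibril reproduces: the two-phase stress–strain shape;
the softening/stiffening dichotomy and its agreement with the
energy-capacity criterion (16 of 18 sweep cells, the two disagreements
sitting near the criterion boundary); the growth and saturation of σ_peak
with k₁, r_break and N_AGE; the monotone growth of stretching energy with
W_AGE; and the census crossover from broken AGEs to broken TC bonds as
W_AGE rises, with >100 % broken TC bonds per molecule at the grid extremes.

What it does not reproduce: the *density independence* of the linear limit.
With only 7 chains, each cross-link changes the slip-arrest statistics of an
interface by O(1), so ε₀ measures 0.13–0.37 depending on N_AGE and seed
instead of a stable ≈ 0.15; at 155 molecules the same densities are small
perturbations. The normalized sliding energy likewise loses its meaning at
this size (heuristic sign breakdown, above). Real collagen features absent
at any scale here: hydration/osmotic effects, enzymatic cross-links,
mineral, molecule-internal sequence heterogeneity, and tissue-scale
structure.

## Numerical and design choices

* Units: Å, fs, kcal/mol internally; stresses reported in MPa via
  1 kcal/mol/Å³ = 6947.7 MPa; 10⁻⁴ Å/fs = 10 m/s.
* One mandatory seed per run config; cross-link sampling uses it directly;
  rebuilds are bit-identical.
* Quadrature: trapezoid on recorded frames (every increment by default).
* Degenerate inputs: zero-capacity bonds (r₀ = r₁ = r_break) are valid;
  compressed bonds push back through the first branch; a fully gripped
  system skips minimization; deformed topologies are rejected by the
  gap/overlap map, which is defined for the initial state only.
* The gap/overlap map measures occupancy by chain coverage intervals
  (bead-count histograms alias when the bin width is incommensurate with
  the bead spacing) and takes the banding period from the dominant
  power-spectrum component.
* Mirror symmetry: reflecting the specimen axially reproduces the
  quasistatic curve to the minimizer force tolerance.
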