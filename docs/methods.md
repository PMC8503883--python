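# Methods

## Scope and model

`nmrxtal` implements the model side and the data side of a
dipolar-coupling-based NMR crystallography protocol, plus the
chemical-shift-tensor conventions needed to compare computed (GIPAW)
shieldings with experimental shifts.  It deliberately does **not**
compute shieldings (DFT/GIPAW), simulate pulse sequences or spin
dynamics, fit spinning-sideband patterns, pick or deconvolve 2D peaks,
place missing hydrogens, or refine structures: it evaluates *given*
models against *given* integrated intensities.

The central physical object is the squared effective dipolar coupling of
a pair class of magnetically unique sites,

    b²_eff(j,k) = s² Σₙ₌₁..M  [K / rₙ³]²,   K = -(μ₀/4π) γ_j γ_k ħ,

a multiplicity-limited lattice sum proportional to the van Vleck dipolar
second moment.  Only coupling magnitudes enter; no orientational
(tensorial) dipolar information is used.  Its assumptions:

- **Quantitative regime.**  Integrated 2D peak intensities are
  proportional to b²_eff only when the recoupling or CP contact period is
  short enough that every pair's intensity is far from its buildup
  maximum.  `quantitativity_check` diagnoses this from a buildup series
  (I/I_max at the analysis point); the warning threshold defaults to 0.5,
  reflecting that the 2Q–1Q intensity ratio relation stays approximately
  valid well beyond the strict short-time limit, and is configurable
  because the safe bound depends on the spin topology.
- **Spin-1/2, rigid lattice apart from declared motional groups.**  Fast
  rotors (NH₃⁺) and water are declared as site groups whose members are
  averaged; the intra-group ¹H–¹H coupling of a three-fold rotor is
  scaled by s = 1/2.  Heteronuclear couplings *to* such groups default to
  s = 1 (experimentally no attenuation is resolved); any pair's scale can
  be overridden in the config.
- **Ordered structures.**  Partial occupancy is rejected at CIF read
  time rather than weighted — the tool evaluates occupancy-1 models.

## Effective distances

The published form of the coupling→distance inversion states its result
lies between the shortest and longest summed distance, closer to the
shortest.  That bracketing forces normalization by the pair multiplicity
before inverting K/r³, i.e. the −6 power mean

    r_eff = [ M K² s² / b²_eff ]^(1/6) = [ M / Σ rₙ⁻⁶ ]^(1/6),

which is how `effective_distance` is implemented (the motional scale is
divided out).  The raw, unnormalized lattice sum is exposed as
`EffectiveCoupling.b_eff_sq_raw` for diagnostic use.  Two consequences
are used as internal invariants: min ≤ r_eff ≤ max (power-mean
inequality, also r_eff ≤ arithmetic mean), and the exact ratio identity
r_eff^NMR / r_eff^model = (f_model/f_NMR)^(1/6), independent of K, M and
b²_tot, which `distances_from_intensities` asserts on every mapped pair.

**Dipolar multiplicity.**  Which M contacts to sum is not uniquely
defined by the physics; the package accepts either an explicit per-pair
M (matching analyses that quote per-pair multiplicities) or, by default,
sums every contact within the cutoff — the reproducible choice when no
multiplicity table is available.

## Lattice sums

Distances are enumerated by an explicit integer-shell image search sized
from the perpendicular lattice-plane spacings to cover the cutoff (plus
one safety shell), *not* by minimum-image convention: the default cutoff
(1000 pm, configurable) exceeds half the cell edge of typical
small-molecule cells (5–13 Å).  The r⁻⁶ decay makes the sums converge
quickly — for pair classes anchored by a bonded or close contact
(≲ 330 pm in an 8–10 Å cell), doubling the cutoff changes b²_eff by
< 1%; classes whose shortest contact is long converge more slowly, which
is why the cutoff is a config knob and the convergence test uses a
bonded fixture.  Correctness of the image search (heteronuclear and
homonuclear) is pinned against a brute-force supercell double loop with
no shortcuts (`brute_force_beff`, also run as a seeded self-check by
`scripts/acceptance.py`).

Homonuclear self-pairs count each unordered (atom, atom, image) contact
once: ordered atom pairs are kept for a < b over all images, and for
a = b only the lexicographically positive half-shell of images, which
excludes the zero-distance self contact.  This is the double-counting-free
reading of the homonuclear sum.

Symmetry handling: CIF ingestion goes through gemmi (explicit operator
records, or a space-group symbol resolved to operators; no symmetry
means P1).  Expansion to P1 and deduplication are done in-package with a
0.01 Å Cartesian merge tolerance — far below any physical interatomic
distance, far above numerical noise.  Fractional coordinates are wrapped
to [0, 1); site groups defined on the asymmetric unit follow their
members' images on expansion.

## Intensities to fractions

`fractional_contacts_nmr` computes f = I/I_tot.  By default I_tot is the
sum of included, assigned intensities, making Σf = 1 — the convention of
tabulated analyses; a whole-spectrum integral can be supplied instead
when unassigned intensity exists, in which case both the raw and
renormalized fractions are reported.  A 2Q–1Q cross peak is recorded as
the *sum* of its two symmetric peaks; autocorrelation (diagonal) peaks
are single entries.  Exclusions are never silent: records marked `n.d.`
or excluded with a reason are dropped from the normalization and carried
through to the reports with the reason attached.

Uncertainty: the implemented propagation is the first-order rule
σ_rel(r) = σ_rel(f)/6 of r ∝ f^(−1/6).  Published homonuclear analyses
quote slightly larger distance uncertainties than f/6 for some classes
(extra contributions from the total-coupling anchor); those additional
terms are not itemized in the source data and are not modelled.

## Shift-tensor conventions

Shielding→shift conversion is δ_αα = σ_ref − σ_αα, with σ_ref calibrated
by offset-only least squares (slope fixed at −1): σ_ref =
mean(δ_exp + σ_calc), cross-checked in the tests against a 1-D grid
search.  Components are relabelled by descending |δ_αα − δ_iso|
(zz, xx, yy), giving δ_aniso = δ_zz − δ_iso, η = (δ_yy − δ_xx)/δ_aniso ∈
[0, 1], span Ω = |δ_zz − δ_xx| and ι = δ_iso − δ_yy; sign(ι) =
sign(δ_aniso) always (property-tested on random tensors).  The common
alternative convention quotes an anisotropy larger by 3/2;
`convert_convention` interconverts exactly.  Numerical choices: exact
ties in |δ_αα − δ_iso| (axially symmetric tensors, and the η = 1
boundary where the sign of δ_aniso is genuinely ambiguous) are broken by
a stable sort on input order; isotropic tensors (relative deviation
≤ 1e−12) report η = 0 with an `isotropic` flag instead of NaN.

## Reference data and known discrepancies

`nmrxtal.refdata` carries the published phosphoserine / calcium
phosphoserine reference tables (cells, isotropic shifts, CSA tensors,
contact analyses) that drive the regression suite.  Values are kept
exactly as printed.  Three classes of internal inconsistency in the
printed values are flagged as `KNOWN_DISCREPANCIES` and asserted *as
documented* rather than patched: (i) the water GIPAW per-site shifts
{2.8, 6.8} ppm average to 4.8, not the printed 4.6; (ii) the printed ¹H
shift-correlation rmsds (0.12/0.37 ppm) are not reproducible from the
rounded printed shift pairs (the ¹³C rmsds 1.4/1.8 ppm are, and are
regression-tested); (iii) three CSA rows do not round-trip at printed
precision from their own 0.1-ppm-rounded principal values (e.g.
η = 14.1/16.7 = 0.844 → 0.84 vs printed 0.85) — these are asserted to
one unit in the last printed digit, the self-consistent rows exactly.

## Synthetic data

The generator (`nmrxtal.synth`) emulates the *quantitative regime*
directly: random P1 cells with uniform site placement under a
periodic-image-aware minimum separation (default 150 pm), and peak
intensities I = b²_eff · exp(σ·z), z ~ N(0,1) — multiplicative lognormal,
because integration error is scale-proportional.  All stochastic
generation requires an explicit seed (NumPy PCG64) and is reproducible
across platforms.  What it does *not* emulate: buildup dynamics and
quantitativity violations, spin diffusion, relaxation, peak overlap, or
assignment ambiguity.  Passing tests therefore demonstrate the
correctness of the lattice-sum → fraction → distance pipeline and its
statistics, not robustness to non-quantitative experimental conditions —
those failure modes are exactly what `quantitativity_check` and the
exclusion mechanism exist to surface on real data.

Problem sizes used in the test suite were chosen for tight feedback
while keeping the statistics meaningful: oracle cross-checks on ≥ 50
random cells, ranking recovery on 100 trials × 4 proton-perturbed decoys
(0.2–0.5 Å displacements), and the σ/6 propagation rule verified by
Monte-Carlo over 100 seeds pooled across pair classes (≈ 600 draws, so
the sampling error of the spread estimate is ≈ 3%).

## Limitations

- Effective distances are class-averaged observables, not individual
  internuclear distances; pair classes dominated by several comparable
  contacts are intrinsically less structure-discriminating.
- The fraction→distance anchor b²_tot comes from the reference model, so
  NMR-derived distances inherit a (common-mode) dependence on it; two
  different reference models give different r_eff^NMR sets by design.
- R² between distance sets is the squared Pearson correlation — it is
  blind to systematic offsets, which is why ranking defaults to the rmsd
  of per-pair deviations (both are always reported).
- Partial occupancy, disorder, and anisotropic displacement are out of
  scope; structures carrying them are rejected or must be pre-processed.
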