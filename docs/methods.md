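# Methods

## The physical model

The package models a self-associating hub protein A (the Nup53 core
fragment, dimerizing through its RRM domain) with two independent classes
of IDR binding sites: a C-terminal site for a karyopherin B (Kap121) and an
N-terminal site for a partner nucleoporin C (Nic96).  Six reaction schemes
of increasing complexity are supported; each is defined by the subset of
equilibrium constants it activates (constants outside the subset are
identically zero, which makes the scheme reductions exact identities rather
than numerical limits):

| scheme | active constants | describes |
|---|---|---|
| `MONOMER_DIMER` | K_sc | dilution/dissociation experiments |
| `SINGLE_SITE` | K3 | classic 1:1 titrations |
| `TWO_MODE` | K3, K4 | 1:1 plus bivalent 2:1 binding of a monomeric hub |
| `MULTI_EQ` | K_sc, K1–K4 | TWO_MODE plus dimerization and dimer–Kap modes |
| `TERNARY` | K_sc, K1–K7 | full allosteric three-component system |
| `TERNARY_MONOMERIC` | K3, K4, K5, K7 | dimerization-deficient hub + Kap + partner |

K1, K3, K5, K6, K7 are bimolecular (M⁻¹); K2 and K4 are overall
termolecular constants (M⁻²).  K5–K7 are *per-site* constants for the
partner: species carrying two hub N-terminal sites bind the first C with a
statistical factor of 2 and the second with the squared constant.  The
allosteric linkage is encoded entirely in K6 < K5 and K7 < K5 (Kap loading
of the C-terminal site weakening the distal N-terminal site); no explicit
coupling energy parameter is introduced.

## Units

Internally: concentrations in molar, volumes in litres, enthalpies in
cal/mol, heats in cal.  The public surfaces (files, CLI JSON, reports) use
µM, µL, kcal/mol and µcal.  This split avoids magnitude-driven round-off in
the solver while matching calorimetry convention where users read numbers.

The gas constant defaults to R = 1.9872 cal mol⁻¹ K⁻¹ and the temperature
to 288 K (15 °C); both are per-scheme fields.  We deliberately use R to
four significant figures rather than the two-decimal convention (1.99)
sometimes quoted in calorimetry tables: at the strongest termolecular
constants handled here (K ≈ 4×10¹⁴ M⁻²) the rounding of R alone shifts
ΔG° by ~0.06 kcal/mol, which is more than the precision such tables print.
ΔG° = −RT ln K takes the logarithm of the numeric value of K in its
tabulated unit (M⁻¹ or M⁻²), with no standard-state decomposition of the
termolecular constants, matching how such tables are conventionally
reported; TΔS° = ΔH° − ΔG° is exact by construction.

## Equilibrium solving

Every species is at most second order in A, so for known free [B] and [C]
the A mass balance is a quadratic p[A]² + q[A] − A_tot = 0 solved in the
cancellation-free form [A] = 2·A_tot/(q + √(q² + 4p·A_tot)), which also
covers p → 0 smoothly.  Free [B] (and [C] for ternary schemes, nested
outside the B solve) are found with Brent's method on the corresponding
mass-balance residual over [0, total]: the residual is −total at 0 and
non-negative at the upper end, so a bracket always exists and convergence
is unconditional.  The absolute x-tolerance is set essentially to zero
(1e-300) with the relative tolerance at scipy's floor (4·eps): free-ligand
roots can sit twenty decades below the total when a tight binder is fully
sequestered, and any total-scaled absolute tolerance terminates Brent's
method before the residual is satisfied.  Mass balances close to better
than 1e-10 relative across K ∈ [10³, 10¹²] and totals ∈ [0.1, 500] µM
(verified against the independent oracle below on 200 seeded draws).

Degenerate limits (zero totals, zero constants, absent components) are
handled analytically, not by epsilon-regularization, so `TWO_MODE` equals
`MULTI_EQ` with K_sc = K1 = K2 = 0 bit-for-bit, and `TERNARY` with
total C = 0 equals the binary solve.

**Verification oracle.**  `oracle_solve` solves the same balances by
damped multiplicative fixed point — every free concentration is rescaled by
(total/reconstructed)^δ with δ ∈ {0.5, 0.25, 0.1} tried in order — from a
species table written independently of the production formulas.  It shares
no code path with the production solver and is used only in tests.

## Injection heats

Each injection is an equilibrium-to-equilibrium step.  The injected volume
is taken as instantaneously mixed before an equal volume of the mixture
overflows the active cell volume, so totals update as
old·(1−v) + syringe·v with v = V_inj/V_cell.  The heat is accumulated per
*bond group*: each complex is decomposed (Hess-style) into its formation
steps, and the concentration of formed bonds of step k, [G_k], carries that
step's enthalpy.  For injection i,

q_i = V_cell · Σ_k ΔH_k · { [G_k]_i − [G_k]_{i−1} − v·[G_k]_syr
                            + v·([G_k]_i + [G_k]_{i−1})/2 }.

The subtraction of v·[G_k]_syr removes bonds delivered pre-formed from the
syringe; the trapezoidal term accounts for material that reacted in the
displaced volume.  This single expression covers forward and reverse
association titrations (where the syringe holds a free component and the
delivery term vanishes), the oligomer-shift contributions (dimer
redistribution when ligand binding consumes or releases dimer), and
dilution-driven dissociation (where the syringe term *is* the signal:
dimer arriving from the concentrated syringe dissociates on dilution,
giving heats of sign opposite to the formation enthalpy).  Exothermic
events give negative q.

Heats are reported raw in µcal; `Isotherm.normalized_q` exposes the
kcal-per-mole-of-injectant view derived from [R]_inj·V_inj.  Fitting is
invariant to which view is used as long as it is used consistently; the
raw view is the fitting surface.

The trapezoidal displacement correction is a first-order discretization:
halving injection volumes changes the cumulative heat by well under 0.1% of
the total absolute heat.  (For biphasic designs the plain cumulative sum
nearly cancels between the endothermic and exothermic phases — the tests
therefore normalize the discretization check by the heat scale, not by the
cancelling sum.)

## Global fitting

Thermodynamic parameters are global across datasets; per-dataset nuisance
parameters are a multiplicative activity factor on all stated
concentrations (bounds [0.5, 1.1], start 0.9, motivated by protein batches
typically 75–100% active) and an additive per-injection heat of dilution
(µcal, unbounded).  Constants are optimized as log₁₀ K with bounds [0, 16];
enthalpies in kcal/mol with bounds ±100 — positivity and conditioning,
bounds far outside plausible values.  χ² is the unweighted sum of squared
µcal residuals (per-dataset weights are available, default 1).

The optimizer is scipy's bounded trust-region-reflective least squares
(a Levenberg–Marquardt-type damped Gauss–Newton step within bounds), run
from multiple starts because the biphasic multi-equilibrium surface can be
multimodal: the first start uses heuristic initials (Wiseman c ≈ 10 for
constants, i.e. K ≈ 10/[hub], squared for M⁻² constants; the
first-injection normalized heat for enthalpies, clipped to 0.5–20
kcal/mol), and subsequent starts perturb constants uniformly within ±2
decades and enthalpies within ±10 kcal/mol from a generator seeded by the
caller.  The lowest-χ² start wins; a start reaching χ² < 1e-10 µcal²
(an exact fit) short-circuits the rest.  Results are deterministic given
the seed.  A solver failure during a trial step contributes
large-but-finite penalty residuals (10⁶ µcal) with a logged warning, so
the optimizer backs away instead of crashing on NaN.

Parameter SDs come from the residual-variance-scaled covariance at the
optimum, cov = s²(JᵀJ)⁻¹ with s² = χ²/(N−p), computed by SVD with
near-null directions reported as unidentifiable by parameter name; SDs are
propagated to the natural scale (sd(K) = K·ln10·sd(log₁₀K)).

**A known degeneracy.**  A single activity factor that scales *every*
concentration in a dataset is exactly degenerate with rescaling the
constants and enthalpies: (K, ΔH, a) and (aK, aΔH, 1) produce identical
heats for any scheme whose constants all float (for an n-th order constant
the compensation is aⁿ⁻¹·… — exact in all cases, as follows from
substituting scaled totals into the mass balances).  Activity is therefore
identifiable only when at least one constant is pinned by a companion
experiment, which is how the fitting strategy is meant to be used; the
uncertainty machinery flags the degenerate configuration as unidentifiable
rather than hiding it.

`compare_models` reports χ²(B)/χ²(A) for two fits of identical datasets
plus a per-dataset residual breakdown locating where the worse model's
misfit concentrates.  Tied parameters (e.g. the no-cooperativity
alternative in which the dimer–Kap constants are dictated by the monomer
1:1 constant as 2K and K²) are expressed as callables evaluated after each
parameter update.

## Populations

Population distributions are fractions of hub monomer equivalents (a dimer
contributes two), so mutually exclusive hub states always partition to 1;
a per-particle weighting is available as an option.  Groupings: per
species, hub states by bound ligand types (free / Kap-only / partner-only /
both), and Kap binding modes (free, 1:1, bivalent 2:1, dimer·Kap,
dimer·Kap₂).  The ternary surface reports partner occupancy — hub-bound C
per hub monomer — on a (C:A, B:A) molar-ratio grid; with the Kap-loaded
site constants below the free-site constant it is strictly decreasing along
the Kap axis.  Default grid: 101 points per axis over ratio 0–3 at 15 µM
hub.  The published 0.6 → 0.3 drop in partner occupancy between zero and
twofold Kap (at 1:1 partner:hub) is reproduced at a hub concentration of
4 µM, found by scanning 1–20 µM since the plotted concentration is not
stated.

## Synthetic data

The generator wraps the forward model with an observation model: true
activity factor, constant per-injection dilution heat, and i.i.d. Gaussian
heat noise from a seeded generator (bit-identical for identical seeds).
Defaults emulate the study conditions — 202.8 µL cell, 20 × 2 µL
injections at 288 K, 15 µM cell / 150 µM syringe (spanning molar ratio
0–2.2), concentration series at 15/30/60 µM for the global analyses,
dilution series at 300/450/600 µM syringe, and σ_q = 0.2 µcal, typical of a
low-volume calorimeter (the source experiments do not state a noise
magnitude).  The injection count is likewise not stated; 20 × 2 µL
(~20% volume delivery) is chosen to cover both phases of the biphasic
isotherms.  `generate_study_suite` writes one fixture class per published
experiment design, each with clean and noisy variants plus a truth sidecar.

What the generator does *not* emulate: baseline drift, injection-volume
errors, first-injection artefacts, slow-equilibration (kinetic) distortion
of peaks, and concentration-dependent aggregation.  Passing recovery tests
therefore demonstrate correctness of the solvers, heat bookkeeping and
optimizer — not robustness to every artefact of real thermograms.

## Numerical and design choices

- Injection heats and fits treat each injection as reaching equilibrium;
  no power-versus-time (kinetic thermogram) modelling, matching how
  integrated heats are analyzed.
- No heat-capacity (ΔCp) term: single-temperature experiments.
- The reverse-titration syringe (concentrated hub) is solved for its own
  dimerization equilibrium, so injected material carries pre-formed dimer.
- Population denominators count monomer equivalents because "fraction of
  hub in state X" is a per-molecule-of-hub quantity in the source plots.
- The model-selection χ² ratio between the cooperative scheme and the
  tied-constant alternative is a qualitative check (> 1): its magnitude
  depends on the experimental noise level, which is not published; at the
  generator's default σ_q = 0.2 µcal it comes out around 4–5.
- The apparent partner constant in the presence of Kap is recovered to
  about +10% of the published 1.3×10⁵ M⁻¹; the exact value depends on the
  (unstated) concentrations of the original competition titrations.

## Known limitations

- Activity factors require pinned constants (see the degeneracy above).
- The heat model's trapezoidal displacement correction is first-order in
  V_inj/V_cell; for the default 1% injection fraction this is far below
  realistic noise but matters if one simulates very large injections.
- Ternary solves nest two scalar root searches; a 101×101 population
  surface takes a few tens of seconds on one core.
- The solver suite covers the schemes above; arbitrary user-defined
  reaction networks are out of scope.
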