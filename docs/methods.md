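# Methods

This note records the models implemented in `solusaxs`, their assumptions,
the numerical choices behind them, and what the synthetic-data exercises do
and do not demonstrate.

## Scattering framework

All models compute the orientation- and size-averaged squared excess
scattering amplitude per particle, ⟨|A(Q)|²⟩, in Å² (amplitude = contrast ×
volume, Δρ in Å⁻², lengths in Å).  Absolute intensity follows as

    I(Q) [cm⁻¹] = n [cm⁻³] · ⟨|A(Q)|²⟩ [Å²] · 10⁻¹⁶ [cm²/Å²] + b,

with a flat background b.  Number densities n come from the composition
ledger: total amphiphile concentrations (minus the CMC-level free monomer,
which is treated as scattering-silent) divided by the per-particle
amphiphile count implied by the model geometry and molecular volumes.
All bodies are centrosymmetric, so amplitudes are real; Q = 0 is evaluated
by series expansion.

X-ray SLDs are ρ = r_e n_e/V with r_e = 2.818×10⁻⁵ Å; water at 0.334 e/Å³
gives 9.41×10⁻⁶ Å⁻².  Each species carries a head/tail partition
(phosphocholine + glycerol + carbonyls vs acyl chains for PC lipids) with
default ambient volumes; per-temperature volumes are supplied by overriding
them on the `Species` (densitometry → `apparent_molecular_volume`).
TX-100, polydisperse in ethoxylation, is carried as a monodisperse average
(MW 625), which reproduces its label molarities.

## Morphologies

**Vesicles.**  Three concentric shells (head / hydrocarbon / head) around a
solvent core; the methyl dip at the bilayer center is deliberately omitted —
at Q ≤ 0.5 Å⁻¹ a three-shell profile describes vesicle curves equally well
and keeps coexistence fits tractable.  Radius polydispersity is a Gaussian
number distribution, truncated at ±3σ and integrated with 25 Gauss–Legendre
nodes; relative σ ≥ 0.5 is rejected because the truncation becomes unsound.
A fraction f_ML of vesicles is multilamellar with N correlated bilayers:
I_ML = I_uni · S_N(Q), where S_N is a 1D paracrystal with Gaussian
cumulative displacement disorder,

    S_N(Q) = 1 + (2/N) Re Σ_{k=1}^{N-1} (N−k) r^k,
    r = exp(iQd − Q²σ_d²/2),

evaluated by complex geometric sums (degenerate r → 1 handled exactly;
S_N(0) = N, Bragg maxima near 2πk/d).  A paracrystal was chosen over a
modified-Caillé form because the kinetic analyses parametrize stacking
growth directly by (f_ML, N).

**Asymmetric vesicles.**  Four shells (head_in / tail_in / tail_out /
head_out); each leaflet's head and tail SLD follows from volume-fraction
mixing of lipid and detergent at leaflet mole fractions x_in, x_out.
Mole-fraction input with volume-weighted mixing was chosen as the physically
standard reading; x_in = x_out reduces exactly to the symmetric model.

**Micelles.**  Core–shell bodies with tails in the core and hydrated heads
in the shell.  Three variants: ellipsoid of revolution (SDS-like), triaxial
ellipsoid (DDM-like), and fuzzy sphere (TX-100-like) in which the outer
interface is smeared by exp(−Q²σ_f²/2) and a fraction of the tail volume
may mix into the shell.  Aggregation numbers follow from core volume over
(per-molecule) tail volume.  Inter-micellar repulsion enters through the
Percus–Yevick hard-sphere structure factor in the decoupling approximation,
S_eff = 1 + β(Q)(S_PY − 1) with β = ⟨A⟩²/⟨A²⟩; β = 1 exactly for spheres.
S_PY uses the closed analytical form for Qd ≥ 0.5 and 64-point quadrature
of the defining PY direct-correlation integral below (numerically stable at
Q → 0, matching S(0) = (1−φ)⁴/(1+2φ)²); φ ≥ 0.74 is rejected.

**Bicelles.**  Core–shell disc: a lipid-tail cylinder capped by polar
faces, with a full-height rim annulus carrying detergent at a rim mole
fraction; rim SLD by volume mixing.  The amplitude is a contrast-step sum
of three coaxial cylinders (2J₁(x)/x radial × sinc axial), orientation
averaged.  rim = 0 with uniform SLD reduces exactly to a homogeneous
cylinder.

**Rods and worms.**  Longitudinal factor × core–shell circular
cross-section (valid for contour ≫ cross-section).  The semiflexible
factor is the Kholodenko worm-like-chain form; for Kuhn length ≥ contour
length the code switches to the exact rigid-rod (Neugebauer) average so the
straight-cylinder limit is exact rather than asymptotic.

**Coexistence.**  Populations add incoherently (uncorrelated dilute
particles, no cross terms).  In mass-conserving mode lipid fractions sum
to 1 and detergent fractions to ≤ 1 (remainder = monomer), and per-population
number densities follow from the assigned fractions and per-particle
compositions.

**Kinetics.**  Time series are fitted frame by frame with shared particle
geometry and one free solubilized-lipid fraction per frame (bounded scalar
minimization; 1σ from the χ² curvature).  Named trajectories
(single-exponential, stretched-exponential, and a two-stage
lag-then-growth form with continuous fraction at the changeover) can be
fitted to the resulting fraction–time tables.  Multilamellar growth is
handled nonparametrically (per-frame f_ML, N with shared vesicle geometry),
since observed stacking kinetics do not follow simple exponential forms.

## Orientational averages and quadrature

Fixed-order Gauss–Legendre: 76 points in the tilt angle for bodies of
revolution, a 76×76 product grid over the orientation octant for triaxial
ellipsoids.  Doubling the order changes intensities by < 0.05% over
Q ≤ 0.5 Å⁻¹ (tested).  The worm-like-chain integral uses 128 nodes with
large-argument asymptotics for sinh ratios.

## Fitting

Bounded trust-region least squares (`lmfit` → `scipy.optimize.least_squares`)
on σ-weighted residuals, with Jacobian-based variable scaling and relative
finite-difference steps of 10⁻⁴.  Options: seeded multi-start (uniform
±15% perturbations of free parameters, best χ² kept) and a coarse
grid scan of a named parameter before the local fit, during which the
particle number density is profiled out analytically — the standard guard
against the oscillatory local minima of shell form factors when the vesicle
radius start is far off.  The number density is fitted as log₁₀(n).
Model comparison ranks candidates by χ² + 2k (AIC-like); non-converged
candidates rank last and ties are flagged.  No instrument resolution
smearing is applied by default (synchrotron point collimation); σ-columns
are used as given.

## Synthetic data

The generator emulates high-flux synchrotron 1D curves: Q = 0.004–0.5 Å⁻¹,
log-spaced, 600 points by default, absolute intensity, Gaussian noise with

    σ(Q) = noise_floor · I(Q) + counting_constant · √I(Q),

noise_floor = 1% (calibration-limited floor) and counting_constant =
2×10⁻³ cm⁻¹ᐟ² (photon statistics dominating where the signal is weak).
Gaussian rather than Poisson noise reflects azimuthally averaged data with
reported σ.  Scenario fixtures cover every morphology (extruded DPPC
vesicles with residual multilamellar fraction 0.25, the three neat
detergent micelles, bicelles, worms, asymmetric vesicles at x_in = 0.05 /
x_out = 0.30), a vesicle+bicelle coexistence at solubilized fraction 0.60,
and kinetic series (staged vesicle→bicelle growth ending at 0.63, a
multilamellarity ramp, a fast-opening/slow-restacking sequence).  Lipid
mass concentration defaults to 2.5 mg/mL.

What passing these exercises shows: the closed forms agree with independent
numerics, and the estimation pipeline recovers known parameters under the
stated noise model.  What it does not show: real detergent/lipid curves
contain features deliberately out of scope here — rippled-bilayer Bragg
patterns (not describable by these analytical models), inter-vesicle
clustering at low Q, resolution smearing, radiation damage — so agreement
with synthetic data bounds implementation correctness, not the adequacy of
any model for a particular measured sample.

## Problem sizes

Recovery exercises use 300-point curves and the model-selection replicates
200-point curves with a 300-evaluation cap per candidate fit; these sizes
give stable verdicts (score gaps of orders of magnitude between generating
and competing models) at interactive runtimes.

## Known limitations

- Multilamellar interference multiplies the polydispersity-averaged
  unilamellar intensity (stacking decoupled from shell curvature), and
  adjacent-shell radii are not tied to d-spacing.
- The decoupling approximation degrades at high anisotropy together with
  high volume fraction.
- The fuzzy-sphere smearing applies to the outer interface only.
- Leaflet mixing ignores partial-volume changes on mixing.
- The worm cross-section factorization neglects end-cap scattering.
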