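# Methods

## Rheological model of post-ablation recoil

The tissue around a linear laser cut is modelled as a zero-dimensional
circuit: a spring *k* representing the ablated cell patch, in combination
with two Kelvin–Voigt elements in series (springs k_f, k_s; dashpots η_f,
η_s), all under a constant stress σ. Ablation removes *k*; writing the force
balance for each KV element, σ = k_i x_i + η_i dx_i/dt, and starting from
the pre-ablation equilibrium x_i(0) = σ(1−κ)/k_i gives the bond displacement

    Δx(t) = X_f (1 − e^{−t/τ_f}) + X_s (1 − e^{−t/τ_s}),

with X_{f,s} = σκ/k_{f,s}, τ_{f,s} = η_{f,s}/k_{f,s}, κ = k/(k + k̄),
k̄ = k_f k_s/(k_f + k_s). Assumptions: σ is unchanged by the ablation, the
response is linear, and spatial structure is ignored (the model describes
the displacement of the bond nearest the cut, not a strain field). Only the
four observables (X_f, X_s, τ_f, τ_s) are identifiable; the five mechanical
parameters are constrained but not unique, so the package never inverts a
single trace for absolute σ or stiffnesses.

Typical parameter scales, used as generator defaults: X_f ≈ 1.8–2.6 µm,
X_s ≈ 6–8 µm, τ_f ≈ 0.65 s, τ_s ≈ 20 s. Times are in seconds, displacements
in micrometres; stresses and elastic constants are in consistent arbitrary
units (only ratios are observable).

### Derived proxies

* Initial recoil velocity v = Δx(δt)/δt with δt = 0.65 s, the dark interval
  during which the laser fires and no imaging is possible. With the scales
  above, 1 − e^{−δt/τ_f} ≈ 63% of X_f but only ≈ 3.2% of X_s has relaxed by
  the first observed frame, so the fast element contributes ≈ 86% of v at
  the band midpoints: v is a fast-mode proxy, not a stress readout.
* Recoil anisotropy δv = v_PD − v_AP across the two cut orientations,
  proportional to the shear stress along the proximal–distal axis.
* Active-stress residual ζ/2K = σ̃/2K − Q from the constitutive relation
  σ̃ = 2KQ + ζ; the normalized stress σ̃/2K is an external input (from a
  circular-ablation method), only the subtraction is performed here.

### Fitting

Bounded (all parameters > 0) trust-region least squares on the full,
unweighted trace, evaluated at t + δt because observed time zero is the
first post-gap frame. Initialisation is deterministic and data-driven — the
plateau from the mean of the last 10% of samples, τ_f from the first sample
reaching 30% of the plateau, τ_s from the time to 80%, X_f/X_s split 20/80 —
so a given trace always yields the same fit; there are no random restarts.
Fitted pairs are reported in canonical order τ_f ≤ τ_s (the model is
symmetric under element exchange); fits whose two timescales agree within 5%
are flagged as effectively single-exponential. Single- vs double-exponential
selection uses AICc on Gaussian residuals (k = 3 vs 5 parameters including
the noise variance). Non-convergence returns the best iterate with
`converged=False`; monotone-decreasing traces are flagged rather than
rejected.

## Kymograph analysis

A kymograph (rows = positions along a line perpendicular to the cut, row 0 =
proximal/anterior; columns = frames at 0.09 s) shows the two membranes of an
ablated cell as bright ridges. Frames during the ablation are dark; the gap
is carried in metadata (duration 0.65 s, matching the first observed
timepoint; the nominal shooting time of 0.67 s is not used because the
velocity definition is anchored to the first observed frame).

Preprocessing is a Gaussian blur of σ = 1 px applied along the spatial axis
only. Blurring across the time axis mixes dark-gap columns into the first
post-gap frame and biases its apparent ridge position by ~0.7 px — exactly
the frame the initial recoil velocity is read from — so temporal smoothing
is opt-in (`sigma_t`).

Tracking is deterministic ridge detection, chosen over a trained pixel
classifier for reproducibility: per frame, spatial smoothing at the
detection scale (σ = 2 px), local maxima above an Otsu threshold computed on
the observed frames, three-point parabolic sub-pixel refinement, and
continuity linking to the previous frame's pair (first frame: the pair
bracketing the image centre). Frames with fewer than two ridges are
interpolated from neighbours and down-weighted in `quality`; >30% such
frames aborts. Measured performance on synthetic kymographs: <0.01 px bias
without noise, ≈0.25 px median RMS separation error at background noise
sd 0.05.

The displacement trace is (current separation) − (mean pre-gap separation)
at each post-gap frame. The dark-frame velocity estimator averages the two
per-membrane jumps across the gap; since the generator splits Δx equally
between membranes, the per-membrane mean is Δx/2, and the default
`bond_displacement=True` rescales by 2 so the image-based and closed-form
velocities agree.

## Cell elongation and shear decomposition

The elongation of a cell with area A_c is the traceless symmetric tensor
ε_xx = (1/A_c)∫cos 2φ dA, ε_xy = (1/A_c)∫sin 2φ dA, with φ the polar angle
about the cell centroid (centroid origin makes the tensor
translation-invariant; it is scale-invariant by construction and rotates by
the double angle). ε_xx is reported as Q, the proximal–distal component
(x = proximal→distal, y = anterior→posterior). The integrals are evaluated
in closed form on the centroid triangle fan: on each signed triangle the
boundary edge is a line r(φ) = d/cos(φ−φ₀), and

    ∫ cos2φ · r²/2 dφ = (d²/2)[cos2φ₀(2ψ − tanψ) + 2 sin2φ₀ ln cosψ],

ψ = φ−φ₀ ∈ (−π/2, π/2), with the analogous sine form. This is exact for any
simple polygon (signed triangles handle non-convexity); a rejection-sampling
Monte-Carlo integrator serves as the independent oracle in the tests. For an
ellipse with semi-axes a ≥ b along x the closed form gives
ε_xx = (a−b)/(a+b); a regular hexagon gives exactly zero.

Regional Q is the unweighted mean of per-cell ε_xx by default; an
area-weighted option exists because which average the original tissue-database
tooling used is not documented.

### Peak alignment (hRPCE)

Movies are aligned on the maximum of blade-mean elongation: a quadratic is
least-squares fitted to the 40 frames on each side of the absolute maximum
(5-min frames ⇒ ±3.3 h window, truncated and flagged at series boundaries)
and the vertex time becomes the 0 hRPCE origin. Ties break to the earliest
index (flagged); an upward-opening fit is an error; a vertex outside the
window falls back to the argmax (flagged). Known limitation: on a peak with
asymmetric rise and decay the wide-window quadratic vertex is systematically
shifted (≈0.2–0.5 h for rise/decay widths of 3/5 h). Because hRPCE is a
relative timescale the shift is common to all movies and cancels in
alignment, but the synthetic timecourse defaults to symmetric widths so that
the recovered peak also matches the generative peak time; asymmetry is
opt-in.

### Coarse shear decomposition

Per interval between mesh snapshots: total_xx is the change of the region's
shape anisotropy ½·ln(λ_PD/λ_AP), where λ are the principal **axis lengths**
(square roots of the eigenvalues) of the region's area-normalized second-
moment tensor accumulated over all cells about the region centroid, and the
PD axis is the eigenvector closer to x. Using axis lengths rather than raw
eigenvalues makes an affine stretch e^s along x register as total_xx = s,
commensurate with the cell-elongation scale (for a near-isotropic cell,
δε_xx ≈ s). cell_shape_xx is the change of regional mean Q, and
rearrangement_xx = total_xx − cell_shape_xx is a residual that absorbs
neighbour exchanges, divisions, extrusions and correlation effects — this is
deliberately NOT the full triangle-method decomposition, which would
separate those terms; the closure total = shape + rearrangement holds
exactly by construction. On a purely affine deformation of a hexagonal mesh
the residual is <1% of total (small-strain mismatch between region-shape and
cell-shape measures plus finite-lattice anisotropy); on a repacking cascade
(cells keep their shapes while their centres spread) the residual carries
essentially all the shear.

## Genotype statistics

Comparison protocol: Shapiro–Wilk on every group at the comparison α
(default 0.05; the gate level is a convention choice). All normal → Student
t (2 groups) or one-way ANOVA (>2); any non-normal group → Mann–Whitney U or
Kruskal–Wallis (conservative any-failure rule). All test statistics come
from scipy; the package's own content is the dispatch rule and the
resampling machinery.

Subsample power: for each candidate size m, draw m values with replacement
from every genotype pool, run the tie-corrected Kruskal–Wallis test across
the groups, repeat n_iter times (default 10,000) and report the significant
fraction. Default sizes are {3,…,10, 20, 40}. The χ² reference for KW is
poor at m = 3 per group (N = 12); a seeded Monte-Carlo permutation reference
(`p_method="permutation"`) is provided for small m. Exact enumeration is not
attempted: resampling ties break exactness anyway, and sampled permutations
give the same calibration benefit. Fully tied resamples count as
non-significant. Under an exchangeable null (every group resampled from one
common pool) the rejection fraction is within binomial noise of α for
m ≥ 5; resampling from four *independently drawn* null pools is slightly
anticonservative because pool-level sampling differences are real
differences between the resampling sources.

Adult-wing shape is summarised as the major-to-minor axis ratio of the
area-normalized second-moment ellipse, √(λ_max/λ_min), computed exactly from
polygon moments or from pixel masks; it is invariant to rotation,
translation and scale.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (scenario, seed).

* Recoil parameters: truncated normals centred in the measured bands
  (X_f: 2.2 ± 0.2 µm on [1.8, 2.6]; X_s: 7.0 ± 0.5 µm on [6, 8];
  τ_f: 0.65 ± 0.05 s; τ_s: 20 ± 2 s). The bands are published ranges; the
  distributional shape and dispersions are stand-ins chosen so that fitted
  scatter resembles published box plots (qualitative calibration, not a
  claim). The mutant scenario multiplies k_f by 1.5 with η_f scaled
  identically, so X_f drops by 1/1.5 while τ_f and the whole slow element
  are conserved — the "only X_f changes, τ_f preserved" phenotype.
* Traces: the closed-form curve at the 0.09 s cadence offset by the 0.65 s
  gap, plus i.i.d. Gaussian noise. Real traces have correlated tracking
  noise and occasional segmentation failures that this does not reproduce.
* Kymographs: two Gaussian ridges (width 0.4 µm) split the bond displacement
  symmetrically, with Gaussian background noise and per-membrane intensity
  jitter; dark gap frames. The intensity profile is this package's own
  construction — image-level comparison with real microscope kymographs is
  not meaningful, only parameter-level recovery is.
* Meshes: regular hexagonal lattices under scripted programs (static, affine
  pure-shear ramp, or repacking "T1 cascade" in which cell centres spread
  along x by e^{2s} while shapes stay fixed). No real topology changes,
  divisions or extrusions are simulated.
* Elongation timecourse: base + peak Gaussian bump (defaults: base 0.02,
  peak 0.20 at 23 hAPF, width 4 h) sampled every 5 min.
* Wing pools: Gaussian aspect ratios at the published pool sizes (wt 53,
  pk 47, stbm 74, fmi 56), sd 0.06, wild-type mean 2.20, and a rounding
  shift of 0.08 (≈1.3 sd) applied to pk and stbm only. The shift is a
  calibrated, arbitrary constant chosen once so that the full four-pool
  Kruskal–Wallis test is decisively significant while the m = 3 subsample
  power is ≈20% — the regime where a real phenotype hides from small
  samples. Passing tests therefore show the machinery behaves correctly in
  that regime, not that real wings have this effect size.

## Numerical choices

* ODE cross-check: the closed-form displacement is validated against LSODA
  integration of the two force balances at rtol 1e-11; agreement is ~1e-10
  relative, far inside the 1e-4 test tolerance.
* Quadrature: none needed — polygon integrals (area, centroid, second
  moments, elongation harmonics) are all closed-form; edges collinear with
  the origin contribute zero and are skipped.
* Fit tolerances: xtol = ftol = 1e-12 so noiseless round-trips recover
  parameters to ~1e-10; the documented recovery tolerances (X_s within 5%,
  τ_s within 15% at noise sd 0.15 µm) come from Monte-Carlo calibration over
  100 seeds, where the observed median total-displacement bias is ≈0.2%.
* Degenerate inputs: zero-area polygons, constant traces, empty regions,
  all-tied resamples, missing gap metadata and unresolvable (<2 px)
  membranes all raise or are flagged explicitly rather than propagating NaNs.
* Problem sizes in the standard verification run (chosen to exercise the
  statistics at meaningful resolution): 20 random circuits for the ODE
  oracle, 100 noisy traces for fit recovery, 50 kymograph seeds, 400-cell
  meshes, 2,000 null resamples and 10,000 power iterations.

## Known limitations

* The circuit model is zero-dimensional; no spatially resolved mechanics,
  and no inference of absolute mechanical parameters.
* The rearrangement term of the coarse decomposition is a residual, not a
  measured quantity; it cannot distinguish neighbour exchanges from
  divisions, extrusions or correlation effects.
* The quadratic peak-refinement inherits a systematic shift on asymmetric
  elongation peaks (documented above).
* The Kruskal–Wallis χ² reference is approximate at three samples per group;
  use the permutation option when absolute calibration at small m matters.
* Synthetic noise is Gaussian and independent everywhere; real measurement
  noise is not, so recovery tolerances verified here are necessary, not
  sufficient, evidence of field performance.
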