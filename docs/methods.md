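# Methods

This note documents the models implemented in `cnetvna`, the defaults and
why they were chosen, the synthetic-data generator's scope, and the numerical
decisions that a maintainer would otherwise have to reverse-engineer.

## Physical model

A fluorophore at distance *d* from the surface of a single-walled carbon
nanotube (SWCNT) transfers excitation energy to the tube's excitons.  For a
point-like donor and a 1D acceptor the transfer rate integrates the FRET-like
R^-6 coupling along the wire,

    k(d) = C ∫ (d² + x²)^-3 dx  =  C (3π/8) d^-5     (infinite wire),

so the quenching efficiency follows

    η(d) = 1 / (1 + (d/d0)^n),   n = 5,

with *d0* the distance of 50% transfer.  `cnet_model.line_transfer_rate`
computes the integral by adaptive quadrature and is tested against the closed
form to 1e-6 relative; the same function with a finite wire length shows the
crossover toward the point-acceptor limit (slope → −6).  Exponents n = 3, 4,
6 (bulk, plane, point acceptors) are retained for model comparison.

Efficiency is measured through lifetimes: η = 1 − τ/τ0, with τ0 the
unquenched lifetime of the same dye in the same dataset (≈3.0 ns for
ATTO542, ≈3.5 ns for ATTO643).  τ0 is treated as exact when propagating
σ_η = σ_τ/τ0; efficiencies outside [0, 1] are clipped with a warning rather
than rejected.

Distances are assembled as *d* = (duplex height) + 1.1 nm, the linker/dye
extension beyond the terminal base pair; the 1.1 nm term carries no
uncertainty.  Duplex heights come either from n_bp × 0.34 nm/bp (nominal
B-DNA rise) or from trajectory means.

## Photon model and lifetime estimation

Simulated photon streams contain (i) signal photons, a Poisson process at the
molecule's brightness that switches off at a single exponentially distributed
photobleaching time, each photon carrying a TCSPC micro-time equal to a
Gaussian IRF draw (σ default 0.1 ns, centre 2.0 ns) plus an exponential decay
draw, wrapped modulo the excitation period (25 ns default, window = period);
and (ii) background photons, uniform in time and in micro-time.  Acquisition
constants (repetition rate, brightness 2×10⁴ counts/s, background ~2% of
signal, 10 ms trace bins, 256 decay bins) are package choices selected to
produce realistic single-molecule traces; they are not instrument values.

Per molecule the chain is:

1. **Trace binning** (10 ms): half-open bins, last partial bin dropped.
2. **Step detection**: recursive binary segmentation of the Poisson count
   trace, accepting a split while the two-segment log-likelihood gain exceeds
   3 ln(n_bins) (a BIC-like penalty).  A rate change falling inside a bin
   leaves one intermediate-count bin which segmentation brackets with two
   changepoints; single-bin segments whose mean lies between their
   neighbours' are coalesced before counting steps.  n_steps = number of
   downward changepoints; molecules are accepted only with exactly one
   (single dye, observed bleach).  The bleach time is the first downward step
   whose post-segment mean is consistent with the final background level.
3. **Decay construction**: pre-bleach micro-times histogrammed into 256 bins
   over the 25 ns window.
4. **Monoexponential fit**: the per-bin model integrates the periodically
   wrapped exponentially-modified Gaussian (analytic exponential ⊗ Gaussian
   IRF convolution) over each bin — evaluated via stable log-space erfc
   forms — mixed with a flat background fraction *b*:
   q_i = (1−b)·P_i/ΣP + b/n_bins.  The default estimator maximizes the
   multinomial/Poisson likelihood over (τ, b, t0) with L-BFGS-B under bounds
   τ ∈ [0.02, 2×window], b ∈ (0, 1), t0 ∈ [0, window/2]; τ standard errors
   come from the central-difference observed information.  A Neyman-weighted
   least-squares mode is kept as a cross-check (agrees within 3% at high
   counts).  Fits pinned at bounds, with b → 1, or with a singular
   information matrix are marked unconverged and the molecule rejected.
   Bin-integrated (not bin-centre) probabilities keep the fit unbiased even
   for τ ≈ 0.1 ns, comparable to the bin width; measured calibration at
   2×10⁴ photons: |bias| < 0.5%, 2σ coverage 92–98% across τ = 0.1–3.5 ns.

Two photon thresholds exist.  The fit itself refuses decays below 100
photons (identifiability floor).  For population decomposition the pipeline
default is 2000 photons/molecule: τ precision scales as ~1.3·τ/√N, and N ≥
2000 keeps single-molecule errors below half a histogram bin (0.05 ns), so
the decomposition sees population structure rather than a heteroscedastic
blur of estimation errors.  Both thresholds are configurable.

## Population decomposition

Accepted lifetimes are histogrammed (0.1 ns bins from 0 to max+bin) and
fitted with sums of m ∈ [1, 5] Gaussians.  Component widths are constrained
to 0.05–0.5 ns: the lower bound matches the narrowest observed single-
molecule populations, the upper bound admits the broadening expected near
50% quenching, where small height fluctuations produce large lifetime
changes.  Parameters are located by bounded least squares from a
k-means-seeded start plus 10 seeded random restarts, then polished by Poisson
maximum likelihood on the bin counts.

Model selection uses the corrected Akaike criterion on the Poisson
likelihood, AICc = 2k − 2 ln L + 2k(k+1)/(N−k−1) with k = 3m and N the
number of bins, choosing the smallest m within 2 units of the minimum.  Two
alternatives were rejected for cause: an AIC built on the unweighted residual
sum of squares overfits structurally (histogram counts are Poisson, so a
narrow component can cancel one noisy bin and buy a large RSS drop against a
fixed penalty), and the uncorrected AIC admits low-weight floor-width
components on ordinary Gaussian-tail fluctuations because k/N is far from
the asymptotic regime (up to 15 parameters on ~40 bins).

Labels follow the physics: the component nearest the reference τ0 (within
0.25 ns) is **unquenched** (dye on glass, not on a tube); among the rest the
largest mean is the **perpendicular**-duplex candidate (the least-quenched
geometry places the dye farthest from the tube) and shorter-lived components
are **tilted** configurations.  The quenching point of a dataset is the
perpendicular component's (mean, sd) converted to (η, σ_η).

## Scaling-law fit

η(d) has a single free parameter at fixed n, so the fit is deterministic: a
200-point log-spaced grid over d0 ∈ [0.5, 50] nm followed by bounded scalar
minimization in the best bracket.  Unweighted SSR by default (inverse-
variance weighting optional); d0 standard errors from the Gauss–Newton
Jacobian with s² = SSR/(n_points − 1).  `compare_exponents` refits each
candidate n with its own optimal d0 and ranks by SSR; with only two points
every exponent nearly interpolates, so the table carries a
`discriminating` flag.  Measured behaviour at the study conditions (five
distances 5.7–8.8 nm, σ_η = 0.03): mean recovered d0 within 0.1% of truth
over 500 seeds.  Discriminating n = 5 from n = 6 at those five narrow-range
points succeeds in only ~73% of seeds — the data genuinely barely
distinguish them — while 12 points spanning 0.5·d0–2·d0 prefer the
generating exponent in >90% of seeds.

## Spectral overlap

J = ∫ F̄_D(λ) ε_A(λ) λ⁴ dλ with the donor emission area-normalized on its
own grid (J is invariant under emission rescaling).  Both spectra are
linearly interpolated onto the denser of the two grids inside the common
wavelength window and integrated by the trapezoid rule; disjoint grids give
J = 0 with a warning.  With ε in M⁻¹cm⁻¹ and λ in nm, J carries
M⁻¹cm⁻¹nm⁴; absolute units cancel in the two-dye Förster-radius ratio
R0₁/R0₂ = ((J₁QY₁)/(J₂QY₂))^(1/6), which assumes equal refractive index and
freely rotating dyes (orientation factors cancel).

## Trajectory geometry

The tube axis is the principal eigenvector of the SWCNT-atom covariance,
sign-fixed so the anchor-strand centroid projects negative — tilt angles
above 90° therefore mean "leaning toward the anchor".  The duplex axis is the
principal axis of per-base-pair centroids (more robust to end fraying than a
first-to-last vector), oriented from the tube-proximal to the tip base pair.
Tilt angle = arccos of the dot product, in [0°, 180°], 90° = perpendicular.
The 5'-tip distance is the minimum distance from the centroid of the flagged
5'-terminal nucleotide to any SWCNT atom — nearest *surface* point rather
than distance-to-axis minus a nominal radius, so it remains meaningful for
deformed tubes.  Summaries report mean/median/5th/95th percentiles and the
Pearson correlation between |θ − 90°| and tip distance (expected negative:
tilting lowers the tip); constant series leave the correlation undefined.

Interchange format: multi-frame XYZ in nm plus a group map
`atom_index,group,bp_index,is_tip`.  The XYZ reader/writer works in float64
(round trips below 1e-6 nm); binary MD formats go through the MDAnalysis
adapter, which converts Å to nm.

## Synthetic trajectories

`simulate_trajectory` places a rigid rod of n_bp × 0.34 nm on a helical
pseudo-atom lattice cylinder (radius 0.38 nm, the (6,5)-tube scale; ring
spacing 0.1 nm, 36 atoms/ring, one lattice site exactly at the anchor).  The
rod direction per frame is cos θ ẑ + sin θ (cos ψ r̂ + sin ψ t̂) with θ the
tilt to the tube axis and ψ an azimuth; at ψ = 0 the tip-to-surface distance
is n_bp·rise·sin θ exactly (no radius correction, since the anchor sits on
the surface).  The mapping ignores the azimuthal curvature of the tube under
the duplex (valid for rod length ≫ tube radius).  Overhang and anchor
strands are represented only by surface marker atoms; their steric effects
enter solely through the tilt distribution.  What the generator does *not*
emulate: duplex flexibility and fraying, base-level structure, solvent, and
any coupling between tilt and azimuth — so geometry tests validate the
estimators, not DNA mechanics.

Likewise the photon generator omits blinking, multi-exponential photophysics
and detector afterpulsing; passing recovery tests demonstrates estimator
correctness under the stated model, not robustness to every artifact of real
hardware.

## Problem sizes and determinism

Simulation-based tests use: 200 replicates for estimator calibration
(2×10⁴ photons each), 50 seeded runs of the 300-molecule two-population
chain, 500/200 seeds for d0 recovery and exponent preference, and 200
replicates for the step-filter classification — sizes chosen to give
comfortable statistical margins at interactive runtimes.  Every stochastic
component takes an explicit seed (numpy `default_rng`); fixed seeds
reproduce all outputs bit-identically, and the pipeline writes a manifest
(config snapshot, input hashes, seeds, record counts) for every run.

## Known limitations

* The Gaussian mixture is fitted to binned counts; results depend mildly on
  the 0.1 ns bin width (configurable).
* τ0 must be supplied (or taken from the preset); it is not estimated
  jointly with the decomposition.
* The d^-5 vs d^-6 comparison is intrinsically weak over a narrow distance
  range (see above); conclusions about the exponent need points spanning the
  dynamic range around d0.
* The forward model treats the duplex as rigid; real tilt-height coupling
  with duplex bending is not represented.
* Efficiencies are clipped to [0, 1] before the scaling fit; with large
  noise this truncation can bias points near the extremes.
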