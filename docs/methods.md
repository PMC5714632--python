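# Methods

`kvscatter` implements a projection-domain scatter correction for kV
cone-beam CT together with the synthetic harness needed to exercise and
certify it: digital phantoms, a fan-beam forward projector, a brute-force
Compton scatter oracle, an ART reconstructor and the consistency metrics a
physicist would report. This note records the model, its assumptions, the
parameters that matter, and what the synthetic results do and do not show
about real scanners.

## The correction model

A measured projection is modeled as

    I = P + S1(P) + Sh,

where `P` is the primary fluence, `S1(P)` the first-order (single-Compton)
scatter expressed as a function of the primary image alone, and `Sh` the
higher-order scatter, closed either as a constant per projection
(`Sh = b`) or as a fraction of the first-order estimate (`Sh = a·S1`).
The primary is recovered by the damped fixed-point iteration

    P(0) = I,    P(k+1) = P(k) + c·(I − P(k) − S1(P(k)) − Sh),

with step parameter `c = 1` by default. In constant-b mode, `b` is
re-optimized at every step; for the L2 objective `‖I − P − S1 − b‖₂` the
optimum is the mean residual, floored at zero. The iteration stops when the
sup-norm of the step, relative to the sup-norm of the current primary,
falls below `stop_tolerance` (default 1%); on oracle-contaminated data it
settles in 2–3 iterations. Three consecutive residual increases abort with
a diagnostic.

The proportionality constant `a` is calibrated once against simulated
ground truth of a cylindrical water phantom: `correct_projection` is run in
proportional mode for each `a` on a 0–1 grid (step 0.05) and the value
minimizing the L2 distance to the true primary is kept, together with the
whole residual curve for audit. The calibration runs its inner iterations
at tighter settings (30 iterations, 1e-4 tolerance) than the user-facing
defaults; with a loose tolerance the stopping phase varies with `a` and
roughens the residual curve.

## The S1(P) estimator

The estimator sees only the detector data. Each column's reading is
converted to a water-equivalent thickness `t = −ln(P/i0)/μ_w` at a single
kernel energy (default: spectrum mean). Scatter sites are laid out along
each ray over a water chord of length `t` centered at the ray's closest
approach to the isocenter; each site emits toward every column with
Klein–Nishina angular weighting, the in-plane angle the column subtends at
the site, and water attenuation of the scattered ray at the
Compton-shifted energy. The integral runs on a column-downsampled grid
(scatter is low-frequency) and is interpolated back.

The free choice is the exit-path rule — the water the scattered photon
crosses on its way out, which a single projection cannot determine
exactly. The default (`fan_map`) builds the object support implied by the
thickness map itself: every ray carries a water chord of its measured
thickness, and the exit segment is integrated through the union of those
chords (midpoint rule on the segment clipped to a bounding circle of the
support). Simpler rules (equivalent centered cylinder; forward remaining
thickness; half the target thickness) are kept as options; they fail
visibly on asymmetric objects such as a bolused phantom.

All accuracy claims are made against the in-repo brute-force oracle, not
against any closed form: on the 10-cm water cylinder of the certification
test the estimator is within 2% of the peak first-order scatter (the
certified bound is 15%); on larger cylinders within 9%; on the bolused
insert phantom within 18% at the worst gantry angle. The residual model
error — not statistical noise — is what limits the end-to-end consistency
gain below.

## The scatter oracle

Two independent realizations of the same physics certify each other:

* a deterministic sum over an explicit coarse grid of scatter sites
  (block-averaged electron density): primary fluence at the site × Compton
  linear attenuation `n_e·σ_KN(E)` × site area × in-plane KN angular
  density × angle subtended by the pixel × attenuation of the scattered
  ray at `E′` through the actual labeled grid;
* a Monte Carlo photon transport: emission toward uniformly sampled
  detector positions (which reproduces the projector's flat open field),
  delta tracking through the voxel grid, Compton scattering with
  rejection-sampled KN angles or photoelectric absorption
  (`μ_photo = μ_total − μ_Compton`, floored at zero), termination below
  10 keV or after 10 interactions, and per-order scoring at the detector
  with per-pixel standard errors.

The harness world is a 2-D fan-beam slice: directions live in the plane
and angular densities are defined per in-plane radian with the KN form
supplying the shape, `p(θ) ∝ dσ/dΩ(|θ|)` normalized over (−π, π]. Both
realizations share this convention exactly, and the source is collimated
to the detector fan in both. The two agree without detectable bias (0.0%
aggregate difference at 10⁶ photons); at 10⁵ photons the per-pixel
max-|z| statistic over a 64-pixel detector occasionally brushes 3 by
max-statistics alone, which is why the cross-check is also reported as an
aggregate z.

Monte Carlo higher-order ground truth used by the experiment is smoothed
(Gaussian, 5 pixels along the detector, 1.5 projections circularly across
angles) — a variance reduction justified by the low spatial and angular
frequency of multiple scatter; the mean is preserved. Without it, MC noise
in the higher-order truth survives the correction and dominates the
reconstruction-domain consistency floor.

## Projector, reconstruction, metrics

Primary projections are exact Siddon line integrals (Beer–Lambert, mono-
or polychromatic, ideal energy-integrating detector by default), with
optional bowtie pre-attenuation per column, an antiscatter grid as two
bulk transmissions (`pixel = Tp·P + Ts·S`, defaults 0.7/0.1 for a "10:1"
grid), and optional seeded Poisson noise. Attenuation tables are a
packaged coarse mass-attenuation CSV (10–150 keV) with linear
interpolation in energy; tissue-substitute inserts are modeled as
ED-scaled water, adequate in the Compton-dominated kV range.

Reconstruction is relaxed Kaczmarz ART over rays traced by the same
Siddon kernel as the projector, with optional non-negativity projection
per sweep. Defaults: relaxation 0.8, 10 sweeps (the reference round-trip
runs 5). 0.8 was chosen because at a 5-sweep budget under-relaxation has
not converged (insert RMSE above 5% of μ_water at 0.25); Kaczmarz is
convergent on consistent systems for any relaxation in (0, 2). CBCT
numbers are an affine map of reconstructed attenuation anchored on two
reference materials (air → −1000, water → 0 by default; scanner-style
anchors configurable).

CNR is `|mean_fg − mean_bg| / std_bg` — the definition is fixed here
because absolute CNR values depend on it. Consistency summaries use the
sample (n−1) standard deviation, which reproduces the published summary
of the packaged 16-insert reference table exactly (mean 128, min 40, max
485, std 118 uncorrected; 80/4/349/99 processed). CBCT-to-ED conversion
is a piecewise-linear lookup through the measured (CBCT, ED) knots,
ordered by CBCT number with exact ties averaged — the clinical CT-ED
table convention; no functional form is fitted.

## The synthetic consistency experiment

The packaged experiment (`kvscatter run`, `gammex_synthetic.yaml`) mirrors
the bolus/no-bolus consistency study at desk scale: a 15-cm water body
with eight ring inserts spanning relative electron density 0.289–1.695, a
3-cm water bolus slab on one side, 72 angles over 360°, monoenergetic
60 keV, 10⁵ photons/pixel with Poisson noise, first-order scatter from the
deterministic oracle and higher-order from the MC, constant-b correction,
ART reconstruction of the contaminated and the corrected stacks, and
per-insert CBCT numbers, consistency summaries, CBCT-to-ED curves and CNR.
Runtime is about two minutes on one CPU; the problem sizes (112² phantom
grid, 144-pixel detector, 64² reconstruction) were chosen for that
budget.

Scale choices that matter for interpretation:

* The 3-cm bolus is the thicker of the two bolus conditions in the
  underlying study. In this 2-D slice world a 1-cm slab changes the
  scatter bias at the insert ROIs by less than the scatter-free ART
  reproducibility floor (~12 CBCT between two scans differing only by the
  slab's rays), so the directional comparison is run at 3 cm where the
  uncorrected inconsistency is well resolved.
* Quantum noise is on because noise-free backgrounds are
  artifact-dominated: uncorrected cupping is locally smooth, giving it an
  artificially tiny background std and meaningless CNR comparisons. With
  noise at clinical-order fluence the paper's mechanism appears —
  correction roughly doubles contrast at comparable noise.

Typical outcomes (seed-dependent; the suite asserts only the directions):
corrected consistency mean 16–35 vs 30–42 uncorrected; mean attenuation
error ~0.013 vs ~0.037 cm⁻¹; CNR of the highest-contrast insert up by
~10–20%; maximum scatter-to-primary ratio ~100% without and ~220% with
the bolus (no grid in the beam).

## What the synthetic results do not show

The harness is a 2-D slice with water-equivalent inserts, an ideal
detector, no detector lag/glare, no beam hardening in the correction loop
(a monoenergetic kernel), and scatter magnitudes that differ from a 3-D
cone beam with a flat panel. Passing tests certify the algorithm's
internal consistency, its fixed-point behavior, the estimator's fidelity
to single-scatter physics, and the direction of the image-domain gains —
not the absolute CBCT-number differences, CNR values or dose effects a
specific scanner would show.

## Degenerate inputs and numerical choices

`P > i0` pixels are clipped to the open field before the thickness
conversion (routine for contaminated candidates, logged at debug level);
negative primaries are clamped to zero and counted; zero or negative
fluence pixels are excluded from the ART system and counted; zero-primary
pixels are excluded from scatter-to-primary maps and counted. Norms:
L2 for `b`, `a` and calibration residuals; sup-norm for the stopping
rule. All randomness (MC transport, Poisson noise, randomized ray order)
flows from explicit integer seeds.
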