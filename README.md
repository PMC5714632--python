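# kvscatter

Projection-domain scatter correction for kV cone-beam CT (CBCT), with the
full synthetic harness needed to exercise it end to end.

Scatter is the dominant contaminant of kV CBCT projections: it depresses
and distorts reconstructed attenuation, makes CBCT numbers (the
scanner-scale analogue of Hounsfield units) inconsistent between scans of
the same object under different scatter conditions, and thereby breaks
CBCT-number-to-electron-density conversion — the quantity dose calculation
needs when CBCT images are used for radiotherapy replanning. This package
is for medical-physics researchers who want a self-contained, certified
implementation of a Klein–Nishina-based correction and a simulation bench
to study it on.

## The model

A measured projection is modeled as

```
I = P + S1(P) + Sh,      Sh = b   (constant per projection)
                    or   Sh = a·S1(P)
```

where `P` is primary fluence, `S1(P)` first-order Compton scatter derived
from the Klein–Nishina differential cross-section
`dσ/dΩ = (r_e²/2)(E′/E)²(E′/E + E/E′ − sin²θ)` and expressed as a
function of the primary image alone, and `Sh` higher-order scatter. The
primary is recovered by the fixed-point iteration

```
P₀ = I,   P_{k+1} = P_k + c·(I − P_k − S1(P_k) − Sh),   c = 1,
```

which stabilizes in 2–3 iterations. `b` is re-optimized per projection
(closed form: mean residual, floored at 0); `a` is calibrated once against
simulated ground truth of a water cylinder. Around the algorithm the
package provides:

- `phantoms` — labeled voxel phantoms (insert cylinders, water bodies,
  bolus slabs), tabulated materials, ROI specs;
- `projector` — Siddon fan-beam primaries, bowtie filter, antiscatter
  grid, optional Poisson noise;
- `scatter_sim` — brute-force first-order Klein–Nishina sum and a Monte
  Carlo photon transport, the ground truth every estimate is certified
  against;
- `scatter_model` / `correction` — the fast in-loop `S1(P)` estimator,
  the closures, the fixed point, `optimize_b`, `calibrate_a`;
- `reconstruction` — Kaczmarz ART and CBCT-number conversion;
- `metrics` — ROI statistics, CNR, bolus/no-bolus consistency summaries,
  piecewise-linear CBCT-to-electron-density curves;
- `experiment` / `cli` — the packaged end-to-end consistency experiment
  (`kvscatter simulate|correct|recon|metrics|run`).

See `docs/methods.md` for assumptions, parameter defaults and the
certification results.

## Worked example

Contaminate a water-cylinder projection with simulated scatter, then
recover the primary:

```python
import numpy as np
import kvscatter as kv
from kvscatter.correction import CorrectionParams, correct_projection
from kvscatter.scatter_model import ScatterModelConfig
from kvscatter.scatter_sim import ScatterGroundTruth

# a 16-cm water cylinder scanned at one gantry angle, 60 keV
phantom = kv.make_cylinder_phantom(80.0, grid_shape=(96, 96), voxel_size_mm=2.0)
geometry = kv.ScanGeometry(detector_size=128, angles_deg=[0.0])
spectrum = kv.Spectrum.mono(60.0)

truth = ScatterGroundTruth.generate(phantom, geometry, spectrum,
                                    site_downsample=4, n_photons=50_000,
                                    rng_seed=1)
spr = kv.scatter_primary_ratio(truth.whole, truth.primary)
print(f"max scatter-to-primary ratio: {spr.max_ratio:.2f}")

result = correct_projection(truth.whole[0],
                            CorrectionParams(mode="constant_b"),
                            ScatterModelConfig(), geometry, spectrum)
p_true = truth.primary[0].pixel_fluence
err_before = np.abs(truth.whole[0].pixel_fluence - p_true).max() / p_true.max()
err_after = np.abs(result.primary_estimate.pixel_fluence - p_true).max() / p_true.max()
print(f"iterations: {result.iterations_used}, fitted b = {result.scatter_estimate.b:.0f}")
print(f"peak primary error: {100*err_before:.1f}% before, {100*err_after:.1f}% after")
```

```
max scatter-to-primary ratio: 0.95
iterations: 2, fitted b = 194
peak primary error: 3.5% before, 1.2% after
```

Scatter inflates this projection by up to 95% of the primary; two
fixed-point iterations with a constant higher-order closure cut the peak
primary error from 3.5% to 1.2% of the open-field-scale signal.

The packaged bolus/no-bolus experiment runs the whole pipeline — simulate,
contaminate, correct, reconstruct, measure — for a tissue-insert phantom
with and without a 3-cm bolus slab:

```
kvscatter run --out results/experiment --seed 1
```

and writes per-insert consistency CSVs, CBCT-to-ED curves and a JSON
manifest (iteration counts, clamp counts, scatter-to-primary ratios,
consistency means, CNR).

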