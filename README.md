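# respivox

Respiratory motion characterization from dynamic torso surface point
clouds, for external–internal tumor motion modeling in robotic
radiosurgery research.

In stereotactic body radiotherapy, the internal tumor position must be
inferred from an externally observable **surrogate signal**, because
continuous X-ray localization would overdose healthy tissue. The common
surrogate — a handful of optical markers on the chest — sees only a few
points of a deforming surface. respivox implements the whole-surface
alternative: per time frame, a depth-camera point cloud of the
thoracoabdominal surface is cleaned, closed into a **watertight point
shell**, converted to a **solid voxel occupancy grid**, and summarized by
physical features (volume `V`, outer-layer area `S`) and by **locally
linear embedding (LLE)** coordinates `ψ` of the binary occupancy vectors,
assembled per frame into the characterization vector

    Γ = [V, S, ψ₁ … ψ_m]ᵀ .

The single embedding dimension most correlated with the internal motion
becomes the surrogate `r` of a **phase-split polynomial correlation
model**

    x_T = Σ_{j=0..N} A_j⁺ r^j  (exhale),   x_T = Σ_{j=0..N} A_j⁻ r^j  (inhale),

with separate branches per breathing phase because pulmonary hysteresis
makes inhale and exhale trace different external–internal curves. Phases
are split at the surrogate's peaks and valleys; N defaults to 2.

A synthetic breathing phantom (half-ellipsoid torso, spatially varying
breathing amplitude, sensor noise and outliers, hysteretic tumor
trajectory) replaces the camera hardware, so the entire chain runs and is
tested at desk scale. See `docs/methods.md` for the model, every default,
and the reasoning behind them.

## Worked example

Run the pipeline on a small phantom (24 s of breathing at 5 Hz, 8 mm
voxels) from a YAML config:

```yaml
# example.yaml
phantom:
  torso_half_axes: [100, 70, 50]
  n_frames: 120
  frame_rate: 5.0
  surface_amplitude_max: 15.0
  tumor_amplitude: 8.0
  point_density: 1500
  noise_sigma: 1.0
  outlier_fraction: 0.02
  seed: 0
resolution: 8.0
lle_k: 10
lle_d: 6
```

```bash
respivox run --config example.yaml --out demo/
```

This simulates the frames, cleans and closes each one, voxelizes, embeds,
selects the respiratory dimension, fits phase-split models for a
skin-marker surrogate and for the reduced voxel feature, and prints the
comparison (abridged):

```json
{
  "marker":          {"train_pearson": 0.799,  "test_mse": 1.897},
  "reduced_feature": {"train_pearson": -0.930, "test_mse": 0.293},
  "n_train": 60,
  "n_test": 60,
  "winner_pearson": "reduced_feature",
  "winner_mse": "reduced_feature"
}
```

Reading this: the reduced LLE feature of the voxel model correlates with
the internal tumor trajectory at |ρ| = 0.93 (sign is arbitrary for an
embedding coordinate) versus 0.80 for the marker, and its held-out
mean-squared prediction error is 0.29 mm² versus 1.90 mm² — the
whole-surface feature is both the better-correlated and the more accurate
surrogate. `demo/selection.json` holds the per-dimension correlations
(here `[0.928, 0.128, 0.117, 0.003, 0.010, 0.016]`): exactly one of the
embedding dimensions carries the respiratory signal, which is why a
one-dimensional surrogate suffices. `demo/features.csv` has the full
per-frame `V`, `S` and `ψ` table.

Each stage is also exposed individually (`respivox simulate | preprocess
| watertight | voxelize | features | correlate`) and as a library:

```python
from respivox import PhantomConfig, PipelineConfig, characterize

result = characterize(PipelineConfig(phantom=PhantomConfig(seed=0)))
print(result.selected_dim, result.selected_rho)
```

## Testing

```bash
python -m pytest -q tests/
```

The suite covers every stage against independent oracles (analytic
volumes and deformation fields, brute-force distance statistics, planted
rigid transforms and polynomials, an external LLE implementation) plus
end-to-end acceptance runs at study scale; the full run takes roughly
15 minutes on one core, most of it in the acceptance replicates.

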