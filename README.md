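# cortexmpm

Synthetic quantitative-MRI (multi-parameter mapping) pipeline: a cortical
phantom generator, estimation of the four quantitative maps (R1, R2*,
MT-saturation, PD*) from simulated three-weighting multi-echo FLASH
volumes, cortical-depth sampling, hierarchical depth-profile modelling,
and jackknifed vertex-wise age-effect mapping with per-hemisphere FDR
control. Every stage is verifiable by parameter recovery against the
phantom's known ground truth — no scanner or cohort data are required.

## Package layout

| module | contents |
| --- | --- |
| `cortexmpm.protocols` | FLASH acquisition descriptions; `cohort1`/`cohort2` presets |
| `cortexmpm.mesh` | two-hemisphere corrugated-ribbon cortical model (thickness, curvature, ROI labels, adjacency) |
| `cortexmpm.phantom` | ground-truth tissue parameters (depth-, region-, age-dependent), subject cohorts, B1+/receive fields, forward signal simulation |
| `cortexmpm.mpm_fit` | ESTATICS joint R2* fit, echo averaging, rational-approximation VFA R1, MT-saturation, WM-calibrated PD* |
| `cortexmpm.surface_sample` | depth-fraction sampling (0.1–0.9), ROI × depth means, iterative surface smoothing |
| `cortexmpm.depth_stats` | three-level mixed models of value vs depth, LRT depth-order selection, age interactions |
| `cortexmpm.age_effects` | residualisation, jackknifed Fisher-z age correlations, BH-FDR, overlap ROIs, ROI age slopes |
| `cortexmpm.io` / `pipeline` / `cli` | NIfTI + plain-text readers/writers, YAML config, manifest, stage orchestration, CLI |

Conventions: TR/TE are stored in milliseconds and converted to seconds
inside the signal formulas; relaxation rates are s⁻¹; MT saturation is a
fraction internally and percent units (pu) in outputs; curvature is
positive-concave (sulcal) / negative-convex (gyral); tissue labels are
0 background, 1 WM, 2 GM, 3 CSF.

## Command-line usage

```sh
# full pipeline into ./demo with a fixed master seed
cortexmpm run --out demo --seed 1

# or stage by stage / a contiguous subset on precomputed outputs
cortexmpm run --config cfg.yaml --out demo --seed 1 --stages sample,depth-stats,age-map
```

Stages: `simulate → fit-mpm → sample → depth-stats → age-map`. A YAML
config (see `cortexmpm.io.RunConfig` for keys) controls cohort size, mesh
resolution, folding amplitude, depth fractions, the LRT alpha and the FDR
q-level. Each run writes `manifest.json` with the config hash, seeds and
SHA-256 checksums of every declared output; reruns with the same config
are byte-identical.

Simulated volumes are NIfTI-1 (either one 4-D file per weighting with
echo as the 4th dimension, or one file per echo — declared in a JSON
sidecar); the cortical model and all statistics tables are plain-text
TSV/JSON.

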