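# rangeocc

Tools for asking whether widespread species fare better than narrow-ranged
ones inside repeatedly surveyed metacommunities. Given presence/absence
surveys of many sites over many years, the package standardizes each study to
a comparable pair of time periods, computes per-species occupancy change,
attaches an independent estimate of each species' geographic range size, and
fits a hierarchical Bayesian model of the relationship between the two —
separating the cross-study mean effect ("winners and losers sort by range
size") from study-level variation.

The package also ships a synthetic-data generator with known ground truth, so
every stage of the analysis can be validated end to end: the generating
slope, study-level variances and the effort-dependence of the residual noise
are all recoverable from simulated surveys.

## What it computes

- **Standardization** (`rangeocc.standardize`): match survey sites across
  years on a spatial grid (or by exact coordinates), pick the pair of
  reference years at least a decade apart with the most co-occurring sites,
  and drop years or sites that break comparability.
- **Occupancy change** (`rangeocc.occupancy`): split retained years into an
  early and a late period around the temporal midpoint, rarefy to equal
  numbers of sites per year, and compute per-species occupancy (proportion
  of site-year samples occupied) in each period. The change Δ ∈ [−1, 1] is
  analysed through the odd transform sign(Δ)·√|Δ|. Species are also classed
  as lost / gained / persisting (up, down, stable).
- **Range size** (`rangeocc.rangesize`): clean occurrence records (missing
  coordinates, unsuitable record bases, high coordinate uncertainty,
  gazetteer flags, per-species duplicates), then estimate area of occupancy
  (occupied grid cells at 10/50/100 km) and extent of occurrence (alpha hull,
  falling back to buffered points for sparse species).
- **Protection** (`rangeocc.protection`): proportion of a study's sites (or
  of its spatial extent) inside protected areas with admissible status
  established before the study's late period.
- **Model** (`rangeocc.model`): y_ij ~ Normal(μ_ij, σ_i) with
  μ_ij = (β₀+u₀ᵢ) + (β₁+u₁ᵢ)·z_j and log σ_i = η₀ + η₁·log(nsamp_i), where
  z_j is centred log₁₀ range size. Fixed and random effects are marginalized
  analytically and an ensemble sampler explores the five remaining
  hyperparameters; exact conditional Gaussian draws of the effects are then
  attached to each retained draw. Variants add per-realm slopes and
  protection or study-covariate interactions.
- **Pipeline** (`rangeocc.pipeline`): run everything in order, writing CSV
  tables, a JSON report, an audit log and a hash manifest so reruns are
  reproducible byte for byte.

## Worked example

A transparent unit first: a species occupying 1 of 4 samples in the early
period and none later has Δ = −0.25, transformed to −0.5:

```python
>>> from rangeocc.occupancy import occupancy_change
>>> occupancy_change(0.25, 0.0)
(-0.25, -0.5)
```

A full synthetic analysis, from simulation to fitted slope:

```python
import json
from rangeocc.synth import SynthConfig
from rangeocc.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    synth=SynthConfig(n_studies=8, n_species_per_study=25, seed=42),
    seed=42,
    rarefaction_iterations=20,
)
bundle = run_pipeline(cfg, "demo_out")
report = bundle.report
print("overall slope:", json.dumps(report["overall_slope"]["range"]))
print("study slope classes:", report["study_slope_classes"])
print("hyperparameters:", {k: round(v, 3) for k, v in report["hyperparameters"].items()})
print("converged:", report["converged"])
```

Output (about 10 s on one CPU; the generator's true slope is 0.02):

```
overall slope: {"mean": 0.015980371656809707, "ci95": [-0.004177847688854042, 0.038213209262342285]}
study slope classes: {'positive-ns': 6, 'positive-significant': 2}
hyperparameters: {'tau0': 0.054, 'tau1': 0.018, 'rho': -0.202, 'eta0': -1.478, 'eta1': -0.363}
converged: True
```

`demo_out/` then contains the intermediate tables (`surveys.csv`,
`standardized.csv`, `occupancy_change.csv`, `range_estimates.csv`,
`protection.csv`, `fit_summary.csv`, `study_slopes.csv`), the `report.json`
above, and `manifest.json` with a SHA-256 hash of every output.

The same run is available from the command line:

```
rangeocc run-all --config config.yaml --out demo_out
```

where `config.yaml` holds the `PipelineConfig` fields (see
`PipelineConfig.from_yaml`). Individual stages are exposed as `rangeocc
simulate`, `standardize`, `occupancy`, `rangesize`, `protection` and `fit`.

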