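# stokbg

Urban **background** air-pollutant concentrations — the concentration that
would be measured if the local sources of a study area were shut down — by
**space/time ordinary kriging (STOK) with measurement error**, for use in
hybrid regional + local exposure modeling.

Hybrid exposure models add a local-scale dispersion estimate Z_LS to a
regional background B:

```
Z(p) = Z_LS(p) + B(p),        p = (s, t)
```

If B is kriged from *all* monitors, the monitors near the local sources
contribute local signal to B and the hybrid total double-counts those
sources.  `stokbg` implements the fix: only far-field background-objective
monitors (≥ 60 km from the local-source region) enter as **hard** (exact)
data, while every other monitor's observation z is converted into a **soft**
datum using the zero-out/total ratio of a paired pair of chemistry-model
runs.  With μ_R and σ²_R the temporal mean and variance of the hourly ratio
CMAQ_ZeroOut/CMAQ_Total at the station's grid cell (after trimming ratios
below the 1st / above the 99th percentile):

```
soft mean      = z(p_s) · μ_R
soft variance  = z(p_s)² · σ²_R
```

Kriging operates on the transformed field x(p) = b(p) − o_B, where the
offset o_B is the mean of the observed background concentrations.  The
space/time covariance of x is a nested sum of separable exponential
structures (three by default),

```
C(r, τ) = Σ_i c_i · exp(−3r / a_ri) · exp(−3τ / a_ti)
```

fitted by pair-count-weighted least squares to the binned empirical
covariance.  The kriging system carries each soft datum's error variance on
its diagonal, so estimates interpolate hard data exactly (zero kriging
variance there) and downweight soft data in proportion to their uncertainty.
Estimates get the offset added back and are combined with dispersion-model
local concentrations into hybrid totals.

The package is aimed at exposure-assessment workflows for air-pollution
epidemiology (NOx, PM2.5, …): hourly receptor-level background surfaces,
their error variances, and old-vs-new hybrid evaluation against monitors.

## Worked example

Everything below runs on a synthetic study whose generator mirrors the method's
assumptions: a 360 × 360 km 12-km model grid, a 4 × 4 zero-out cell block with
three point sources inside it, 10 background monitors at 85–125 km from the
block and 10 nonbackground monitors in and around it, 720 hourly values, and a
three-structure exponential background field (total sill 1, mean 7.8 µg/m³).

```python
import numpy as np
from stokbg import ScenarioConfig, generate_scenario, NeighborhoodSpec
from stokbg.hybrid_eval import (
    run_new_hybrid, run_old_hybrid, PipelineParams, evaluate, loo_crossvalidate,
)

scenario = generate_scenario(ScenarioConfig(seed=2026))
inputs = scenario.pipeline_inputs()          # monitors double as receptors
params = PipelineParams(fit_seed=1)

new = run_new_hybrid(inputs, params)         # ratio-based soft data
old = run_old_hybrid(inputs, params)         # every monitor hard

print("offset o_B:", round(new.transform_spec.offset, 3))
for s in new.model.structures:
    print(f"  ({s.sill:.3f}, {s.spatial_range:.1f}, {s.temporal_range:.1f})")

in_region = scenario.in_region_site_ids()
obs = {k: v for k, v in scenario.observations.items() if k in in_region}
for name, res in [("old hybrid", old), ("new hybrid", new)]:
    pred = res.hybrid.rename(columns={"total": "value"})[["receptor_id", "hour", "value"]]
    pooled = evaluate(pred[pred.receptor_id.isin(in_region)], obs).pooled
    print(f"{name}: bias {pooled['bias']:+.2f}  rmse {pooled['rmse']:.2f}")

loo = loo_crossvalidate(new.dataset, new.model,
                        NeighborhoodSpec.from_model(new.model),
                        max_hours_per_site=240)
print("LOO standardized residuals: mean {:+.3f}, variance {:.3f}".format(
    loo.summary["std_residual_mean"], loo.summary["std_residual_variance"]))
```

prints

```
offset o_B: 7.699
  (0.557, 134.1, 27.3)
  (0.206, 7.0, 3.1)
  (0.183, 718.7, 24.8)
old hybrid: bias +4.69  rmse 5.60
new hybrid: bias +0.35  rmse 1.01
LOO standardized residuals: mean +0.027, variance 0.998
```

Read: the fitted covariance recovers the simulated total sill (0.95 vs 1.0;
individual structures trade mass, see `docs/methods.md`).  At the monitors
*inside* the local-source block, the old hybrid — which kriges every
observation as hard data — overshoots by ~4.7 µg/m³, almost exactly the mean
local contribution it double-counts; the soft-data pipeline removes nearly
all of that bias and cuts RMSE more than five-fold.  Site-withheld
cross-validated residuals divided by the kriging standard deviation have
variance ≈ 1: the reported kriging variances are trustworthy.

## Command-line pipeline

The same computation runs as file-coupled stages (`simulate` is the synthetic
front end; with real data you provide the files it would have written):

```sh
stokbg simulate --config cfg.yaml     # or: your own observation/model files
stokbg classify --config cfg.yaml
stokbg ratios   --config cfg.yaml
stokbg soft     --config cfg.yaml
stokbg fitcov   --config cfg.yaml
stokbg krige    --config cfg.yaml
stokbg hybrid   --config cfg.yaml
stokbg evaluate --config cfg.yaml
stokbg crossval --config cfg.yaml
```

Each stage writes its outputs plus a manifest (config hash, seed, version,
row counts) into the configured work directory and refuses to run before its
upstream stage.  See `stokbg <stage> --help`.

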