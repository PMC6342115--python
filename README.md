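# prefsdm

Species distribution models that correct for **preferential sampling** —
the common situation in which survey locations were chosen *because* the
species was expected there (fishing fleets, whale-watching boats, citizen
science), violating the independence assumption of standard geostatistics
and biasing abundance maps upward in poorly sampled, low-abundance areas.

The package is aimed at quantitative ecologists and fishery scientists who
have a point table of locations and abundances (and optionally covariate
rasters) and want bias-corrected predictive maps, plus the simulation
machinery to see how large the bias is.

## Model

The data are read as a **marked point pattern**: sampling locations form a
log-Gaussian Cox process, the measured abundances are its marks, and one
latent Matérn field W (smoothness ν = 1, SPDE/GMRF form) is shared between
the two layers:

    y_i  ~  Ga(μ_i, ρ),            log μ_i  = β0' + W(s_i)        (marks)
    s    ~  LGCP(Λ),               log Λ(s) = β0  + α·W(s)        (locations)

The sharing coefficient α absorbs the scale difference between intensities
and abundances; α ≠ 0 is what lets empty regions testify that abundance is
low there.  The non-preferential baseline is the mark layer alone
(equivalently, an independent field for the point pattern).  Gaussian,
lognormal and Poisson marks, and a shared RW2 covariate smooth f(d) with
its own scale α_d, are also supported.

Inference is empirical-Bayes Laplace (inner Newton over the latent field,
outer optimization of the Laplace-approximated hyperparameter posterior) —
see `docs/methods.md` for the full account, priors, and limitations.
Models are compared with DIC, LCPO (leave-one-out predictive density) and
MAE against a known simulation truth; lower is better for all three.

## Worked example

Simulate one preferentially sampled scenario on a 32×32 grid and fit both
models to the *preferential* sample:

```python
from prefsdm import (GridGeometry, MaternHyperparams, ModelSpec, ScenarioConfig,
                     compute_dic, compute_lcpo, compute_mae, fit, make_scenario,
                     predict_surface, true_abundance_surface)

cfg = ScenarioConfig(grid=GridGeometry(32, 32),
                     hyper=MaternHyperparams(sigma2=1.0, range_=6.4),
                     n=100, b=1.0)
scenario = make_scenario(cfg, seed=3)
truth = true_abundance_surface(scenario)

for name, spec in [("preferential", ModelSpec(preferential=True)),
                   ("non-preferential", ModelSpec(preferential=False))]:
    fr = fit(spec, scenario.preferential, hyper_se=False)
    mean, _ = predict_surface(fr)
    h = fr.hyper_mode
    line = (f"{name:>16}: DIC {compute_dic(fr, scenario.preferential).dic:7.1f}"
            f"  LCPO {compute_lcpo(fr, scenario.preferential).lcpo:.3f}"
            f"  MAE {compute_mae(mean.values, truth):.3f}"
            f"  range {h['range']:.1f}  sd {h['sd']:.2f}  shape {h['dispersion']:.1f}")
    if "alpha" in h:
        line += f"  alpha {h['alpha']:.2f}"
    print(line)
```

prints:

```
    preferential: DIC   398.8  LCPO 2.249  MAE 0.847  range 8.6  sd 1.26  shape 8.8  alpha 0.90
non-preferential: DIC   399.4  LCPO 2.301  MAE 1.772  range 6.8  sd 1.04  shape 9.0
```

Both models recover the field hyperparameters (truth: range 6.4, sd 1,
shape 10), and the joint model estimates the sharing scale α̂ = 0.90 near
its true value 1.  The headline is the last column: against the known true
abundance surface, the preferential correction **halves the prediction
error** (MAE 0.85 vs 1.77) on this replicate, because the mark-only model
extrapolates the over-sampled high-abundance areas into the unsampled
low-abundance ones.  LCPO prefers the joint model as well; DIC — computed
on the mark likelihood only so the two models are comparable — differs
much less sharply.

## Command line

The same pipeline is scriptable:

```bash
prefsdm simulate-field --nx 100 --ny 100 --seed 1 --out run/field
prefsdm sample --field run/field/field.asc --design preferential --n 100 --seed 2 --out run/pts
prefsdm predict --points run/pts/points.csv --model preferential --config run.cfg --out run/maps
prefsdm study --config study.cfg --seed 7 --out run/study
```

Every subcommand takes a shared INI-style `--config` (flags override file
values) and writes a `manifest.json` with the config hash, seed and library
versions, so any artifact can be reproduced exactly.

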