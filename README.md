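# deerscr

Spatial capture-recapture (SCR) density estimation from non-invasive
genetic sampling, with habitat covariates on both density and detection.

Fecal-DNA surveys identify individual animals from microsatellite
genotypes and record *where* each individual was detected. `deerscr` turns
such data into population density estimates and habitat-selection
inference for a clustered-plot deer survey design: it builds consensus
genotypes from replicated PCR calls, matches samples to individuals,
assembles per-session encounter histories, and fits multi-session
sex-structured SCR models by maximum likelihood. It is aimed at wildlife
ecologists and quantitative biologists who want a scriptable, fully
testable pipeline — including a synthetic-data generator that emulates the
whole survey, so methods can be validated without field data.

## The model

Activity centers follow an inhomogeneous Poisson point process over a
discrete state space (120 m pixels in a 1000 m buffer around the plots):

    log μ_g(s) = x_d(s, g)ᵀ β_d                        (density, per pixel)
    p_jk(s, sex) = p0_jk(sex) · exp(−d(s,j)² / 2σ²)    (half-normal detection)
    logit p0 = x_p(j, k, g, sex)ᵀ β_p,   log σ = x_σ(g, sex)ᵀ β_σ

with a logit-scale sex-ratio parameter ψ mixing female and male detection
regimes. The observed-data likelihood marginalises each individual's
center over the pixels and adds the Poisson correction for the expected
number of detected individuals; models are compared by AIC with Akaike
weights, using a two-step strategy (best homogeneous model first, habitat
covariates added second). Habitat terms on density measure second-order
selection (where home ranges sit); terms on detection measure third-order
selection (how space is used within home ranges).

## Worked example

Simulate a survey at the preset design and fit a habitat-density model
(`examples/03_fit_density_model.py` is the full script):

```python
import numpy as np, deerscr
from deerscr import landscape as ls
from deerscr.scr_model import ModelSpec
from deerscr.synthetic import DesignConfig, LandscapeConfig, TruthConfig

rng = np.random.default_rng(3)
traps = deerscr.gen_design(DesignConfig(n_cols=3, n_rows=3, drop_clusters=()))
raster, _ = deerscr.gen_landscape(traps, LandscapeConfig(forest_margin_m=150.0),
                                  buffer_m=700.0, rng=rng)
space = deerscr.build_state_space(traps, buffer_m=700.0)
space.habitat = ls.aggregate_majority(raster, space)

truth = TruthConfig(density_intercept=np.log(30 * 0.0144), density_session={},
                    density_habitat={"coniferous": -2.0, "mixed": -0.5,
                                     "transitional": -2.0},
                    p0_intercept=-1.0, p0_session={}, log_sigma=np.log(160.0))
pop = deerscr.simulate_population(space, truth, ["2016"], rng=rng)
records = deerscr.simulate_detections(pop, traps, {"2016": 4}, truth, rng=rng)
enc = deerscr.build_encounter_array(records, traps, {"2016": 4})

res = deerscr.fit(ModelSpec(density="~habitat", detection="~1", sigma="~1"),
                  enc, space, traps)
surf = deerscr.predict_density(res)
print(surf.per_class[["habitat", "density_km2"]])
```

which prints (truncated):

```
predicted density by habitat class (individuals/km^2):
session      habitat  density_km2       lcl        ucl
   2016 agricultural 6.074604e+01 33.334849 110.697407
   2016        mixed 1.897190e+01  3.896909  92.363728
   2016   coniferous 5.567027e-07  0.000000        inf
```

Read: deer density in agricultural fields is estimated at ~61/km² against
~19/km² in mixed forest, and essentially zero in coniferous forest — the
simulation's truth ordering — with wide intervals for classes where few
individuals were detected, a known property of habitat-specific SCR
estimates. `examples/01_simulate_survey.py`, `02_genotype_and_match.py`
and `04_model_selection.py` walk the other stages (survey summaries,
consensus genotyping and probability-of-identity statistics, and two-step
AIC selection); a thin CLI (`deerscr simulate|genotype|encounters|fit|
select|predict --config config.yaml ...`) wraps the same functions for
shell pipelines.

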