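# kinloc

Hierarchical Bayesian models of **intergenerational migration** and
**postmarital residence** from genealogical birthplace records.

Demographic interviews in kinship studies often record, for one
interviewed participant (the *proband*), the birthplaces of seven family
members across three generations: self, mother, father, and all four
grandparents. Two classes of questions follow from such records:

1. **Who migrated, and how far?** Each child–parent pair is a *dyad*
   whose migration distance is the great-circle distance between the two
   birthplaces. Distance is semicontinuous — many people never move —
   and informants often know a forebear's birthplace only "somewhere in
   region X", which censors the distance to an interval.
2. **Where did couples settle?** Comparing a child's birthplace with
   both parents' classifies each couple as *equilocal* (child born where
   both parents were), *matrilocal* (mother's place only), *patrilocal*
   (father's place only) or *neolocal* (neither).

`kinloc` implements the full analysis pipeline for a two-region study of
this design: reading genealogy tables, gazetteers and region polygons;
building outcomes with interval censoring derived from polygon geometry;
two hierarchical Bayesian models; posterior sampling with diagnostics;
PSIS-LOO model comparison; and a synthetic-data generator that draws
complete study datasets from the models with known parameters, so every
stage is testable without access to field data.

## The models

**Migration** is a two-part (hurdle) model: migrate with probability π,
and if so move a log-normal distance,

    h(d) = 1 − π              (d = 0)
         = π · g(d; μ, σ_E)   (d > 0)

    logit(π_i) = x_i'β + S_l(i) + T_b(i)
    log d_i    = x_i'γ + U_l(i) + V_b(i) + E_i

with crossed varying intercepts for extended family *l(i)* and
birthplace *b(i)*, covariates x (proband birth year; sex × generation ×
region full factorial; optional settlement-size or genetic-ancestry
terms), and censored dyads contributing log-normal CDF differences.
Latent-status dyads (same-region censoring) contribute
(1 − π) + π·Φ((log d_max − μ)/σ_E), marginalizing the unknown migration
indicator.

**Residence** is a hierarchical multi-logit over
{equilocal, neolocal, matrilocal, patrilocal} with equilocality (the
most common type) as reference:

    log(π_rc/π_ec) = x_c'δ_r + W_r,l(c) + Y_r,b_m(c) + Z_r,b_f(c)

with correlated intercept triples for family (W), male birthplace (Y)
and female birthplace (Z).

Priors are regularizing and hierarchical: multivariate Gaussian
coefficient priors whose covariances decompose into half-Cauchy(0,1)
scales and LKJ(2) correlations; the log-distance intercept prior centres
on log(100) (100 km). Posteriors are sampled with a built-in no-U-turn
sampler over the analytically differentiated log-posteriors; models are
compared by PSIS-LOO. See `docs/methods.md` for the complete account.

## Worked example

```python
import numpy as np
from kinloc import (SimConfig, simulate_families, degrade,
                    build_distance_matrix, build_migration_outcomes,
                    build_residence_outcomes, summarize_outcomes,
                    build_migration_design, MigrationModel, FitConfig, fit)

cfg = SimConfig(seed=3)                       # 2 x 150 families, 100 + 75 places
fams, gaz, polys, truth = simulate_families(cfg)
obs = degrade(fams, cfg, truth, gaz)          # censoring + missingness
mig = build_migration_outcomes(obs, build_distance_matrix(gaz), gaz, polys)
res = build_residence_outcomes(obs, gaz)
ov = summarize_outcomes(mig, res, gaz)["migration_overall"]
print({k: round(v, 3) if isinstance(v, float) else v for k, v in ov.items()})

design = build_migration_design(mig, obs, gaz)          # baseline variant
post = fit(MigrationModel(design), FitConfig(chains=2, warmup=300, draws=300, seed=5))
beta = {c: post.get(f"beta[{c}]").mean() for c in design.colnames}
print(round(beta["region_richtersveld"], 2), round(beta["gen_parent"], 2))
print(round(float(np.exp(post.get("ls_T")).mean()), 2))
```

prints (numbers from this exact seed):

```
{'n_complete': 1217, 'prop_migrated': 0.528, 'median_km': 70.251, 'iqr_km': 67.611}
0.76 0.49
0.86
```

meaning: of the 1217 fully observed dyads, 52.8% migrated with a median
move of ~70 km; family members anchored in the richtersveld have about
e^0.76 ≈ 2.1× the odds of migrating of their cederberg counterparts
(true simulated effect 0.5), the parental generation about e^0.49 ≈ 1.6×
the odds of grandparents (truth 0.5); and the birthplace log-odds scale
σ_T is estimated at 0.86 (truth 1.0) — birthplaces matter a lot for
whether people leave.

The same pipeline is scriptable from the shell:

```bash
kinloc simulate --seed 11 --families 150 --out data/
kinloc outcomes --data data/ --out tables/
kinloc fit --model migration --variant settlement_size --data data/ --out runs/settle/
kinloc compare --runs runs/base runs/settle
```

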