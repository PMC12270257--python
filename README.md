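# penfam

Bayesian estimation of age-specific, sex-specific penetrance — the
cumulative probability that a carrier of a pathogenic germline variant
develops disease by a given age — from family pedigree data.

The carrier onset model is a threshold-shifted Weibull CDF scaled by a
lifetime asymptote, parameterized for estimation by the first-quartile and
median onset ages, the asymptote and the threshold.  Family likelihoods
are computed exactly for a single autosomal biallelic locus by
Elston-Stewart peeling (with Hardy-Weinberg founder priors derived from a
carrier prevalence, and a registry-style baseline risk table approximating
noncarrier penetrance).  The posterior is explored with an adaptive
random-walk Metropolis sampler with hard bound rejection, empirical
initialization and optional in-chain imputation of missing ages.

## Features

- **Pedigree I/O** (`penfam.pedigrees`): the ten-column family table
  (PedigreeID, ID, Sex, MotherID, FatherID, isProband, CurAge, isAff, Age,
  Geno), full validation reports, loop detection, proband-removal
  ascertainment correction.
- **Onset model** (`penfam.model`): modified Weibull penetrance, exact
  quantile-space reparameterization, baseline risk tables.
- **Likelihood** (`penfam.likelihood`): numba-accelerated peeling engine,
  brute-force enumeration oracle, carrier-probability posteriors.
- **Priors** (`penfam.priors`): default scaled-Beta/Uniform priors,
  explicit parameterization, and elicitation from published relative risks
  or Kaplan-Meier-style age-specific risk points.
- **Sampler** (`penfam.mcmc`): multi-chain adaptive Metropolis over the
  quantile-space parameters, per-sex blocks, seeded and reproducible.
- **Imputation** (`penfam.imputation`): carrier-probability-weighted
  redraws of missing onset/censoring ages during sampling.
- **Simulator** (`penfam.simulate`): three-generation family studies with
  carrier-proband ascertainment and known ground truth.
- **Reporting** (`penfam.reporting`): penetrance curves with credible
  bands, parameter summaries in both parameter spaces, ACF/ESS/split-Rhat
  diagnostics.

## CLI

```sh
# estimate penetrance from a pedigree table and a baseline risk table
penfam estimate --pedigree families.csv --baseline seer.csv --prev 0.005 \
    --iters 20000 --burn-in 0.1 --chains 4 --seed 1 --out results/

# simulate a family study with known truth
penfam simulate --design design.yaml --seed 1 --out study.csv --truth-out truth.json

# summarize / diagnose a saved samples table
penfam summarize --samples results/samples.csv --out summary/
penfam diagnose --samples results/samples.csv --out diagnostics.csv
```

`estimate` writes `samples.csv` (one row per retained draw),
`penetrance_F.csv` / `penetrance_M.csv` (age-by-statistic curve tables),
`parameters.csv`, `diagnostics.csv`, `validation.json` and a `config.json`
echo.  Exit codes: 0 success, 2 input validation failure, 3 estimation
failure.

## Library use

```python
import numpy as np
from penfam import (
    parse_pedigrees, BaselineRisk, GenotypeModel, default_priors,
    McmcConfig, run_chains, summarize, diagnostics,
)

peds = parse_pedigrees("families.csv")
baseline = BaselineRisk.read("seer.csv")
cfg = McmcConfig(n_chains=4, n_iter=20000, burn_in=0.1, seed=1)
samples = run_chains(peds, GenotypeModel(0.005), baseline, default_priors(), cfg)
summary = summarize(samples)
print(summary.params)
```

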