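# archorisk

Macroevolution and extinction risk for turtle- and crocodilian-like clades:
an end-to-end, fully tested pipeline covering episodic birth–death
diversification with mass-extinction detection, Lévy jump-diffusion
body-size evolution, fair-proportion evolutionary distinctiveness (ED) and
EDGE prioritization over a tree posterior, ensemble imputation of IUCN
threat status, and gridded richness maps. Everything runs on synthetic data
with known ground truth, so every stage can be validated by recovery
experiments rather than trusted on faith.

## The scientific problem

Turtles and crocodilians are ancient, slowly diversifying clades in which a
large fraction of species is threatened, and many species lack an IUCN
assessment. Three questions drive the pipeline:

1. **Diversification.** Did the clade experience mass extinctions or shifts
   in speciation/extinction rates? We fit a reconstructed birth–death
   process with piecewise-constant rates λ(t), μ(t), sampling fraction ρ,
   and instantaneous mass-extinction events at which each lineage survives
   with probability *s*. Writing u(t) for the probability that a lineage at
   age *t* leaves a sampled descendant, u obeys the logistic flow
   du/dt = u(λ−μ−λu) with u(0)=ρ, and a mass extinction multiplies u (and
   the per-lineage density flow) by *s*. Event counts get compound-Poisson
   priors and a reversible-jump MCMC samples shifts and mass extinctions;
   support is summarized as 2lnBF with thresholds 6 and 10.
2. **Body size.** Is body-size evolution gradual or punctuated? The trait
   follows Brownian motion (rate σ²) plus compound-Poisson jumps: each
   branch of length L carries c ~ Poisson(λ_J·L) jumps, each adding
   N(0, α·σ²) displacement, so conditional on the jump counts the tip
   vector is Gaussian with branch variance σ²(L + cα). The per-branch jump
   counts are sampled by MCMC; branches with posterior jump probability
   > 0.85 are called, and α is profiled on a half-decade log grid.
3. **Distinctiveness and threat.** Which species concentrate irreplaceable
   evolutionary history and risk? ED is the fair-proportion share of tree
   length (each branch divided equally among its descendant tips; ED sums
   to total tree length), medianed over a posterior of dated trees, and
   combined with the IUCN weight GE (LC=0 … CR=4) as
   EDGE = ln(1+ED) + GE·ln2. Missing statuses are imputed by an ensemble of
   a phylogenetic/spatial GLS, a random forest, and a single-hidden-layer
   perceptron over 32 predictors (traits, range area, climate, plus 2+2
   phylogenetic and spatial PCoA axes), pooled by the mean on the ordinal
   scale [1, 6].

## Layout

- `src/archorisk/` — the library: `simulate` (synthetic data generators),
  `trees` (I/O, validation, taxonomic imputation), `diversification`,
  `bodysize`, `distinctiveness`, `threat_models`, `geography`, `summaries`,
  `experiments` (canonical recovery experiments), `pipeline` (one-seed
  orchestration with a manifest).
- `analysis/01_simulate_data.py … 07_summary.py` — the numbered analysis
  drivers; each writes its tables under `results/`.
- `tests/` — unit, property, and end-to-end recovery tests with
  independent oracles (numeric ODE integration, dense matrix algebra,
  closed forms).

## Worked example

```bash
python analysis/01_simulate_data.py
python analysis/02_diversification.py
python analysis/05_threat_imputation.py
```

prints (abridged; exact numbers depend on the fixed seeds in the scripts):

```
simulated tree: 225 extant species, 173 extinct lineages pruned
species table: 225 rows, 68 statuses masked
constant-rate ML: lambda=0.0831, mu=0.0521 per Myr (turnover 0.63)
P(>=1 mass extinction) = 0.063, 2lnBF = -4.46 (constant-rate data: no support expected)
imputed 68 masked statuses: accuracy 41.2% (chance 16.7%), mean |category error| 0.65
  pglm: top predictors ['range_area', 'ecoregion=eco02', 'ecoregion=eco10']
  rf: top predictors ['range_area', 'hei', 'phy_pcoa2']
  ann: top predictors ['range_area', 'phy_pcoa1', 'spa_pcoa1']
```

The tree was simulated at constant rates, so the mass-extinction Bayes
factor is (correctly) negative; the dominant predictor of threat status is
(correctly) range area in all three models; and imputation accuracy is
well above the 1-in-6 chance level while erring by less than one category
on average.

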