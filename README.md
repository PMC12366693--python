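# demicwave

Spatially explicit simulation and approximate Bayesian computation (ABC) of
the continental-route Neolithic expansion: how incoming farmers (FA) from
Anatolia interacted — demographically and genetically — with the Indigenous
European hunter-gatherers (HG) they met on the way to central Europe.

The package is aimed at population geneticists who want to confront
spatially explicit demographic scenarios with ancient-genome diversity data:
it simulates two interacting population layers on a lattice of 100 × 100 km
demes, generates paleogenome-like pseudo-haploid sequence panels with a
backward coalescent conditioned on the recorded demography, summarizes them
exactly as the empirical data are summarized, and infers scenarios and
parameters with a two-step ABC machine.

## Model

Each lattice cell holds one HG and one FA deme. Per 25-year generation:

* **growth + competition** — logistic growth with Lotka–Volterra
  interspecific competition,
  `N' = N + rN(1 − (N + αN_other)/K)` (realized stochastically on integer
  gene copies), with the competition coefficient α symmetric between layers
  and zone-dependent: `α_S = 1` south of latitude 43.2°N, `α_N` free north
  of it;
* **assimilation** — unidirectional HG→FA admixture: expected transfers
  `γ_t · N_HG N_FA / (N_HG + N_FA)`, where the local rate γ_t may ramp up
  linearly over `t_inc` generations of cohabitation (scenario-dependent);
* **migration** — each copy emigrates with probability `m` to one of the 4
  orthogonal neighbours; for farmers a fraction `P_LDD` of emigration events
  are long-distance dispersals with a Gamma(1.209, rate 0.15046
  per deme-width) displacement (≈800 km mean).

Six admixture scenarios (AM1–AM6) vary γ over space (constant, 10-zone
gradient away from Anatolia, or two zones split at 43.2°N) and time
(constant, ramp over the whole cohabitation, or ramp over a variable
`t_inc`). A backward structured coalescent traces sampled lineages through
the recorded inflows (serial sampling at the ages of 23 ancient population
samples), drops finite-site mutations at μ = 2.15×10⁻⁸/site/generation on
50 × 1000 bp loci and adds a sequencing-error rate ε. The summary statistics
are the mean pairwise pseudo-haploid diversities within and between samples
(267 values for the study scheme). Inference: a demographic filter (every
sample realizable, HGs extinct by the end), random-forest scenario choice,
and PLS-reduced rejection ABC with GLM regression adjustment (posterior
mode, mean and 95% highest-density intervals).

## Worked example

```python
import numpy as np
from demicwave import synth, inference, sumstats
from demicwave.scenarios import PriorSpec

toy = synth.make_toy_world()            # 10 x 6 lattice, 200 generations
scheme = synth.toy_scheme(toy)          # 7 HG/FA samples, 19 genomes
priors = PriorSpec()                    # the study's uniform priors

campaign = synth.run_campaign(toy, "AM1", priors, 400, scheme, seed=7)
print(f"filter pass rate: {campaign.passed.mean():.2f}")

stats, kept = synth.stat_matrix(campaign)
params = campaign.loc[kept, ["gamma", "K_HG", "K_FA"]].to_numpy()
reducer = sumstats.PLSReducer().fit(stats, params)
reduced = reducer.transform(stats)

observed = reduced[0]                   # treat one simulation as observed
keep = inference.reject(reduced, observed, delta=0.5)
post = inference.glm_adjust(
    reduced[keep], params[keep], observed,
    prior_bounds=[(0, 0.1), (270, 450), (1200, 2400)],
    names=["gamma", "K_HG", "K_FA"],
)
print(post.summary().to_string(index=False))
```

Output:

```
filter pass rate: 0.76
parameter  posterior_mode  posterior_mean    hdi_2.5%   hdi_97.5%
    gamma        0.074274        0.052906    0.004905    0.095796
     K_HG      295.405405      348.568657  270.180180  428.378378
     K_FA     2138.138138     1918.837075 1353.753754 2400.000000
```

The pass rate is the fraction of simulations that realized every sample at
its deme, generation and population layer with the HGs extinct by the end
(the demographic filter, i.e. the first ABC step). The posterior table has
the layout of the study's parameter summaries: for each parameter the
GLM-adjusted posterior mode, mean and 95% HDI, truncated to the prior.
Here the "observed" data are one retained simulation, so the intervals
simply demonstrate the machinery on a self-consistent target.

The same pipeline is scriptable from the shell:

```bash
demicwave synth-scheme --variant full --out scheme.csv
demicwave campaign --scenario AM1 --n 400 --seed 7 --out campaign.tsv
demicwave run --config run.yaml --outdir results/
```

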