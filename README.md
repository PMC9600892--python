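# steadycross

Community metabolic modeling of cross-feeding between a fiber-degrading and a
butyrate-producing gut microbe.

Dietary fibers such as inulin and xylan are fermented in the colon by
consortia in which primary degraders release organic acids (lactate,
succinate, acetate) that butyrogenic partners convert into butyrate.
`steadycross` predicts these exchanges from genome-scale metabolic models by
community flux balance analysis: it fixes the community at the experimentally
observed growth rate, relaxes the fiber budget just enough to expose the
metabolic flexibility of the consortium, and then maps that flexibility with
flux variability analysis, Monte Carlo flux sampling and statistical
classification of every exchanged metabolite.

## The model

Members *k* = 1…K share an extracellular pool and grow balanced at a common
rate μ.  With abundances X_k (Σ X_k = 1), absolute member fluxes V_k and pool
exchanges E, a community state is feasible when

    S_k · V_k = 0                         (member steady state)
    LB_jk · X_k ≤ V_jk ≤ UB_jk · X_k      (abundance-scaled capacity)
    V_biomass,k = μ · X_k                 (biomass coupling)
    Σ_k V_ex(m),k − E_m = 0               (pool balance per metabolite m)

with the medium bounding E at the pool boundary (negative flux = uptake).
For fixed μ this is a linear program; the maximum balanced growth rate μ* is
located by bisection on feasibility.  The analysis pipeline then:

1. fixes μ at the observed community growth rate and minimizes fiber uptake
   (equivalent to maximizing growth at fixed fiber consumption);
2. computes the fiber budget u′ that would allow (1+ε)-fold faster growth
   (ε = 0.05 by default) and re-fixes growth at the observed rate with
   uptake ≤ u′ — the *suboptimal scenario*;
3. runs flux variability analysis (FVA) over abundances and exchange fluxes;
4. samples the suboptimal flux polytope with an artificial-centering
   hit-and-run chain (200,000 retained points, thinning 100, at full scale);
5. classifies each (member, metabolite) exchange as produced / consumed /
   indeterminate by a one-sample Wilcoxon signed-rank test of the sampled
   flux against zero (P < 0.01), and quantifies coupling between members'
   exchanges with Pearson correlations.

Model quality is scored against experimental phenotype tables (substrate
utilization, product formation) via precision, recall, accuracy and the
F-score 2·TP/(2·TP + FP + FN).

A fully synthetic two-member degrader/butyrogen community with closed-form
optima ships with the package, so every stage is testable without external
model downloads.

## Worked example

```python
import steadycross as sx
from steadycross.sampling import SamplerConfig, sample_hit_and_run
from steadycross.stats import classify_exchanges

cm, answers, medium = sx.make_toy_degrader_butyrogen()
opt = sx.max_community_growth(cm)

scenario = sx.ScenarioSpec(mu_exp=0.3, fiber_id="fiber_e", suboptimality_factor=0.05)
sol = sx.min_fiber_uptake(cm, scenario.mu_exp, scenario.fiber_id)
budget = sx.suboptimal_budget(cm, scenario)
ranges = {r.quantity_id: r for r in sx.community_fva(cm, scenario, fiber_budget=budget)}

poly = sx.scenario_polytope(cm, scenario, fiber_budget=budget)
samples = sample_hit_and_run(poly, SamplerConfig(n_samples=2000, thinning=100, seed=1))
report = classify_exchanges(samples, alpha=0.01,
                            columns=["degrader:EX_lac", "butyrogen:EX_lac"])
```

prints (via the obvious `print` statements):

```
maximum balanced community growth: mu* = 0.3500 /h
abundances at optimum: degrader 0.2857, butyrogen 0.7143
minimal fiber uptake at mu = 0.3 /h: 0.8571 mmol/h
suboptimal fiber budget (eps = 0.05): 0.9000 mmol/h
degrader abundance range: [0.2857, 0.3000]
degrader:EX_lac: median +4.320 mmol/h -> produced (p = 0)
butyrogen:EX_lac: median -4.320 mmol/h -> consumed (p = 0)
lactate exchange correlation: -1.0
```

Reading: the community grows fastest at 0.35 h⁻¹ with the butyrogen at 71%
abundance; at the observed rate of 0.3 h⁻¹ it needs at least 0.857 mmol/h of
fiber; granting the 5% headroom budget opens the degrader abundance to a
0.286–0.300 band; and across the sampled flux space the degrader secretes the
lactate that the butyrogen consumes, flux-for-flux (the pool has no
environment sink), hence the exact −1 correlation.

The same pipeline runs from the shell:

```sh
steadycross make-fixtures --out fixtures --seed 0
steadycross run scenario.yaml --out results --seed 1
```

with per-stage subcommands (`validate`, `steadycom`, `fva`, `sample`,
`crossfeed`) for piecemeal use.

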