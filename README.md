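# regflux

Regulatory analysis of metabolic flux: how much of a microbe's
condition-to-condition flux change is carried by enzyme concentration
(gene expression), and how much by the metabolic state?

`regflux` integrates per-condition **fluxes** (e.g. from ¹³C metabolic flux
analysis), **transcript signals**, **metabolite concentrations** and
**growth rates** across many steady-state growth conditions, and quantifies
for every reaction:

- **ρ_h** — the *hierarchical regulation coefficient*: the slope of centered
  log₂ enzyme concentration vs centered log₂ flux magnitude. ρ_h = 1 means
  flux changes are fully matched by enzyme changes (transcriptional
  control); ρ_h = 0 means the enzyme level is flat and the metabolic state
  (substrates, effectors, modifications) does all the work. The metabolic
  coefficient is ρ_m = 1 − ρ_h.
- **ρ_hr** — the analogous slope at a metabolic branch point, relating log
  flux *split ratios* to log enzyme *concentration ratios*. Under
  first-order kinetics this slope is exactly 1, a prediction the bundled
  mechanistic two-enzyme Michaelis–Menten simulator verifies and bounds.
- **ρ_es** — the combined coefficient when the predictor includes the
  substrate through the power law ΔJ = ΔE·ΔS^λ (the S-system form); the
  exponent λ captures saturation (λ<1) or cooperativity (λ>1), and
  δ = ρ_es − ρ_h is the additional explanatory contribution of the
  substrate.

Enzyme concentrations are inferred from transcript signals with a
steady-state dilution model, E ∝ m·T(μ)/μ, where T(μ) is the affine
total-mRNA-per-biomass model and μ the growth rate. All slopes use a
**weighted Theil-Sen estimator** (weighted median of pairwise slopes,
weights (xᵢ−xⱼ)²) with confidence intervals and P-values from a
subset-plus-measurement-noise resampling scheme (N = 2000 draws). The
package also includes growth-rate-scaling analysis of biosynthetic enzyme
expression, fold-change summaries for on/off (uptake-like) reactions, a
ground-truth synthetic data generator, and a pipeline orchestrator with a
`regflux` command-line interface.

Intended users: systems-biology groups with multi-omic steady-state
datasets who want a tested, reproducible implementation of regulatory
analysis rather than one-off scripts.

## Worked example

Generate a synthetic 8-condition dataset with known regulation
(true ρ_h ∈ {0, 0.3, 0.7, 1.0}, a substrate-driven reaction with λ = 1, a
kinetically simulated branch point, two on/off uptake genes at 10- and
100-fold induction, realistic measurement noise) and run the full
analysis:

```python
from regflux import (PipelineConfig, ResampleConfig, default_spec,
                     generate_dataset, run_pipeline)

dataset, truth = generate_dataset(default_spec(seed=17))
cfg = PipelineConfig(out_dir="demo_out",
                     resample=ResampleConfig(n_iter=2000, seed=17))
res = run_pipeline(dataset, cfg)
for f in res["rho_h"]:
    print(f"{f.task_id:28s} rho={f.rho:+.2f}  "
          f"CI=[{f.ci_low:+.2f}, {f.ci_high:+.2f}]  class={f.fit_class}")
```

prints

```
R_metabolic:g_R_metabolic    rho=-0.05  CI=[-0.20, +0.17]  class=metabolic
R_partial:g_R_partial        rho=+0.30  CI=[+0.09, +0.41]  class=partial
R_mixed:g_R_mixed            rho=+0.61  CI=[+0.38, +0.86]  class=partial
R_hier:g_R_hier              rho=+0.89  CI=[+0.73, +1.07]  class=full_hierarchical
R_substrate:g_R_substrate    rho=-0.11  CI=[-0.28, +0.07]  class=metabolic
...
```

The generated truth is recovered: the reaction built with ρ_h = 0.3 fits at
0.30, the fully transcriptional reaction (ρ_h = 1) is classified
`full_hierarchical` (its CI covers 1), and the substrate-driven reaction is
correctly called `metabolic` at the enzyme level. The combined fit then
resolves it (`res["rho_es"]`):

```
                                   id  lambda  rho_h  rho_es  delta
R_substrate:g_R_substrate@S_substrate    1.18  -0.11    0.99   1.10
                     R_es:g_R_es@S_es    0.98   0.48    0.89   0.41
```

— a flat enzyme with ρ_es ≈ 1 means the substrate, not the enzyme, drives
the flux. The branch point fits `rho_hr=1.11 CI=[0.72, 1.61]` (simulated in
the near-first-order regime, so the truth is 1), and the on/off summary
recovers the induction folds (`g_uptake1: 97.8`, `g_uptake2: 7.5` against
true folds 100 and 10).

The same analysis runs from the shell on TSV inputs:

```bash
regflux simulate --seed 17 --out demo_data/
regflux run --conditions demo_data/conditions.tsv --fluxes demo_data/fluxes.tsv \
    --transcripts demo_data/transcripts.tsv --metabolites demo_data/metabolites.tsv \
    --map demo_data/map.tsv --branches demo_data/branches.tsv --out demo_out
```

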