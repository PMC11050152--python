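# pahmix

Component-based additivity modeling for chemical mixtures, built around
a transcriptional case study: polycyclic aromatic hydrocarbons (PAHs)
applied to differentiated human bronchial epithelium, read out as qPCR
log2 fold changes of toxicity biomarker genes.

**Who it is for.** Mixture toxicologists and biostatisticians who have
single-component dose–response data and want to ask: *is the mixture
response what the components predict under additivity, or is there
synergy/antagonism?*

## The model

For each gene, every mixture component is fit with a dose–response
curve (drc-style log-logistic, Weibull, Michaelis–Menten, asymptotic
regression and Gompertz families, plus linear/quadratic fallbacks),
selected by AIC with the rule that a polynomial only wins when its AIC
beats the best saturating family by more than 2. The mixture response
at dose *c* is then predicted by a modified independent-action (IA)
model that handles both up- and down-regulated components:

```
up(c)   = (1 − ∏ᵢ (1 − uᵢ(c))) · maxlog2FC_up
down(c) = (1 − ∏ⱼ (1 − vⱼ(c))) · maxlog2FC_down
log2FC_mix(c) = up(c) + down(c)
```

where `uᵢ = clamp(log2FC(cᵢ,up) / maxlog2FC_up, 0, 1)` is component
*i*'s fitted effect normalized by the largest fitted up-effect across
components (`vⱼ` analogously for down-regulation). Two dose axes are
supported: plain µM concentrations, and toxic-equivalency-factor (TEF)
scaled benzo[e]pyrene-equivalent concentrations, where each component's
curve is re-indexed by its TEF.

Agreement between prediction and observation is quantified by the
Pearson correlation of the fitted curves (weak |r| < 0.3, moderate
0.3–0.5, strong > 0.5) and the RMSE against the per-dose mean response
(small < 1, moderate 1–2, large > 2, in log2 units).

Because raw bench data are not distributed with the package, a
synthetic-data module generates replicate-level qPCR-style inputs
(ΔΔCt arithmetic included) from known ground-truth curves, with a
controllable interaction factor, so every pipeline stage is verifiable
end to end.

## Worked example

```python
from pahmix import RunConfig, run_pipeline

config = RunConfig(mode="simulate", seed=1, noise_sd=0.3, axes=("uM", "bep"))
result = run_pipeline(config)
print("genes selected:", result["manifest"]["genes_selected"])
print(result["evaluation"][["gene", "axis", "pearson_r", "rmse",
                            "r_category", "rmse_category"]].round(3))
```

prints

```
genes selected: ['CYP1A1', 'CYP1B1', 'ALDH3A1', 'GSTA', 'HMOX1', 'NQO1']
   gene axis  pearson_r   rmse r_category rmse_category
 CYP1A1   uM      0.962  0.161     strong         small
 CYP1B1   uM      0.979  0.163     strong         small
ALDH3A1   uM      0.980  0.129     strong         small
   GSTA   uM      0.982  0.259     strong         small
  HMOX1   uM      0.991  0.261     strong         small
   NQO1   uM      0.984  0.327     strong         small
 CYP1A1  bep      0.939 13.492     strong         large
 CYP1B1  bep      0.986 10.602     strong         large
ALDH3A1  bep      0.969  1.217     strong      moderate
   GSTA  bep      0.985  1.283     strong      moderate
  HMOX1  bep      0.930  1.046     strong      moderate
   NQO1  bep      0.842  0.926     strong         small
```

Nine biomarker genes are simulated; the two inclusion filters (at least
two valid replicates per treatment cell, at least three components with
a significant Dunnett-adjusted response per gene) keep six for IA
modeling. On the µM axis the additively generated data are recovered
with strong correlation and small error. On the BeP-equivalent axis
the same data show inflated RMSE for the most responsive genes: TEF
scaling evaluates low-TEF components far above their tested dose range,
a known bias of the TEF-adjusted IA variant (see
`docs/methods.md`).

The same workflow is available from the shell:

```sh
pahmix run-all --out results/run1          # simulate → evaluate, default config
pahmix simulate --seed 1 --out sim.csv     # just the synthetic dataset
pahmix evaluate --in sim.csv --axis uM --out eval.csv
```

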