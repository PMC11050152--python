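# Methods

## Problem setting

A component-based mixture assessment asks whether a mixture's response
can be predicted from its components' individual dose–response curves
under an additivity assumption. The package implements this for
transcriptional endpoints: log2 fold changes (log2FC) of biomarker
genes versus a vehicle control, measured by qPCR after exposure to a
PAH mixture or to each of its components singly.

The bundled mixture ("ToxMix") has seven components at fixed fractions
of the total concentration — retene 68.6%, benzo[a]fluorene 16.8%,
benzo[b]fluorene 8.42%, benzo[c]fluorene 4.21%, triphenylene 1.68%,
benzo[e]pyrene 0.168%, benzo[ghi]perylene 0.0842% — with toxic
equivalency factors (TEFs) of 0.001 for the first five, 1 for
benzo[e]pyrene (the reference chemical) and 0.01 for
benzo[ghi]perylene. The printed percentages sum to 99.95%; they are
renormalized to exactly 1 at load time and the printed values kept for
reporting. A second bundled mixture ("AbundMix", six components, no
TEFs) exercises the µM-only path.

## Dose axes

Relative concentration `r` (fraction of full mixture strength) maps
linearly to doses. With `T` the full-strength total (µM) and `p_i`
component *i*'s proportion:

* component dose: `r · T · p_i` (µM). Single-component exposures at
  "r%" are taken at the component's concentration within the r%
  mixture — the only mapping that makes component and mixture doses
  commensurable.
* BeP-equivalent mixture dose: `r · T · Σ p_i · TEF_i`. A component
  dose maps to the BeP axis as `dose · TEF_i`, so the whole-mixture
  identity `bep(r) = Σ tef_i · dose_i(r)` holds to machine precision.

The absolute stock concentration `T` is a configuration value
(default 100 µM). All correlation/RMSE conclusions are invariant to it;
it only labels the dose axis.

## Dose–response fitting

Candidate families use the drc parameterization (`b` slope, `c` lower
asymptote, `d` upper asymptote, `e` inflection/half-max dose):
log-logistic with 2/3/4 parameters, both Weibull types, Michaelis–
Menten, asymptotic regression, Gompertz, and linear/quadratic
polynomials. The vehicle dose (0) enters through each family's exact
x→0 limit; no pseudo-dose offset is used.

Fitting is bounded least squares with a deterministic multi-start: `c`
and `d` seeded from the low-/high-dose mean responses, `e` from the
dose nearest the half response, and a fixed five-point grid on `b`
covering both orientations. The four-parameter log-logistic
additionally starts from the nested three-parameter solution (and LL.3
from LL.2), which guarantees a richer family never ends with a larger
residual sum of squares than its nested relative. No RNG is involved,
so fits are bit-reproducible.

Model selection minimizes a Gaussian AIC, `n·ln(RSS/n) + 2k`, where `k`
counts curve parameters plus one for the residual variance (constants
dropped uniformly; only AIC differences matter). A polynomial winner is
accepted only when its AIC beats the best saturating family by more
than 2 — polynomials are descriptive fallbacks, not mechanistic
dose–response models. Relative EC50s (the dose at the midpoint of the
modeled span, `c + (d−c)/2`) have closed forms for every saturating
family; a bracketed root-finder (relative tolerance 1e-9) covers any
parameter corner where the closed form degenerates. EC50 is absent —
never an exception — for polynomial or flat fits.

Direction of effect is the sign of the largest-magnitude fitted
response over the observed dose range; magnitudes below 0.1 log2 units
count as flat. Curves that fail to converge are flagged and excluded
from selection rather than silently zeroed.

## Preprocessing and inclusion filters

* **ΔΔCt.** Per well `ΔCt = Ct_target − Ct_reference`; per
  gene × treatment the vehicle wells define the baseline, and
  `log2FC = −ΔΔCt` (fold change `2^−ΔΔCt`). Invariance to any constant
  added to both Ct columns, or to the reference gene globally, is a
  tested property.
* **Outliers.** Off by default; Tukey IQR fences (`k`=1.5) and
  iterative two-sided Grubbs (α=0.05) are selectable, applied within
  gene × treatment × dose cells of at least 3 observations. Every
  removal (and every skipped small cell) is logged, so the choice is
  auditable. The exact procedure used upstream of published datasets is
  rarely stated; exposing it as a logged option is the safest default.
* **Significance.** One-way many-to-one comparison of each dose group
  against vehicle with Dunnett's adjustment (scipy implementation,
  cross-checked against R's multcomp in the tests). The adjustment
  family is the dose groups within one gene × treatment panel; no
  across-gene correction is applied because results are reported
  per gene. The randomized multivariate-t quadrature is pinned to a
  fixed RNG so identical inputs give identical p-values. Degenerate
  cells do not crash the pipeline: exact ties give p=1 with a warning,
  zero within-group variance with separated means gives p=0 (the
  noise-free limit).
* **Filters.** A treatment cell needs ≥ 2 valid replicate observations
  (interpreted as surviving replicates — replicate-level "significance"
  is undefined for fold-change data, and the observed removal of a
  single-replicate cell matches this reading). A gene needs ≥ 3
  components with a significant response at any concentration; the
  mixture itself does not count. Both filters are idempotent and log
  every exclusion exactly once.

## Independent action with direction partitioning

Components are partitioned by fitted direction. Within a direction,
effects are normalized by the cross-component extremum of the fitted
effects over the modeled mixture dose range (`maxlog2FC_up ≥ 0`,
`maxlog2FC_down ≤ 0`), clamped to [0, 1], combined by response addition
`1 − ∏(1 − u_i)`, rescaled by the extremum, and the two direction terms
added. This form (a) reduces exactly to the component curve when only
one component is active, (b) is bounded by the per-direction extrema,
and (c) is monotone in each component's effect. A circulating typeset
variant that omits the inner complement violates the single-component
identity; it is available behind `literal_form=True` strictly for
comparison.

Component effects come from fitted curves, not observed means: within
the mixture each component sits at `p_i` times the mixture dose, below
its lowest singly-tested dose, so model-based interpolation is
unavoidable. On the BeP axis, component *i*'s curve is re-indexed by
its TEF and evaluated at `x / TEF_i` at the common BeP-equivalent
coordinate `x`.

**Known hazard (documented, not patched away):** on the BeP axis a
low-TEF component is evaluated up to `1/TEF_i` times beyond its tested
dose range. Saturating families extrapolate to their plateau, but a
shallow unsaturated fit (e.g. a log-logistic with its inflection far
above the data, behaving linearly in-range) can extrapolate to large
effects, inflating `maxlog2FC_up` and the RMSE of the TEF-adjusted
variant. This reproduces the characteristic biases of the two variants:
the µM model tracks the most abundant component, the TEF model tracks
the highest-TEF component and tends to larger errors.

## Synthetic data

The generator emulates the study design: nine genes, seven components
at 0.5/1/5/10% relative concentration, four replicates, vehicle rows,
additive Gaussian noise of SD 0.3 log2 units (constant across doses, as
ΔΔCt noise is approximately additive in Ct space). Four replicates
match the component-exposure design; the replicate count is
configurable where a different design (e.g. five replicates) is to be
emulated. Ground-truth curves are four-parameter log-logistics with
half-max at 30% of each component's top tested dose and amplitudes
graded by component potency and gene sensitivity; the encoded
activity pattern gives exactly six genes with ≥ 3 active components.
The mixture response is generated through the same IA kernel the
analyzer uses (shared code, so generator and analyzer cannot drift),
scaled by an interaction factor `s` (1 additive, >1 synergy,
<1 antagonism). A raw-Ct generator inverts the ΔΔCt arithmetic exactly
at zero noise. All generators are pure functions of
(config, truth, seed).

What passing tests on these data do **not** show: robustness to
heteroscedastic or dose-dependent noise, plate effects, primer
efficiencies ≠ 2, correlated replicates, or real mechanistic
interactions — none of which the generator emulates.

## Evaluation

Pearson r is computed between the fitted mixture curve and the IA
prediction on a 100-point log-spaced grid spanning the tested mixture
dose range (sensitivity to grid size ≥ 50 is below 0.01 on fixtures);
it is absent, with a recorded reason, when the mixture lacks a
dose–response fit or either curve is flat. RMSE compares the IA
prediction with the per-dose mean observed response over the tested
doses (replicate-level RMSE is a flag). Category boundaries
(|r| = 0.3, 0.5; RMSE = 1, 2) are not assigned by the strict printed
inequalities; they are closed upward (a boundary value lands in the
higher category).

## Problem sizes and numerical choices

The default run fits ten families × eight treatments × six genes and
completes in well under a minute; the acceptance script uses 200
simulated fits for EC50 recovery and 5,000 null simulations for the
Dunnett calibration, sizes at which the Monte-Carlo standard error
(≈ 0.003 on a 0.05 rate) is well inside the ±0.01 acceptance band.
Overflow in the log-dose families is guarded by clipping exponents at
±700; `e` is bounded in [1e-12, 1e12]; the IA conservation and oracle
identities are asserted at 1e-12 absolute.

## Limitations

* Concentration addition and generalized concentration addition are
  out of scope; the package quantifies departure from IA additivity
  descriptively (r, RMSE) and fits no interaction parameter.
* No confidence intervals on EC50 or on r/RMSE.
* The BeP-axis extrapolation hazard above.
* Single timepoint per run; a timecourse is a loop over runs, not a
  modeled quantity.
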