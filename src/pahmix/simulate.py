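"""Synthetic qPCR-style datasets with known ground truth.

Emulates a component-based mixture study: nine transcriptional biomarker
genes, seven mixture components exposed singly at 0.5/1/5/10% of full
mixture strength, vehicle controls, and the mixture itself.  Replicate
log2 fold changes are drawn as ``true_curve(dose) + N(0, noise_sd)`` —
additive Gaussian noise on the log2 scale, constant across doses, which
is how ΔΔCt noise propagates from Ct space.

The mixture response is generated through the *same* independent-action
kernel the analyzer uses (``ia_predict_from_truth``), scaled by an
interaction factor ``s`` (1 = additive, s > 1 synergy, s < 1
antagonism), so end-to-end additivity closure is exact up to noise and
fit error.  All generators are pure functions of (config, truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .ia import ia_predict_from_truth
from .mixtures import MixtureDefinition, component_dose, toxmix
from .preprocess import CT_COLUMNS, RESPONSE_COLUMNS
from .dose_response import FittedCurve
from .families import FAMILIES

__all__ = [
    "TrueCurveSpec",
    "SimulationConfig",
    "generate_component_responses",
    "generate_mixture_response",
    "generate_ct_table",
    "default_truth",
    "reference_significance_pattern",
    "STUDY_GENES",
    "MODELED_GENES",
    "SIGNIFICANCE_PATTERN",
]

#: The nine biomarker genes of the emulated study design.
STUDY_GENES = (
    "CYP1A1", "CYP1B1", "ALDH3A1", "GSTA", "HMOX1",
    "NQO1", "TJP2", "GJA1", "DDB2",
)

#: Which components elicit a significant response per gene in the
#: emulated design.  CYP1A1 responds to every treatment; retene and
#: benzo[b]fluorene are the most active components (all six modeled
#: genes); benzo[e]pyrene responds in three and benzo[ghi]perylene in
#: four of the modeled genes; TJP2 responds only to benzo[a]fluorene and
#: benzo[ghi]perylene (too few components to model); GJA1 and DDB2 are
#: silent.
SIGNIFICANCE_PATTERN: dict[str, frozenset[str]] = {
    "CYP1A1": frozenset({
        "retene", "benzo[a]fluorene", "benzo[b]fluorene", "benzo[c]fluorene",
        "triphenylene", "benzo[e]pyrene", "benzo[ghi]perylene",
    }),
    "CYP1B1": frozenset({
        "retene", "benzo[a]fluorene", "benzo[b]fluorene", "benzo[c]fluorene",
        "triphenylene", "benzo[e]pyrene", "benzo[ghi]perylene",
    }),
    "ALDH3A1": frozenset({
        "retene", "benzo[a]fluorene", "benzo[b]fluorene", "benzo[ghi]perylene",
    }),
    "GSTA": frozenset({"retene", "benzo[b]fluorene", "benzo[c]fluorene"}),
    "HMOX1": frozenset({
        "retene", "benzo[a]fluorene", "benzo[b]fluorene", "benzo[e]pyrene",
    }),
    "NQO1": frozenset({
        "retene", "benzo[a]fluorene", "benzo[b]fluorene", "benzo[ghi]perylene",
    }),
    "TJP2": frozenset({"benzo[a]fluorene", "benzo[ghi]perylene"}),
    "GJA1": frozenset(),
    "DDB2": frozenset(),
}

#: Genes expected to pass the >= 3-significant-components filter.
MODELED_GENES = ("CYP1A1", "CYP1B1", "ALDH3A1", "GSTA", "HMOX1", "NQO1")


@dataclass(frozen=True)
class TrueCurveSpec:
    """Ground-truth dose-response curve for one gene x treatment pair.

    ``family is None`` denotes a null (identically zero) response.
    ``direction`` may be given or left to be derived from the curve.
    """

    gene: str
    treatment: str
    family: Optional[str] = None
    params: dict[str, float] = field(default_factory=dict)
    direction: Optional[str] = None

    def __post_init__(self):
        if self.family is None:
            if self.params:
                raise ConfigurationError(
                    f"null curve for {self.gene}/{self.treatment} must have no params"
                )
            return
        fam = FAMILIES.get(self.family)
        if fam is None:
            raise ConfigurationError(f"unknown family {self.family!r}")
        missing = set(fam.param_names) - set(self.params)
        if missing:
            raise ConfigurationError(
                f"{self.gene}/{self.treatment}: family {self.family} missing "
                f"parameters {sorted(missing)}"
            )

    def mean(self, doses) -> np.ndarray:
        doses = np.atleast_1d(np.asarray(doses, dtype=float))
        if self.family is None:
            return np.zeros_like(doses)
        fam = FAMILIES[self.family]
        return fam.evaluate(doses, [self.params[n] for n in fam.param_names])


TruthLike = Union[Mapping[tuple[str, str], TrueCurveSpec], Iterable[TrueCurveSpec]]


def _truth_map(truth: TruthLike) -> dict[tuple[str, str], TrueCurveSpec]:
    if isinstance(truth, Mapping):
        return dict(truth)
    return {(t.gene, t.treatment): t for t in truth}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated design: four relative concentrations
    (0.5/1/5/10% of full mixture strength), four replicates, noise SD
    0.3 log2 units.  ``seed`` is mandatory — there is no hidden RNG
    state.  ``interaction_factor`` scales the additive mixture mean
    (1 = additive; > 1 synergy; < 1 antagonism).  Optional outliers
    (probability ``outlier_rate``, shift ``outlier_magnitude``) exercise
    the outlier-removal stage and are off by default.
    """

    mixture: MixtureDefinition
    seed: int
    genes: tuple[str, ...] = STUDY_GENES
    rel_concs: tuple[float, ...] = (0.005, 0.01, 0.05, 0.10)
    n_replicates: int = 4
    noise_sd: float = 0.3
    interaction: str = "additive"
    interaction_factor: float = 1.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed is required and must be an integer")
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "rel_concs", tuple(float(r) for r in self.rel_concs))
        if any(r <= 0 for r in self.rel_concs) or any(
            b <= a for a, b in zip(self.rel_concs, self.rel_concs[1:])
        ):
            raise ConfigurationError("rel_concs must be positive and strictly increasing")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.interaction not in {"additive", "synergy", "antagonism"}:
            raise ConfigurationError(f"unknown interaction mode {self.interaction!r}")
        s = self.interaction_factor
        if self.interaction == "additive" and s != 1.0:
            raise ConfigurationError("additive mode requires interaction_factor == 1")
        if self.interaction == "synergy" and s < 1.0:
            raise ConfigurationError("synergy requires interaction_factor >= 1")
        if self.interaction == "antagonism" and not (0.0 < s <= 1.0):
            raise ConfigurationError("antagonism requires 0 < interaction_factor <= 1")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ConfigurationError("outlier_rate must be in [0, 1)")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _require_truth(
    truth: dict, gene: str, treatment: str
) -> TrueCurveSpec:
    try:
        return truth[(gene, treatment)]
    except KeyError:
        raise ConfigurationError(
            f"no ground-truth curve specified for gene {gene!r}, "
            f"treatment {treatment!r}"
        ) from None


def _noisy_rows(
    rows: list[tuple[str, str, float, float]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand (gene, treatment, rel_conc, mean) cells into replicate rows."""
    n = config.n_replicates
    means = np.repeat([m for *_k, m in rows], n)
    z = rng.standard_normal(means.size)
    values = means + config.noise_sd * z
    u = rng.random(means.size)
    flip = rng.random(means.size) < 0.5
    if config.outlier_rate > 0:
        shift = np.where(flip, -config.outlier_magnitude, config.outlier_magnitude)
        values = np.where(u < config.outlier_rate, values + shift, values)
    return pd.DataFrame(
        {
            "gene": np.repeat([r[0] for r in rows], n),
            "treatment": np.repeat([r[1] for r in rows], n),
            "rel_conc": np.repeat([r[2] for r in rows], n),
            "replicate": np.tile(np.arange(1, n + 1), len(rows)),
            "log2fc": values,
        },
        columns=RESPONSE_COLUMNS,
    )


def generate_component_responses(
    config: SimulationConfig, truth: TruthLike
) -> pd.DataFrame:
    """Replicate-level log2FC table for all single-component exposures.

    Single-component exposures at relative concentration ``r`` are dosed
    at the component's concentration within the r% mixture
    (``r * full_strength_total * proportion``).  Vehicle rows
    (rel_conc = 0, mean 0) are included per gene x component.
    """
    tmap = _truth_map(truth)
    mix = config.mixture
    rows = []
    for gene in config.genes:
        for spec in mix.components:
            t = _require_truth(tmap, gene, spec.name)
            for r in (0.0,) + config.rel_concs:
                mean = (
                    0.0
                    if r == 0.0
                    else float(t.mean(component_dose(mix, r, spec.name))[0])
                )
                rows.append((gene, spec.name, r, mean))
    return _noisy_rows(rows, config, _rng(config, 1))


def generate_mixture_response(
    config: SimulationConfig, truth: TruthLike
) -> pd.DataFrame:
    """Replicate-level mixture response generated under (scaled) IA additivity.

    The mean at relative concentration ``r`` is the independent-action
    combination of the true component curves on the uM axis, multiplied
    by ``interaction_factor``.
    """
    tmap = _truth_map(truth)
    mix = config.mixture
    s = config.interaction_factor
    rows = []
    for gene in config.genes:
        per_comp = {
            spec.name: _require_truth(tmap, gene, spec.name)
            for spec in mix.components
        }
        doses_um = np.array(config.rel_concs) * mix.full_strength_total
        ia = ia_predict_from_truth(per_comp, mix, doses_um, axis="uM", gene=gene)
        rows.append((gene, mix.name, 0.0, 0.0))
        for r, mean in zip(config.rel_concs, ia.predicted):
            rows.append((gene, mix.name, r, s * float(mean)))
    return _noisy_rows(rows, config, _rng(config, 2))


#: Vehicle-well baseline Cts used when synthesizing raw Ct tables.
_CT_REFERENCE = 20.0
_CT_TARGET_BASE = 24.0


def generate_ct_table(
    config: SimulationConfig,
    truth: TruthLike,
    reference_gene: str = "PPIA",
) -> pd.DataFrame:
    """Raw Ct table (components + mixture) that inverts the ΔΔCt arithmetic.

    Each well's target Ct is ``ct_reference + baseline_gene - log2fc``,
    so the comparative ΔΔCt computation recovers the generated log2FC
    exactly when ``noise_sd = 0`` (with noise, the recovered values
    differ only by the vehicle-mean recentering).  The reference gene
    contributes a constant Ct; shifting it leaves fold changes unchanged.
    """
    if not reference_gene:
        raise ConfigurationError("a reference gene name is required")
    responses = pd.concat(
        [
            generate_component_responses(config, truth),
            generate_mixture_response(config, truth),
        ],
        ignore_index=True,
    )
    baselines = {
        gene: _CT_TARGET_BASE + 0.25 * i for i, gene in enumerate(config.genes)
    }
    out = responses.copy()
    out["ct_reference"] = _CT_REFERENCE
    out["ct_target"] = (
        _CT_REFERENCE
        + out["gene"].map(baselines)
        - out["log2fc"]
    )
    out.attrs["reference_gene"] = reference_gene
    return out[CT_COLUMNS]


def default_truth(
    mix: Optional[MixtureDefinition] = None,
    genes: Sequence[str] = STUDY_GENES,
    pattern: Optional[Mapping[str, frozenset[str]]] = None,
) -> dict[tuple[str, str], TrueCurveSpec]:
    """Ground-truth curves reproducing the emulated study's activity pattern.

    Active gene x component pairs get four-parameter log-logistic curves
    with half-max dose at 30% of the component's top tested dose and
    amplitudes graded by component potency (retene largest) and gene
    sensitivity (CYP1A1 largest); TJP2 is down-regulated.  Inactive
    pairs are null curves.
    """
    mix = mix if mix is not None else toxmix()
    pattern = dict(pattern) if pattern is not None else SIGNIFICANCE_PATTERN
    comp_amp = {
        "retene": 3.0,
        "benzo[a]fluorene": 2.0,
        "benzo[b]fluorene": 2.0,
        "benzo[c]fluorene": 1.2,
        "triphenylene": 1.0,
        "benzo[e]pyrene": 1.0,
        "benzo[ghi]perylene": 1.2,
    }
    gene_scale = {
        "CYP1A1": 1.5, "CYP1B1": 1.2, "ALDH3A1": 0.9, "GSTA": 0.8,
        "HMOX1": 0.9, "NQO1": 0.8, "TJP2": -1.0,
    }
    top_rel = 0.10
    truth: dict[tuple[str, str], TrueCurveSpec] = {}
    for gene in genes:
        active = pattern.get(gene, frozenset())
        for spec in mix.components:
            if spec.name not in active:
                truth[(gene, spec.name)] = TrueCurveSpec(gene=gene, treatment=spec.name)
                continue
            top_dose = top_rel * mix.full_strength_total * spec.proportion
            d = comp_amp.get(spec.name, 1.0) * gene_scale.get(gene, 0.8)
            truth[(gene, spec.name)] = TrueCurveSpec(
                gene=gene,
                treatment=spec.name,
                family="LL.4",
                params={"b": -1.5, "c": 0.0, "d": d, "e": 0.3 * top_dose},
                direction="up" if d > 0 else "down",
            )
    return truth


def reference_significance_pattern(
    mixture_name: str = "ToxMix",
    rel_concs: Sequence[float] = (0.005, 0.01, 0.05, 0.10),
) -> pd.DataFrame:
    """Significance table encoding the emulated study's reported pattern.

    One row per gene x treatment x concentration with an adjusted p-value
    of 0.001 where the design marks the pair active (significance is
    granted at the top concentration) and 0.5 elsewhere.  Mixture rows
    are included so gene selection can demonstrate excluding them from
    the component tally.
    """
    mixture_sig = {"CYP1A1", "CYP1B1", "ALDH3A1", "HMOX1", "TJP2"}
    rows = []
    top = max(rel_concs)
    all_treatments = sorted(
        {c for s in SIGNIFICANCE_PATTERN.values() for c in s}
    ) + [mixture_name]
    for gene in STUDY_GENES:
        for treatment in all_treatments:
            active = (
                gene in mixture_sig
                if treatment == mixture_name
                else treatment in SIGNIFICANCE_PATTERN[gene]
            )
            for r in rel_concs:
                hit = active and r == top
                rows.append(
                    {
                        "gene": gene,
                        "treatment": treatment,
                        "rel_conc": float(r),
                        "p_adj": 0.001 if hit else 0.5,
                        "significant": hit,
                    }
                )
    return pd.DataFrame(rows)
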