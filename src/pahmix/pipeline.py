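"""End-to-end orchestration: simulate/load -> preprocess -> fit -> IA -> evaluate.

``run_pipeline`` executes the stages in order, collects every exclusion
into a single machine-readable log, and emits a manifest (config hash,
seed, library versions, per-stage record counts).  The whole run is a
pure function of (config, seed): rerunning with the same configuration
reproduces all outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .dose_response import DoseResponseRegressor, FittedCurve
from .errors import ConfigurationError, FitError
from .evaluate import evaluate_gene
from .ia import build_context, ia_predict
from .mixtures import MixtureDefinition, abundmix, load_mixture, toxmix
from .preprocess import (
    filter_treatments,
    fold_change_from_ct,
    read_ct_csv,
    read_response_csv,
    remove_outliers,
    select_genes_for_ia,
    significance_table,
    write_response_csv,
)
from .simulate import (
    SimulationConfig,
    default_truth,
    generate_component_responses,
    generate_mixture_response,
)

__all__ = ["RunConfig", "run_pipeline", "fit_response_curves"]

_BUILTIN_MIXTURES = {"toxmix": toxmix, "abundmix": abundmix}


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    ``mode`` selects the input: ``"simulate"`` (synthetic data from the
    built-in ground truth), ``"log2fc"`` (a response CSV) or ``"ct"``
    (a raw Ct CSV put through the ΔΔCt computation).  ``mixture`` is a
    built-in name (``"toxmix"``/``"abundmix"``) or a YAML/CSV path.
    ``axes`` lists the dose axes to model (``"uM"``, ``"bep"``).
    """

    mode: str = "simulate"
    mixture: str = "toxmix"
    input_path: Optional[str] = None
    seed: int = 0
    full_strength_total: Optional[float] = None
    # simulation settings (mode == "simulate")
    rel_concs: tuple[float, ...] = (0.005, 0.01, 0.05, 0.10)
    n_replicates: int = 4
    noise_sd: float = 0.3
    interaction: str = "additive"
    interaction_factor: float = 1.0
    # preprocessing
    outlier_method: str = "none"
    outlier_k: float = 1.5
    outlier_alpha: float = 0.05
    min_obs: int = 2
    min_components: int = 3
    # modeling
    families: Optional[tuple[str, ...]] = None
    axes: tuple[str, ...] = ("uM", "bep")
    grid_size: int = 100
    replicate_level_rmse: bool = False
    literal_form: bool = False

    def __post_init__(self):
        if self.mode not in {"simulate", "log2fc", "ct"}:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode != "simulate" and not self.input_path:
            raise ConfigurationError(f"mode {self.mode!r} requires input_path")
        if self.mode != "simulate" and not Path(self.input_path).exists():
            raise ConfigurationError(f"input file not found: {self.input_path}")
        object.__setattr__(self, "axes", tuple(self.axes))
        object.__setattr__(self, "rel_concs", tuple(self.rel_concs))
        if self.families is not None:
            object.__setattr__(self, "families", tuple(self.families))
        for axis in self.axes:
            if axis not in {"uM", "bep"}:
                raise ConfigurationError(f"unknown axis {axis!r}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rel_concs"] = list(self.rel_concs)
        d["axes"] = list(self.axes)
        d["families"] = None if self.families is None else list(self.families)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_mixture(config: RunConfig) -> MixtureDefinition:
    if config.mixture in _BUILTIN_MIXTURES:
        return _BUILTIN_MIXTURES[config.mixture](config.full_strength_total)
    return load_mixture(config.mixture, full_strength_total=config.full_strength_total)


def fit_response_curves(
    responses: pd.DataFrame,
    mix: MixtureDefinition,
    genes: Sequence[str],
    families: Optional[Sequence[str]] = None,
) -> dict[str, dict[str, Optional[FittedCurve]]]:
    """Fit a uM-axis dose-response curve per gene x treatment.

    Component doses are the within-mixture concentrations
    (``rel_conc * total * proportion``); the mixture treatment is dosed
    at ``rel_conc * total``.  Unfittable panels yield ``None``.
    """
    curves: dict[str, dict[str, Optional[FittedCurve]]] = {}
    proportions = {c.name: c.proportion for c in mix.components}
    for gene in genes:
        sub_gene = responses[responses["gene"] == gene]
        curves[gene] = {}
        for treatment, sub in sub_gene.groupby("treatment", sort=False):
            scale = proportions.get(treatment, 1.0) * mix.full_strength_total
            doses = sub["rel_conc"].to_numpy(float) * scale
            try:
                reg = DoseResponseRegressor(
                    families=families, gene=gene, treatment=treatment
                ).fit(doses, sub["log2fc"].to_numpy(float))
                curves[gene][treatment] = reg.curve_
            except FitError:
                curves[gene][treatment] = None
    return curves


def _load_responses(config: RunConfig, mix: MixtureDefinition) -> pd.DataFrame:
    if config.mode == "simulate":
        sim = SimulationConfig(
            mixture=mix,
            seed=config.seed,
            rel_concs=config.rel_concs,
            n_replicates=config.n_replicates,
            noise_sd=config.noise_sd,
            interaction=config.interaction,
            interaction_factor=config.interaction_factor,
        )
        truth = default_truth(mix)
        return pd.concat(
            [
                generate_component_responses(sim, truth),
                generate_mixture_response(sim, truth),
            ],
            ignore_index=True,
        )
    if config.mode == "ct":
        return fold_change_from_ct(read_ct_csv(config.input_path))
    return read_response_csv(config.input_path)


def run_pipeline(config: RunConfig, out_dir: Optional[Union[str, Path]] = None) -> dict:
    """Execute all stages; return (and optionally write) every artifact.

    The returned dict carries the manifest plus in-memory artifacts
    (response table, significance table, fitted curves, IA contexts and
    predictions, evaluation results).  With ``out_dir`` set, all tabular
    outputs are written as CSV, logs as JSON lines, and the manifest as
    JSON.
    """
    mix = _resolve_mixture(config)
    axes = [a for a in config.axes if a == "uM" or mix.has_tefs]

    responses = _load_responses(config, mix)
    n_raw = len(responses)

    responses, outlier_log = remove_outliers(
        responses,
        method=config.outlier_method,
        k=config.outlier_k,
        alpha=config.outlier_alpha,
    )
    significance = significance_table(responses)
    responses, treatment_log = filter_treatments(
        responses, significance, min_obs=config.min_obs
    )
    genes = select_genes_for_ia(
        significance,
        min_components=config.min_components,
        exclude_treatments=(mix.name,),
    )
    gene_log = [
        {
            "action": "excluded",
            "reason": f"fewer than {config.min_components} significant components",
            "gene": g,
        }
        for g in significance["gene"].drop_duplicates()
        if g not in genes
    ]

    curves = fit_response_curves(responses, mix, genes, families=config.families)
    sig_components = {
        gene: set(
            significance[
                (significance["gene"] == gene)
                & significance["significant"]
                & (significance["treatment"] != mix.name)
            ]["treatment"]
        )
        for gene in genes
    }

    rels = np.sort(responses.loc[responses["rel_conc"] > 0, "rel_conc"].unique())
    contexts, predictions, evaluations = {}, [], []
    for axis in axes:
        axis_scale = (
            mix.full_strength_total
            if axis == "uM"
            else mix.full_strength_total * mix.tef_weighted_sum
        )
        dose_range = (float(rels.min()) * axis_scale, float(rels.max()) * axis_scale)
        for gene in genes:
            comp_curves = {
                name: curve
                for name, curve in curves[gene].items()
                if name != mix.name
            }
            ctx = build_context(
                gene,
                comp_curves,
                sig_components[gene],
                mix,
                axis=axis,
                dose_range=dose_range,
            )
            contexts[(gene, axis)] = ctx
            grid = np.geomspace(
                max(dose_range[0], dose_range[1] * 1e-6), dose_range[1],
                config.grid_size,
            )
            predictions.append(
                ia_predict(ctx, grid, literal_form=config.literal_form).to_frame()
            )
            mix_curve = curves[gene].get(mix.name)
            if mix_curve is not None and axis == "bep":
                mix_curve = mix_curve.rescale_dose_axis(
                    mix.tef_weighted_sum, axis="bep"
                )
            observed = responses[
                (responses["gene"] == gene) & (responses["treatment"] == mix.name)
            ]
            if observed[observed["rel_conc"] > 0].empty:
                gene_log.append(
                    {
                        "action": "skipped-evaluation",
                        "reason": "no mixture observations",
                        "gene": gene,
                        "axis": axis,
                    }
                )
                continue
            evaluations.append(
                evaluate_gene(
                    mix_curve,
                    ctx,
                    observed,
                    grid_size=config.grid_size,
                    replicate_level=config.replicate_level_rmse,
                )
            )

    prediction_df = (
        pd.concat(predictions, ignore_index=True) if predictions else pd.DataFrame()
    )
    evaluation_df = pd.DataFrame([e.to_dict() for e in evaluations])
    fits_records = [
        c.to_dict()
        for gene in curves
        for c in curves[gene].values()
        if c is not None
    ]
    exclusions = (
        [{"stage": "outliers", **e} for e in outlier_log]
        + [{"stage": "treatments", **e} for e in treatment_log]
        + [{"stage": "genes", **e} for e in gene_log]
    )
    manifest = {
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "mixture": mix.name,
        "axes": axes,
        "counts": {
            "responses_raw": n_raw,
            "responses_filtered": len(responses),
            "significance_records": len(significance),
            "outliers_removed": sum(e["action"] == "removed" for e in outlier_log),
            "treatment_cells_removed": len(treatment_log),
            "genes_total": int(significance["gene"].nunique()),
            "genes_selected": len(genes),
            "curves_fit": len(fits_records),
            "evaluations": len(evaluations),
        },
        "genes_selected": genes,
        "evaluation": [e.to_dict() for e in evaluations],
    }
    result = {
        "manifest": manifest,
        "responses": responses,
        "significance": significance,
        "curves": curves,
        "contexts": contexts,
        "predictions": prediction_df,
        "evaluation": evaluation_df,
        "exclusions": exclusions,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_response_csv(responses, out / "responses.csv")
        sig_out = significance.copy()
        sig_out.insert(2, "rel_conc_percent", sig_out.pop("rel_conc") * 100.0)
        sig_out.to_csv(out / "significance.csv", index=False)
        if not prediction_df.empty:
            prediction_df.to_csv(out / "ia_predictions.csv", index=False)
        if not evaluation_df.empty:
            evaluation_df.to_csv(out / "evaluation.csv", index=False)
        pd.DataFrame(fits_records).to_csv(out / "fits.csv", index=False)
        with open(out / "fits.json", "w") as fh:
            json.dump(fits_records, fh, indent=2, sort_keys=True)
        with open(out / "ia_contexts.json", "w") as fh:
            json.dump(
                {f"{g}|{a}": c.to_dict() for (g, a), c in contexts.items()},
                fh, indent=2, sort_keys=True,
            )
        with open(out / "exclusions.jsonl", "w") as fh:
            for entry in exclusions:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        _write_report(out / "report.md", manifest, evaluation_df)
    return result


def _write_report(path: Path, manifest: dict, evaluation: pd.DataFrame) -> None:
    lines = [
        "# Mixture additivity report",
        "",
        f"Mixture: **{manifest['mixture']}** — "
        f"{manifest['counts']['genes_selected']} of "
        f"{manifest['counts']['genes_total']} genes entered IA modeling.",
        "",
    ]
    if not evaluation.empty:
        lines += [
            "| gene | axis | r | r category | RMSE | RMSE category |",
            "|---|---|---|---|---|---|",
        ]
        for _, row in evaluation.iterrows():
            r = "—" if row["pearson_r"] is None or pd.isna(row["pearson_r"]) else f"{row['pearson_r']:.3f}"
            lines.append(
                f"| {row['gene']} | {row['axis']} | {r} | {row['r_category']} "
                f"| {row['rmse']:.3f} | {row['rmse_category']} |"
            )
    path.write_text("\n".join(lines) + "\n")
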