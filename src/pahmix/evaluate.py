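"""Comparison of IA predictions with the observed mixture response.

Two descriptive metrics, each with the qualitative bands used when
reporting them:

* Pearson r between the fitted mixture curve and the IA prediction,
  both evaluated on a common log-spaced dose grid — "how similar are
  the curve shapes".  Bands on |r|: weak (< 0.3), moderate (0.3-0.5),
  strong (> 0.5).  Requires the mixture data to have a dose-response
  fit; otherwise r is not computable.
* RMSE between the per-dose observed mean response and the IA
  prediction at the tested doses — "how far off is the predicted
  magnitude".  Bands: small (< 1), moderate (1-2), large (> 2) log2
  units.

Boundary values fall in the higher category (closed lower bounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dose_response import FittedCurve, evaluate_curve
from .errors import ConfigurationError
from .ia import IAContext, ia_predict

__all__ = [
    "EvaluationResult",
    "pearson_between_curves",
    "rmse_observed_vs_model",
    "categorize",
    "evaluate_gene",
    "plot_gene",
]

#: |r| thresholds for weak/moderate/strong, RMSE thresholds for small/moderate/large.
R_BANDS = (0.3, 0.5)
RMSE_BANDS = (1.0, 2.0)
DEFAULT_GRID_SIZE = 100
_VAR_TOL = 1e-20


@dataclass(frozen=True)
class EvaluationResult:
    """Per-gene, per-axis model-performance summary."""

    gene: Optional[str]
    axis: str
    pearson_r: Optional[float]
    rmse: float
    r_category: str
    rmse_category: str
    reason: Optional[str] = None  # why r is absent, when it is

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "axis": self.axis,
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "r_category": self.r_category,
            "rmse_category": self.rmse_category,
            "reason": self.reason,
        }


def pearson_between_curves(
    mix_curve: Optional[FittedCurve],
    ctx: IAContext,
    grid_size: int = DEFAULT_GRID_SIZE,
    dose_range: Optional[tuple[float, float]] = None,
) -> tuple[Optional[float], Optional[str]]:
    """Pearson r between fitted mixture curve and IA prediction on a log grid.

    Returns ``(r, reason)`` where ``reason`` explains an absent value:
    no mixture fit, or zero variance of either curve over the grid (a
    flat mixture response carries no trend to correlate with).
    """
    if mix_curve is None or not mix_curve.converged:
        return None, "mixture data did not fit a dose-response curve"
    if grid_size < 2:
        raise ConfigurationError("grid_size must be >= 2")
    lo, hi = dose_range if dose_range is not None else ctx.dose_range
    if not hi > 0:
        raise ConfigurationError(f"invalid dose range {(lo, hi)!r}")
    lo = max(lo, hi * 1e-6)
    grid = np.geomspace(lo, hi, grid_size)
    y_mix = evaluate_curve(mix_curve, grid)
    y_ia = ia_predict(ctx, grid).predicted
    if np.var(y_mix) < _VAR_TOL or np.var(y_ia) < _VAR_TOL:
        return None, "zero variance over the dose grid"
    r = float(np.corrcoef(y_mix, y_ia)[0, 1])
    return r, None


def rmse_observed_vs_model(
    observed: pd.DataFrame,
    ctx: IAContext,
    mixture_doses: Optional[np.ndarray] = None,
    replicate_level: bool = False,
) -> float:
    """RMSE between observed mixture response and IA prediction.

    ``observed`` holds the mixture treatment's replicate rows with
    columns ``rel_conc`` and ``log2fc``; predictions are compared with
    per-dose observed means over the tested (non-vehicle) doses, or with
    every replicate when ``replicate_level=True``.  ``mixture_doses``
    maps each non-vehicle ``rel_conc`` onto the context's axis; by
    default the uM/BeP-equivalent dose is derived from the mixture
    definition.
    """
    obs = observed[observed["rel_conc"] > 0]
    if obs.empty:
        raise ConfigurationError("no non-vehicle mixture observations")
    rels = np.sort(obs["rel_conc"].unique())
    if mixture_doses is None:
        mix = ctx.mixture
        scale = (
            mix.full_strength_total
            if ctx.axis == "uM"
            else mix.full_strength_total * mix.tef_weighted_sum
        )
        mixture_doses = rels * scale
    mixture_doses = np.asarray(mixture_doses, dtype=float)
    if mixture_doses.size != rels.size:
        raise ConfigurationError(
            "need one mixture dose per tested concentration "
            f"({rels.size} concentrations, {mixture_doses.size} doses)"
        )
    pred = ia_predict(ctx, mixture_doses).predicted
    by_dose = dict(zip(rels, pred))
    if replicate_level:
        resid = obs["log2fc"].to_numpy(float) - obs["rel_conc"].map(by_dose).to_numpy(float)
    else:
        means = obs.groupby("rel_conc")["log2fc"].mean()
        resid = means.to_numpy(float) - np.array([by_dose[r] for r in means.index])
    return float(np.sqrt(np.mean(resid**2)))


def categorize(
    r: Optional[float], rmse: float
) -> tuple[str, str]:
    """Qualitative bands for (|r|, RMSE); boundaries go to the higher band."""
    if rmse < 0:
        raise ConfigurationError("rmse must be nonnegative")
    if r is None:
        r_cat = "not-computable"
    else:
        a = abs(r)
        r_cat = "weak" if a < R_BANDS[0] else ("moderate" if a < R_BANDS[1] else "strong")
    rmse_cat = (
        "small"
        if rmse < RMSE_BANDS[0]
        else ("moderate" if rmse < RMSE_BANDS[1] else "large")
    )
    return r_cat, rmse_cat


def evaluate_gene(
    mix_curve: Optional[FittedCurve],
    ctx: IAContext,
    observed: pd.DataFrame,
    grid_size: int = DEFAULT_GRID_SIZE,
    replicate_level: bool = False,
) -> EvaluationResult:
    """Full per-gene evaluation: r, RMSE, and their categories."""
    r, reason = pearson_between_curves(mix_curve, ctx, grid_size=grid_size)
    rmse = rmse_observed_vs_model(observed, ctx, replicate_level=replicate_level)
    r_cat, rmse_cat = categorize(r, rmse)
    return EvaluationResult(
        gene=ctx.gene,
        axis=ctx.axis,
        pearson_r=r,
        rmse=rmse,
        r_category=r_cat,
        rmse_category=rmse_cat,
        reason=reason,
    )


def plot_gene(
    mix_curve: Optional[FittedCurve],
    ctx: IAContext,
    observed: pd.DataFrame,
    ax=None,
    grid_size: int = DEFAULT_GRID_SIZE,
):
    """Observed mixture points, fitted mixture curve and IA prediction.

    Returns the matplotlib axes; the dose axis is logarithmic in the
    context's units (uM or BeP-equivalent uM).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    lo, hi = ctx.dose_range
    lo = max(lo, hi * 1e-6)
    grid = np.geomspace(lo, hi, grid_size)
    mix = ctx.mixture
    scale = (
        mix.full_strength_total
        if ctx.axis == "uM"
        else mix.full_strength_total * mix.tef_weighted_sum
    )
    obs = observed[observed["rel_conc"] > 0]
    ax.scatter(obs["rel_conc"] * scale, obs["log2fc"], s=12, c="black", label="observed")
    if mix_curve is not None and mix_curve.converged:
        ax.plot(grid, evaluate_curve(mix_curve, grid), "k-", label="mixture fit")
    ax.plot(grid, ia_predict(ctx, grid).predicted, "b-", label="IA prediction")
    ax.set_xscale("log")
    unit = "uM" if ctx.axis == "uM" else "BeP-eq uM"
    ax.set_xlabel(f"mixture dose ({unit})")
    ax.set_ylabel("log2 fold change")
    if ctx.gene:
        ax.set_title(str(ctx.gene))
    ax.legend(fontsize=8)
    return ax
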