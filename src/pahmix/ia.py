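"""Modified independent-action (IA) prediction of a mixture response.

Independent action (response addition) combines component effects that
arise through dissimilar mechanisms.  For a gene whose components are
partitioned by direction of effect (up- vs down-regulation), the
predicted mixture log2 fold change at mixture dose ``c`` is

    up_term(c)   = (1 - prod_i (1 - u_i(c))) * max_up
    down_term(c) = (1 - prod_j (1 - v_j(c))) * max_down
    prediction(c) = up_term(c) + down_term(c)

where ``u_i = clamp(E_i / max_up, 0, 1)`` is component i's fitted effect
normalized by the largest fitted up-effect across components over the
modeled dose range (``v_j`` analogously with the most negative
down-effect ``max_down <= 0``).  With a single component the prediction
reduces exactly to that component's curve, and each direction term is
bounded by its maximum.

A widely circulated typeset variant of this formula omits the inner
complement (``1 - prod u_i`` instead of ``1 - prod (1 - u_i)``); that
variant violates the single-component identity and is provided only for
comparison via ``literal_form=True``.

Two dose axes are supported:

* ``"uM"`` — the mixture coordinate is total mixture concentration in
  uM; component i is evaluated at its within-mixture dose
  ``proportion_i * c``.
* ``"bep"`` — the common coordinate is BeP-equivalent concentration;
  component i's curve is re-indexed by its TEF and evaluated at
  ``x / tef_i``.  Components with large TEFs then dominate the shape of
  the prediction, components with tiny TEFs sit on their plateaus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dose_response import (
    DoseResponseRegressor,
    FittedCurve,
    evaluate_curve,
)
from .errors import ConfigurationError, FitError
from .families import FAMILIES
from .mixtures import ComponentSpec, MixtureDefinition

__all__ = [
    "IAContext",
    "IAPrediction",
    "build_context",
    "ia_predict",
    "ia_predict_from_truth",
    "curve_from_truth",
    "IndependentActionModel",
]

_AXES = ("uM", "bep")
_MAX_GRID = 256  # dense grid used to locate per-direction maxima


@dataclass(frozen=True)
class IAPrediction:
    """IA prediction over a mixture-axis dose grid, with per-direction terms."""

    gene: Optional[str]
    axis: str
    grid: np.ndarray
    predicted: np.ndarray
    up_term: np.ndarray
    down_term: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene,
                "axis": self.axis,
                "dose": self.grid,
                "predicted_log2fc": self.predicted,
                "up_term": self.up_term,
                "down_term": self.down_term,
            }
        )


@dataclass(frozen=True)
class IAContext:
    """Per-gene component curve set partitioned by direction of effect.

    ``entries`` pairs every mixture component with its fitted curve or
    ``None`` (non-significant / flat / unfit components contribute zero
    effect, which is neutral under IA).  ``max_up``/``max_down`` are the
    per-direction extrema of the fitted component effects over the
    modeled mixture dose range ``dose_range`` (on ``axis``).
    """

    gene: Optional[str]
    axis: str
    mixture: MixtureDefinition
    entries: tuple[tuple[ComponentSpec, Optional[FittedCurve]], ...]
    up_set: tuple[str, ...]
    down_set: tuple[str, ...]
    max_up: float
    max_down: float
    dose_range: tuple[float, float]

    @property
    def n_up(self) -> int:
        return len(self.up_set)

    @property
    def n_down(self) -> int:
        return len(self.down_set)

    @property
    def is_empty(self) -> bool:
        return self.n_up == 0 and self.n_down == 0

    def component_effect(self, spec: ComponentSpec, curve: FittedCurve, doses) -> np.ndarray:
        """Fitted effect of one component at mixture-axis doses."""
        doses = np.asarray(doses, dtype=float)
        if self.axis == "uM":
            return evaluate_curve(curve, spec.proportion * doses)
        if spec.tef is None:
            raise ConfigurationError(
                f"component {spec.name!r} has no TEF; BeP-equivalent axis unavailable"
            )
        return evaluate_curve(curve, doses / spec.tef)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "axis": self.axis,
            "mixture": self.mixture.name,
            "up_set": list(self.up_set),
            "down_set": list(self.down_set),
            "max_up": self.max_up,
            "max_down": self.max_down,
            "dose_range": list(self.dose_range),
            "components": {
                spec.name: (curve.to_dict() if curve is not None else None)
                for spec, curve in self.entries
            },
        }


def _dense_grid(dose_range: tuple[float, float]) -> np.ndarray:
    lo, hi = dose_range
    if not (hi > 0 and hi >= lo >= 0):
        raise ConfigurationError(f"invalid dose range {dose_range!r}")
    lo = max(lo, hi * 1e-6)
    return np.geomspace(lo, hi, _MAX_GRID)


def build_context(
    gene: Optional[str],
    fitted_components: Mapping[str, Optional[FittedCurve]],
    significant: Optional[Iterable[str]],
    mix: MixtureDefinition,
    axis: str = "uM",
    dose_range: Optional[tuple[float, float]] = None,
) -> IAContext:
    """Partition component curves by direction and locate per-direction maxima.

    ``significant`` lists component names that passed the inclusion
    filters (``None`` means every component with a curve).  Components
    that are absent, non-significant, unconverged or flat are assigned
    null curves and contribute zero effect.  ``dose_range`` is the
    modeled mixture dose range on ``axis``; by default it spans the
    fitted mixture-equivalent of the component curves' dose range.
    """
    if axis not in _AXES:
        raise ConfigurationError(f"axis must be one of {_AXES}, got {axis!r}")
    sig = None if significant is None else set(significant)

    if dose_range is None:
        his = []
        for spec in mix.components:
            curve = fitted_components.get(spec.name)
            if curve is None or not curve.converged:
                continue
            scale = spec.proportion if axis == "uM" else (spec.tef or np.nan)
            if axis == "uM":
                his.append(curve.dose_max / scale)
            elif spec.tef is not None:
                his.append(curve.dose_max * spec.tef)
        if not his:
            raise ConfigurationError("cannot infer a dose range without any curves")
        hi = float(min(his))
        dose_range = (hi * 1e-3, hi)

    entries: list[tuple[ComponentSpec, Optional[FittedCurve]]] = []
    up, down = [], []
    effects: dict[str, np.ndarray] = {}
    grid = _dense_grid(dose_range)
    for spec in mix.components:
        curve = fitted_components.get(spec.name)
        include = (
            curve is not None
            and curve.converged
            and curve.direction != "flat"
            and (sig is None or spec.name in sig)
        )
        if not include:
            entries.append((spec, None))
            continue
        entries.append((spec, curve))
        if axis == "bep" and spec.tef is None:
            raise ConfigurationError(
                f"component {spec.name!r} has no TEF; BeP-equivalent axis unavailable"
            )
        eff = (
            evaluate_curve(curve, spec.proportion * grid)
            if axis == "uM"
            else evaluate_curve(curve, grid / spec.tef)
        )
        effects[spec.name] = eff
        (up if curve.direction == "up" else down).append(spec.name)

    max_up = max((float(np.max(effects[n])) for n in up), default=0.0)
    max_down = min((float(np.min(effects[n])) for n in down), default=0.0)
    max_up = max(max_up, 0.0)
    max_down = min(max_down, 0.0)
    return IAContext(
        gene=gene,
        axis=axis,
        mixture=mix,
        entries=tuple(entries),
        up_set=tuple(up),
        down_set=tuple(down),
        max_up=max_up,
        max_down=max_down,
        dose_range=tuple(dose_range),
    )


def _direction_term(
    effects: list[np.ndarray],
    extremum: float,
    n_doses: int,
    literal_form: bool,
    label: str,
) -> np.ndarray:
    """Combine one direction's normalized effects; extremum may be negative."""
    if not effects:
        return np.zeros(n_doses)
    if extremum == 0.0:
        warnings.warn(
            f"{label}-direction has members but a zero maximum; "
            "the direction contributes no effect",
            stacklevel=3,
        )
        return np.zeros(n_doses)
    U = np.clip(np.vstack(effects) / extremum, 0.0, 1.0)
    if literal_form:
        combined = 1.0 - np.prod(U, axis=0)
    else:
        combined = 1.0 - np.prod(1.0 - U, axis=0)
    return combined * extremum


def ia_predict(
    ctx: IAContext,
    mixture_doses,
    literal_form: bool = False,
) -> IAPrediction:
    """Predict the mixture response at the given mixture-axis doses."""
    doses = np.atleast_1d(np.asarray(mixture_doses, dtype=float))
    if np.any(doses < 0):
        raise ConfigurationError("mixture doses must be nonnegative")
    curves = {spec.name: (spec, curve) for spec, curve in ctx.entries}
    up_effects = [
        ctx.component_effect(*curves[name], doses) for name in ctx.up_set
    ]
    down_effects = [
        ctx.component_effect(*curves[name], doses) for name in ctx.down_set
    ]
    up_term = _direction_term(up_effects, ctx.max_up, doses.size, literal_form, "up")
    down_term = _direction_term(
        down_effects, ctx.max_down, doses.size, literal_form, "down"
    )
    return IAPrediction(
        gene=ctx.gene,
        axis=ctx.axis,
        grid=doses,
        predicted=up_term + down_term,
        up_term=up_term,
        down_term=down_term,
    )


def curve_from_truth(spec_like, *, dose_max: float, treatment=None, gene=None) -> FittedCurve:
    """Adapt a ground-truth curve description into a :class:`FittedCurve`.

    ``spec_like`` needs ``family``, ``params`` and (optionally)
    ``direction`` attributes; direction is recomputed from the curve when
    not given.  The generator and the analyzer share the IA kernel
    through this adapter, so the two cannot drift apart.
    """
    family = spec_like.family
    params = dict(spec_like.params)
    direction = getattr(spec_like, "direction", None)
    if direction is None:
        from .dose_response import _direction  # deterministic grid scan

        fam = FAMILIES[family]
        direction = _direction(
            fam, [params[name] for name in fam.param_names], float(dose_max)
        )
    return FittedCurve(
        family=family, params=params, rss=0.0,
        n_obs=0, aic=0.0, dose_min=0.0, dose_max=float(dose_max),
        direction=direction, gene=gene, treatment=treatment,
    )


def ia_predict_from_truth(
    truth: Mapping[str, Optional[object]],
    mix: MixtureDefinition,
    doses,
    axis: str = "uM",
    gene: Optional[str] = None,
    literal_form: bool = False,
) -> IAPrediction:
    """IA prediction computed directly from ground-truth component curves.

    ``truth`` maps component name -> TrueCurveSpec-like object (or
    ``None`` for a silent component).  Identical arithmetic to
    :func:`ia_predict`; used by the synthetic-data generator.
    """
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    hi = float(np.max(doses)) if doses.size else 1.0
    if hi <= 0:
        hi = 1.0
    fitted: dict[str, Optional[FittedCurve]] = {}
    for spec in mix.components:
        t = truth.get(spec.name)
        if t is None or getattr(t, "family", None) is None:
            fitted[spec.name] = None
            continue
        comp_hi = spec.proportion * hi if axis == "uM" else hi / spec.tef
        fitted[spec.name] = curve_from_truth(
            t, dose_max=comp_hi, treatment=spec.name, gene=gene
        )
    ctx = build_context(
        gene, fitted, None, mix, axis=axis, dose_range=(hi * 1e-3, hi)
    )
    return ia_predict(ctx, doses, literal_form=literal_form)


class IndependentActionModel(BaseEstimator):
    """Scikit-learn style IA predictor for one gene.

    ``fit`` consumes a long-format table of single-component exposures
    (columns ``treatment``, ``rel_conc``, ``log2fc``; ``rel_conc`` as a
    fraction of full mixture strength, 0 = vehicle), fits a
    dose-response curve per component, and assembles the IA context.
    ``predict`` evaluates the mixture prediction at mixture-axis doses.

    Parameters
    ----------
    mixture : MixtureDefinition
    axis : {"uM", "bep"}
    families : sequence of str, optional
        Candidate families for the per-component fits.
    literal_form : bool
        Use the complement-free product variant (comparison only).

    Attributes
    ----------
    curves_ : dict of component name -> FittedCurve
    context_ : IAContext
    """

    def __init__(self, mixture=None, axis="uM", families=None, literal_form=False):
        self.mixture = mixture
        self.axis = axis
        self.families = families
        self.literal_form = literal_form

    def fit(self, X, y=None, *, significant: Optional[Iterable[str]] = None):
        if self.mixture is None:
            raise ConfigurationError("IndependentActionModel requires a mixture")
        df = pd.DataFrame(X)
        required = {"treatment", "rel_conc", "log2fc"}
        if not required.issubset(df.columns):
            raise ConfigurationError(
                f"fit table must have columns {sorted(required)}"
            )
        mix = self.mixture
        gene = df["gene"].iloc[0] if "gene" in df.columns else None
        curves: dict[str, Optional[FittedCurve]] = {}
        for spec in mix.components:
            sub = df[df["treatment"] == spec.name]
            if sub.empty:
                curves[spec.name] = None
                continue
            doses = sub["rel_conc"].to_numpy(float) * mix.full_strength_total * spec.proportion
            try:
                reg = DoseResponseRegressor(
                    families=self.families, gene=gene, treatment=spec.name
                ).fit(doses, sub["log2fc"].to_numpy(float))
                curves[spec.name] = reg.curve_
            except FitError:
                curves[spec.name] = None
        rel = df.loc[df["rel_conc"] > 0, "rel_conc"]
        if rel.empty:
            raise ConfigurationError("no non-vehicle observations to model")
        lo_r, hi_r = float(rel.min()), float(rel.max())
        if self.axis == "uM":
            dose_range = (lo_r * mix.full_strength_total, hi_r * mix.full_strength_total)
        else:
            scale = mix.full_strength_total * mix.tef_weighted_sum
            dose_range = (lo_r * scale, hi_r * scale)
        self.curves_ = curves
        self.context_ = build_context(
            gene, curves, significant, mix, axis=self.axis, dose_range=dose_range
        )
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "context_"):
            raise FitError("estimator is not fitted; call fit first")
        doses = np.asarray(X, dtype=float)
        if doses.ndim == 2:
            doses = doses[:, 0]
        return ia_predict(
            self.context_, doses, literal_form=self.literal_form
        ).predicted
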