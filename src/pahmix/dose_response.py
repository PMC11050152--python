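"""Dose-response curve fitting, AIC model selection and EC50 extraction.

Each candidate family is fit by least squares with a deterministic
multi-start initialization (no RNG involved), scored with a Gaussian AIC

    AIC = n ln(RSS / n) + 2 k,

where ``k`` counts the curve parameters plus one for the residual
variance.  Model selection takes the smallest AIC, except that a
polynomial (linear/quadratic) winner is only accepted when its AIC beats
the best saturating family by more than 2 — polynomials are fallbacks,
not mechanistic dose-response models.

:class:`DoseResponseRegressor` wraps the same machinery as a
scikit-learn estimator (``fit(X, y)`` / ``predict(X)``) so curve fits
compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError
from .families import DEFAULT_FAMILIES, FAMILIES, POLYNOMIAL_FAMILIES, Family

__all__ = [
    "FittedCurve",
    "fit_family",
    "fit_all_families",
    "select_model",
    "ec50",
    "evaluate_curve",
    "DoseResponseRegressor",
    "FLAT_THRESHOLD",
]

#: Fitted responses smaller than this magnitude (log2 units) over the
#: observed dose range are treated as no effect ("flat").
FLAT_THRESHOLD = 0.1

#: ΔAIC margin a polynomial must beat the best saturating family by.
POLY_AIC_MARGIN = 2.0


@dataclass(frozen=True)
class FittedCurve:
    """One least-squares dose-response fit.

    ``params`` are the drc-style named parameters of the family; ``ec50``
    is the relative EC50 (midpoint of the modeled span) and is absent for
    polynomial or flat fits.  ``direction`` is ``"up"``/``"down"``/``"flat"``
    from the sign of the largest-magnitude fitted response over the
    observed dose range.
    """

    family: str
    params: dict[str, float]
    rss: float
    n_obs: int
    aic: float
    dose_min: float
    dose_max: float
    ec50: Optional[float] = None
    direction: str = "flat"
    converged: bool = True
    gene: Optional[str] = None
    treatment: Optional[str] = None
    axis: str = "uM"

    @property
    def is_polynomial(self) -> bool:
        return self.family in POLYNOMIAL_FAMILIES

    def __call__(self, doses) -> np.ndarray:
        return evaluate_curve(self, doses)

    def rescale_dose_axis(self, kappa: float, axis: Optional[str] = None) -> "FittedCurve":
        """Return the same curve indexed by ``dose * kappa``.

        Every family here depends on dose only through ``x / e`` or
        ``x - e`` style terms, so rescaling the axis rescales ``e`` (and,
        for Gompertz, divides ``b``) without refitting.
        """
        if not kappa > 0:
            raise ValueError(f"kappa must be > 0, got {kappa!r}")
        p = dict(self.params)
        if self.family in POLYNOMIAL_FAMILIES:
            if self.family == "linear":
                p["b"] /= kappa
            else:
                p["b"] /= kappa
                p["c2"] /= kappa**2
        elif self.family == "G.4":
            p["b"] /= kappa
            p["e"] *= kappa
        else:
            p["e"] *= kappa
        return replace(
            self,
            params=p,
            dose_min=self.dose_min * kappa,
            dose_max=self.dose_max * kappa,
            ec50=None if self.ec50 is None else self.ec50 * kappa,
            axis=axis if axis is not None else self.axis,
        )

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "treatment": self.treatment,
            "axis": self.axis,
            "family": self.family,
            "params": dict(self.params),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "aic": None if not np.isfinite(self.aic) else self.aic,
            "ec50": self.ec50,
            "direction": self.direction,
            "converged": self.converged,
        }


def _gaussian_aic(rss: float, n: int, k_curve: int) -> float:
    # +1 counts the residual variance so comparisons across families are
    # consistent; additive constants are dropped uniformly.
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * (k_curve + 1)


def _direction(fam: Family, params: Sequence[float], dose_max: float) -> str:
    grid = np.linspace(0.0, dose_max, 201)
    y = fam.evaluate(grid, params)
    y = y[np.isfinite(y)]
    if y.size == 0:
        return "flat"
    extreme = y[np.argmax(np.abs(y))]
    if abs(extreme) < FLAT_THRESHOLD:
        return "flat"
    return "up" if extreme > 0 else "down"


def _fit_polynomial(fam: Family, doses: np.ndarray, responses: np.ndarray):
    deg = 1 if fam.name == "linear" else 2
    coef = np.polyfit(doses, responses, deg)  # highest power first
    params = coef[::-1]  # (a, b[, c2])
    resid = responses - fam.evaluate(doses, params)
    return params, float(resid @ resid)


def fit_family(
    doses,
    responses,
    family: str,
    *,
    gene: Optional[str] = None,
    treatment: Optional[str] = None,
    axis: str = "uM",
) -> FittedCurve:
    """Least-squares fit of one family; never raises on non-convergence.

    A curve that fails to converge is returned with ``converged=False``
    and infinite AIC so that :func:`select_model` can skip (and log) it.
    Requires at least ``n_params + 1`` observations and nonnegative doses
    (dose 0 rows anchor the vehicle response).
    """
    fam = FAMILIES[family]
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be matching 1-d arrays")
    if np.any(doses < 0):
        raise ValueError("doses must be nonnegative")
    n = doses.size
    if n < fam.n_params + 1:
        raise FitError(
            f"{family}: need at least {fam.n_params + 1} observations, got {n}"
        )

    if fam.is_polynomial:
        params, rss = _fit_polynomial(fam, doses, responses)
        converged = bool(np.all(np.isfinite(params)))
    else:
        starts = [np.asarray(s, float) for s in fam.starts_fn(doses, responses)]
        if fam.nested_parent is not None:
            nested = fit_family(doses, responses, fam.nested_parent)
            if nested.converged:
                starts.append(_promote_params(fam, nested))
        lower = np.asarray(fam.lower, float)
        upper = np.asarray(fam.upper, float)

        def resid(p):
            r = responses - fam.evaluate(doses, p)
            return np.where(np.isfinite(r), r, 1e6)

        best_p, best_rss = None, np.inf
        for p0 in starts:
            p0 = np.clip(p0, lower, upper)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sol = least_squares(
                        resid, p0, bounds=(lower, upper), method="trf",
                        max_nfev=2000,
                    )
            except Exception:
                continue
            rss_i = float(sol.fun @ sol.fun)
            if np.all(np.isfinite(sol.x)) and rss_i < best_rss:
                best_p, best_rss = sol.x, rss_i
        params, rss = best_p, best_rss
        converged = best_p is not None and np.isfinite(best_rss)

    if not converged:
        return FittedCurve(
            family=family, params={}, rss=math.inf, n_obs=n, aic=math.inf,
            dose_min=float(doses.min()), dose_max=float(doses.max()),
            converged=False, gene=gene, treatment=treatment, axis=axis,
        )

    named = dict(zip(fam.param_names, (float(v) for v in params)))
    direction = _direction(fam, params, float(doses.max()))
    curve = FittedCurve(
        family=family,
        params=named,
        rss=float(rss),
        n_obs=n,
        aic=_gaussian_aic(float(rss), n, fam.n_params),
        dose_min=float(doses.min()),
        dose_max=float(doses.max()),
        direction=direction,
        gene=gene,
        treatment=treatment,
        axis=axis,
    )
    return replace(curve, ec50=ec50(curve))


def _promote_params(fam: Family, nested: FittedCurve) -> np.ndarray:
    """Embed a nested family's solution as a start for the richer family."""
    p = nested.params
    if fam.name == "LL.3":  # from LL.2 (d fixed at 1)
        return np.array([p["b"], 1.0, p["e"]])
    if fam.name == "LL.4":  # from LL.3 (c fixed at 0)
        return np.array([p["b"], 0.0, p["d"], p["e"]])
    raise ValueError(f"no promotion rule for {fam.name}")


def fit_all_families(
    doses,
    responses,
    families: Optional[Iterable[str]] = None,
    **meta,
) -> list[FittedCurve]:
    """Fit every candidate family, skipping those with too few observations."""
    out = []
    for name in families or DEFAULT_FAMILIES:
        try:
            out.append(fit_family(doses, responses, name, **meta))
        except FitError:
            continue
    if not out:
        raise FitError("no family had enough observations to fit")
    return out


def select_model(candidates: Sequence[FittedCurve]) -> FittedCurve:
    """Smallest-AIC candidate, with the polynomial ΔAIC > 2 rule.

    A polynomial winner is returned only when its AIC is smaller than the
    best saturating (non-polynomial) candidate's by more than 2;
    otherwise the best saturating candidate wins.
    """
    usable = [c for c in candidates if c.converged and np.isfinite(c.aic)]
    if not usable:
        raise FitError("no converged candidate curves to select from")
    best = min(usable, key=lambda c: c.aic)
    if not best.is_polynomial:
        return best
    non_poly = [c for c in usable if not c.is_polynomial]
    if not non_poly:
        return best
    best_np = min(non_poly, key=lambda c: c.aic)
    if best.aic < best_np.aic - POLY_AIC_MARGIN:
        return best
    return best_np


def ec50(curve: FittedCurve) -> Optional[float]:
    """Relative EC50: the dose where the fit crosses ``c + (d - c)/2``.

    Closed form for every family that admits one, with a bracketed
    root-finding fallback; ``None`` (never an exception) for polynomial
    or flat curves.
    """
    if curve.family in POLYNOMIAL_FAMILIES or curve.direction == "flat":
        return None
    fam = FAMILIES[curve.family]
    p = [curve.params[name] for name in fam.param_names]
    value = fam.ec50(p)
    if value is not None and np.isfinite(value) and value > 0:
        return float(value)
    # Fallback: bracketed root of f(x) - midpoint on the observed range.
    named = curve.params
    c = named.get("c", 0.0)
    d = named.get("d", named.get("c", 0.0))
    target = c + 0.5 * (d - c)
    lo = max(curve.dose_min, 1e-12)
    hi = max(curve.dose_max, lo * 10)
    f = lambda x: float(fam.evaluate(np.array([x]), p)[0] - target)
    try:
        if f(lo) * f(hi) > 0:
            return None
        root = brentq(f, lo, hi, xtol=1e-15, rtol=1e-9)
    except ValueError:
        return None
    return float(root) if root > 0 else None


def evaluate_curve(curve: FittedCurve, doses) -> np.ndarray:
    """Fitted mean response at each dose (dose 0 via the family's limit)."""
    fam = FAMILIES[curve.family]
    p = [curve.params[name] for name in fam.param_names]
    return fam.evaluate(np.asarray(doses, dtype=float), p)


class DoseResponseRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style dose-response fit with AIC family selection.

    Parameters
    ----------
    families : sequence of str, optional
        Candidate family names (default: all ten families).
    gene, treatment, axis :
        Metadata attached to the fitted curve.

    Attributes
    ----------
    curve_ : FittedCurve
        The selected model.
    candidates_ : list of FittedCurve
        All converged and non-converged candidate fits.
    family_ : str
    params_ : dict
    aic_ : float
    ec50_ : float or None
    direction_ : str
    """

    def __init__(self, families=None, gene=None, treatment=None, axis="uM"):
        self.families = families
        self.gene = gene
        self.treatment = treatment
        self.axis = axis

    @staticmethod
    def _as_doses(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single dose column")
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be 1-d doses or a (n, 1) column")
        return X

    def fit(self, X, y):
        doses = self._as_doses(X)
        y = np.asarray(y, dtype=float)
        if y.shape != doses.shape:
            raise ValueError("X and y lengths differ")
        if doses.size == 0:
            raise ValueError("empty input")
        self.candidates_ = fit_all_families(
            doses, y, self.families,
            gene=self.gene, treatment=self.treatment, axis=self.axis,
        )
        self.curve_ = select_model(self.candidates_)
        self.family_ = self.curve_.family
        self.params_ = dict(self.curve_.params)
        self.aic_ = self.curve_.aic
        self.ec50_ = self.curve_.ec50
        self.direction_ = self.curve_.direction
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "curve_"):
            raise FitError("estimator is not fitted; call fit first")
        return evaluate_curve(self.curve_, self._as_doses(X))
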