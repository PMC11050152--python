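"""Dose-response model families.

Families follow the drc (R) parameterization with named parameters
``b`` (slope), ``c`` (lower asymptote), ``d`` (upper asymptote) and
``e`` (inflection / half-saturation dose):

======================  =====================================================
LL.2                    ``1 / (1 + exp(b (ln x - ln e)))``  (c = 0, d = 1)
LL.3                    ``d / (1 + exp(b (ln x - ln e)))``  (c = 0)
LL.4                    ``c + (d - c) / (1 + exp(b (ln x - ln e)))``
W1.4 (Weibull type 1)   ``c + (d - c) exp(-exp(b (ln x - ln e)))``
W2.4 (Weibull type 2)   ``c + (d - c) (1 - exp(-exp(b (ln x - ln e))))``
MM.3 (Michaelis-Menten) ``c + (d - c) x / (e + x)``
AR.3 (asymptotic regr.) ``c + (d - c) (1 - exp(-x / e))``
G.4  (Gompertz)         ``c + (d - c) exp(-exp(b (x - e)))``
linear                  ``a + b x``
quadratic               ``a + b x + c2 x**2``
======================  =====================================================

The vehicle dose x = 0 is evaluated through each family's well-defined
x -> 0 limit; no pseudo-dose offset is used.  Relative EC50s (the dose at
the midpoint of the modeled span, ``c + (d - c)/2``) have closed forms for
every non-polynomial family here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Family", "FAMILIES", "DEFAULT_FAMILIES", "POLYNOMIAL_FAMILIES"]

_LN2 = math.log(2.0)
_CLIP = 700.0  # exp overflow guard


def _log_term(x: np.ndarray, b: float, e: float) -> np.ndarray:
    """``exp(b (ln x - ln e))`` with the x = 0 limit (0 for b > 0, inf for b < 0)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x > 0
    with np.errstate(over="ignore", divide="ignore"):
        out[pos] = np.exp(np.clip(b * (np.log(x[pos]) - math.log(e)), -_CLIP, _CLIP))
    out[~pos] = 0.0 if b >= 0 else np.inf
    return out


def _f_ll2(x, p):
    b, e = p
    t = _log_term(x, b, e)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + t)


def _f_ll3(x, p):
    b, d, e = p
    t = _log_term(x, b, e)
    with np.errstate(over="ignore"):
        return d / (1.0 + t)


def _f_ll4(x, p):
    b, c, d, e = p
    t = _log_term(x, b, e)
    with np.errstate(over="ignore"):
        return c + (d - c) / (1.0 + t)


def _f_w14(x, p):
    b, c, d, e = p
    t = _log_term(x, b, e)
    with np.errstate(over="ignore", under="ignore"):
        return c + (d - c) * np.exp(-t)


def _f_w24(x, p):
    b, c, d, e = p
    t = _log_term(x, b, e)
    with np.errstate(over="ignore", under="ignore"):
        return c + (d - c) * (1.0 - np.exp(-t))


def _f_mm3(x, p):
    c, d, e = p
    x = np.asarray(x, dtype=float)
    return c + (d - c) * x / (e + x)


def _f_ar3(x, p):
    c, d, e = p
    x = np.asarray(x, dtype=float)
    return c + (d - c) * (1.0 - np.exp(-x / e))


def _f_g4(x, p):
    b, c, d, e = p
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        inner = np.exp(np.clip(b * (x - e), -_CLIP, _CLIP))
        return c + (d - c) * np.exp(-inner)


def _f_linear(x, p):
    a, b = p
    return a + b * np.asarray(x, dtype=float)


def _f_quadratic(x, p):
    a, b, c2 = p
    x = np.asarray(x, dtype=float)
    return a + b * x + c2 * x * x


# -- relative EC50 closed forms ------------------------------------------


def _ec50_e(p_named: dict) -> Optional[float]:
    return p_named["e"]


def _ec50_weibull(p_named: dict) -> Optional[float]:
    # exp(-T) = 1/2  (W1) or 1 - exp(-T) = 1/2 (W2)  =>  T = ln 2
    b, e = p_named["b"], p_named["e"]
    if b == 0 or e <= 0:
        return None
    log_ec = math.log(e) + math.log(_LN2) / b
    if abs(log_ec) > _CLIP:
        return None
    ec = math.exp(log_ec)
    return ec if np.isfinite(ec) and ec > 0 else None


def _ec50_ar(p_named: dict) -> Optional[float]:
    return p_named["e"] * _LN2


def _ec50_gompertz(p_named: dict) -> Optional[float]:
    b, e = p_named["b"], p_named["e"]
    if b == 0:
        return None
    ec = e + math.log(_LN2) / b
    return ec if ec > 0 else None


# -- starting values ------------------------------------------------------


def _anchors(doses: np.ndarray, responses: np.ndarray):
    """Mean response at the lowest and highest dose, and a midpoint dose guess."""
    doses = np.asarray(doses, float)
    responses = np.asarray(responses, float)
    lo, hi = doses.min(), doses.max()
    y0 = float(responses[doses == lo].mean())
    y1 = float(responses[doses == hi].mean())
    pos = np.unique(doses[doses > 0])
    if pos.size == 0:
        return y0, y1, 1.0, pos
    mid = 0.5 * (y0 + y1)
    means = np.array([responses[doses == d].mean() for d in pos])
    e0 = float(pos[np.argmin(np.abs(means - mid))])
    if e0 <= 0:
        e0 = float(np.exp(np.mean(np.log(pos))))
    return y0, y1, e0, pos


#: Fixed multi-start grid on the slope parameter; orientation (which of
#: c/d is the low-dose asymptote) flips with the sign of b, so both signs
#: are covered for the asymmetric families.
_B_STARTS = (-3.0, -1.5, -0.75, -0.3, 0.75)


def _starts_loglogistic(n_extra: int):
    """Starts for LL.2/LL.3/LL.4 (b < 0 orients low dose at c, high at d)."""

    def gen(doses, responses):
        y0, y1, e0, pos = _anchors(doses, responses)
        out = []
        for b in _B_STARTS:
            c0, d0 = (y0, y1) if b < 0 else (y1, y0)
            if n_extra == 0:  # LL.2: (b, e)
                out.append([b, e0])
            elif n_extra == 1:  # LL.3: (b, d, e)
                out.append([b, d0 if b < 0 else c0, e0])
            else:  # LL.4: (b, c, d, e)
                out.append([b, c0, d0, e0])
        return out

    return gen


def _starts_weibull(doses, responses):
    y0, y1, e0, pos = _anchors(doses, responses)
    out = []
    for b in _B_STARTS:
        c0, d0 = (y0, y1) if b < 0 else (y1, y0)
        out.append([b, c0, d0, e0])
    return out


def _starts_saturating(doses, responses):
    """Starts for MM.3/AR.3: vary e over the positive dose range."""
    y0, y1, e0, pos = _anchors(doses, responses)
    es = [e0]
    if pos.size:
        es += [float(pos.min()), float(np.exp(np.mean(np.log(pos)))), float(pos.max())]
    return [[y0, y1, e] for e in dict.fromkeys(es)]


def _starts_gompertz(doses, responses):
    y0, y1, e0, pos = _anchors(doses, responses)
    scale = float(np.max(doses)) or 1.0
    out = []
    for b in _B_STARTS:
        c0, d0 = (y0, y1) if b < 0 else (y1, y0)
        out.append([b / scale * 3.0, c0, d0, e0])
    return out


@dataclass(frozen=True)
class Family:
    """One dose-response family: evaluation, starts, bounds and EC50."""

    name: str
    param_names: tuple[str, ...]
    fn: Callable[[np.ndarray, Sequence[float]], np.ndarray]
    is_polynomial: bool = False
    ec50_fn: Optional[Callable[[dict], Optional[float]]] = None
    starts_fn: Optional[Callable] = None
    lower: Optional[tuple[float, ...]] = None
    upper: Optional[tuple[float, ...]] = None
    nested_parent: Optional[str] = None  # simpler family whose fit seeds this one

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def evaluate(self, x, params: Sequence[float]) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self.fn(x, np.asarray(params, dtype=float))

    def ec50(self, params: Sequence[float]) -> Optional[float]:
        if self.ec50_fn is None:
            return None
        named = dict(zip(self.param_names, params))
        return self.ec50_fn(named)


_E_LO, _E_HI = 1e-12, 1e12
_B_LO, _B_HI = -50.0, 50.0
_INF = np.inf

FAMILIES: dict[str, Family] = {
    f.name: f
    for f in [
        Family(
            "LL.2", ("b", "e"), _f_ll2,
            ec50_fn=_ec50_e, starts_fn=_starts_loglogistic(0),
            lower=(_B_LO, _E_LO), upper=(_B_HI, _E_HI),
        ),
        Family(
            "LL.3", ("b", "d", "e"), _f_ll3,
            ec50_fn=_ec50_e, starts_fn=_starts_loglogistic(1),
            lower=(_B_LO, -_INF, _E_LO), upper=(_B_HI, _INF, _E_HI),
            nested_parent="LL.2",
        ),
        Family(
            "LL.4", ("b", "c", "d", "e"), _f_ll4,
            ec50_fn=_ec50_e, starts_fn=_starts_loglogistic(2),
            lower=(_B_LO, -_INF, -_INF, _E_LO), upper=(_B_HI, _INF, _INF, _E_HI),
            nested_parent="LL.3",
        ),
        Family(
            "W1.4", ("b", "c", "d", "e"), _f_w14,
            ec50_fn=_ec50_weibull, starts_fn=_starts_weibull,
            lower=(_B_LO, -_INF, -_INF, _E_LO), upper=(_B_HI, _INF, _INF, _E_HI),
        ),
        Family(
            "W2.4", ("b", "c", "d", "e"), _f_w24,
            ec50_fn=_ec50_weibull, starts_fn=_starts_weibull,
            lower=(_B_LO, -_INF, -_INF, _E_LO), upper=(_B_HI, _INF, _INF, _E_HI),
        ),
        Family(
            "MM.3", ("c", "d", "e"), _f_mm3,
            ec50_fn=_ec50_e, starts_fn=_starts_saturating,
            lower=(-_INF, -_INF, _E_LO), upper=(_INF, _INF, _E_HI),
        ),
        Family(
            "AR.3", ("c", "d", "e"), _f_ar3,
            ec50_fn=_ec50_ar, starts_fn=_starts_saturating,
            lower=(-_INF, -_INF, _E_LO), upper=(_INF, _INF, _E_HI),
        ),
        Family(
            "G.4", ("b", "c", "d", "e"), _f_g4,
            ec50_fn=_ec50_gompertz, starts_fn=_starts_gompertz,
            lower=(-_INF, -_INF, -_INF, -_INF), upper=(_INF, _INF, _INF, _INF),
        ),
        Family("linear", ("a", "b"), _f_linear, is_polynomial=True),
        Family("quadratic", ("a", "b", "c2"), _f_quadratic, is_polynomial=True),
    ]
}

#: Families entered into AIC selection by default (all of them).
DEFAULT_FAMILIES: tuple[str, ...] = tuple(FAMILIES)

POLYNOMIAL_FAMILIES: frozenset[str] = frozenset(
    name for name, fam in FAMILIES.items() if fam.is_polynomial
)
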