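"""Mixture composition and concentration-axis arithmetic.

A mixture is a set of named components, each occupying a fixed fraction of
the total concentration and optionally carrying a toxic equivalency factor
(TEF) relative to a reference chemical (benzo[e]pyrene for the bundled PAH
mixture).  All dose arithmetic is linear:

* a *relative concentration* ``r`` (fraction of full strength, e.g. 0.10
  for a "10%" exposure) maps to a per-component dose
  ``r * full_strength_total * proportion`` in uM;
* a component dose maps onto the BeP-equivalent axis by multiplying with
  its TEF, and the whole mixture's BeP-equivalent concentration at ``r``
  is ``r * full_strength_total * sum(proportion_i * tef_i)``.

Two fixtures ship with the package: :func:`toxmix` (seven PAHs with TEFs)
and :func:`abundmix` (six PAHs, no TEFs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .errors import ConfigurationError, UnknownComponentError

__all__ = [
    "ComponentSpec",
    "MixtureDefinition",
    "component_dose",
    "bep_equivalent",
    "component_axis_transform",
    "load_mixture",
    "save_mixture",
    "toxmix",
    "abundmix",
]

#: Tolerance on the proportion sum: printed mixture tables round component
#: percentages, so columns sum to ~100% within half a percentage point.
PROPORTION_SUM_TOL = 0.005


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component.

    Parameters
    ----------
    name : str
        Component identifier, unique within a mixture.
    proportion : float
        Fraction of the total mixture concentration in (0, 1].
    tef : float, optional
        Toxic equivalency factor (> 0) relative to the reference chemical;
        ``None`` when no TEF is assigned.
    raw_percent : float, optional
        The percentage as printed in the source table, preserved verbatim
        when proportions are renormalized at load time.
    """

    name: str
    proportion: float
    tef: Optional[float] = None
    raw_percent: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("component name must be non-empty")
        if not (0.0 < self.proportion <= 1.0):
            raise ConfigurationError(
                f"component {self.name!r}: proportion must be in (0, 1], "
                f"got {self.proportion!r}"
            )
        if self.tef is not None and not self.tef > 0:
            raise ConfigurationError(
                f"component {self.name!r}: tef must be > 0, got {self.tef!r}"
            )


@dataclass(frozen=True)
class MixtureDefinition:
    """A named mixture: ordered components plus the full-strength total.

    ``full_strength_total`` is the concentration in uM of the 100% mixture.
    Every downstream correlation/RMSE result is invariant to this scale
    factor; it only sets the units of the dose axis.
    """

    name: str
    components: tuple[ComponentSpec, ...]
    full_strength_total: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise ConfigurationError(f"mixture {self.name!r} has no components")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ConfigurationError(
                f"mixture {self.name!r}: component names must be unique"
            )
        total = sum(c.proportion for c in self.components)
        if abs(total - 1.0) > PROPORTION_SUM_TOL:
            raise ConfigurationError(
                f"mixture {self.name!r}: proportions sum to {total:.6f}, "
                f"expected 1 within {PROPORTION_SUM_TOL}"
            )
        if not self.full_strength_total > 0:
            raise ConfigurationError(
                f"mixture {self.name!r}: full_strength_total must be > 0"
            )

    # -- lookups ---------------------------------------------------------

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def component(self, name: str) -> ComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise UnknownComponentError(
            f"mixture {self.name!r} has no component {name!r}; "
            f"known: {', '.join(self.component_names)}"
        )

    @property
    def has_tefs(self) -> bool:
        return all(c.tef is not None for c in self.components)

    @property
    def tef_weighted_sum(self) -> float:
        """``sum(proportion_i * tef_i)`` — the uM -> BeP-equivalent scale factor."""
        self._require_tefs()
        return sum(c.proportion * c.tef for c in self.components)

    def _require_tefs(self) -> None:
        missing = [c.name for c in self.components if c.tef is None]
        if missing:
            raise ConfigurationError(
                f"mixture {self.name!r}: no TEF assigned for "
                f"{', '.join(missing)}; the BeP-equivalent axis is unavailable"
            )


# -- dose arithmetic -----------------------------------------------------


def component_dose(mix: MixtureDefinition, rel_conc: float, component: str) -> float:
    """uM dose of one component when the mixture is applied at ``rel_conc``.

    ``rel_conc`` is a fraction of full strength (0.10 for a 10% exposure).
    Single-component exposures at "r%" are taken at the component's
    concentration within the r% mixture, which keeps component and mixture
    doses commensurable.
    """
    if rel_conc < 0:
        raise ConfigurationError(f"rel_conc must be >= 0, got {rel_conc!r}")
    spec = mix.component(component)
    return rel_conc * mix.full_strength_total * spec.proportion


def bep_equivalent(mix: MixtureDefinition, rel_conc: float) -> float:
    """BeP-equivalent concentration of the whole mixture at ``rel_conc``.

    Each component's uM dose is scaled by its TEF and the contributions
    summed: ``rel_conc * total * sum(p_i * tef_i)``.
    """
    if rel_conc < 0:
        raise ConfigurationError(f"rel_conc must be >= 0, got {rel_conc!r}")
    return rel_conc * mix.full_strength_total * mix.tef_weighted_sum


def component_axis_transform(dose_um: float, tef: float) -> float:
    """Map a component uM dose onto the BeP-equivalent axis (``dose * tef``)."""
    if not tef > 0:
        raise ConfigurationError(f"tef must be > 0, got {tef!r}")
    return dose_um * tef


# -- I/O -----------------------------------------------------------------


def _components_from_records(records: Iterable[dict]) -> tuple[ComponentSpec, ...]:
    raw = []
    for rec in records:
        name = rec.get("component") or rec.get("name")
        if name is None:
            raise ConfigurationError(f"component record missing a name: {rec!r}")
        pct = rec.get("proportion_percent")
        if pct is None:
            raise ConfigurationError(
                f"component {name!r} missing 'proportion_percent'"
            )
        tef = rec.get("tef")
        if tef is not None and pd.isna(tef):
            tef = None
        raw.append((str(name), float(pct), None if tef is None else float(tef)))
    total = sum(pct for _, pct, _ in raw)
    if not 95.0 <= total <= 105.0:
        raise ConfigurationError(
            f"proportion_percent column sums to {total:.4f}, expected ~100"
        )
    # Printed percentages carry rounding; renormalize so proportions sum to
    # exactly 1 while preserving the printed value for reporting.
    return tuple(
        ComponentSpec(name=n, proportion=pct / total, tef=t, raw_percent=pct)
        for n, pct, t in raw
    )


def load_mixture(
    source: Union[str, Path],
    full_strength_total: Optional[float] = None,
) -> MixtureDefinition:
    """Load a mixture definition from YAML or CSV.

    YAML schema: ``{name, full_strength_total, components: [{component,
    proportion_percent, tef}]}``.  CSV schema: columns ``component,
    proportion_percent[, tef]`` (mixture name taken from the file stem).
    ``full_strength_total`` overrides the file's value when given.
    """
    path = Path(source)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        comps = _components_from_records(doc["components"])
        total = full_strength_total or float(doc.get("full_strength_total", 100.0))
        return MixtureDefinition(
            name=str(doc.get("name", path.stem)),
            components=comps,
            full_strength_total=total,
        )
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        comps = _components_from_records(df.to_dict("records"))
        return MixtureDefinition(
            name=path.stem,
            components=comps,
            full_strength_total=full_strength_total or 100.0,
        )
    raise ConfigurationError(f"unsupported mixture file format: {path.name}")


def save_mixture(mix: MixtureDefinition, path: Union[str, Path]) -> None:
    """Write a mixture definition as YAML (or CSV if the suffix is .csv)."""
    path = Path(path)
    records = [
        {
            "component": c.name,
            "proportion_percent": (
                c.raw_percent if c.raw_percent is not None else 100.0 * c.proportion
            ),
            **({"tef": c.tef} if c.tef is not None else {}),
        }
        for c in mix.components
    ]
    if path.suffix.lower() == ".csv":
        pd.DataFrame(records).to_csv(path, index=False)
        return
    doc = {
        "name": mix.name,
        "full_strength_total": mix.full_strength_total,
        "components": records,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _load_builtin(name: str, full_strength_total: Optional[float]) -> MixtureDefinition:
    ref = resources.files("pahmix.data").joinpath(f"{name}.yaml")
    with resources.as_file(ref) as path:
        return load_mixture(path, full_strength_total=full_strength_total)


def toxmix(full_strength_total: Optional[float] = None) -> MixtureDefinition:
    """The bundled seven-component toxicity-based PAH mixture (with TEFs)."""
    return _load_builtin("toxmix", full_strength_total)


def abundmix(full_strength_total: Optional[float] = None) -> MixtureDefinition:
    """The bundled six-component abundance-based PAH mixture (no TEFs)."""
    return _load_builtin("abundmix", full_strength_total)
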