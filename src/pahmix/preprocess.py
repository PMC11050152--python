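"""qPCR preprocessing and the statistics feeding the additivity filters.

Covers the comparative ΔΔCt fold-change computation, optional outlier
removal, one-way many-to-one testing against the vehicle control
(Dunnett), and the two inclusion filters applied before independent-
action modeling:

* a treatment cell (gene x treatment x concentration) needs at least
  ``min_obs`` valid replicate observations, and
* a gene needs at least ``min_components`` components with a significant
  (adjusted p < 0.05) response at any concentration (the mixture itself
  is not required to respond).

Long-format tables use columns ``gene, treatment, rel_conc, replicate,
log2fc`` with ``rel_conc`` as a fraction of full mixture strength and
``rel_conc == 0`` marking vehicle-control wells.  CSV files at the I/O
boundary carry ``rel_conc_percent`` instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, MissingControlError

__all__ = [
    "SignificanceRecord",
    "ALPHA",
    "fold_change_from_ct",
    "remove_outliers",
    "dunnett_vs_control",
    "significance_table",
    "filter_treatments",
    "select_genes_for_ia",
    "read_response_csv",
    "write_response_csv",
    "read_ct_csv",
    "write_ct_csv",
]

#: Adjusted-p significance cutoff used throughout.
ALPHA = 0.05

_CELL = ["gene", "treatment", "rel_conc"]
RESPONSE_COLUMNS = ["gene", "treatment", "rel_conc", "replicate", "log2fc"]
CT_COLUMNS = ["gene", "treatment", "rel_conc", "replicate", "ct_target", "ct_reference"]


@dataclass(frozen=True)
class SignificanceRecord:
    """Dunnett-adjusted contrast of one dose group against vehicle."""

    gene: str
    treatment: str
    rel_conc: float
    p_adj: float
    significant: bool

    def __post_init__(self):
        if not 0.0 <= self.p_adj <= 1.0:
            raise ConfigurationError(f"p_adj out of [0, 1]: {self.p_adj!r}")


def _records_frame(records: Iterable[SignificanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "treatment": r.treatment,
                "rel_conc": r.rel_conc,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in records
        ],
        columns=["gene", "treatment", "rel_conc", "p_adj", "significant"],
    )


# -- ΔΔCt ----------------------------------------------------------------


def fold_change_from_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Comparative ΔΔCt: Ct tables -> vehicle-normalized log2 fold changes.

    Per well ``ΔCt = ct_target - ct_reference``; per gene x treatment the
    vehicle wells (rel_conc == 0) define the baseline, and
    ``log2fc = -(ΔCt - mean vehicle ΔCt)`` so that fold change equals
    ``2**(-ΔΔCt)``.  Any constant added to both Ct columns of a well, or
    to the reference gene across all wells, cancels exactly.
    """
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ConfigurationError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(ct[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ConfigurationError("Ct values must be finite")
    out = ct.copy()
    out["_dct"] = out["ct_target"] - out["ct_reference"]
    rows = []
    for (gene, treatment), grp in out.groupby(["gene", "treatment"], sort=False):
        vehicle = grp.loc[grp["rel_conc"] == 0, "_dct"]
        if vehicle.empty:
            raise MissingControlError(
                f"no vehicle-control wells for gene {gene!r}, treatment {treatment!r}"
            )
        base = vehicle.mean()
        g = grp.copy()
        g["log2fc"] = -(g["_dct"] - base)
        rows.append(g)
    result = pd.concat(rows, ignore_index=True)
    return result[RESPONSE_COLUMNS]


# -- outlier removal ------------------------------------------------------


def _iqr_flags(values: np.ndarray, k: float) -> np.ndarray:
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def _grubbs_flags(values: np.ndarray, alpha: float) -> np.ndarray:
    """Iterative two-sided Grubbs test; flags one extreme value per pass."""
    flags = np.zeros(values.size, dtype=bool)
    active = list(range(values.size))
    while len(active) >= 3:
        sub = values[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        g = np.abs(sub - sub.mean()) / sd
        idx = int(np.argmax(g))
        n = len(active)
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        if g[idx] > g_crit:
            flags[active[idx]] = True
            del active[idx]
        else:
            break
    return flags


def remove_outliers(
    table: pd.DataFrame,
    method: str = "none",
    k: float = 1.5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[dict]]:
    """Flag and drop outlying replicates within each gene x treatment x dose cell.

    ``method`` is ``"none"`` (default), ``"iqr"`` (Tukey fences at
    ``k`` x IQR) or ``"grubbs"`` (iterative Grubbs at level ``alpha``).
    Cells with fewer than 3 observations are left untouched and logged.
    Returns the filtered table and a removal log (one dict per dropped or
    skipped record).
    """
    if method not in {"none", "iqr", "grubbs"}:
        raise ConfigurationError(f"unknown outlier method {method!r}")
    log: list[dict] = []
    if method == "none":
        return table.copy(), log
    table = table.reset_index(drop=True)
    keep = np.ones(len(table), dtype=bool)
    for key, grp in table.groupby(_CELL, sort=False):
        if len(grp) < 3:
            log.append(
                {
                    "action": "skipped",
                    "reason": f"cell size {len(grp)} < 3",
                    "gene": key[0],
                    "treatment": key[1],
                    "rel_conc": key[2],
                }
            )
            continue
        values = grp["log2fc"].to_numpy(float)
        flags = (
            _iqr_flags(values, k) if method == "iqr" else _grubbs_flags(values, alpha)
        )
        for pos, flagged in zip(grp.index, flags):
            if flagged:
                keep[pos] = False
                log.append(
                    {
                        "action": "removed",
                        "reason": f"{method} outlier",
                        "gene": key[0],
                        "treatment": key[1],
                        "rel_conc": key[2],
                        "replicate": int(table.loc[pos, "replicate"]),
                        "log2fc": float(table.loc[pos, "log2fc"]),
                    }
                )
    return table.loc[keep].reset_index(drop=True), log


# -- Dunnett many-to-one testing -----------------------------------------


def dunnett_vs_control(
    table: pd.DataFrame,
    gene: str,
    treatment: str,
    alpha: float = ALPHA,
) -> list[SignificanceRecord]:
    """Dunnett-adjusted contrasts of each dose group against vehicle.

    The adjustment family is the set of dose groups within this single
    gene x treatment panel.  Degenerate data are handled without
    exceptions: exact ties across all groups give ``p_adj = 1`` with a
    warning, while zero within-group variance with separated means gives
    ``p_adj = 0`` (an infinitely strong effect on this noise model).
    """
    sub = table[(table["gene"] == gene) & (table["treatment"] == treatment)]
    control = sub.loc[sub["rel_conc"] == 0, "log2fc"].to_numpy(float)
    if control.size == 0:
        raise MissingControlError(
            f"no vehicle rows for gene {gene!r}, treatment {treatment!r}"
        )
    doses = sorted(c for c in sub["rel_conc"].unique() if c > 0)
    if not doses:
        raise ConfigurationError(
            f"no dose groups for gene {gene!r}, treatment {treatment!r}"
        )
    groups = [sub.loc[sub["rel_conc"] == c, "log2fc"].to_numpy(float) for c in doses]
    if control.size < 2 or any(g.size < 2 for g in groups):
        raise ConfigurationError(
            f"gene {gene!r}, treatment {treatment!r}: every group needs >= 2 observations"
        )

    pooled_var = np.concatenate([g - g.mean() for g in groups + [control]]).var()
    if pooled_var < 1e-24:
        means_differ = [
            not np.isclose(g.mean(), control.mean(), atol=1e-12) for g in groups
        ]
        if not any(means_differ):
            warnings.warn(
                f"gene {gene!r}, treatment {treatment!r}: all observations tied; "
                "p_adj set to 1",
                stacklevel=2,
            )
        pvals = [0.0 if differ else 1.0 for differ in means_differ]
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # the multivariate-t quadrature is randomized; pin its RNG so
            # identical inputs always give identical adjusted p-values
            pvals = stats.dunnett(
                *groups, control=control, rng=np.random.default_rng(0)
            ).pvalue
    return [
        SignificanceRecord(
            gene=gene,
            treatment=treatment,
            rel_conc=float(c),
            p_adj=float(min(max(p, 0.0), 1.0)),
            significant=bool(p < alpha),
        )
        for c, p in zip(doses, pvals)
    ]


def significance_table(
    table: pd.DataFrame,
    treatments: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run :func:`dunnett_vs_control` over every gene x treatment panel."""
    records: list[SignificanceRecord] = []
    for (gene, treatment), _ in table.groupby(["gene", "treatment"], sort=False):
        if treatments is not None and treatment not in treatments:
            continue
        records.extend(dunnett_vs_control(table, gene, treatment, alpha=alpha))
    return _records_frame(records)


# -- inclusion filters ----------------------------------------------------


def filter_treatments(
    table: pd.DataFrame,
    significance: Optional[pd.DataFrame] = None,
    min_obs: int = 2,
) -> tuple[pd.DataFrame, list[dict]]:
    """Drop dose cells with fewer than ``min_obs`` valid replicate observations.

    "Valid observations" means replicates surviving outlier removal; the
    boundary is inclusive (a cell with exactly ``min_obs`` rows stays).
    Vehicle cells are never dropped.  ``significance`` is accepted for
    interface symmetry with the gene filter but is not consulted:
    replicate-level significance is undefined for fold-change data, so
    the count-of-observations reading is used.  Idempotent.
    """
    if min_obs < 1:
        raise ConfigurationError(f"min_obs must be >= 1, got {min_obs!r}")
    log: list[dict] = []
    table = table.reset_index(drop=True)
    keep = np.ones(len(table), dtype=bool)
    for key, grp in table.groupby(_CELL, sort=False):
        if key[2] == 0 or len(grp) >= min_obs:
            continue
        keep[grp.index.to_numpy()] = False
        log.append(
            {
                "action": "removed",
                "reason": f"{len(grp)} valid observation(s) < min_obs={min_obs}",
                "gene": key[0],
                "treatment": key[1],
                "rel_conc": key[2],
            }
        )
    return table.loc[keep].reset_index(drop=True), log


def select_genes_for_ia(
    significance: Union[pd.DataFrame, Iterable[SignificanceRecord]],
    min_components: int = 3,
    exclude_treatments: Sequence[str] = (),
) -> list[str]:
    """Genes with >= ``min_components`` components showing a significant response.

    A component counts when any of its concentrations is significant.
    ``exclude_treatments`` names treatments (the mixture itself) that do
    not count toward the component tally.  Idempotent by construction;
    gene order follows first appearance in the input.
    """
    if not isinstance(significance, pd.DataFrame):
        significance = _records_frame(significance)
    sig = significance[~significance["treatment"].isin(exclude_treatments)]
    hits = (
        sig[sig["significant"]]
        .groupby("gene", sort=False)["treatment"]
        .nunique()
    )
    order = significance["gene"].drop_duplicates().tolist()
    return [g for g in order if hits.get(g, 0) >= min_components]


# -- CSV I/O (percent notation at the boundary) ---------------------------


def read_response_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "rel_conc_percent" in df.columns:
        df["rel_conc"] = df.pop("rel_conc_percent") / 100.0
    return df[RESPONSE_COLUMNS]


def write_response_csv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    out = table[RESPONSE_COLUMNS].copy()
    out.insert(2, "rel_conc_percent", out.pop("rel_conc") * 100.0)
    out.to_csv(path, index=False)


def read_ct_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "rel_conc_percent" in df.columns:
        df["rel_conc"] = df.pop("rel_conc_percent") / 100.0
    return df[CT_COLUMNS]


def write_ct_csv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    out = table[CT_COLUMNS].copy()
    out.insert(2, "rel_conc_percent", out.pop("rel_conc") * 100.0)
    out.to_csv(path, index=False)
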