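"""Read-across and trend-analysis data-gap filling over chemical categories.

A *category* is the set of database chemicals sharing the target's organic
functional group profile.  Two gap-filling methods operate on it:

* **read-across** averages the experimental LC50 of the k analogues nearest
  to the target in log Kow (k = 5 by default).  Averaging is done in log
  space (geometric mean) by default, since baseline aquatic toxicity is
  log-linear in hydrophobicity; an arithmetic mode mimics tools that
  average raw concentrations.
* **trend analysis** fits an ordinary least-squares line of log10 LC50 on
  log Kow across the whole category and evaluates it at the target's
  log Kow.  A linear-space mode (LC50 regressed directly on log Kow) is
  provided because some workflows use it; it can extrapolate to negative
  concentrations, which downstream scoring treats as unclassifiable.

The applicability-domain rule for both: the target's log Kow must lie within
the range spanned by the analogues, and its functional groups must all occur
among the analogues' groups.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .records import AdStatus, ChemicalRecord


class SolubilityVerdict(str, enum.Enum):
    PLAUSIBLE = "plausible"
    IMPLAUSIBLE = "implausible"
    UNKNOWN = "unknown"


class CategoryMethod(str, enum.Enum):
    READ_ACROSS = "read_across"
    TREND_ANALYSIS = "trend_analysis"


@dataclass(frozen=True)
class AnalogueRecord:
    """A database chemical with a measured LC50, usable as an analogue."""

    chemical: ChemicalRecord
    lc50: float
    source_db: str = ""

    def __post_init__(self) -> None:
        if self.chemical.log_kow is None:
            raise ValueError(
                f"analogue {self.chemical.cas_number} needs a log_kow"
            )
        if not self.chemical.functional_groups:
            raise ValueError(
                f"analogue {self.chemical.cas_number} needs functional groups"
            )
        if not (math.isfinite(self.lc50) and self.lc50 > 0):
            raise ValueError(
                f"analogue LC50 must be positive, got {self.lc50} for "
                f"{self.chemical.cas_number}"
            )


@dataclass
class CategoryPrediction:
    """Outcome of one data-gap filling run.

    ``lc50`` may be non-positive in linear-space trend mode.  Regression
    diagnostics are filled for trend analysis only.
    """

    lc50: float
    method: CategoryMethod
    ad_status: AdStatus
    analogue_ids: list[str] = field(default_factory=list)
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None


def build_category(
    target: ChemicalRecord,
    db: Sequence[AnalogueRecord],
    mode: str = "strict",
) -> list[AnalogueRecord]:
    """Analogues matching the target's functional-group profile.

    ``mode="strict"`` keeps analogues whose group set equals the target's;
    ``mode="subset"`` also keeps analogues whose groups are a subset of the
    target's (no foreign functionality).  The target itself is excluded by
    CAS number.
    """
    if not target.functional_groups:
        raise ValueError("target must carry functional group labels")
    groups = frozenset(target.functional_groups)
    out = []
    for rec in db:
        if rec.chemical.cas_number == target.cas_number:
            continue
        rec_groups = frozenset(rec.chemical.functional_groups or ())
        if mode == "strict":
            keep = rec_groups == groups
        elif mode == "subset":
            keep = rec_groups <= groups
        else:
            raise ValueError(f"unknown category mode {mode!r}")
        if keep:
            out.append(rec)
    return out


def _nearest_by_kow(
    target: ChemicalRecord, analogues: Sequence[AnalogueRecord], k: int
) -> list[AnalogueRecord]:
    if target.log_kow is None:
        raise ValueError("target must carry a log_kow for nearest-analogue search")
    ranked = sorted(
        analogues,
        key=lambda rec: (
            abs(rec.chemical.log_kow - target.log_kow),  # type: ignore[operator]
            rec.chemical.cas_number,
        ),
    )
    return ranked[:k]


def read_across(
    target: ChemicalRecord,
    analogues: Sequence[AnalogueRecord],
    k: int = 5,
    average: str = "geometric",
) -> CategoryPrediction | None:
    """Average the k analogues nearest in log Kow; None without analogues.

    Ties in |log Kow distance| break deterministically by CAS ascending.
    The AD check runs against the full analogue list (the collected
    category), not just the k selected.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    usable = [a for a in analogues if a.lc50 > 0]
    if not usable:
        return None
    selected = _nearest_by_kow(target, usable, k)
    values = np.array([a.lc50 for a in selected])
    if average == "geometric":
        pred = float(10 ** np.mean(np.log10(values)))
    elif average == "arithmetic":
        pred = float(np.mean(values))
    else:
        raise ValueError(f"unknown averaging mode {average!r}")
    return CategoryPrediction(
        lc50=pred,
        method=CategoryMethod.READ_ACROSS,
        ad_status=category_ad_check(target, analogues),
        analogue_ids=[a.chemical.cas_number for a in selected],
    )


def trend_analysis(
    target: ChemicalRecord,
    analogues: Sequence[AnalogueRecord],
    space: str = "log",
) -> CategoryPrediction | None:
    """OLS of toxicity on log Kow over the category, evaluated at the target.

    Default regresses log10 LC50 (predictions are always positive); in
    ``space="linear"`` the raw LC50 is regressed and extrapolation can
    produce values <= 0, which are returned as-is.  None when fewer than 3
    analogues or no log Kow spread.
    """
    if space not in ("log", "linear"):
        raise ValueError(f"unknown regression space {space!r}")
    if target.log_kow is None:
        raise ValueError("target must carry a log_kow")
    if len(analogues) < 3:
        return None
    x = np.array([a.chemical.log_kow for a in analogues], dtype=float)
    if np.ptp(x) == 0:
        return None
    y = np.array([a.lc50 for a in analogues], dtype=float)
    if space == "log":
        y = np.log10(y)
    fit = stats.linregress(x, y)
    fitted = fit.intercept + fit.slope * target.log_kow
    pred = float(10**fitted) if space == "log" else float(fitted)
    return CategoryPrediction(
        lc50=pred,
        method=CategoryMethod.TREND_ANALYSIS,
        ad_status=category_ad_check(target, analogues),
        analogue_ids=[a.chemical.cas_number for a in analogues],
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


def remove_outliers(
    analogues: Sequence[AnalogueRecord], exclude: Sequence[str]
) -> list[AnalogueRecord]:
    """Drop the explicitly listed CAS numbers (expert-driven refinement).

    Nothing is removed automatically; use :func:`flag_outliers` to obtain
    data-driven suggestions for the exclude list.
    """
    excluded = set(exclude)
    return [a for a in analogues if a.chemical.cas_number not in excluded]


def flag_outliers(
    analogues: Sequence[AnalogueRecord],
    threshold: float = 3.0,
    space: str = "log",
) -> list[str]:
    """CAS numbers whose externally studentized residual exceeds ``threshold``.

    Residuals come from the same toxicity-on-log-Kow regression trend
    analysis uses.  This only *suggests* candidates; removal stays an
    explicit, expert decision via :func:`remove_outliers`.
    """
    if len(analogues) < 4:  # studentized residuals need n - p - 1 >= 1
        return []
    import statsmodels.api as sm

    x = np.array([a.chemical.log_kow for a in analogues], dtype=float)
    y = np.array([a.lc50 for a in analogues], dtype=float)
    if space == "log":
        y = np.log10(y)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if model.mse_resid < 1e-20:  # numerically perfect fit: nothing to flag
        return []
    student = model.get_influence().resid_studentized_external
    return [
        analogues[i].chemical.cas_number
        for i in np.flatnonzero(np.abs(student) > threshold)
    ]


def category_ad_check(
    target: ChemicalRecord, analogues: Sequence[AnalogueRecord]
) -> AdStatus:
    """Kow-range plus functional-group coverage applicability rule.

    Inside iff the target's log Kow lies within [min, max] of the analogues'
    log Kow AND every target functional group occurs somewhere among the
    analogues.
    """
    if not analogues:
        raise ValueError("AD check needs at least one analogue")
    if target.log_kow is None:
        return AdStatus.OUTSIDE
    kows = [a.chemical.log_kow for a in analogues]
    group_union: set[str] = set()
    for a in analogues:
        group_union |= set(a.chemical.functional_groups or ())
    in_range = min(kows) <= target.log_kow <= max(kows)  # type: ignore[type-var]
    covered = set(target.functional_groups or ()) <= group_union
    return AdStatus.INSIDE if in_range and covered else AdStatus.OUTSIDE


def solubility_check(
    lc50: float, water_solubility: float | None
) -> SolubilityVerdict:
    """Flag an LC50 exceeding the substance's water solubility.

    An acute LC50 above the solubility limit cannot have been a truly
    dissolved exposure, so such experimental values are suspect.  The rule
    is strict: LC50 equal to the solubility is still plausible.
    """
    if not lc50 > 0:
        raise ValueError("lc50 must be positive")
    if water_solubility is None:
        return SolubilityVerdict.UNKNOWN
    if not water_solubility > 0:
        raise ValueError("water_solubility must be positive")
    return (
        SolubilityVerdict.IMPLAUSIBLE
        if lc50 > water_solubility
        else SolubilityVerdict.PLAUSIBLE
    )
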