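"""Performance statistics for LC50 prediction tools.

Two qualitative scores are distinguished.  Total accuracy divides the number
of correct GHS category assignments by the number of chemicals the tool
actually predicted:

    total accuracy = n_correct / (n_all - n_missing) * 100%

Predictive power treats a missing prediction as a wrong one:

    predictive power = n_correct / n_all * 100%

so total accuracy >= predictive power always, with equality iff nothing is
missing.  Quantitative scores work on the log10 ratio between predicted and
experimental LC50: accuracy within a fold factor F is the share of
non-missing predictions with |log10(pred) - log10(exp)| <= log10(F), and
RMSE / R^2 / error distributions are computed on log10 values.  Non-positive
predictions have no logarithm; they stay in fold-accuracy denominators as
failures but are excluded from RMSE, R^2 and the error distribution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .ghs import qualitative_agreement, try_classify_ghs
from .records import (
    AdStatus,
    ChemicalRecord,
    Endpoint,
    EvaluationReport,
    ExperimentalToxicity,
    Scope,
    Tool,
    ToolPrediction,
)

#: fold factors reported in the summary tables
DEFAULT_FOLD_FACTORS: tuple[int, ...] = (10, 100, 1000)

#: slack for "within a factor F" comparisons at the boundary, where the
#: log10 difference is only float-exact up to rounding
_FOLD_EPS = 1e-12


@dataclass(frozen=True)
class PairedObservation:
    """One chemical's experimental LC50 paired with one tool's prediction."""

    chemical: ChemicalRecord
    exp_lc50: float
    pred_lc50: float | None
    ad_status: AdStatus = AdStatus.UNKNOWN

    def __post_init__(self) -> None:
        if not (math.isfinite(self.exp_lc50) and self.exp_lc50 > 0):
            raise ValueError(
                f"exp_lc50 must be positive and finite, got {self.exp_lc50}"
            )

    @property
    def missing(self) -> bool:
        return self.pred_lc50 is None

    @property
    def usable_log(self) -> bool:
        """Prediction present, positive and finite: log-space metrics apply."""
        return (
            self.pred_lc50 is not None
            and math.isfinite(self.pred_lc50)
            and self.pred_lc50 > 0
        )


def make_pairs(
    experiments: Sequence[ExperimentalToxicity],
    predictions: Sequence[ToolPrediction],
    tool: Tool,
    endpoint: Endpoint | None = None,
) -> list[PairedObservation]:
    """Join experiments with one tool's predictions on CAS number.

    Chemicals without a prediction record at all become missing pairs, so
    the pairing is always 1:1 with the experimental dataset.
    """
    by_cas: dict[str, ToolPrediction] = {}
    for p in predictions:
        if p.tool is not tool:
            continue
        if endpoint is not None and p.endpoint is not endpoint:
            continue
        key = p.chemical.cas_number
        if key in by_cas:
            raise ValueError(
                f"duplicate prediction for {key} ({tool.value}, "
                f"{p.endpoint.value})"
            )
        by_cas[key] = p
    pairs = []
    for e in experiments:
        if endpoint is not None and e.endpoint is not endpoint:
            continue
        p = by_cas.get(e.chemical.cas_number)
        pairs.append(
            PairedObservation(
                chemical=e.chemical,
                exp_lc50=e.lc50,
                pred_lc50=None if p is None else p.lc50,
                ad_status=AdStatus.UNKNOWN if p is None else p.ad_status,
            )
        )
    return pairs


def total_accuracy(n_correct: int, n_all: int, n_missing: int) -> float | None:
    """Correct assignments as a % of non-missing predictions.

    Returns None when every prediction is missing (undefined denominator).
    """
    if not 0 <= n_missing <= n_all:
        raise ValueError(f"need 0 <= n_missing <= n_all, got {n_missing}/{n_all}")
    if not 0 <= n_correct <= n_all - n_missing:
        raise ValueError(
            f"need 0 <= n_correct <= n_all - n_missing, got "
            f"{n_correct}/{n_all - n_missing}"
        )
    if n_all == n_missing:
        return None
    return 100.0 * n_correct / (n_all - n_missing)


def predictive_power(n_correct: int, n_all: int) -> float:
    """Correct assignments as a % of all chemicals (missing counts as wrong)."""
    if n_all <= 0:
        raise ValueError("n_all must be positive")
    if not 0 <= n_correct <= n_all:
        raise ValueError(f"need 0 <= n_correct <= n_all, got {n_correct}/{n_all}")
    return 100.0 * n_correct / n_all


def fold_error(exp_lc50: float, pred_lc50: float | None) -> float:
    """|log10(pred) - log10(exp)|; +inf when the prediction is unusable."""
    if not (math.isfinite(exp_lc50) and exp_lc50 > 0):
        raise ValueError(f"exp_lc50 must be positive, got {exp_lc50}")
    if pred_lc50 is None or not math.isfinite(pred_lc50) or pred_lc50 <= 0:
        return math.inf
    return abs(math.log10(pred_lc50) - math.log10(exp_lc50))


def fold_accuracy(
    pairs: Iterable[PairedObservation], factor: float
) -> float | None:
    """% of non-missing predictions within a multiplicative ``factor``.

    Non-positive predictions stay in the denominator and count as failures;
    returns None when every prediction is missing.
    """
    if factor <= 1:
        raise ValueError("factor must exceed 1")
    threshold = math.log10(factor) + _FOLD_EPS
    n = n_within = 0
    for pair in pairs:
        if pair.missing:
            continue
        n += 1
        if fold_error(pair.exp_lc50, pair.pred_lc50) <= threshold:
            n_within += 1
    if n == 0:
        return None
    return 100.0 * n_within / n


def _log_errors(pairs: Iterable[PairedObservation]) -> np.ndarray:
    return np.array(
        [
            math.log10(p.pred_lc50) - math.log10(p.exp_lc50)
            for p in pairs
            if p.usable_log
        ]
    )


def rmse_log10(pairs: Iterable[PairedObservation]) -> float | None:
    """Root-mean-square error of log10 LC50 over usable predictions."""
    errors = _log_errors(pairs)
    if errors.size == 0:
        return None
    return float(np.sqrt(np.mean(errors**2)))


def r_squared(xs: Sequence[float], ys: Sequence[float]) -> float | None:
    """Squared Pearson correlation; None for n < 3 or zero variance."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError("xs and ys must have equal length")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def error_distribution(
    pairs: Iterable[PairedObservation],
) -> tuple[float, float, int] | None:
    """(mean, sample SD, n) of log10(pred) - log10(exp) over usable pairs.

    Positive errors mean the prediction exceeds the experiment, i.e.
    toxicity was underestimated.  SD uses the n-1 denominator and is 0 for a
    single observation.
    """
    errors = _log_errors(pairs)
    if errors.size == 0:
        return None
    mean = float(np.mean(errors))
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return mean, sd, int(errors.size)


def evaluate_tool(
    pairs: Sequence[PairedObservation],
    scope: Scope | str = Scope.ENTIRE,
    tool: Tool = Tool.ECOSAR,
    endpoint: Endpoint = Endpoint.DAPHNIA_48H,
    fold_factors: Sequence[int] = DEFAULT_FOLD_FACTORS,
) -> EvaluationReport:
    """Fill an :class:`EvaluationReport` for one tool's paired observations.

    ``scope=inside_ad`` restricts every statistic to predictions flagged
    inside the applicability domain; predictive power is only meaningful on
    the entire dataset and is left unset for the in-AD scope.
    """
    scope = Scope(scope)
    if not pairs:
        raise ValueError("cannot evaluate an empty pair list")
    n_all = len(pairs)
    n_inside = sum(p.ad_status is AdStatus.INSIDE for p in pairs)
    scoped = (
        [p for p in pairs if p.ad_status is AdStatus.INSIDE]
        if scope is Scope.INSIDE_AD
        else list(pairs)
    )

    n_missing = sum(p.missing for p in scoped)
    n_correct = sum(
        not p.missing and qualitative_agreement(p.exp_lc50, p.pred_lc50)
        for p in scoped
    )
    n_incorrect = len(scoped) - n_missing - n_correct

    class_pairs = [
        (classify_exp, classify_pred)
        for p in scoped
        if not p.missing
        for classify_exp in [try_classify_ghs(p.exp_lc50)]
        for classify_pred in [try_classify_ghs(p.pred_lc50)]
        if classify_pred is not None
    ]
    log_pairs = [
        (math.log10(p.exp_lc50), math.log10(p.pred_lc50))
        for p in scoped
        if p.usable_log
    ]

    dist = error_distribution(scoped)
    report = EvaluationReport(
        tool=tool,
        endpoint=endpoint,
        scope=scope,
        n_all=n_all,
        n_missing=n_missing,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        n_inside_ad=n_inside,
        total_accuracy_pct=total_accuracy(
            n_correct, len(scoped), n_missing
        ),
        predictive_power_pct=(
            predictive_power(n_correct, n_all) if scope is Scope.ENTIRE else None
        ),
        fold_accuracy_pct={
            int(f): fold_accuracy(scoped, f) for f in fold_factors
        },
        r2_class=r_squared(
            [int(c) for c, _ in class_pairs], [int(c) for _, c in class_pairs]
        )
        if class_pairs
        else None,
        r2_log10=r_squared([x for x, _ in log_pairs], [y for _, y in log_pairs])
        if log_pairs
        else None,
        rmse_log10=rmse_log10(scoped),
        error_mean=None if dist is None else dist[0],
        error_sd=None if dist is None else dist[1],
        error_n=0 if dist is None else dist[2],
    )
    return report
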