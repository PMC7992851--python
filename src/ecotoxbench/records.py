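"""Domain types for acute aquatic toxicity model evaluation.

All concentrations are LC50 values in mg/L: the concentration lethal to 50%
of test organisms after 48 h (daphnia) or 96 h (fish) exposure. Predictions
may be absent (the tool declined or failed) and, for trend extrapolation in
linear concentration space, may even be non-positive; both situations are
first-class states rather than errors so that batch evaluation never aborts.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Endpoint(str, enum.Enum):
    """Acute aquatic toxicity endpoint."""

    DAPHNIA_48H = "daphnia_48h"
    FISH_96H = "fish_96h"


class Tool(str, enum.Enum):
    """The in-silico prediction tools under evaluation."""

    ECOSAR = "ECOSAR"
    TEST = "TEST"
    DANISH = "DANISH"
    VEGA = "VEGA"
    KATE = "KATE"
    READ_ACROSS = "READ_ACROSS"
    TREND_ANALYSIS = "TREND_ANALYSIS"


class AdStatus(str, enum.Enum):
    """Applicability-domain membership of a single prediction."""

    INSIDE = "inside"
    OUTSIDE = "outside"
    UNKNOWN = "unknown"


class Scope(str, enum.Enum):
    """Evaluation scope: whole dataset, or restricted to in-AD predictions."""

    ENTIRE = "entire"
    INSIDE_AD = "inside_ad"


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical: identity plus the descriptors the pipeline may use.

    ``log_kow`` is the base-10 logarithm of the octanol-water partition
    coefficient (dimensionless), ``water_solubility`` is in mg/L and
    ``functional_groups`` are pre-computed organic functional group labels
    (group derivation from structures is out of scope; labels are inputs).
    """

    cas_number: str
    name: str = ""
    log_kow: float | None = None
    water_solubility: float | None = None
    functional_groups: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.cas_number:
            raise ValueError("cas_number must be non-empty")
        if self.water_solubility is not None and not self.water_solubility > 0:
            raise ValueError(
                f"water_solubility must be > 0, got {self.water_solubility} "
                f"for {self.cas_number}"
            )
        if self.log_kow is not None and not math.isfinite(self.log_kow):
            raise ValueError(f"log_kow must be finite for {self.cas_number}")
        if self.functional_groups is not None and not isinstance(
            self.functional_groups, frozenset
        ):
            object.__setattr__(
                self, "functional_groups", frozenset(self.functional_groups)
            )


@dataclass(frozen=True)
class ExperimentalToxicity:
    """A measured LC50 (mg/L, strictly positive) for one chemical/endpoint."""

    chemical: ChemicalRecord
    endpoint: Endpoint
    lc50: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lc50) and self.lc50 > 0):
            raise ValueError(
                f"experimental lc50 must be a positive finite value, got "
                f"{self.lc50} for {self.chemical.cas_number}"
            )


@dataclass(frozen=True)
class ToolPrediction:
    """One tool's consolidated LC50 prediction for one chemical/endpoint.

    ``lc50 is None`` means the tool produced no prediction (counted as
    missing in all metrics).  A present value may be <= 0 when it came from
    trend extrapolation in linear space; such values are kept as printed and
    scored as unclassifiable/incorrect downstream.
    """

    chemical: ChemicalRecord
    tool: Tool
    endpoint: Endpoint
    lc50: float | None
    ad_status: AdStatus = AdStatus.UNKNOWN
    note: str = ""


@dataclass
class EvaluationReport:
    """All counts and summary statistics for one tool x endpoint x scope.

    Percentages are kept at full precision here; rounding to the printed
    integer happens only when a report table is written out.  ``None`` marks
    a statistic whose denominator was empty (e.g. no usable predictions).
    """

    tool: Tool
    endpoint: Endpoint
    scope: Scope
    n_all: int
    n_missing: int
    n_correct: int
    n_incorrect: int
    n_inside_ad: int | None = None
    total_accuracy_pct: float | None = None
    predictive_power_pct: float | None = None
    fold_accuracy_pct: dict[int, float | None] = field(default_factory=dict)
    r2_class: float | None = None
    r2_log10: float | None = None
    rmse_log10: float | None = None
    error_mean: float | None = None
    error_sd: float | None = None
    error_n: int = 0

    def __post_init__(self) -> None:
        if self.scope is Scope.ENTIRE:
            if self.n_correct + self.n_incorrect + self.n_missing != self.n_all:
                raise ValueError(
                    "correct + incorrect + missing must equal n_all in "
                    "entire-dataset scope"
                )
        for pct in (self.total_accuracy_pct, self.predictive_power_pct):
            if pct is not None and not 0 <= pct <= 100:
                raise ValueError(f"percentage out of range: {pct}")
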