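"""Per-tool rules that reduce raw multi-output tool results to one LC50.

Each tool under evaluation emits more than one number per chemical (several
structural classes, sub-models or QSAR methodologies); validation uses a
single value per chemical.  The rules implemented here are the ones used in
regulatory practice:

* experimental data: the lowest reasonable value is kept (worst case);
* ECOSAR: freshwater predictions only, minimum over structural classes;
* KATE: minimum over the matching structural classes;
* Danish QSAR Database: the Battery estimate first, else the lower of the
  Leadscope and SciQSAR estimates;
* T.E.S.T.: the consensus value, accepted only when at least two component
  methodologies contributed (a one-method consensus is deemed unreliable);
* VEGA: a stepwise integration over sub-models driven by the reliability
  stars and the Applicability Domain Index (ADI), see
  :func:`vega_integrate`.

All rules return an explicitly *missing* result on empty input rather than
raising, except ``vega_integrate`` which requires at least one model output.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import AdStatus

#: order in which the four ADI sub-indices are compared lexicographically
#: when global ADI ties (integration step 4)
ADI_SUB_ORDER: tuple[str, ...] = ("similarity", "accuracy", "concordance", "acf")

#: minimum reliability stars for a VEGA winner to be flagged inside the AD
DEFAULT_STAR_THRESHOLD = 2


class VegaOutputKind(str, enum.Enum):
    VALUE = "value"
    CLASS = "class"


@dataclass(frozen=True)
class VegaModelOutput:
    """One VEGA sub-model result.

    ``reliability_stars`` is VEGA's 0-3 star reliability grade;
    ``adi_global`` the composite Applicability Domain Index in [0, 1];
    ``adi_sub`` the four sub-indices (similarity, accuracy, concordance,
    atom-centred-fragment coverage).  Classification sub-models report a
    GHS-like band (``tox_class``) instead of a value.
    """

    model_name: str
    output_kind: VegaOutputKind
    lc50: float | None = None
    tox_class: str | None = None
    reliability_stars: int = 0
    adi_global: float = 0.0
    adi_sub: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reliability_stars not in (0, 1, 2, 3):
            raise ValueError(f"stars must be in 0..3, got {self.reliability_stars}")
        for label, value in [("adi_global", self.adi_global), *self.adi_sub.items()]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"ADI {label} must lie in [0, 1], got {value}")
        if self.output_kind is VegaOutputKind.VALUE and self.lc50 is None:
            raise ValueError(f"{self.model_name}: value output requires lc50")
        if self.output_kind is VegaOutputKind.CLASS and not self.tox_class:
            raise ValueError(f"{self.model_name}: class output requires tox_class")


@dataclass(frozen=True)
class ConsolidatedPrediction:
    """The single LC50 (or explicit absence) a rule settled on."""

    lc50: float | None
    ad_status: AdStatus = AdStatus.UNKNOWN
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.lc50 is not None and not self.provenance:
            raise ValueError("provenance required whenever a value is present")

    @property
    def missing(self) -> bool:
        return self.lc50 is None


MISSING = ConsolidatedPrediction(lc50=None, provenance="")


def select_experimental(values: Sequence[float]) -> float:
    """Lowest (most conservative) of several experimental LC50 values."""
    if not values:
        raise ValueError("no experimental values to select from")
    if any(v <= 0 for v in values):
        raise ValueError("experimental LC50 values must be positive")
    return min(values)


def consolidate_kate(values: Sequence[float]) -> ConsolidatedPrediction:
    """KATE: the lowest predicted value across matched structural classes."""
    if not values:
        return MISSING
    return ConsolidatedPrediction(lc50=min(values), provenance="KATE lowest value")


def consolidate_danish(
    battery: float | None,
    leadscope: float | None,
    sciqsar: float | None,
) -> ConsolidatedPrediction:
    """Danish QSAR Database: Battery first, else min(Leadscope, SciQSAR)."""
    if battery is not None:
        return ConsolidatedPrediction(lc50=battery, provenance="Danish battery")
    candidates = [
        (v, name)
        for v, name in ((leadscope, "Leadscope"), (sciqsar, "SciQSAR"))
        if v is not None
    ]
    if not candidates:
        return MISSING
    value, name = min(candidates, key=lambda pair: pair[0])
    return ConsolidatedPrediction(lc50=value, provenance=f"Danish {name} (lowest)")


def consolidate_test(
    consensus: float | None, n_contributing_methods: int
) -> ConsolidatedPrediction:
    """T.E.S.T.: consensus value, valid only with >= 2 contributing methods.

    A valid consensus is by definition inside the AD (that is how the tool
    exposes its final applicability decision).
    """
    if n_contributing_methods < 0:
        raise ValueError("method count cannot be negative")
    if consensus is None or n_contributing_methods < 2:
        return MISSING
    return ConsolidatedPrediction(
        lc50=consensus,
        ad_status=AdStatus.INSIDE,
        provenance=f"TEST consensus of {n_contributing_methods} methods",
    )


def consolidate_ecosar(
    class_predictions: Iterable[tuple[str, str, float]],
    prefer: str = "min",
) -> ConsolidatedPrediction:
    """ECOSAR: keep freshwater predictions, then resolve across classes.

    ``class_predictions`` holds (structural class, medium, LC50) triples;
    medium is matched case-insensitively against "fresh"*.  ``prefer`` is
    "min" (conservative default) or "first" (the first reported class).
    """
    fresh = [
        (cls, value)
        for cls, medium, value in class_predictions
        if medium.lower().startswith("fresh")
    ]
    if not fresh:
        return MISSING
    if prefer == "first":
        cls, value = fresh[0]
    elif prefer == "min":
        cls, value = min(fresh, key=lambda pair: pair[1])
    else:
        raise ValueError(f"unknown preference {prefer!r}")
    return ConsolidatedPrediction(
        lc50=value, provenance=f"ECOSAR {cls} (freshwater)"
    )


def class_band_to_value(tox_class: str) -> float:
    """Convert a GHS-like band label to a working LC50 value.

    The band's lower concentration limit plus 0.1 mg/L is used, e.g.
    "toxic-3" (10-100 mg/L) becomes 10.1 mg/L.  The trailing integer of the
    label selects the band.
    """
    digits = "".join(ch for ch in tox_class if ch.isdigit())
    if not digits:
        raise ValueError(f"cannot read a category code from {tox_class!r}")
    code = int(digits[-1])
    lower = {1: 0.0, 2: 1.0, 3: 10.0, 4: 100.0}.get(code)
    if lower is None:
        raise ValueError(f"no GHS band with code {code} in {tox_class!r}")
    return lower + 0.1


def _effective_lc50(model: VegaModelOutput) -> float:
    if model.output_kind is VegaOutputKind.CLASS:
        return class_band_to_value(model.tox_class)  # type: ignore[arg-type]
    assert model.lc50 is not None
    return model.lc50


def _adi_sub_key(model: VegaModelOutput) -> tuple[float, ...]:
    return tuple(model.adi_sub.get(name, 0.0) for name in ADI_SUB_ORDER)


def vega_integrate(
    models: Sequence[VegaModelOutput],
    star_threshold: int = DEFAULT_STAR_THRESHOLD,
) -> ConsolidatedPrediction:
    """Integrate several VEGA sub-model outputs into one prediction.

    Stepwise rule (the experimental-value step of the published strategy is
    deliberately skipped, since experimental values are what the evaluation
    is scored against):

    1. a *unique* model with 3 reliability stars and every ADI equal to 1 is
       used outright;
    2. otherwise the model with the strictly highest global ADI;
    3. otherwise the four ADI sub-indices are compared lexicographically in
       the order similarity, accuracy, concordance, ACF;
    4. any remaining tie is broken by the lowest (most conservative) LC50.

    Class outputs enter the comparison as their band's lower limit + 0.1
    mg/L.  The winner is flagged inside the AD iff its reliability stars
    reach ``star_threshold``.
    """
    if not models:
        raise ValueError("vega_integrate requires at least one model output")

    def finish(model: VegaModelOutput, step: str) -> ConsolidatedPrediction:
        return ConsolidatedPrediction(
            lc50=_effective_lc50(model),
            ad_status=(
                AdStatus.INSIDE
                if model.reliability_stars >= star_threshold
                else AdStatus.OUTSIDE
            ),
            provenance=f"VEGA {model.model_name} ({step})",
        )

    perfect = [
        m
        for m in models
        if m.reliability_stars == 3
        and m.adi_global == 1.0
        and all(
            m.adi_sub.get(name, 1.0) == 1.0 for name in ADI_SUB_ORDER
        )
    ]
    if len(perfect) == 1:
        return finish(perfect[0], "3 stars, all ADI = 1")

    best_global = max(m.adi_global for m in models)
    candidates = [m for m in models if m.adi_global == best_global]
    if len(candidates) == 1:
        return finish(candidates[0], "highest global ADI")

    best_sub = max(_adi_sub_key(m) for m in candidates)
    candidates = [m for m in candidates if _adi_sub_key(m) == best_sub]
    if len(candidates) == 1:
        return finish(candidates[0], "highest ADI sub-indices")

    winner = min(candidates, key=_effective_lc50)
    return finish(winner, "tie broken by lowest LC50")
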