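"""GHS acute aquatic toxicity categories and qualitative agreement.

The Globally Harmonized System bins an acute LC50 (mg/L) into four hazard
categories with cut-offs at 1, 10 and 100 mg/L; upper bounds are inclusive,
so 100 mg/L is still category 3 (harmful).  The bins partition (0, inf):

    category 1 (very toxic):        LC50 <= 1
    category 2 (toxic):        1 <  LC50 <= 10
    category 3 (harmful):     10 <  LC50 <= 100
    category 4 (not harmful): 100 <  LC50

A prediction is qualitatively "correct" when it lands in the same category
as the experimental value.  Non-positive or non-finite values (possible for
linear-space trend extrapolation) are unclassifiable; callers decide how to
score them — the evaluation pipeline counts them as incorrect so a single
extrapolation artifact never aborts a batch run.
"""
from __future__ import annotations

import enum
import math


class GhsCategory(enum.IntEnum):
    """The four GHS acute aquatic hazard categories; lower code = more toxic."""

    VERY_TOXIC = 1
    TOXIC = 2
    HARMFUL = 3
    NOT_HARMFUL = 4

    @property
    def label(self) -> str:
        return self.name.lower()


#: Inclusive upper bound (mg/L) of each category, in code order.
_UPPER_BOUNDS: tuple[tuple[float, GhsCategory], ...] = (
    (1.0, GhsCategory.VERY_TOXIC),
    (10.0, GhsCategory.TOXIC),
    (100.0, GhsCategory.HARMFUL),
    (math.inf, GhsCategory.NOT_HARMFUL),
)


class UnclassifiableError(ValueError):
    """Raised when an LC50 cannot be placed in any GHS category."""


def classify_ghs(lc50: float) -> GhsCategory:
    """Assign the GHS acute aquatic category for an LC50 in mg/L.

    Raises :class:`UnclassifiableError` for non-positive or non-finite
    values.  Use :func:`try_classify_ghs` for a non-raising variant.
    """
    cat = try_classify_ghs(lc50)
    if cat is None:
        raise UnclassifiableError(f"LC50 {lc50!r} mg/L has no GHS category")
    return cat


def try_classify_ghs(lc50: float | None) -> GhsCategory | None:
    """Like :func:`classify_ghs` but returns None for unclassifiable input."""
    if lc50 is None or not math.isfinite(lc50) or lc50 <= 0:
        return None
    for bound, cat in _UPPER_BOUNDS:
        if lc50 <= bound:
            return cat
    raise AssertionError("unreachable: bins cover (0, inf)")


def qualitative_agreement(exp_lc50: float, pred_lc50: float | None) -> bool:
    """True iff prediction and experiment fall in the same GHS category.

    The experimental value must be classifiable (positive, finite); an
    unclassifiable prediction simply disagrees.
    """
    exp_cat = classify_ghs(exp_lc50)
    return try_classify_ghs(pred_lc50) == exp_cat
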