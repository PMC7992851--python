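"""Synthetic data generators for end-to-end pipeline testing.

Two kinds of data are emulated, matching the structural assumptions the
evaluation pipeline makes about real inputs:

* **analogue databases** for the category engine: hydrophobicity (log Kow)
  drawn uniformly, toxicity log-linear in log Kow with lognormal scatter
  (``log10 LC50 = intercept + slope * logKow + N(0, noise_sd)``), and
  functional-group labels drawn from a small vocabulary;
* **tool prediction tables** for the metrics pipeline: multiplicative
  lognormal prediction error around the experimental truth
  (``log10 pred = log10 exp + bias + N(0, error_sd)``), with independent
  missing-prediction and AD-outside Bernoulli events.

Default magnitudes mirror a confidential new-chemicals validation exercise:
42 chemicals per endpoint batch, baseline-toxicity slope -0.8 log10 units
per log Kow unit, experimental scatter 0.3 and tool error 0.8 log10 units
(the RMSE range real tools showed), 10% missing predictions and 20%
AD-outside rate.

Randomness is reproducible and *extensible*: each chemical row derives its
own substream from (seed, row index), so enlarging ``n_chemicals`` appends
rows without reshuffling earlier ones.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .category import AnalogueRecord
from .records import (
    AdStatus,
    ChemicalRecord,
    Endpoint,
    ExperimentalToxicity,
    Tool,
    ToolPrediction,
)

#: functional-group vocabulary loosely following groups common in new
#: industrial chemicals
DEFAULT_GROUPS: tuple[str, ...] = (
    "aryl",
    "aryl halide",
    "aromatic amine",
    "phenol",
    "nitrile",
    "ketone",
    "ether",
    "carboxylic acid ester",
    "alcohol",
    "alkene",
    "amide",
    "alkyl halide",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Units: ``slope`` in log10(mg/L) per log Kow unit, ``intercept`` in
    log10(mg/L), ``noise_sd``/``tool_error_sd``/``tool_bias`` in log10
    units; probabilities in [0, 1].
    """

    n_chemicals: int = 42
    kow_range: tuple[float, float] = (-1.0, 6.0)
    slope: float = -0.8
    intercept: float = 2.0
    noise_sd: float = 0.3
    group_vocabulary: tuple[str, ...] = DEFAULT_GROUPS
    n_groups_per_chemical: int = 2
    tool_error_sd: float = 0.8
    tool_bias: float = 0.0
    missing_prob: float = 0.1
    ad_out_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be positive")
        low, high = self.kow_range
        if not low < high:
            raise ValueError("kow_range must satisfy low < high")
        if self.noise_sd < 0 or self.tool_error_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for name in ("missing_prob", "ad_out_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not 1 <= self.n_groups_per_chemical <= len(self.group_vocabulary):
            raise ValueError("n_groups_per_chemical out of range")


def _row_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    # one substream per (row, purpose); adding rows never reshuffles old ones
    return np.random.default_rng([seed, stream, index])


def gen_analogue_db(spec: SyntheticSpec) -> list[AnalogueRecord]:
    """Generate an analogue database with log-linear toxicity structure."""
    records = []
    for i in range(spec.n_chemicals):
        rng = _row_rng(spec.seed, i, stream=0)
        low, high = spec.kow_range
        kow = float(rng.uniform(low, high))
        log_lc50 = spec.intercept + spec.slope * kow
        if spec.noise_sd > 0:
            log_lc50 += float(rng.normal(0.0, spec.noise_sd))
        groups = frozenset(
            rng.choice(
                np.array(spec.group_vocabulary, dtype=object),
                size=spec.n_groups_per_chemical,
                replace=False,
            )
        )
        chem = ChemicalRecord(
            cas_number=f"SYN-{i:05d}",
            name=f"synthetic analogue {i}",
            log_kow=kow,
            functional_groups=groups,
        )
        records.append(
            AnalogueRecord(chemical=chem, lc50=10.0**log_lc50, source_db="synthetic")
        )
    return records


def gen_experiments(
    spec: SyntheticSpec, endpoint: Endpoint = Endpoint.DAPHNIA_48H
) -> list[ExperimentalToxicity]:
    """Experimental LC50 records drawn from the same log-linear model."""
    return [
        ExperimentalToxicity(chemical=a.chemical, endpoint=endpoint, lc50=a.lc50)
        for a in gen_analogue_db(spec)
    ]


def gen_prediction_table(
    spec: SyntheticSpec,
    experiments: Sequence[ExperimentalToxicity],
    tool: Tool = Tool.ECOSAR,
) -> list[ToolPrediction]:
    """Emulate one tool's predictions for the given experimental records.

    Per chemical i (substreams keyed to i): the prediction is the truth
    perturbed by ``tool_bias`` plus N(0, tool_error_sd) in log10 space, the
    prediction is dropped with ``missing_prob`` and flagged AD-outside with
    ``ad_out_prob``, all independently.
    """
    if not experiments:
        raise ValueError("experiments must be non-empty")
    predictions = []
    for i, exp in enumerate(experiments):
        rng = _row_rng(spec.seed, i, stream=1)
        noise = float(rng.normal(0.0, spec.tool_error_sd)) if spec.tool_error_sd else 0.0
        u_missing, u_ad = rng.uniform(size=2)
        log_pred = math.log10(exp.lc50) + spec.tool_bias + noise
        missing = u_missing < spec.missing_prob
        predictions.append(
            ToolPrediction(
                chemical=exp.chemical,
                tool=tool,
                endpoint=exp.endpoint,
                lc50=None if missing else 10.0**log_pred,
                ad_status=(
                    AdStatus.UNKNOWN
                    if missing
                    else (
                        AdStatus.OUTSIDE
                        if u_ad < spec.ad_out_prob
                        else AdStatus.INSIDE
                    )
                ),
            )
        )
    return predictions
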