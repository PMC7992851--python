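# Methods

## Scope and model of the problem

`ecotoxbench` evaluates point predictions of acute aquatic toxicity — the
LC50 in mg/L for 48-h daphnia and 96-h fish exposure — against experimental
values, one (chemical, tool, endpoint) triple at a time. A prediction is a
single consolidated value with an applicability-domain (AD) flag; how each
tool's raw multi-model output collapses to that value is part of the method
and is implemented in `consolidate`. Missing predictions and non-positive
values (possible under linear-space trend extrapolation) are first-class
states: they never abort a batch run, and the metrics define exactly how
they are counted.

## GHS classification

The four GHS acute categories partition (0, ∞) with inclusive upper bounds
at 1, 10 and 100 mg/L; 100 mg/L is category 3. Boundary handling is a
genuine convention choice (the regulatory text is a table, not a function);
inclusive upper bounds follow the table's "≤" directly. Non-positive and
non-finite values are unclassifiable; the evaluation scores them as
incorrect rather than raising, because a trend extrapolation that produces
−84 mg/L is a real (failed) prediction, not a data error.

## Accuracy metrics

* `total_accuracy = 100·n_correct/(n_all − n_missing)`; undefined (absent)
  when every prediction is missing.
* `predictive_power = 100·n_correct/n_all` — missing counts as wrong, so
  total accuracy ≥ predictive power always.
* Fold accuracy at factor F: share of non-missing predictions with
  |log10(pred/exp)| ≤ log10 F, with a 1e−12 slack so an exactly 10-fold
  deviation counts as inside. Non-positive predictions stay in the
  denominator as failures (they were predictions, and they are wrong), but
  are excluded from RMSE, R² and the error distribution, whose logarithms
  they have no place in.
* R² is the squared Pearson correlation (computed on GHS class codes 1–4
  for the qualitative table and on log10 LC50 for the quantitative one);
  a coefficient-of-determination-vs-identity alternative was considered and
  rejected as the default because the summary statistic being emulated is a
  correlation. Needs ≥3 points and non-zero variance, else absent.
* Error distribution: mean and sample SD (n−1) of log10(pred) − log10(exp);
  positive = toxicity underestimated.
* Inside-AD scope recomputes everything on the subset with `ad_status =
  inside`; predictive power is only reported for the entire scope, where
  "all chemicals" has its intended meaning.

Percentages are held at full precision internally and rounded half-up to
integers (R²/RMSE to two decimals) only when a report table is written.

## Tool consolidation

ECOSAR: freshwater results only; across structural classes the minimum is
taken (conservative, consistent with the lowest-value convention used
elsewhere; a "first class" mode exists). KATE: minimum across matched
classes. Danish QSAR Database: Battery estimate first, else the lower of
Leadscope/SciQSAR. T.E.S.T.: the consensus value only when ≥2 component
methodologies contributed; a valid consensus is by construction inside the
AD.

VEGA integration proceeds stepwise: (1) a unique sub-model with 3
reliability stars and all ADI components equal to 1 wins outright; (2) else
the strictly highest global ADI; (3) else the four ADI sub-indices compared
lexicographically in the order similarity, accuracy, concordance, ACF —
the published strategy names no aggregation rule for this step, and
lexicographic comparison in the listed order is the recorded assumption;
(4) remaining ties go to the lowest LC50. Classification sub-models enter
as their band's lower limit + 0.1 mg/L (generalising the documented
"toxic-3 → 10.1 mg/L" example). "Good reliability" for the AD flag is
operationalised as stars ≥ 2, configurable, since no numeric rule is
published.

## Category engine

Categories are formed by functional-group profile; the default demands set
equality of group labels ("strict"), with a "subset" mode (analogues whose
groups are contained in the target's) because the nesting semantics of
group categorisation are underspecified. Read-across averages the k = 5
analogues nearest in |Δlog Kow| — ties break by CAS ascending for
determinism — using the geometric mean by default (toxicity is modelled
log-linearly throughout; an arithmetic mode mimics tools that average raw
concentrations). Trend analysis is OLS of log10 LC50 on log Kow
(`scipy.stats.linregress`), requiring ≥3 analogues with Kow spread; the
linear-space mode regresses raw LC50 and can extrapolate below zero, which
is deliberately preserved since real workflows produce such values. The AD
rule: target log Kow within the analogues' range and target groups covered
by the analogues' union — monotone in the analogue set by construction.

Outlier removal is expert-driven: `remove_outliers` only drops explicitly
listed CAS numbers, and `flag_outliers` (externally studentized residuals
via statsmodels, threshold 3) merely suggests candidates. A numerically
perfect fit flags nothing. The solubility screen marks an experimental LC50
implausible strictly above the water solubility, since a dissolved exposure
cannot exceed it.

## Synthetic data

The generators emulate the two input shapes: analogue databases with
log10 LC50 = intercept + slope·logKow + N(0, σ) and random group labels,
and prediction tables with log10 pred = log10 exp + bias + N(0, s), plus
independent Bernoulli missing/AD-outside events. Defaults are the study
conditions: 42 chemicals per batch (the daphnia batch size of the
confidential new-chemicals set this stands in for; the fish batch uses 82),
Kow range −1..6, slope −0.8 and intercept 2.0 (baseline-toxicity
regression magnitudes), experimental scatter 0.3, tool error 0.8 log10
units (the RMSE range real tools exhibit), missing probability 0.1 and
AD-outside probability 0.2. Each row draws from a substream seeded by
(seed, purpose, row index), so identical seeds are bit-reproducible and
enlarging a dataset appends rows without reshuffling earlier ones.

What the generators do *not* emulate: real chemistry (group co-occurrence,
structural similarity), tool-specific error shapes beyond bias/variance,
correlation between missingness and difficulty. Passing synthetic checks
therefore demonstrates the statistical machinery (estimator recovery,
analytic fold-10 accuracy 2Φ(1/s)−1, invariants), not real-world tool
rankings.

## Fixtures and the published comparison

The two validation tables (37 priority controlled chemicals × 7 tools per
endpoint) were transcribed from typeset tables in which several cells are
fused or garbled. Each affected row carries a free-text note; splits were
chosen to be typographically valid and consistent with the printed summary
counts where possible (e.g. the daphnia dichloromethane cell reads
27.01/46.0, the only split under which the ECOSAR correct count is 24), and
rows whose reading stays uncertain (fish chloroform, acetaldehyde) are
advisory. The printed summary tables themselves contain internal
inconsistencies (the T.E.S.T. inside-AD count contradicts the per-chemical
AD flags; the KATE daphnia qualitative counts cannot be derived from the
per-chemical table under any GHS reading). `published.compare_with_published`
therefore reports each cell as match / within tolerance (±3 percentage
points ≈ ±1 chemical of 37, ±0.05 on R²/RMSE) / discrepant, and discrepant
cells are listed rather than reconciled.

## Problem sizes and numerical choices

Monte-Carlo checks use n = 10⁴ pairs (fold-10 vs analytic value, binomial
3-SE bands), n = 5·10³ for error-distribution recovery, and 200 replicates
of n = 200 for slope recovery — sizes at which 3-standard-error assertions
are stable across seeds while the whole suite stays fast. Fixture
evaluation is exact arithmetic on 37 records and takes milliseconds.
Half-up decimal rounding (`decimal.ROUND_HALF_UP`) is used at the
presentation layer so 64.86 prints as 65 and 0.705 as 0.71, matching the
printed tables' conventions.

## Known limitations

* The consolidation rules operate on already-exported tool outputs; running
  the external tools is out of scope.
* Functional groups and log Kow are inputs, never computed from structures.
* The category engine's "nearest" is pure |Δlog Kow|, as documented for the
  emulated workflow; composite similarity measures are not implemented.
* Published-table agreement is limited by the source's own inconsistencies;
  the comparison report is the ground truth for which cells reproduce.
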