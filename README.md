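# ecotoxbench

Evaluation pipeline for in-silico acute aquatic toxicity predictions.

Regulators screening industrial chemicals rely on computational tools —
QSAR packages (ECOSAR, T.E.S.T., the Danish QSAR Database, VEGA, KATE) and
chemical-category approaches (read-across and trend analysis) — to predict
acute toxicity to daphnia (48-h LC50) and fish (96-h LC50) when no test
data exist. `ecotoxbench` benchmarks such predictions against experimental
values the way regulatory validation exercises do, and re-implements the
category approach itself so it can be studied on synthetic data.

## What it computes

**Qualitative scoring.** Experimental and predicted LC50 (mg/L) are binned
into the four GHS acute aquatic hazard categories (cut-offs at 1, 10 and
100 mg/L, upper bounds inclusive); a prediction is correct when it lands in
the experimental category. Two rates are reported:

    total accuracy   = n_correct / (n_all − n_missing) × 100%
    predictive power = n_correct / n_all × 100%

so a tool is penalised for declining to predict only in the second.

**Quantitative scoring.** On log10 LC50: accuracy within fold factors 10 /
100 / 1000 (|log10 pred − log10 exp| ≤ log10 F), RMSE, squared Pearson
correlation (on class codes and on log10 values), and the signed error
distribution (mean, SD, n), where positive error = toxicity underestimated.
Both scopes are computed: the entire dataset and the subset inside each
tool's applicability domain (AD).

**Tool consolidation.** Rules that reduce each tool's raw multi-model
output to the single validation value: freshwater-only minimum for ECOSAR,
lowest value for KATE, battery-first for the Danish database, ≥2-method
consensus for T.E.S.T., and the stepwise VEGA integration over sub-models
driven by reliability stars and the Applicability Domain Index (ADI), with
class outputs mapped to their band's lower limit + 0.1 mg/L.

**Category engine.** Read-across (geometric mean of the 5 analogues nearest
in log Kow) and trend analysis (OLS of log10 LC50 on log Kow across the
functional-group category), with the Kow-range + group-coverage AD rule,
expert-driven outlier removal with a studentized-residual flagger, and a
water-solubility plausibility screen for experimental values.

**Fixtures.** The published validation tables for 37 priority controlled
chemicals (daphnia and fish, seven tools each) ship as CSV fixtures,
together with the published summary tables; `ecotoxbench.published`
recomputes every summary cell and lists agreement cell-by-cell.
Typographically fused cells of the typeset source are note-flagged in the
fixtures.

## Worked example

```python
from ecotoxbench import (
    Endpoint, Scope, Tool, evaluate_tool, load_pcc_fixture, make_pairs,
)

predictions, experiments = load_pcc_fixture(Endpoint.DAPHNIA_48H)
pairs = make_pairs(experiments, predictions, Tool.ECOSAR)
report = evaluate_tool(pairs, scope=Scope.ENTIRE, tool=Tool.ECOSAR)
print(report.n_correct, round(report.total_accuracy_pct, 1))
print({f: round(v, 1) for f, v in report.fold_accuracy_pct.items()})
```

prints

```
24 64.9
{10: 78.4, 100: 86.5, 1000: 97.3}
```

ECOSAR assigns 24 of the 37 daphnia chemicals to the correct GHS category
(total accuracy 64.9%, printed as 65%), and 86.5% / 97.3% of its
predictions fall within a factor of 100 / 1000 of the measured LC50.

The same run from the shell:

```bash
ecotoxbench evaluate --endpoint daphnia --scope all --out results/
ecotoxbench report --published --out results/   # + published-table comparison
ecotoxbench classify -- 1.68 45.7 -84.0
```

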