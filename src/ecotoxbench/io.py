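"""CSV readers/writers and packaged validation fixtures.

The prediction-table schema is one row per chemical::

    cas,name,exp_lc50,<tool>_lc50,<tool>_ad,...,note

with tool column prefixes ``ecosar, test, danish, vega, read_across,
trend_analysis, kate``.  Empty cells and ``NA`` mean a missing prediction;
AD cells hold ``In``/``Out`` (``NA``/empty = unknown).  Values are stored
with a period decimal separator in UTF-8.  A free-text ``note`` column
records known typographic ambiguities of the printed source tables so that
affected rows can be excluded explicitly.

Two packaged fixtures, ``pcc_daphnia`` and ``pcc_fish``, hold the printed
validation tables for the 37 priority controlled chemicals (48-h daphnia
and 96-h fish LC50, seven tools each); ``ghs_criteria``, ``solubility`` and
the ``published_*`` summary tables accompany them.
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .category import AnalogueRecord
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

#: column prefix -> tool, in the layout order of the printed tables
TOOL_COLUMNS: tuple[tuple[str, Tool], ...] = (
    ("ecosar", Tool.ECOSAR),
    ("test", Tool.TEST),
    ("danish", Tool.DANISH),
    ("vega", Tool.VEGA),
    ("read_across", Tool.READ_ACROSS),
    ("trend_analysis", Tool.TREND_ANALYSIS),
    ("kate", Tool.KATE),
)

_MISSING_TOKENS = {"", "na", "nan", "none"}

_AD_TO_TOKEN = {AdStatus.INSIDE: "In", AdStatus.OUTSIDE: "Out", AdStatus.UNKNOWN: "NA"}


class DataFormatError(ValueError):
    """A cell of an input table could not be interpreted."""


def _parse_float(
    text: str, row: int, column: str, allow_missing: bool
) -> float | None:
    stripped = text.strip()
    if stripped.lower() in _MISSING_TOKENS:
        if allow_missing:
            return None
        raise DataFormatError(f"row {row}: column {column!r} must hold a value")
    try:
        return float(stripped.replace("−", "-"))  # tolerate unicode minus
    except ValueError:
        raise DataFormatError(
            f"row {row}: column {column!r} holds non-numeric value {text!r}"
        ) from None


def _parse_ad(text: str, row: int, column: str) -> AdStatus:
    token = text.strip().lower()
    if token == "in":
        return AdStatus.INSIDE
    if token == "out":
        return AdStatus.OUTSIDE
    if token in _MISSING_TOKENS:
        return AdStatus.UNKNOWN
    raise DataFormatError(
        f"row {row}: column {column!r} holds unknown AD flag {text!r}"
    )


def load_predictions(
    path: str | Path, endpoint: Endpoint = Endpoint.DAPHNIA_48H
) -> tuple[list[ToolPrediction], list[ExperimentalToxicity]]:
    """Read a prediction table; returns (predictions, experiments).

    Only tool columns present in the header are read, so partial tables
    (a single tool) load fine.  Errors name the offending row and column.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"cas", "name", "exp_lc50"}
    if not required <= set(frame.columns):
        raise DataFormatError(
            f"{path}: header must contain {sorted(required)}, got "
            f"{list(frame.columns)}"
        )
    tools_present = [
        (prefix, tool)
        for prefix, tool in TOOL_COLUMNS
        if f"{prefix}_lc50" in frame.columns
    ]
    has_note = "note" in frame.columns

    predictions: list[ToolPrediction] = []
    experiments: list[ExperimentalToxicity] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2  # 1-based with header line
        cas = row["cas"].strip()
        if not cas:
            raise DataFormatError(f"row {rownum}: empty CAS number")
        if cas in seen:
            raise DataFormatError(f"row {rownum}: duplicate CAS number {cas}")
        seen.add(cas)
        chem = ChemicalRecord(cas_number=cas, name=row["name"].strip())
        exp_value = _parse_float(row["exp_lc50"], rownum, "exp_lc50", False)
        experiments.append(
            ExperimentalToxicity(chemical=chem, endpoint=endpoint, lc50=exp_value)
        )
        note = row["note"].strip() if has_note else ""
        for prefix, tool in tools_present:
            value = _parse_float(row[f"{prefix}_lc50"], rownum, f"{prefix}_lc50", True)
            ad_col = f"{prefix}_ad"
            ad = (
                _parse_ad(row[ad_col], rownum, ad_col)
                if ad_col in frame.columns
                else AdStatus.UNKNOWN
            )
            predictions.append(
                ToolPrediction(
                    chemical=chem,
                    tool=tool,
                    endpoint=endpoint,
                    lc50=value,
                    ad_status=ad,
                    note=note,
                )
            )
    return predictions, experiments


def _format_value(value: float | None) -> str:
    if value is None:
        return "NA"
    return format(value, "g")


def write_predictions(
    predictions: Sequence[ToolPrediction],
    experiments: Sequence[ExperimentalToxicity],
    path: str | Path,
) -> None:
    """Inverse of :func:`load_predictions`; round-trips values and AD flags."""
    by_chem: dict[str, dict[Tool, ToolPrediction]] = {}
    for p in predictions:
        by_chem.setdefault(p.chemical.cas_number, {})[p.tool] = p
    rows = []
    for e in experiments:
        cell: dict[str, str] = {
            "cas": e.chemical.cas_number,
            "name": e.chemical.name,
            "exp_lc50": _format_value(e.lc50),
        }
        note = ""
        for prefix, tool in TOOL_COLUMNS:
            p = by_chem.get(e.chemical.cas_number, {}).get(tool)
            cell[f"{prefix}_lc50"] = _format_value(None if p is None else p.lc50)
            cell[f"{prefix}_ad"] = _AD_TO_TOKEN[
                AdStatus.UNKNOWN if p is None else p.ad_status
            ]
            if p is not None and p.note:
                note = p.note
        cell["note"] = note
        rows.append(cell)
    pd.DataFrame(rows).to_csv(path, index=False)


# --- report tables -------------------------------------------------------

#: metric key -> printed row label, in table order
REPORT_ROWS: tuple[tuple[str, str], ...] = (
    ("n_missing", "Number of missing predictions"),
    ("n_inside_ad", "Number of inside AD"),
    ("n_outside_or_missing", "Number of outside AD and missing prediction"),
    ("n_correct", "Number of correct"),
    ("n_incorrect", "Number of incorrect"),
    ("total_accuracy_pct", "Total accuracy (%)"),
    ("predictive_power_pct", "Predictive power (%)"),
    ("r2_class", "R2 (toxicity class)"),
    ("fold10_pct", "Accuracy within a factor of 10 (%)"),
    ("fold100_pct", "Accuracy within a factor of 100 (%)"),
    ("fold1000_pct", "Accuracy within a factor of 1000 (%)"),
    ("rmse_log10", "RMSE (log10)"),
    ("r2_log10", "R2 (log10 LC50)"),
    ("error_mean", "Error mean (log10)"),
    ("error_sd", "Error SD (log10)"),
    ("error_n", "Error N"),
)


def round_half_up(value: float, digits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def report_cells(report: EvaluationReport) -> dict[str, float | int | None]:
    """Flatten a report into the metric keys used by the table layout."""
    inside_scope = report.scope is Scope.INSIDE_AD
    cells: dict[str, float | int | None] = {
        "n_missing": None if inside_scope else report.n_missing,
        "n_inside_ad": report.n_inside_ad if inside_scope else None,
        "n_outside_or_missing": (
            report.n_all - report.n_inside_ad
            if inside_scope and report.n_inside_ad is not None
            else None
        ),
        "n_correct": report.n_correct,
        "n_incorrect": report.n_incorrect,
        "total_accuracy_pct": report.total_accuracy_pct,
        "predictive_power_pct": report.predictive_power_pct,
        "r2_class": report.r2_class,
        "rmse_log10": report.rmse_log10,
        "r2_log10": report.r2_log10,
        "error_mean": report.error_mean,
        "error_sd": report.error_sd,
        "error_n": report.error_n,
    }
    for factor, value in report.fold_accuracy_pct.items():
        cells[f"fold{factor}_pct"] = value
    return cells


def _render(metric: str, value: float | int | None) -> str:
    if value is None:
        return ""
    if metric.startswith("n_") or metric == "error_n":
        return str(int(value))
    if metric.endswith("_pct"):
        return str(int(round_half_up(value)))
    return f"{round_half_up(value, 2):.2f}"


def write_report(reports: Sequence[EvaluationReport], path: str | Path) -> None:
    """Write reports as a metric-per-row, tool-per-column CSV table.

    Percentages are rounded half-up to integers and RMSE/R2 to two decimals
    at this presentation step only.
    """
    if not reports:
        raise ValueError("no reports to write")
    tools = [r.tool for r in reports]
    if len(set(tools)) != len(tools):
        raise ValueError("one report per tool expected")
    all_cells = {r.tool: report_cells(r) for r in reports}
    rows = []
    for metric, label in REPORT_ROWS:
        if all(all_cells[t].get(metric) is None for t in tools):
            continue  # e.g. RMSE rows absent from entire-dataset tables
        rows.append(
            {
                "metric": label,
                **{
                    t.value: _render(metric, all_cells[t].get(metric))
                    for t in tools
                },
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# --- analogue databases --------------------------------------------------


def load_analogue_db(path: str | Path) -> list[AnalogueRecord]:
    """Read an analogue database CSV.

    Schema: ``cas,name,log_kow,groups,lc50,source_db`` with groups
    semicolon-delimited.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 2
        groups = frozenset(
            g.strip() for g in row["groups"].split(";") if g.strip()
        )
        chem = ChemicalRecord(
            cas_number=row["cas"].strip(),
            name=row.get("name", "").strip(),
            log_kow=_parse_float(row["log_kow"], rownum, "log_kow", False),
            functional_groups=groups,
        )
        records.append(
            AnalogueRecord(
                chemical=chem,
                lc50=_parse_float(row["lc50"], rownum, "lc50", False),
                source_db=row.get("source_db", "").strip(),
            )
        )
    return records


def write_analogue_db(records: Sequence[AnalogueRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cas": a.chemical.cas_number,
                "name": a.chemical.name,
                "log_kow": format(a.chemical.log_kow, "g"),
                "groups": ";".join(sorted(a.chemical.functional_groups or ())),
                "lc50": format(a.lc50, "g"),
                "source_db": a.source_db,
            }
            for a in records
        ]
    ).to_csv(path, index=False)


# --- packaged fixtures ---------------------------------------------------

_ENDPOINT_FIXTURE = {
    Endpoint.DAPHNIA_48H: "pcc_daphnia.csv",
    Endpoint.FISH_96H: "pcc_fish.csv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV (without extension)."""
    candidate = resources.files("ecotoxbench").joinpath("fixtures", f"{name}.csv")
    with resources.as_file(candidate) as concrete:
        return Path(concrete)


def load_pcc_fixture(
    endpoint: Endpoint,
) -> tuple[list[ToolPrediction], list[ExperimentalToxicity]]:
    """The packaged 37-chemical validation table for one endpoint."""
    name = _ENDPOINT_FIXTURE[Endpoint(endpoint)]
    return load_predictions(fixture_path(name[:-4]), endpoint=Endpoint(endpoint))


def load_solubility() -> pd.DataFrame:
    """Water solubilities for the frequently mispredicted chemicals."""
    return pd.read_csv(fixture_path("solubility"))


def load_ghs_criteria() -> pd.DataFrame:
    return pd.read_csv(fixture_path("ghs_criteria"))
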