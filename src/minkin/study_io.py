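"""Study I/O: curve CSV schema, fit-table rendering and Markdown reports.

Curves travel in a long (tidy) CSV with columns
``soil,treatment,replicate,time_d,cum_pct`` (comma separator, dot decimal,
UTF-8).  Fit tables replicate the conventional kinetics summary layout:
one row per soil × treatment with the selected model, its parameters,
DT50, the observed extent of mineralization and the chi-square error
percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitOutcome
from .models import ModelId
from .simulate import ConfigError, MineralizationCurve

__all__ = [
    "ValidationError",
    "CURVE_COLUMNS",
    "FitReportRow",
    "read_curves_csv",
    "write_curves_csv",
    "fit_report_rows",
    "write_fit_table",
    "write_markdown_report",
]

CURVE_COLUMNS = ("soil", "treatment", "replicate", "time_d", "cum_pct")

DASH = "-"
INF_SENTINEL = ">10^7"

#: tolerated cumulative decrease (%) before a file is rejected
MONOTONE_TOL = 0.5


class ValidationError(ValueError):
    """Input file violates the curve schema or trap physics."""


def read_curves_csv(path) -> list[MineralizationCurve]:
    """Load and validate mineralization curves from a long-format CSV.

    Replicates need not be balanced (missing times become NaN cells).
    Raises :class:`ValidationError` listing the offending rows for
    duplicate measurements, out-of-range percentages, or cumulative values
    that decrease by more than 0.5%.
    """
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df.loc[:, list(CURVE_COLUMNS)].copy()

    key = ["soil", "treatment", "replicate", "time_d"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        raise ValidationError(
            "duplicate (soil,treatment,replicate,time_d) rows: "
            f"{df.index[dup].tolist()}"
        )
    bad_range = (df["cum_pct"] < 0) | (df["cum_pct"] > 100)
    if bad_range.any():
        raise ValidationError(
            f"cum_pct outside [0, 100] at rows {df.index[bad_range].tolist()}"
        )

    bad_rows: list[int] = []
    for _, grp in df.groupby(["soil", "treatment", "replicate"], sort=False):
        grp = grp.sort_values("time_d")
        drops = grp["cum_pct"].diff()
        bad = grp.index[drops < -MONOTONE_TOL]
        bad_rows.extend(bad.tolist())
    if bad_rows:
        raise ValidationError(
            f"cumulative values decrease by more than {MONOTONE_TOL}% at rows "
            f"{sorted(bad_rows)}"
        )

    curves = []
    for (soil, trt), grp in df.groupby(["soil", "treatment"], sort=True):
        wide = grp.pivot(index="replicate", columns="time_d", values="cum_pct")
        wide = wide.sort_index(axis=0).sort_index(axis=1)
        curves.append(
            MineralizationCurve(
                soil=str(soil),
                treatment=str(trt),
                times=wide.columns.to_numpy(dtype=float),
                values=wide.to_numpy(dtype=float),
                provenance="file",
            )
        )
    return curves


def write_curves_csv(curves: Iterable[MineralizationCurve], path) -> None:
    """Serialize curves to the long CSV schema (round-trips with the reader)."""
    records = []
    for curve in curves:
        for r in range(curve.replicates):
            for t, v in zip(curve.times, curve.values[r]):
                if not np.isnan(v):
                    records.append((curve.soil, curve.treatment, r + 1, t, v))
    df = pd.DataFrame.from_records(records, columns=CURVE_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fit-table rendering


@dataclass(frozen=True)
class FitReportRow:
    """One rendered summary row: soil, treatment, selected model and endpoints."""

    soil: str
    treatment: str
    kinetic_model: str
    k1: str
    k2: str
    tb: str
    alpha: str
    beta: str
    dt50: str
    extent_pct: str
    chi2_error_pct: str


def _fmt_rate(value: Optional[float]) -> str:
    if value is None:
        return DASH
    return f"{value:.1e}"


def _fmt_dt(value: float) -> str:
    if math.isinf(value):
        return INF_SENTINEL
    if value >= 100:
        return f"{value:.0f}"
    return f"{value:.1f}"


def fit_report_rows(outcomes: Sequence[FitOutcome]) -> list[FitReportRow]:
    """Render batch-fit outcomes as formatted table rows.

    Parameters not used by the selected model print as a dash; rates and
    shape/location parameters use two significant figures in scientific
    notation; DT50 prints as whole days above 100 d, one decimal below,
    and ``>10^7`` when unreachable.  Rows are ordered by soil then
    treatment.  Curves whose fits all failed render dashes throughout.
    """
    rows = []
    for out in sorted(outcomes, key=lambda o: (o.soil, o.treatment)):
        if out.selected is None:
            rows.append(
                FitReportRow(out.soil, out.treatment, "failed", *([DASH] * 8))
            )
            continue
        fit = out.selected
        p = fit.params
        rows.append(
            FitReportRow(
                soil=out.soil,
                treatment=out.treatment,
                kinetic_model=p.model_id.value,
                k1=_fmt_rate(p.k1),
                k2=_fmt_rate(p.k2),
                tb=DASH if p.tb is None else f"{p.tb:.1f}",
                alpha=_fmt_rate(p.alpha),
                beta=_fmt_rate(p.beta),
                dt50=_fmt_dt(fit.dt50.value),
                extent_pct=f"{fit.extent_observed:.1f}",
                chi2_error_pct=f"{fit.chi2_error_pct:.1f}",
            )
        )
    return rows


_TABLE_HEADER = [
    "soil",
    "treatment",
    "kinetic_model",
    "k1_per_d",
    "k2_per_d",
    "tb_d",
    "alpha",
    "beta_d",
    "dt50_d",
    "extent_pct",
    "chi2_error_pct",
]


def write_fit_table(rows: Sequence[FitReportRow], path, format: str = "csv") -> None:
    """Write rendered fit rows as CSV or a Markdown pipe table."""
    df = pd.DataFrame([row.__dict__ for row in rows])
    df.columns = _TABLE_HEADER[: len(df.columns)] if len(df) else _TABLE_HEADER
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "markdown":
        lines = ["| " + " | ".join(_TABLE_HEADER) + " |"]
        lines.append("|" + "|".join(["---"] * len(_TABLE_HEADER)) + "|")
        for row in rows:
            lines.append("| " + " | ".join(row.__dict__.values()) + " |")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_markdown_report(
    curves: Sequence[MineralizationCurve],
    outcomes: Sequence[FitOutcome],
    path,
    assay_tables: Optional[dict[str, pd.DataFrame]] = None,
) -> None:
    """Per-soil Markdown report: extent and DT50 ranking across treatments.

    ``assay_tables`` (name -> DataFrame) are appended verbatim, e.g. CFU
    counts or extractability percentages.
    """
    by_key = {(o.soil, o.treatment): o for o in outcomes}
    lines = ["# Mineralization kinetics report", ""]
    for soil in sorted({c.soil for c in curves}):
        lines.append(f"## Soil {soil}")
        lines.append("")
        lines.append("| treatment | model | extent (%) | DT50 (d) | chi2 err (%) |")
        lines.append("|---|---|---|---|---|")
        ranked = []
        for curve in sorted(
            (c for c in curves if c.soil == soil), key=lambda c: c.treatment
        ):
            out = by_key.get((curve.soil, curve.treatment))
            if out is None or out.selected is None:
                lines.append(f"| {curve.treatment} | failed | - | - | - |")
                continue
            fit = out.selected
            lines.append(
                f"| {curve.treatment} | {fit.params.model_id.value} "
                f"| {fit.extent_observed:.1f} | {_fmt_dt(fit.dt50.value)} "
                f"| {fit.chi2_error_pct:.1f} |"
            )
            ranked.append((fit.dt50.value, curve.treatment))
        if ranked:
            ranked.sort()
            order = " < ".join(trt for _, trt in ranked)
            lines.append("")
            lines.append(f"DT50 ranking (fastest first): {order}")
        lines.append("")
    if assay_tables:
        for name, df in assay_tables.items():
            lines.append(f"## {name}")
            lines.append("")
            lines.append("| " + " | ".join(map(str, df.columns)) + " |")
            lines.append("|" + "|".join(["---"] * len(df.columns)) + "|")
            for _, row in df.iterrows():
                lines.append("| " + " | ".join(str(v) for v in row) + " |")
            lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
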