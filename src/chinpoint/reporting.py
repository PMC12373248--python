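"""Result serialization: per-table CSVs, a JSON summary and a markdown report."""

from __future__ import annotations

import json
from pathlib import Path

from .errors import ValidationError
from .lips import LIP_VARIABLES
from .stats import CohortResults

__all__ = ["write_results", "render_report", "RESULT_TABLES"]

RESULT_TABLES = ("table2", "table3", "table4", "table5", "correlations", "normality")

_VARIABLE_LABELS = {
    "ul_s": "UL / S line",
    "ul_e": "UL / E line",
    "ll_s": "LL / S line",
    "ll_e": "LL / E line",
}


def write_results(results: CohortResults, path: str | Path) -> list[Path]:
    """Write one CSV per output table plus ``summary.json`` into ``path``.

    Numbers are written at full (shortest round-trip) precision; rounding
    for human consumption happens only in :func:`render_report`.  Output
    is deterministic: fixed table and column order, fixed row sort.
    """
    if results.table2.empty:
        raise ValidationError("no paired subjects: nothing to write")
    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create results directory {outdir}: {exc}") from exc
    written = []
    for name in RESULT_TABLES + ("measurements",):
        df = getattr(results, name)
        target = outdir / f"{name}.csv"
        df.to_csv(target, index=False, lineterminator="\n")
        written.append(target)
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(results.summary, indent=1, sort_keys=True) + "\n")
    written.append(summary_path)
    return written


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_report(results: CohortResults) -> str:
    """Human-readable markdown report (rounded to 2 decimals)."""
    s = results.summary
    lines = [
        "# Modified chin point validation report",
        "",
        f"Subjects: {s['n_subjects']} ({s['n_male']} male, {s['n_female']} female); "
        f"QC-excluded: {len(s['qc_excluded'])}",
        f"Target convexity angle: {s['target_angle_deg']} deg; distance mode: "
        f"{s['distance_mode']}; significance threshold p < "
        f"{s['significance_threshold']} ({s['bonferroni_mode']} mode)",
        "",
        "## Lip positions, ACP vs MCP (mm)",
        "",
        "| timepoint | variable | ACP mean ± SD | MCP mean ± SD | p |",
        "|---|---|---|---|---|",
    ]
    for r in results.table2.itertuples(index=False):
        lines.append(
            f"| {r.timepoint} | {_VARIABLE_LABELS[r.variable]} | "
            f"{_fmt(r.acp_mean)} ± {_fmt(r.acp_sd)} | "
            f"{_fmt(r.mcp_mean)} ± {_fmt(r.mcp_sd)} | {r.p:.3g} |"
        )
    lines += [
        "",
        "## ACP-to-MCP distance |x| (mm)",
        "",
        "| timepoint | mean ± SD | median | IQR | Wilcoxon p |",
        "|---|---|---|---|---|",
    ]
    for r in results.table3.itertuples(index=False):
        lines.append(
            f"| {r.timepoint} | {_fmt(r.mean)} ± {_fmt(r.sd)} | {_fmt(r.median)} | "
            f"{_fmt(r.iqr25)}–{_fmt(r.iqr75)} | {r.wilcoxon_p:.3g} |"
        )
    lines += [
        "",
        "## Method agreement at T1 (ACP − MCP, mm)",
        "",
        "| variable | ME mean ± SD | ME range | MAE mean ± SD | MAE range |",
        "|---|---|---|---|---|",
    ]
    for r in results.table4.itertuples(index=False):
        lines.append(
            f"| {_VARIABLE_LABELS[r.variable]} | {_fmt(r.me_mean)} ± {_fmt(r.me_sd)} | "
            f"{_fmt(r.me_min)} … {_fmt(r.me_max)} | "
            f"{_fmt(r.mae_mean)} ± {_fmt(r.mae_sd)} | "
            f"{_fmt(r.mae_min)} … {_fmt(r.mae_max)} |"
        )
    lines += [
        "",
        "## Post-surgery MCP-based lip positions by sex (mm)",
        "",
        "| variable | male mean ± SD | female mean ± SD | Welch p |",
        "|---|---|---|---|",
    ]
    for r in results.table5.itertuples(index=False):
        lines.append(
            f"| {_VARIABLE_LABELS[r.variable]} | {_fmt(r.male_mean)} ± "
            f"{_fmt(r.male_sd)} | {_fmt(r.female_mean)} ± {_fmt(r.female_sd)} | "
            f"{r.p:.3g} |"
        )
    lines += [
        "",
        "## Correlations",
        "",
        "| variable | r (ACP T1 vs MCP T1) | r (MCP T0 vs MCP T1) |",
        "|---|---|---|",
    ]
    for r in results.correlations.itertuples(index=False):
        lines.append(
            f"| {_VARIABLE_LABELS[r.variable]} | {r.acp_t1_vs_mcp_t1_r:.3f} | "
            f"{r.mcp_t0_vs_mcp_t1_r:.3f} |"
        )
    window = s["aesthetic_window_mm"]
    lines += ["", f"## Aesthetic window (|d| ≤ {window} mm), T1 MCP-based", ""]
    for var in LIP_VARIABLES:
        frac = s["aesthetic_within_fraction_t1_mcp"][var]
        lines.append(f"- {_VARIABLE_LABELS[var]}: {100 * frac:.0f}% of subjects within")
    lines.append("")
    return "\n".join(lines)
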