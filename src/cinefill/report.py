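"""Human-readable rendering of diagnostic performance tables."""

from __future__ import annotations

from .classify import DiagnosticReport, PerformanceMetrics

_COLUMNS = ("Sensitivity", "Specificity", "Accuracy", "PPV", "NPV")

_GRADE_TITLES = {
    "grade1": "GRADE 1 (mild)",
    "grade2": "GRADE 2 (moderate)",
    "grade3": "GRADE 3 (severe)",
}

_INDEX_TITLES = {
    "dvr80": "Diastolic Volume Recovery80",
    "tpfr": "Time to Peak Filling Rate",
    "pfr": "Peak Filling Rate",
    "npfr": "Normalized Peak Filling Rate",
}

_THRESHOLD_UNITS = {"dvr80": "%", "tpfr": " msec", "pfr": " ml/sec", "npfr": "/sec"}


def format_cell(numerator: int, denominator: int) -> str:
    """Render one table cell as ``NN% (a/b)``; absent when b == 0."""
    from .classify import round_half_up

    if denominator == 0:
        return "-"
    return f"{round_half_up(100.0 * numerator / denominator)}% ({numerator}/{denominator})"


def cells_for_metrics(perf: PerformanceMetrics) -> dict[str, str]:
    m = perf.matrix
    return {
        "Sensitivity": format_cell(m.tp, m.tp + m.fn),
        "Specificity": format_cell(m.tn, m.tn + m.fp),
        "Accuracy": format_cell(m.tp + m.tn, m.total),
        "PPV": format_cell(m.tp, m.tp + m.fp),
        "NPV": format_cell(m.tn, m.tn + m.fn),
    }


def render_performance_table(report: DiagnosticReport) -> str:
    """Format a diagnostic report in the per-grade threshold/metrics layout."""
    header = ["Index", "Threshold", *_COLUMNS]
    lines: list[str] = []
    widths = [30, 12, 14, 14, 14, 14, 14]

    def fmt_row(cells: list[str]) -> str:
        return "  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip()

    lines.append(fmt_row(header))
    if report.entries.empty:
        return "\n".join(lines)
    for grade in ("grade1", "grade2", "grade3"):
        block = report.entries[report.entries["grade"] == grade]
        if block.empty:
            continue
        lines.append(_GRADE_TITLES.get(grade, grade.upper()))
        for _, row in block.iterrows():
            perf = report.metrics(grade, row["index"])
            cells = cells_for_metrics(perf)
            threshold = f"{row['threshold']:g}{_THRESHOLD_UNITS.get(row['index'], '')}"
            lines.append(
                fmt_row(
                    [
                        _INDEX_TITLES.get(row["index"], row["index"]),
                        threshold,
                        *[cells[c] for c in _COLUMNS],
                    ]
                )
            )
    return "\n".join(lines)
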