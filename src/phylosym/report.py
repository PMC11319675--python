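"""Plain-text and HTML rendering of a pipeline results directory."""

from __future__ import annotations

import html as html_mod
from pathlib import Path
from typing import List, Tuple

import pandas as pd


def _read(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def render_report(results_dir) -> Tuple[str, str]:
    """Render stage counts and result tables (sorted by p-value, stable).

    Returns (plain_text, html). Missing tables are skipped; empty tables
    render with zero rows.
    """
    d = Path(results_dir)
    sections: List[Tuple[str, pd.DataFrame]] = []

    lines: List[str] = ["# phylosym run report", ""]
    summary = d / "summary.txt"
    if summary.exists():
        lines.append("## Stage counts")
        lines.extend(
            line.replace("\t", ": ")
            for line in summary.read_text(encoding="utf-8").splitlines()
        )
        lines.append("")

    for name, title, sort_key in (
        ("function_enrichment", "Function enrichment (lifestyle)", "p_boot"),
        ("group_enrichment", "BGC-group enrichment (lifestyle)", "p_boot"),
        ("count_enrichment", "BGC-count enrichment (lifestyle)", "p_boot"),
        ("dstat", "Phylogenetic signal (D statistic)", "p_random"),
    ):
        path = d / f"{name}.tsv"
        if not path.exists():
            continue
        df = _read(path)
        if sort_key in df.columns:
            df = df.sort_values(sort_key, kind="stable", na_position="last")
        sections.append((title, df))
        lines.append(f"## {title} ({len(df)} rows)")
        lines.append(df.to_string(index=False) if len(df) else "(no rows)")
        lines.append("")

    text = "\n".join(lines)

    parts = ["<html><head><title>phylosym report</title></head><body>",
             "<h1>phylosym run report</h1>"]
    if summary.exists():
        parts.append("<h2>Stage counts</h2><pre>")
        parts.append(html_mod.escape(summary.read_text(encoding="utf-8")))
        parts.append("</pre>")
    for title, df in sections:
        parts.append(f"<h2>{html_mod.escape(title)} ({len(df)} rows)</h2>")
        parts.append(df.to_html(index=False))
    parts.append("</body></html>")
    return text, "\n".join(parts)
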