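"""Render QC run statistics as formatted text, TSV and a consolidated
HTML report, plus the chart images behind it.

All three renderings are generated from the same :class:`QCRunStats`
record, so they are value-consistent by construction; the TSV form is
strictly one ``section TAB key TAB value`` record per line and can be
parsed back losslessly.  Charts plot the series held in a
:class:`DistributionSet` directly — golden tests compare the data series,
not pixels.
"""

from __future__ import annotations

import html
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .illumina_pipeline import QCRunStats
from .stats import DistributionSet

SECTION_PARAMETERS = "Parameters"
SECTION_QC = "QC statistics"
SECTION_DETAILED = "Detailed QC statistics"

_STAGE_LABELS = {
    "low_quality": "Reads discarded: low quality",
    "adaptor": "Reads discarded: primer/adaptor contamination",
    "short_input": "Reads removed: shorter than length cutoff",
    "homopolymer_trim_short": "Reads removed: short after homopolymer trimming",
    "adaptor_trim_short": "Reads removed: short after adaptor trimming",
}

CHART_NAMES = (
    "per_position_quality",
    "gc_distribution",
    "quality_distribution",
    "base_composition",
    "length_distribution",
    "quality_range_per_position",
    "summary_pie",
)


def _pct(part: int, whole: int) -> str:
    return f"{(100.0 * part / whole if whole else 0.0):.2f}"


def _qc_rows(stats: QCRunStats) -> List[Tuple[str, str, str]]:
    """(label, count, percent-of-input) triples for the QC section."""
    rows = [("Input reads", str(stats.input_reads), "100.00" if stats.input_reads else "0.00")]
    if stats.pairs_in:
        rows.append(("Input pairs", str(stats.pairs_in), ""))
    for stage, count in stats.stage_counts.items():
        label = _STAGE_LABELS.get(stage, f"Reads removed: {stage}")
        rows.append((label, str(count), _pct(count, stats.input_reads)))
    rows.append(("HQ filtered reads", str(stats.hq_reads), _pct(stats.hq_reads, stats.input_reads)))
    if stats.pairs_in:
        rows.append(
            ("Surviving pairs", str(stats.paired_surviving),
             _pct(stats.paired_surviving, stats.pairs_in))
        )
        rows.append(
            ("Unpaired surviving reads", str(stats.unpaired_surviving),
             _pct(stats.unpaired_surviving, stats.input_reads))
        )
    return rows


def _detailed_rows(stats: QCRunStats) -> List[Tuple[str, str, str]]:
    inp = stats.input_stats.as_rows()
    out = stats.output_stats.as_rows()
    return [(label, str(v_in), str(v_out)) for (label, v_in), (_, v_out) in zip(inp, out)]


def render_text_report(stats: QCRunStats, style: str = "formatted") -> str:
    """The three report tables as text.

    ``style='formatted'`` is human-readable; ``style='tab'`` emits one
    ``section<TAB>key<TAB>value...`` record per line for machine parsing
    (see :func:`parse_tab_report`).
    """
    if style not in ("formatted", "tab"):
        raise ValueError(f"unknown style {style!r}")
    lines: List[str] = []
    tab = style == "tab"

    def section(title: str, rows: Sequence[Tuple], header: Optional[Tuple] = None):
        if tab:
            for row in rows:
                lines.append("\t".join([title, *map(str, row)]))
        else:
            lines.append(title)
            lines.append("-" * len(title))
            if header:
                rows = [header, *rows]
            width = max((len(str(r[0])) for r in rows), default=0)
            for row in rows:
                first, *rest = row
                lines.append("  ".join([str(first).ljust(width), *map(str, rest)]))
            lines.append("")

    section(SECTION_PARAMETERS, list(stats.parameters.items()))
    section(SECTION_QC, _qc_rows(stats), header=("Step", "Reads", "% of input"))
    section(SECTION_DETAILED, _detailed_rows(stats), header=("Statistic", "Input", "HQ filtered"))
    return "\n".join(lines) + "\n"


def parse_tab_report(text: str) -> Dict[str, Dict[str, List[str]]]:
    """Parse the TSV rendering back into ``{section: {key: values}}``."""
    out: Dict[str, Dict[str, List[str]]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        section, key, *values = line.split("\t")
        out.setdefault(section, {})[key] = values
    return out


def render_html_report(
    stats: QCRunStats,
    distributions: Optional[DistributionSet] = None,
    image_paths: Sequence = (),
    title: str = "QC report",
) -> str:
    """Self-contained HTML report: the three tables plus chart images.

    Static markup with inline CSS only — no scripts, no external assets
    beyond the referenced images.
    """

    def table(rows: Sequence[Tuple], header: Optional[Tuple] = None) -> str:
        parts = ["<table>"]
        if header:
            parts.append(
                "<tr>" + "".join(f"<th>{html.escape(str(h))}</th>" for h in header) + "</tr>"
            )
        for row in rows:
            parts.append(
                "<tr>" + "".join(f"<td>{html.escape(str(c))}</td>" for c in row) + "</tr>"
            )
        parts.append("</table>")
        return "\n".join(parts)

    body = [
        f"<h1>{html.escape(title)}</h1>",
        f"<h2>{SECTION_PARAMETERS}</h2>",
        table(list(stats.parameters.items())),
        f"<h2>{SECTION_QC}</h2>",
        table(_qc_rows(stats), ("Step", "Reads", "% of input")),
        f"<h2>{SECTION_DETAILED}</h2>",
        table(_detailed_rows(stats), ("Statistic", "Input", "HQ filtered")),
    ]
    if image_paths:
        body.append("<h2>Charts</h2>")
        for p in image_paths:
            body.append(f'<img src="{html.escape(str(p))}" alt="{html.escape(Path(str(p)).stem)}">')
    css = (
        "body{font-family:sans-serif;margin:2em}"
        "table{border-collapse:collapse;margin-bottom:1.5em}"
        "td,th{border:1px solid #999;padding:2px 8px;text-align:left}"
        "th{background:#eee}img{max-width:45%;margin:4px}"
    )
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title><style>{css}</style></head>\n<body>\n"
        + "\n".join(body)
        + "\n</body></html>\n"
    )


def plot_distributions(
    distributions: DistributionSet,
    out_dir,
    stats: Optional[QCRunStats] = None,
    prefix: str = "qc",
) -> List[Path]:
    """Write one PNG per chart; returns the paths (deterministic names).

    The summary pie needs ``stats`` and is skipped without it.  A missing
    plotting backend degrades to a warning and an empty list, never a
    crash.
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception as exc:  # pragma: no cover - backend-less hosts
        warnings.warn(f"plotting backend unavailable ({exc}); no charts written")
        return []

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d = distributions
    paths: List[Path] = []

    def save(fig, name: str) -> None:
        path = out_dir / f"{prefix}_{name}.png"
        fig.savefig(path, dpi=90)
        plt.close(fig)
        paths.append(path)

    positions = range(1, len(d.per_position_mean_quality) + 1)

    fig, ax = plt.subplots()
    ax.plot(positions, d.per_position_mean_quality, color="tab:green")
    ax.set(xlabel="Base position", ylabel="Mean quality score",
           title="Average quality per base position")
    save(fig, "per_position_quality")

    fig, ax = plt.subplots()
    ax.bar(range(101), d.gc_histogram, color="tab:blue", width=1.0)
    ax.set(xlabel="GC content (%)", ylabel="Reads", title="GC content distribution")
    save(fig, "gc_distribution")

    fig, ax = plt.subplots()
    ax.bar(range(len(d.mean_quality_histogram)), d.mean_quality_histogram,
           color="tab:orange", width=1.0)
    ax.set(xlabel="Mean quality score", ylabel="Reads",
           title="Average quality distribution")
    save(fig, "quality_distribution")

    fig, ax = plt.subplots()
    bases = ["A", "C", "G", "T", "N"]
    ax.bar(bases, [d.base_composition.get(b, 0) for b in bases], color="tab:purple")
    ax.set(xlabel="Base", ylabel="Count", title="Base composition")
    save(fig, "base_composition")

    fig, ax = plt.subplots()
    lengths = sorted(d.length_histogram)
    ax.bar(lengths, [d.length_histogram[x] for x in lengths], color="tab:red", width=1.0)
    ax.set(xlabel="Read length", ylabel="Reads", title="Read length distribution")
    save(fig, "length_distribution")

    fig, ax = plt.subplots()
    if len(d.quality_range_fractions):
        bottom = None
        import numpy as np

        for i, edge in enumerate(d.quality_bins):
            upper = (
                f"{d.quality_bins[i + 1] - 1}" if i + 1 < len(d.quality_bins) else "max"
            )
            series = 100.0 * d.quality_range_fractions[:, i]
            ax.bar(positions, series, bottom=bottom, width=1.0,
                   label=f"Q{edge}-{upper}")
            bottom = series if bottom is None else bottom + series
        ax.legend(fontsize="small")
    ax.set(xlabel="Base position", ylabel="Reads (%)",
           title="Quality score ranges per base position")
    save(fig, "quality_range_per_position")

    if stats is not None:
        fig, ax = plt.subplots()
        labels = ["HQ reads"] + [
            _STAGE_LABELS.get(s, s) for s in stats.stage_counts
        ]
        sizes = [stats.hq_reads] + list(stats.stage_counts.values())
        keep = [(l, s) for l, s in zip(labels, sizes) if s > 0]
        if keep:
            ax.pie([s for _, s in keep], labels=[l for l, _ in keep],
                   autopct="%1.1f%%", textprops={"fontsize": 7})
        ax.set_title("QC summary")
        save(fig, "summary_pie")

    return paths


def write_reports(
    stats: QCRunStats,
    out_dir,
    prefix: str,
    distributions: Optional[DistributionSet] = None,
    plots: bool = False,
) -> Dict[str, Path]:
    """Write the text, TSV and HTML reports (and charts) for one run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    txt = out_dir / f"{prefix}_stats.txt"
    txt.write_text(render_text_report(stats, "formatted"))
    paths["stats_txt"] = txt
    tsv = out_dir / f"{prefix}_stats.tsv"
    tsv.write_text(render_text_report(stats, "tab"))
    paths["stats_tsv"] = tsv
    images: List[Path] = []
    if plots and distributions is not None:
        images = plot_distributions(distributions, out_dir, stats, prefix=prefix)
        for img in images:
            paths[img.stem[len(prefix) + 1 :]] = img
    html_path = out_dir / f"{prefix}_report.html"
    html_path.write_text(
        render_html_report(stats, distributions, [p.name for p in images],
                           title=f"QC report: {prefix}")
    )
    paths["report_html"] = html_path
    return paths
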