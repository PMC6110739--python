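"""Publication-style rendering of demographic tables and survival curves.

Tables are emitted as CSV and markdown; curves as a right-continuous step
plot (survival drops AT event times) with censor ticks and pointwise
confidence bands, plus a companion CSV identical to the survival module's
export.  P-values below the configured floor are shown as ``<floor``
(e.g. ``<0.001``) following the usual journal convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .demographics import DemographicTable
from .survival import KMCurve, LogRankResult, median_survival


@dataclass
class RenderOptions:
    decimals: dict[str, int] = field(default_factory=lambda: {"p": 3, "stat": 2, "desc": 1})
    p_floor: float = 0.001
    formats: tuple[str, ...] = ("csv", "markdown")

    def __post_init__(self) -> None:
        if not (0 < self.p_floor <= 0.01):
            raise ValueError("p_floor must lie in (0, 0.01]")
        if any(d < 0 for d in self.decimals.values()):
            raise ValueError("decimals must be >= 0")

    def fmt_p(self, p: float) -> str:
        d = self.decimals.get("p", 3)
        if p < self.p_floor:
            return f"<{self.p_floor:g}"
        return f"{p:.{d}f}"

    def fmt(self, x: float, kind: str = "desc") -> str:
        d = self.decimals.get(kind, 1)
        return f"{x:.{d}f}"


def render_table1(
    table: DemographicTable, opts: RenderOptions, out_base: str | Path
) -> list[Path]:
    """Write the demographic table as ``<base>.csv`` and ``<base>.md``.

    Continuous rows show mean (sd) [min-max] and n per group; categorical
    rows show count (percent).  Empty sections are omitted entirely.
    """
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "csv" in opts.formats:
        csv_path = out_base.with_suffix(".csv")
        table.to_dataframe().to_csv(csv_path, index=False)
        written.append(csv_path)

    if "markdown" in opts.formats:
        md_path = out_base.with_suffix(".md")
        md_path.write_text(_table1_markdown(table, opts), encoding="utf-8")
        written.append(md_path)
    return written


def _table1_markdown(table: DemographicTable, opts: RenderOptions) -> str:
    group_names = [table.group_labels[g] for g in table.group_levels]
    header = ["variable"] + group_names + ["test", "p"]
    lines = [
        f"# Baseline characteristics by {table.strat_variable}",
        "",
        "| " + " | ".join(header) + " |",
        "|" + "---|" * len(header),
    ]
    if table.continuous_rows:
        for var, res in table.continuous_rows.items():
            cells = []
            gs = res.group_summaries.set_index("group")
            for g in table.group_levels:
                if g in gs.index:
                    r = gs.loc[g]
                    cells.append(
                        f"{opts.fmt(r['mean'])} ({opts.fmt(r['sd'])}) "
                        f"[{opts.fmt(r['min'])}-{opts.fmt(r['max'])}] n={int(r['n'])}"
                    )
                else:
                    cells.append("-")
            lines.append(
                f"| {var} | " + " | ".join(cells)
                + f" | {res.test.selected} | {opts.fmt_p(res.p_value)} |"
            )
    if table.categorical_rows:
        for var, res in table.categorical_rows.items():
            gs = res.group_summaries
            for lev in sorted(gs["level"].unique()):
                cells = []
                for g in table.group_levels:
                    row = gs[(gs["level"] == lev) & (gs["group"] == g)]
                    if len(row):
                        c = int(row["count"].iloc[0])
                        pct = float(row["percent"].iloc[0])
                        cells.append(f"{c} ({opts.fmt(pct)}%)")
                    else:
                        cells.append("0 (0.0%)")
                lines.append(
                    f"| {var}={lev:g} | " + " | ".join(cells)
                    + f" | {res.test.selected} | {opts.fmt_p(res.p_value)} |"
                )
    for var, reason in table.untestable.items():
        lines.append(f"| {var} | " + " | ".join(["-"] * len(table.group_levels))
                     + f" | untestable: {reason} | |")
    lines.append("")
    return "\n".join(lines)


def render_km(
    curves: dict[str, KMCurve] | KMCurve,
    test: LogRankResult | None,
    opts: RenderOptions,
    out_base: str | Path,
) -> list[Path]:
    """Write survival curves as ``<base>.svg`` and ``<base>.csv``.

    The CSV stacks each curve's (time, n_risk, n_event, survival, ci) rows
    with a group column; the plot annotates the log-rank p when a test is
    given and reports medians ("not reached" when the curve never crosses
    one half).
    """
    if isinstance(curves, KMCurve):
        curves = {curves.label or "all": curves}
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    frames = []
    for name, curve in curves.items():
        df = curve.to_dataframe()
        df.insert(0, "group", name)
        frames.append(df)
    csv_path = out_base.with_suffix(".csv")
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    written.append(csv_path)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    summary_lines = []
    for name, curve in curves.items():
        t = [0.0, *curve.event_times]
        s = [1.0, *curve.survival]
        (line,) = ax.step(t, s, where="post", label=name)
        if curve.event_times.size:
            ax.fill_between(
                curve.event_times, curve.ci_lower, curve.ci_upper,
                step="post", alpha=0.15, color=line.get_color(),
            )
        if curve.censor_times.size:
            cens_s = [curve.survival_at(ct) for ct in curve.censor_times]
            ax.plot(curve.censor_times, cens_s, "|", color=line.get_color(), ms=8)
        med = median_survival(curve)
        summary_lines.append(
            f"{name}: median " + (opts.fmt(med) if med is not None else "not reached")
        )
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if len(curves) > 1:
        ax.legend(loc="best", fontsize=8)
    if test is not None:
        ax.set_title(f"log-rank p = {opts.fmt_p(test.p_value)}", fontsize=10)
    fig.tight_layout()
    svg_path = out_base.with_suffix(".svg")
    fig.savefig(svg_path)
    plt.close(fig)
    written.append(svg_path)

    txt_path = out_base.with_suffix(".txt")
    txt_path.write_text("\n".join(summary_lines) + "\n", encoding="utf-8")
    written.append(txt_path)
    return written
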