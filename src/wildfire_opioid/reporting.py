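"""Publication-shaped rendering of simulation summaries."""

from __future__ import annotations

import json
from pathlib import Path

from .montecarlo import SimulationSummary

__all__ = ["render_summary_table", "summary_to_dict", "write_summary_json"]

_SCENARIO_TITLES = {
    "S1": "Scenario 1 (base case; more prevalent anxiety)",
    "S2": "Scenario 2 (opioid pre-disposed anxiety)",
    "S3": "Scenario 3 (worsening pre-existing anxiety)",
}


def _pct(x: float) -> str:
    return f"{100.0 * x:.1f}%"


def render_summary_table(summary: SimulationSummary) -> str:
    """Markdown table of per-scenario prevalence and PR with 95% UIs.

    Percentages are printed to one decimal place and ratios to two, the
    precision of the published results table; unrounded values live in
    the JSON summary.
    """
    lines = [
        "| Scenario | Opioid misuse prevalence (95% UI) | Prevalence ratio (95% UI) |",
        "| --- | --- | --- |",
    ]
    for sc, s in summary.scenarios.items():
        prev = f"{_pct(s.mean_prevalence)} ({_pct(s.prevalence_ui[0])} - {_pct(s.prevalence_ui[1])})"
        pr = f"{s.mean_pr:.2f} ({s.pr_ui[0]:.2f}–{s.pr_ui[1]:.2f})"
        lines.append(f"| {_SCENARIO_TITLES.get(sc, sc)} | {prev} | {pr} |")
    return "\n".join(lines)


def summary_to_dict(summary: SimulationSummary) -> dict:
    """JSON-serialisable summary keyed by scenario, with run provenance."""
    return {
        "scenarios": {
            sc: {
                "mean_prevalence": s.mean_prevalence,
                "prevalence_ui": list(s.prevalence_ui),
                "mean_pr": s.mean_pr,
                "pr_ui": list(s.pr_ui),
            }
            for sc, s in summary.scenarios.items()
        },
        "anxiety_pr": summary.anxiety_pr,
        "n_iterations": summary.n_iterations,
        "seed": summary.seed,
        "dialect": summary.dialect,
    }


def write_summary_json(summary: SimulationSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary_to_dict(summary), indent=2))
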