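"""Rendering of benchmark results into report tables.

Numbers are formatted at 2 decimals with half-up rounding only at this
boundary; JSON output carries full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .mock_eval import (ControlSummary, MockControlReport, OERatioRecord,
                        round_half_up)
from .reproducibility import DICCResult, WilcoxonResult, interpret_dicc

__all__ = [
    "performance_frame", "oe_frame", "repro_frame",
    "write_tsv", "write_json", "summary_dict",
]


def _fmt(x: float) -> str:
    return f"{round_half_up(x):.2f}"


def performance_frame(reports: Sequence[MockControlReport]) -> pd.DataFrame:
    """Controls as columns; confusion counts and scores as rows."""
    rows = ["true_positives", "false_positives", "false_negatives",
            "precision", "sensitivity", "f_score", "percent_correct"]
    data = {}
    for r in reports:
        data[r.control_id] = [
            r.counts.tp, r.counts.fp, r.counts.fn,
            _fmt(r.scores.precision), _fmt(r.scores.sensitivity),
            _fmt(r.scores.f_score), _fmt(r.percent_correct),
        ]
    return pd.DataFrame(data, index=rows)


def oe_frame(records: Sequence[OERatioRecord],
             percent_correct: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Species as rows: theoretical %, observed % per control, O/E summary."""
    controls = [cid for cid, _, _ in records[0].per_control] if records else []
    rows = {}
    for rec in records:
        row = {"theoretical_percent": f"{rec.theoretical_percent:g}"}
        for cid, obs, _ in rec.per_control:
            row[cid] = _fmt(obs)
        row["oe_median_range"] = rec.formatted()
        rows[rec.species_label] = row
    frame = pd.DataFrame(rows).T
    if percent_correct is not None:
        totals = {"theoretical_percent": "100"}
        totals.update({cid: _fmt(percent_correct[cid]) for cid in controls})
        totals["oe_median_range"] = "-"
        frame.loc["% correctly classified"] = totals
    return frame


def repro_frame(wilcoxon: Mapping[str, WilcoxonResult],
                diccs: Mapping[str, DICCResult]) -> pd.DataFrame:
    rows = {}
    for metric, w in wilcoxon.items():
        rows[metric] = {
            "kind": "paired_wilcoxon", "n_pairs": w.n_pairs,
            "statistic": _fmt(w.statistic), "p_value": f"{w.p_value:.3g}",
            "estimate": _fmt(w.estimate),
            "ci95": f"({round_half_up(w.ci_low):.2f}, {round_half_up(w.ci_high):.2f})",
            "label": "-",
        }
    for metric, d in diccs.items():
        rows[metric] = {
            "kind": "dicc", "n_pairs": d.n_pairs,
            "statistic": f"{d.dicc:.3f}", "p_value": "-", "estimate": "-",
            "ci95": "-", "label": interpret_dicc(d),
        }
    return pd.DataFrame(rows).T


def summary_dict(reports: Sequence[MockControlReport],
                 summary: ControlSummary,
                 records: Sequence[OERatioRecord]) -> dict:
    """Full-precision JSON-ready summary of a mock-control evaluation."""
    return {
        "n_controls": summary.n_controls,
        "f_score": {"median": summary.f_median,
                    "min": summary.f_min, "max": summary.f_max},
        "controls": {
            r.control_id: {
                "tp": r.counts.tp, "fp": r.counts.fp, "fn": r.counts.fn,
                "precision": r.scores.precision,
                "sensitivity": r.scores.sensitivity,
                "f_score": r.scores.f_score,
                "percent_correct": r.percent_correct,
                "genus_rescues": list(r.genus_rescues),
            } for r in reports
        },
        "oe_ratios": {
            rec.species_label: {
                "theoretical_percent": rec.theoretical_percent,
                "median": rec.median, "min": rec.min, "max": rec.max,
            } for rec in records
        },
    }


def write_tsv(frame: pd.DataFrame, path: str | Path, index_name: str = "") -> None:
    out = frame.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
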