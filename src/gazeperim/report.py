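"""Exam report assembly and rendering.

A report has an upper administrative section (patient name and identifier,
exam start/stop, test type, false-positive and false-negative counts) and a
lower results section: the full per-location dB map, a simplified
pass/fail view obtained by thresholding the full map at the 12.5 dB defect
midpoint, and a histogram of locations per 1-dB bin.

Reports persist as a versioned JSON document (machine-readable and
byte-stable for fixed inputs) plus a PNG panel with the two arm profiles
rendered in gray levels (darker = lower sensitivity) and the histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .geometry import HORIZONTAL, VERTICAL
from .mapping import DB_CEILING, DEFECT_MIDPOINT_DB, SensitivityMap

__all__ = ["ExamReport", "build_report", "render_report", "load_report"]

SCHEMA_VERSION = 1
N_BINS = int(DB_CEILING) + 1  # one bin per whole dB, 0..25


@dataclass(frozen=True)
class ExamReport:
    """Complete exam report (administrative header + numerical results)."""

    patient_name: str | None
    patient_id: str | None
    start_s: float
    stop_s: float
    test_type: str
    false_positives: int
    false_negatives: int
    fixation_losses: int
    full_results: dict[tuple[str, float], float | None]
    simplified_results: dict[tuple[str, float], bool]
    histogram: list[int]

    def __post_init__(self) -> None:
        if self.stop_s < self.start_s:
            raise ValueError("exam stop must not precede start")
        n_det = sum(1 for v in self.full_results.values() if v is not None)
        if sum(self.histogram) != n_det:
            raise ValueError("histogram must sum to the determined-location count")


def build_report(
    m: SensitivityMap,
    patient_name: str | None = None,
    patient_id: str | None = None,
) -> ExamReport:
    """Derive the report from a sensitivity map and patient metadata.

    The simplified view marks a location "pass" when its threshold is at or
    above the 12.5 dB defect midpoint; the histogram counts determined
    locations per whole-dB bin (thresholds rounded to the nearest dB).
    """
    hist = [0] * N_BINS
    simplified = {}
    for key, v in m.thresholds.items():
        if v is None:
            continue
        hist[int(np.clip(round(v), 0, N_BINS - 1))] += 1
        simplified[key] = v >= DEFECT_MIDPOINT_DB
    return ExamReport(
        patient_name=patient_name,
        patient_id=patient_id,
        start_s=m.exam_start,
        stop_s=m.exam_stop,
        test_type=m.mode,
        false_positives=m.false_positives,
        false_negatives=m.false_negatives,
        fixation_losses=m.fixation_losses,
        full_results=dict(m.thresholds),
        simplified_results=simplified,
        histogram=hist,
    )


def _report_dict(r: ExamReport) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "patient_name": r.patient_name,
        "patient_id": r.patient_id,
        "start_s": r.start_s,
        "stop_s": r.stop_s,
        "test_type": r.test_type,
        "false_positives": r.false_positives,
        "false_negatives": r.false_negatives,
        "fixation_losses": r.fixation_losses,
        "full_results": [
            {"arm": a, "angle_deg": ang, "threshold_db": v}
            for (a, ang), v in sorted(r.full_results.items())
        ],
        "simplified_results": [
            {"arm": a, "angle_deg": ang, "pass": bool(p)}
            for (a, ang), p in sorted(r.simplified_results.items())
        ],
        "histogram": list(r.histogram),
    }


def report_to_json(r: ExamReport) -> str:
    return json.dumps(_report_dict(r), indent=2, sort_keys=True)


def report_from_json(text: str) -> ExamReport:
    d = json.loads(text)
    return ExamReport(
        patient_name=d["patient_name"],
        patient_id=d["patient_id"],
        start_s=d["start_s"],
        stop_s=d["stop_s"],
        test_type=d["test_type"],
        false_positives=d["false_positives"],
        false_negatives=d["false_negatives"],
        fixation_losses=d.get("fixation_losses", 0),
        full_results={
            (e["arm"], float(e["angle_deg"])): e["threshold_db"]
            for e in d["full_results"]
        },
        simplified_results={
            (e["arm"], float(e["angle_deg"])): e["pass"]
            for e in d["simplified_results"]
        },
        histogram=list(d["histogram"]),
    )


def _arm_strip(ax, r: ExamReport, arm: str) -> None:
    items = sorted(
        (ang, v) for (a, ang), v in r.full_results.items() if a == arm and v is not None
    )
    if not items:
        ax.set_axis_off()
        return
    angles = np.array([a for a, _ in items])
    values = np.array([v for _, v in items])
    ax.imshow(
        values[None, :],
        cmap="gray",
        vmin=0,
        vmax=DB_CEILING,
        aspect="auto",
        extent=[angles.min(), angles.max(), 0, 1],
    )
    ax.set_yticks([])
    ax.set_xlabel(f"{arm} angle (deg)")


def render_report(r: ExamReport, out_dir) -> dict[str, str]:
    """Write ``report.json`` and ``report.png`` under ``out_dir``.

    The JSON is byte-stable for identical reports.  Returns the paths.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    json_path = os.path.join(out_dir, "report.json")
    png_path = os.path.join(out_dir, "report.png")
    with open(json_path, "w") as fh:
        fh.write(report_to_json(r))

    fig = plt.figure(figsize=(8, 6))
    header = (
        f"Patient: {r.patient_name or '—'}   ID: {r.patient_id or '—'}\n"
        f"Test: {r.test_type}   start {r.start_s:.1f} s   stop {r.stop_s:.1f} s\n"
        f"False positives: {r.false_positives}   "
        f"False negatives: {r.false_negatives}   "
        f"Fixation losses: {r.fixation_losses}"
    )
    fig.suptitle(header, fontsize=10, ha="center")
    ax_h = fig.add_axes([0.1, 0.62, 0.8, 0.08])
    ax_v = fig.add_axes([0.1, 0.45, 0.8, 0.08])
    ax_hist = fig.add_axes([0.1, 0.08, 0.8, 0.28])
    _arm_strip(ax_h, r, HORIZONTAL)
    _arm_strip(ax_v, r, VERTICAL)
    ax_hist.bar(range(N_BINS), r.histogram, width=0.9, color="0.4")
    ax_hist.set_xlabel("sensitivity threshold (dB)")
    ax_hist.set_ylabel("locations")
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    return {"json": json_path, "png": png_path}


def load_report(path) -> ExamReport:
    with open(path) as fh:
        return report_from_json(fh.read())
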