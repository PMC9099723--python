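"""Ablation runs: the same input tracked under different configurations.

Two comparisons matter for this tracker: two-stage matching (cascade +
central-point, no IoU stage) against the full three-stage matching, and
trajectory reconstruction off against on.  Each configuration is run on
identical detections and scored against the same ground truth, yielding one
metrics row per configuration.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import pandas as pd

from .io import Detection, GroundTruthEntry, RunConfig
from .metrics import MetricsReport, evaluate
from .synthetic import Scenario
from .tracker import group_by_frame, run

__all__ = ["run_configuration", "compare_matching_stages", "compare_reconstruction", "ablation_table"]


def run_configuration(
    detections: Sequence[Detection],
    ground_truth: Sequence[GroundTruthEntry],
    config: RunConfig,
    reconstruction: bool = True,
    start_frame: int = 1,
    n_frames: Optional[int] = None,
    name: str = "",
) -> MetricsReport:
    """Track the detections under one configuration and score the result."""
    stream = group_by_frame(list(detections), n_frames)
    trajectories = run(stream, config, reconstruction=reconstruction)
    return evaluate(
        ground_truth,
        trajectories.records,
        iou_threshold=config.metric_iou_threshold,
        start_frame=start_frame,
        name=name,
    )


def compare_matching_stages(
    scenario: Scenario, config: RunConfig, reconstruction: bool = True
) -> dict[str, MetricsReport]:
    """Two-stage (cascade + center) vs three-stage (plus IoU) matching."""
    start = max(scenario.confirmed_from.values())
    out = {}
    for label, use_iou in (("two_stage", False), ("three_stage", True)):
        cfg = dataclasses.replace(config, use_iou_stage=use_iou)
        out[label] = run_configuration(
            scenario.detections,
            scenario.ground_truth,
            cfg,
            reconstruction=reconstruction,
            start_frame=start,
            n_frames=scenario.config.n_frames,
            name=label,
        )
    return out


def compare_reconstruction(scenario: Scenario, config: RunConfig) -> dict[str, MetricsReport]:
    """Trajectory reconstruction disabled vs enabled on identical input."""
    start = max(scenario.confirmed_from.values())
    out = {}
    for label, recon in (("reconstruction_off", False), ("reconstruction_on", True)):
        out[label] = run_configuration(
            scenario.detections,
            scenario.ground_truth,
            config,
            reconstruction=recon,
            start_frame=start,
            n_frames=scenario.config.n_frames,
            name=label,
        )
    return out


def ablation_table(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """One row per configuration: FP, FN, IDs, MOTA (percent), IDF1 (percent)."""
    return pd.DataFrame(
        {
            "Configuration": list(reports),
            "FP": [r.FP for r in reports.values()],
            "FN": [r.FN for r in reports.values()],
            "IDs": [r.IDSW for r in reports.values()],
            "MOTA": [round(100 * r.MOTA, 2) for r in reports.values()],
            "IDF1": [round(100 * r.IDF1, 2) for r in reports.values()],
        }
    )
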