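"""Model/Results interface over the cohort analysis.

`PointingCohortModel` binds a tidy per-participant metrics table and a
participant metadata table (or raw trials, via :meth:`from_trials`) to a
statistics plan; :meth:`fit` runs the battery and returns a
`PointingCohortResults` carrying the group tests, contrasts and correlations
with a text ``summary()``.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import pandas as pd

from .geometry import TargetGrid
from .scoring import metrics_to_frame, score_participant
from .stats import StatisticsPlan, default_plan, report_to_markdown, run_statistics

__all__ = ["PointingCohortModel", "PointingCohortResults"]


class PointingCohortModel:
    """Cohort-level group-comparison model for pointing-task metrics.

    Parameters
    ----------
    metrics : tidy metrics table (one row per participant x frame x plane)
    metadata : participant table with at least participant_id and group
    plan : StatisticsPlan, defaults to the standard age-corrected plan
    """

    def __init__(self, metrics: pd.DataFrame, metadata: pd.DataFrame,
                 plan: StatisticsPlan | None = None):
        if "participant_id" not in metrics.columns:
            raise ValueError("metrics table lacks participant_id")
        self.metrics = metrics
        self.metadata = metadata
        self.plan = plan or default_plan()

    @classmethod
    def from_trials(cls, trials: Sequence, metadata: pd.DataFrame,
                    grid: TargetGrid | None = None,
                    exclusion_threshold: float = 10.0,
                    plan: StatisticsPlan | None = None,
                    aggregate_map: Mapping | None = None) -> "PointingCohortModel":
        """Score raw PointingTrial sequences (grouped by participant) and build the model."""
        grid = grid or TargetGrid()
        by_pid: dict[str, list] = {}
        for t in trials:
            by_pid.setdefault(t.participant_id, []).append(t)
        all_metrics = [score_participant(ts, grid, exclusion_threshold, aggregate_map)
                       for ts in by_pid.values()]
        return cls(metrics_to_frame(all_metrics), metadata, plan)

    def fit(self, seed: int | None = None) -> "PointingCohortResults":
        """Run the statistical battery; ``seed`` overrides the plan's bootstrap seed."""
        plan = self.plan
        if seed is not None:
            from dataclasses import replace
            plan = replace(plan, seed=int(seed))
        report = run_statistics(self.metrics, self.metadata, plan)
        return PointingCohortResults(self, report)


class PointingCohortResults:
    """Fitted cohort comparison: report dict plus convenience accessors."""

    def __init__(self, model: PointingCohortModel, report: dict):
        self.model = model
        self.report = report

    @property
    def group_tests(self) -> dict:
        return self.report["group_tests"]

    @property
    def correlations(self) -> dict:
        return self.report["correlations"]

    def pvalue(self, outcome: str) -> float:
        return self.report["group_tests"][outcome]["test"]["p"]

    def summary(self) -> str:
        """Markdown-formatted tables of all group tests and correlations."""
        return report_to_markdown(self.report)

    def to_json(self, path=None, indent: int = 2):
        payload = json.dumps(self.report, indent=indent)
        if path is None:
            return payload
        with open(path, "w") as fh:
            fh.write(payload)
        return path
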