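"""Named scenario suites: configuration, batch execution, comparison tables.

A :class:`ScenarioSuite` bundles labelled scenarios — each a base schedule
plus an optional list of innovations — with a shared cohort configuration
and a designated baseline for excess-treatment comparisons.  Suites
round-trip through plain YAML/JSON configs, so a whole analysis is
reproducible from one text file.  The bundled ``benchmark_scenarios.yaml``
encodes the benchmark and innovation scenarios used throughout the analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cascade import CascadeConfig, CascadeResult, compare_scenarios, run_cascade
from .schedules import ImprovementSpec, ResponseSchedule, apply_improvement

__all__ = ["Scenario", "ScenarioSuite", "run_suite", "bundled_suite"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Scenario:
    """A labelled schedule config plus the innovations applied to it."""

    label: str
    schedule: ResponseSchedule
    improvements: tuple[ImprovementSpec, ...] = ()

    def effective_schedule(self) -> ResponseSchedule:
        sched = self.schedule
        for spec in self.improvements:
            sched = apply_improvement(sched, spec)
        return sched

    def to_config(self) -> dict:
        cfg = {"schedule": self.schedule.to_config()}
        if self.improvements:
            cfg["improvements"] = [s.to_config() for s in self.improvements]
        return cfg

    @classmethod
    def from_config(cls, label: str, cfg: Mapping) -> "Scenario":
        return cls(
            label=label,
            schedule=ResponseSchedule.from_config(cfg["schedule"]),
            improvements=tuple(
                ImprovementSpec.from_config(c) for c in cfg.get("improvements", [])
            ),
        )


@dataclass(frozen=True)
class ScenarioSuite:
    """Uniquely labelled scenarios sharing one cascade config and baseline."""

    scenarios: tuple[Scenario, ...]
    config: CascadeConfig
    baseline: str

    def __post_init__(self) -> None:
        labels = [s.label for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise ValueError("scenario labels must be unique")
        if self.baseline not in labels:
            raise ValueError(f"baseline label {self.baseline!r} not among scenarios")

    def __getitem__(self, label: str) -> Scenario:
        for s in self.scenarios:
            if s.label == label:
                return s
        raise KeyError(label)

    def to_config(self) -> dict:
        return {
            "cohort_size": self.config.cohort_size,
            "coverage_target": self.config.coverage_target,
            "rounding": self.config.rounding.value,
            "baseline": self.baseline,
            "scenarios": {s.label: s.to_config() for s in self.scenarios},
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ScenarioSuite":
        config = CascadeConfig(
            cohort_size=int(cfg.get("cohort_size", 100)),
            coverage_target=float(cfg.get("coverage_target", 0.99)),
            rounding=cfg.get("rounding", "per_step_half_up"),
            allow_nonconverged=bool(cfg.get("allow_nonconverged", False)),
        )
        scenarios = tuple(
            Scenario.from_config(label, sc) for label, sc in cfg["scenarios"].items()
        )
        return cls(scenarios=scenarios, config=config, baseline=cfg["baseline"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSuite":
        """Load a suite from a YAML (or JSON — valid YAML) file."""
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=False))


def bundled_suite() -> ScenarioSuite:
    """The benchmark and innovation scenarios shipped with the package."""
    text = resources.files("treatcascade.data").joinpath("benchmark_scenarios.yaml").read_text()
    return ScenarioSuite.from_config(yaml.safe_load(text))


def run_suite(suite: ScenarioSuite, strict: bool = True) -> pd.DataFrame:
    """Run every scenario and tabulate against the suite's baseline.

    Returns one row per scenario: ``label, n_steps, total_treatments,
    excess_treatments, pct_reduction_vs_baseline, converged`` (the baseline
    row has reduction 0).  With ``strict`` (default) a non-converged
    scenario raises; otherwise its row is flagged and the reduction is NaN.
    """
    config = suite.config
    if not strict:
        config = CascadeConfig(
            cohort_size=config.cohort_size,
            coverage_target=config.coverage_target,
            rounding=config.rounding,
            allow_nonconverged=True,
        )
    results: dict[str, CascadeResult] = {}
    for scen in suite.scenarios:
        results[scen.label] = run_cascade(scen.effective_schedule(), config)
        logger.info(
            "scenario %s: %d steps, %s treatments",
            scen.label,
            results[scen.label].n_steps,
            results[scen.label].total_treatments,
        )
        for rec in results[scen.label].steps:
            logger.debug(
                "  step %d: p=%.6f survival_before=%.10f treated=%s",
                rec.step,
                rec.response_prob,
                rec.survival_before,
                rec.treated_count,
            )
    base = results[suite.baseline]
    rows = []
    for scen in suite.scenarios:
        res = results[scen.label]
        if res.converged and base.converged:
            pct = compare_scenarios(base, res).pct_reduction
        else:
            pct = float("nan")
        rows.append(
            {
                "label": scen.label,
                "n_steps": res.n_steps,
                "total_treatments": res.total_treatments,
                "excess_treatments": res.excess_treatments,
                "pct_reduction_vs_baseline": pct,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)
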