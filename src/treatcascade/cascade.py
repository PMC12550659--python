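"""Deterministic cohort cascade and its absorbing-Markov-chain cross-check.

The cascade follows a closed cohort (default 100 patients) through
successive treatment steps: everyone still unresponsive before step k is
treated at step k and responds with probability ``p_k``.  The cohort
survival fraction propagates continuously, ``S_k = S_{k-1} * (1 - p_k)``,
and the cascade stops at the first step after which fewer than
``cohort_size * (1 - coverage_target)`` patients remain unresponsive
(with the default 100-patient cohort and >99% coverage: fewer than one
patient).

Treated head-counts can be reported two ways: ``per_step_half_up`` rounds
the surviving fraction to whole patients at each step before summing
(``treated_k = round_half_up(cohort_size * S_{k-1})``), matching how such
ledgers are tabulated by hand; ``continuous`` sums the real-valued counts.
Survival itself is never rounded — propagating rounded integer cohorts
stalls near the coverage target, where rounded responder counts hit zero
with one or two survivors left.

The same process is an absorbing Markov chain whose transient states are
"awaiting treatment k"; :func:`markov_expected_treatments` computes the
expected number of treatments per patient from the fundamental matrix
N = (I - Q)^-1 and serves as an independent check on the cascade ledger
(the two must agree: expected treatments = sum of survival fractions).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schedules import ResponseSchedule, round_half_up

__all__ = [
    "Rounding",
    "CascadeConfig",
    "StepRecord",
    "CascadeResult",
    "ScenarioComparison",
    "NonConvergenceError",
    "run_cascade",
    "markov_expected_treatments",
    "compare_scenarios",
    "cumulative_response_curve",
]


class Rounding(str, enum.Enum):
    PER_STEP_HALF_UP = "per_step_half_up"
    CONTINUOUS = "continuous"


class NonConvergenceError(RuntimeError):
    """Schedule exhausted before the coverage target was reached."""

    def __init__(self, coverage_achieved: float, n_steps: int):
        self.coverage_achieved = coverage_achieved
        self.n_steps = n_steps
        super().__init__(
            f"coverage target not reached: {100 * coverage_achieved:.2f}% "
            f"responded after {n_steps} steps"
        )


@dataclass(frozen=True)
class CascadeConfig:
    """Cohort size, stopping rule and treated-count rounding convention."""

    cohort_size: int = 100
    coverage_target: float = 0.99
    rounding: Rounding = Rounding.PER_STEP_HALF_UP
    allow_nonconverged: bool = False

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if not 0.0 < self.coverage_target < 1.0:
            raise ValueError("coverage_target must be in (0, 1)")
        object.__setattr__(self, "rounding", Rounding(self.rounding))


@dataclass(frozen=True)
class StepRecord:
    """One row of the per-step cascade ledger (1-based ``step``)."""

    step: int
    response_prob: float
    survival_before: float
    survival_after: float
    treated_count: float
    cumulative_response_pct: float


@dataclass(frozen=True)
class CascadeResult:
    """Per-step ledger plus totals for one cascade run."""

    steps: tuple[StepRecord, ...]
    config: CascadeConfig
    schedule: ResponseSchedule
    converged: bool

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def total_treatments(self) -> float:
        total = sum(rec.treated_count for rec in self.steps)
        if self.config.rounding is Rounding.PER_STEP_HALF_UP:
            return int(total)
        return total

    @property
    def excess_treatments(self) -> float:
        return self.total_treatments - self.config.cohort_size

    @property
    def coverage_achieved(self) -> float:
        return 1.0 - self.steps[-1].survival_after

    @property
    def mean_treatments_per_patient(self) -> float:
        return self.total_treatments / self.config.cohort_size

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-step ledger (one row per treatment step)."""
        return pd.DataFrame(
            {
                "step": [r.step for r in self.steps],
                "response_prob": [r.response_prob for r in self.steps],
                "survival_before": [r.survival_before for r in self.steps],
                "treated": [r.treated_count for r in self.steps],
                "cumulative_response_pct": [r.cumulative_response_pct for r in self.steps],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "n_steps": self.n_steps,
            "total_treatments": self.total_treatments,
            "excess_treatments": self.excess_treatments,
            "coverage_achieved": self.coverage_achieved,
            "converged": self.converged,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


@dataclass(frozen=True)
class ScenarioComparison:
    """Excess treatments of a baseline versus an alternative scenario."""

    baseline_excess: float
    alternative_excess: float

    @property
    def absolute_reduction(self) -> float:
        return self.baseline_excess - self.alternative_excess

    @property
    def pct_reduction(self) -> int:
        """Percent reduction in excess treatments, rounded half up."""
        return int(round_half_up(100.0 * self.absolute_reduction / self.baseline_excess))


def run_cascade(schedule: ResponseSchedule, config: CascadeConfig | None = None) -> CascadeResult:
    """Treat a cohort step by step until the coverage target is reached.

    At step k the ``cohort_size * S_{k-1}`` still-unresponsive patients are
    treated; a fraction ``p_k`` of them responds.  Steps continue while at
    least ``cohort_size * (1 - coverage_target)`` patients remain, i.e.
    ``n_steps`` is the smallest K with ``S_K < 1 - coverage_target``.

    Raises :class:`NonConvergenceError` if the schedule runs out first,
    unless ``config.allow_nonconverged`` is set, in which case the capped
    result is returned with ``converged=False``.
    """
    config = config or CascadeConfig()
    threshold = 1.0 - config.coverage_target
    half_up = config.rounding is Rounding.PER_STEP_HALF_UP

    records: list[StepRecord] = []
    survival = 1.0
    for k, p in enumerate(schedule.probs, start=1):
        if survival < threshold:
            break
        treated = config.cohort_size * survival
        if half_up:
            treated = int(round_half_up(treated))
        survival_after = survival * (1.0 - p)
        records.append(
            StepRecord(
                step=k,
                response_prob=p,
                survival_before=survival,
                survival_after=survival_after,
                treated_count=treated,
                cumulative_response_pct=100.0 * (1.0 - survival_after),
            )
        )
        survival = survival_after

    converged = survival < threshold
    if not converged and not config.allow_nonconverged:
        raise NonConvergenceError(coverage_achieved=1.0 - survival, n_steps=len(records))
    return CascadeResult(
        steps=tuple(records), config=config, schedule=schedule, converged=converged
    )


def markov_expected_treatments(schedule: ResponseSchedule, horizon: int) -> float:
    """Expected treatments per patient within ``horizon`` steps.

    Builds the absorbing-chain transient block Q over states "awaiting
    treatment k" (k = 1..horizon; from state k the patient absorbs into
    "responded" with probability ``p_k`` and otherwise moves to state
    k+1) and returns the first-row sum of the fundamental matrix
    N = (I - Q)^-1 — the expected number of transient states visited,
    i.e. treatments received, starting from step 1.

    Equals the survival-fraction sum ``sum_{k=0}^{horizon-1} S_k`` exactly;
    the matrix route exists as an independent cross-check on the cascade
    ledger.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if horizon > len(schedule):
        raise ValueError(f"horizon {horizon} exceeds schedule length {len(schedule)}")
    q = np.zeros((horizon, horizon))
    for k in range(horizon - 1):
        q[k, k + 1] = 1.0 - schedule.probs[k]
    n_visits = np.linalg.solve(np.eye(horizon) - q, np.ones(horizon))
    # n_visits[0] = sum over j of N[0, j]: expected visits to each "awaiting
    # treatment j" state starting from step 1.
    return float(n_visits[0])


def compare_scenarios(baseline: CascadeResult, alternative: CascadeResult) -> ScenarioComparison:
    """Compare two converged cascade runs by excess treatments."""
    if not (baseline.converged and alternative.converged):
        raise ValueError("both cascades must have converged for a comparison")
    if (
        baseline.config.cohort_size != alternative.config.cohort_size
        or baseline.config.coverage_target != alternative.config.coverage_target
    ):
        raise ValueError("cascades were run under different cohort/coverage configs")
    return ScenarioComparison(
        baseline_excess=baseline.excess_treatments,
        alternative_excess=alternative.excess_treatments,
    )


def cumulative_response_curve(result: CascadeResult) -> list[tuple[int, float]]:
    """(step, percent responded) pairs, starting at (0, 0.0)."""
    curve = [(0, 0.0)]
    curve.extend((rec.step, rec.cumulative_response_pct) for rec in result.steps)
    return curve
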