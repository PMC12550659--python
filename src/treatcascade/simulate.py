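"""Patient-level Monte Carlo realisation of the treatment cascade.

The deterministic cohort ledger in :mod:`.cascade` tracks expected
fractions; this module samples individual trajectories — each patient
undergoes an independent Bernoulli response trial at every step, with the
step-k success probability taken from the schedule, until response or a
censoring cap.  Simulated cohorts let every cascade-level claim be checked
stochastically, and :func:`estimate_schedule_from_trajectories` closes the
loop by recovering the per-step probabilities from simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .schedules import ResponseSchedule

__all__ = ["TrajectorySet", "simulate_cohort", "estimate_schedule_from_trajectories"]

# Below this responder count the normal-approximation interval is unreliable;
# fall back to the exact Clopper-Pearson interval.
_EXACT_CI_COUNT = 5


@dataclass(frozen=True)
class TrajectorySet:
    """Simulated per-patient outcomes under one schedule.

    ``treatments_received[i]`` is the number of treatment steps patient i
    underwent; ``responded[i]`` is False only for patients censored at
    ``censored_at`` steps without responding (for whom
    ``treatments_received == censored_at``).
    """

    treatments_received: np.ndarray
    responded: np.ndarray
    censored_at: int
    seed: int
    schedule_ref: ResponseSchedule

    @property
    def n_patients(self) -> int:
        return len(self.treatments_received)

    @property
    def total_treatments(self) -> int:
        return int(self.treatments_received.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": np.arange(self.n_patients),
                "treatments_received": self.treatments_received,
                "responded": self.responded.astype(int),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        censored_at: int,
        schedule_ref: ResponseSchedule | None = None,
        seed: int = -1,
    ) -> "TrajectorySet":
        """Rebuild a trajectory set from an exported table (for re-estimation)."""
        return cls(
            treatments_received=frame["treatments_received"].to_numpy(dtype=np.int64),
            responded=frame["responded"].to_numpy(dtype=bool),
            censored_at=censored_at,
            seed=seed,
            schedule_ref=schedule_ref,
        )


def simulate_cohort(
    schedule: ResponseSchedule, n_patients: int, cap: int, seed: int
) -> TrajectorySet:
    """Simulate ``n_patients`` independent trajectories under ``schedule``.

    Each patient receives treatments until the first success or until
    ``cap`` steps, whichever comes first.  Patient i consumes a fixed slice
    of the seeded random stream (``cap`` uniforms), so a given patient's
    trajectory is identical regardless of ``n_patients``; identical
    (seed, schedule, n_patients, cap) inputs give identical output.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 1 <= cap <= len(schedule):
        raise ValueError(f"cap must be in [1, {len(schedule)}] (schedule length)")
    rng = np.random.default_rng(seed)
    # (n_patients, cap) uniforms; draw row-major so patient i's draws do not
    # depend on how many patients follow.
    u = rng.random((n_patients, cap))
    success = u < np.asarray(schedule.probs[:cap])
    responded = success.any(axis=1)
    first = np.argmax(success, axis=1)  # 0 when no success; masked below
    treatments = np.where(responded, first + 1, cap).astype(np.int64)
    return TrajectorySet(
        treatments_received=treatments,
        responded=responded,
        censored_at=cap,
        seed=seed,
        schedule_ref=schedule,
    )


def estimate_schedule_from_trajectories(trajectories: TrajectorySet) -> pd.DataFrame:
    """Per-step response-rate estimates with 95% binomial confidence intervals.

    At step k the risk set is every patient who reached step k (received at
    least k treatments); the estimate is responders-at-k / risk set.  The
    interval is the normal approximation, or exact Clopper-Pearson when the
    responder count at a step falls below 5.  Steps nobody reached are
    marked inestimable (NaN estimate, ``estimable=False``).

    Returns a DataFrame with columns
    ``step, n_treated, n_responded, estimate, ci_low, ci_high, estimable``.
    """
    if trajectories.n_patients == 0:
        raise ValueError("empty trajectory set")
    received = trajectories.treatments_received
    responded = trajectories.responded
    rows = []
    for k in range(1, trajectories.censored_at + 1):
        at_risk = int((received >= k).sum())
        successes = int(((received == k) & responded).sum())
        if at_risk == 0:
            rows.append((k, 0, 0, np.nan, np.nan, np.nan, False))
            continue
        method = "normal" if min(successes, at_risk - successes) >= _EXACT_CI_COUNT else "beta"
        lo, hi = proportion_confint(successes, at_risk, alpha=0.05, method=method)
        rows.append((k, at_risk, successes, successes / at_risk, float(lo), float(hi), True))
    return pd.DataFrame(
        rows,
        columns=[
            "step",
            "n_treated",
            "n_responded",
            "estimate",
            "ci_low",
            "ci_high",
            "estimable",
        ],
    )
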