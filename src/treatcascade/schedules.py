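"""Per-step response-probability schedules for sequential depression treatment.

A schedule lists, for each treatment step k (step 1 = first-ever treatment),
the probability that a patient still unresponsive before step k responds to
the treatment offered at that step.  Schedules come in three generated kinds
— constant, geometric decline (each step a fixed fraction less effective
than the previous one) and linear decline — plus ``custom`` for schedules
edited step-wise, e.g. by an innovation that boosts a single step.

Innovations are described by :class:`ImprovementSpec`: a standardised mean
difference (SMD) increment against placebo, a percentage-point gain on the
first-step response rate, or a direct replacement of one step's rate.  SMD
increments are translated to response rates with the Hasselblad–Hedges
log-odds transform, ln(OR) = SMD * pi / sqrt(3).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from scipy.special import expit, logit

__all__ = [
    "ScheduleKind",
    "ImprovementScope",
    "ResponseSchedule",
    "ImprovementSpec",
    "smd_to_response",
    "build_schedule",
    "apply_improvement",
    "round_half_up",
]

#: ln(OR) per unit SMD under the logistic-distribution assumption.
LOGODDS_PER_SMD = math.pi / math.sqrt(3.0)

#: Safety cap on schedule length: a cascade that has not reached its
#: coverage target within this many steps is treated as non-terminating.
DEFAULT_MAX_STEPS = 100

#: Lower bound for linearly declining probabilities (probabilities must
#: stay positive for the cascade to terminate).
DEFAULT_LINEAR_FLOOR = 0.01


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half away from zero at ``ndigits`` decimal places.

    Python's built-in ``round`` uses banker's rounding; cohort ledgers and
    reported percentages here follow the conventional half-up rule instead
    (e.g. 27.5 -> 28).
    """
    scale = 10.0**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * math.copysign(1.0, x)


class ScheduleKind(str, enum.Enum):
    CONSTANT = "constant"
    GEOMETRIC_DECLINE = "geometric_decline"
    LINEAR_DECLINE = "linear_decline"
    CUSTOM = "custom"


class ImprovementScope(str, enum.Enum):
    FIRST_STEP_ONLY = "first_step_only"
    ALL_STEPS = "all_steps"
    SINGLE_STEP = "single_step"


@dataclass(frozen=True)
class ResponseSchedule:
    """Ordered per-step response probabilities plus generation metadata.

    Attributes
    ----------
    probs:
        Tuple of per-step response probabilities, each in (0, 1];
        ``probs[0]`` is step 1.
    kind:
        How the schedule was generated; ``custom`` once edited step-wise.
    first_response:
        Response probability at step 1 of the *generating* rule.
    decline_rate:
        Fractional (geometric) or absolute (linear) per-step decline.
    max_steps:
        Length cap; ``len(probs) <= max_steps``.
    """

    probs: tuple[float, ...]
    kind: ScheduleKind = ScheduleKind.CUSTOM
    first_response: float | None = None
    decline_rate: float = 0.0
    max_steps: int = DEFAULT_MAX_STEPS

    def __post_init__(self) -> None:
        if not self.probs:
            raise ValueError("schedule must contain at least one step")
        if len(self.probs) > self.max_steps:
            raise ValueError(
                f"schedule length {len(self.probs)} exceeds max_steps={self.max_steps}"
            )
        for k, p in enumerate(self.probs, start=1):
            if not 0.0 < p <= 1.0:
                raise ValueError(f"response probability at step {k} is {p}, not in (0, 1]")

    def __len__(self) -> int:
        return len(self.probs)

    def prob_at(self, step: int) -> float:
        """Response probability at 1-based treatment step ``step``."""
        if not 1 <= step <= len(self.probs):
            raise ValueError(f"step {step} outside schedule of length {len(self.probs)}")
        return self.probs[step - 1]

    def with_probs(self, probs: Sequence[float]) -> "ResponseSchedule":
        """Copy of this schedule with step-wise edited probabilities."""
        return replace(self, probs=tuple(probs), kind=ScheduleKind.CUSTOM)

    def to_config(self) -> dict:
        """Plain key-value form, round-trippable through YAML/JSON."""
        cfg: dict = {"kind": self.kind.value, "max_steps": self.max_steps}
        if self.kind is ScheduleKind.CUSTOM:
            cfg["probs"] = list(self.probs)
        else:
            cfg["first_response"] = self.first_response
            cfg["decline_rate"] = self.decline_rate
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ResponseSchedule":
        kind = ScheduleKind(cfg["kind"])
        max_steps = int(cfg.get("max_steps", DEFAULT_MAX_STEPS))
        if kind is ScheduleKind.CUSTOM:
            return cls(probs=tuple(cfg["probs"]), kind=kind, max_steps=max_steps)
        return build_schedule(
            kind,
            float(cfg["first_response"]),
            float(cfg.get("decline_rate", 0.0)),
            max_steps,
            floor_p=float(cfg.get("floor_p", DEFAULT_LINEAR_FLOOR)),
        )


@dataclass(frozen=True)
class ImprovementSpec:
    """Strength and scope of a candidate innovation.

    Exactly one of ``smd_delta`` (SMD increment over the comparator),
    ``point_gain`` (percentage-point gain on the first-step rate, as a
    fraction) or ``replacement_p`` (direct replacement rate, single step
    only) must be given.  ``scope`` says where the gain applies: the first
    step only, every step (decline re-applied from the boosted start), or
    one specific later step (``step_index``, 1-based).
    """

    scope: ImprovementScope
    smd_delta: float | None = None
    point_gain: float | None = None
    step_index: int | None = None
    replacement_p: float | None = None

    def __post_init__(self) -> None:
        drivers = [v is not None for v in (self.smd_delta, self.point_gain, self.replacement_p)]
        if sum(drivers) != 1:
            raise ValueError(
                "exactly one of smd_delta, point_gain, replacement_p must be given"
            )
        if self.smd_delta is not None and self.smd_delta < 0:
            raise ValueError("smd_delta must be >= 0")
        if self.point_gain is not None and not 0.0 <= self.point_gain < 1.0:
            raise ValueError("point_gain must be in [0, 1)")
        if self.scope is ImprovementScope.SINGLE_STEP:
            if self.step_index is None or self.replacement_p is None:
                raise ValueError("single_step scope requires step_index and replacement_p")
            if self.step_index < 1:
                raise ValueError("step_index is 1-based and must be >= 1")
            if not 0.0 < self.replacement_p <= 1.0:
                raise ValueError("replacement_p must be in (0, 1]")
        elif self.replacement_p is not None or self.step_index is not None:
            raise ValueError("replacement_p/step_index only valid with single_step scope")

    def to_config(self) -> dict:
        cfg: dict = {"scope": self.scope.value}
        for key in ("smd_delta", "point_gain", "step_index", "replacement_p"):
            val = getattr(self, key)
            if val is not None:
                cfg[key] = val
        return cfg

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ImprovementSpec":
        return cls(
            scope=ImprovementScope(cfg["scope"]),
            smd_delta=cfg.get("smd_delta"),
            point_gain=cfg.get("point_gain"),
            step_index=cfg.get("step_index"),
            replacement_p=cfg.get("replacement_p"),
        )


def smd_to_response(baseline_response: float, smd_delta: float) -> float:
    """Translate an SMD increment into a boosted response probability.

    Uses the log-odds effect-size conversion ln(OR) = SMD * pi / sqrt(3):
    the new response rate satisfies logit(p_new) = logit(p_base) +
    smd_delta * pi / sqrt(3).  With a 50% baseline, an increment of 0.15
    SMD (an SMD of 0.45 versus the 0.30 of current antidepressants) gives
    0.5676, i.e. 57% to the nearest percent.

    Parameters
    ----------
    baseline_response:
        Current response probability, strictly inside (0, 1).
    smd_delta:
        Non-negative SMD increment over the comparator.
    """
    if not 0.0 < baseline_response < 1.0:
        raise ValueError("baseline_response must be strictly between 0 and 1 (logit undefined at the ends)")
    if smd_delta < 0:
        raise ValueError("smd_delta must be >= 0")
    if smd_delta == 0.0:
        return baseline_response
    return float(expit(logit(baseline_response) + smd_delta * LOGODDS_PER_SMD))


def build_schedule(
    kind: ScheduleKind | str,
    first_response: float,
    decline_rate: float = 0.0,
    max_steps: int = DEFAULT_MAX_STEPS,
    *,
    floor_p: float = DEFAULT_LINEAR_FLOOR,
) -> ResponseSchedule:
    """Generate a response schedule of the given kind.

    ``constant`` keeps ``first_response`` at every step; ``geometric_decline``
    multiplies it by ``(1 - decline_rate)`` each step (a treatment 10% less
    effective than the previous one has ``decline_rate=0.10``);
    ``linear_decline`` subtracts ``decline_rate`` per step, floored at
    ``floor_p`` so probabilities stay positive.
    """
    kind = ScheduleKind(kind)
    if kind is ScheduleKind.CUSTOM:
        raise ValueError("custom schedules are built from explicit probs, not generated")
    if not 0.0 < first_response <= 1.0:
        raise ValueError("first_response must be in (0, 1]")
    if not 0.0 <= decline_rate < 1.0:
        raise ValueError("decline_rate must be in [0, 1)")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if kind is ScheduleKind.CONSTANT:
        probs = (first_response,) * max_steps
    elif kind is ScheduleKind.GEOMETRIC_DECLINE:
        probs = tuple(first_response * (1.0 - decline_rate) ** k for k in range(max_steps))
    else:  # linear decline with floor
        if not 0.0 < floor_p <= first_response:
            raise ValueError("floor_p must be in (0, first_response]")
        probs = tuple(
            max(first_response - k * decline_rate, floor_p) for k in range(max_steps)
        )
    return ResponseSchedule(
        probs=probs,
        kind=kind,
        first_response=first_response,
        decline_rate=decline_rate,
        max_steps=max_steps,
    )


def _boosted_first_response(schedule: ResponseSchedule, spec: ImprovementSpec) -> float:
    """First-step rate after the innovation, rounded to the nearest percent.

    SMD-driven gains are converted with :func:`smd_to_response` and then
    rounded half up to a whole percent before cascade use — effect sizes
    translated from meta-analytic SMDs carry no more precision than that,
    and downstream cascade totals are quoted at whole-percent schedules.
    """
    base = schedule.probs[0]
    if spec.smd_delta is not None:
        boosted = round_half_up(smd_to_response(base, spec.smd_delta), 2)
    else:
        boosted = base + spec.point_gain
    if boosted >= 1.0:
        raise ValueError(f"boosted first-step probability {boosted} is not < 1")
    return boosted


def apply_improvement(schedule: ResponseSchedule, spec: ImprovementSpec) -> ResponseSchedule:
    """Return the schedule modified by an innovation.

    * ``first_step_only`` — step 1 is boosted; later steps keep the
      original (declined) rates: a better first-line treatment does not
      help the steps after it.
    * ``all_steps`` — the schedule is regenerated from the boosted
      first-step rate with the original kind and decline, so every step
      gains by the same multiplicative factor under geometric decline.
    * ``single_step`` — one step's rate is replaced outright (e.g. a
      treatment for the treatment-resistant group at step 3 restored to
      first-treatment effectiveness).
    """
    if spec.scope is ImprovementScope.SINGLE_STEP:
        idx = spec.step_index - 1
        if idx >= len(schedule.probs):
            raise ValueError(
                f"step_index {spec.step_index} outside schedule of length {len(schedule.probs)}"
            )
        probs = list(schedule.probs)
        probs[idx] = spec.replacement_p
        return schedule.with_probs(probs)

    boosted = _boosted_first_response(schedule, spec)
    if spec.scope is ImprovementScope.FIRST_STEP_ONLY:
        probs = (boosted,) + schedule.probs[1:]
        return schedule.with_probs(probs)

    # all_steps: decline re-applies from the boosted start
    if schedule.kind is ScheduleKind.CUSTOM:
        # no generating rule to re-apply; scale every step by the same factor
        factor = boosted / schedule.probs[0]
        probs = tuple(min(p * factor, 1.0) for p in schedule.probs)
        return schedule.with_probs(probs)
    return build_schedule(
        schedule.kind, boosted, schedule.decline_rate, schedule.max_steps
    )
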