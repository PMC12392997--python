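"""Screening strategies, schedules, and the endoscopy/follow-up rounds.

Forty strategies combine a starting age (40/45/50/55), a screening interval
(annual, biennial, every 5/10/15 years, or once in a lifetime) and, for the
sparser intervals, periodic endoscopic surveillance ("follow-up") of
screen-detected precancerous lesions.  Screening invitations stop after age
70; codes follow the ``y<start>_<f|nf>_i<interval>`` convention (``in`` =
once in a lifetime).

A screening round attends a compliance fraction of the live cohort, detects
lesions with the endoscope's sensitivity, and manages detections: severe
dysplasia/CIS and HGIN are resected (reverting to a post-treatment state),
early cancers are resected, newly-entered advanced cancers are tagged
screen-detected for costing, and lower-grade lesions either enter
surveillance (follow-up arms) or return to natural history untouched.
Healthy attenders test falsely positive with probability 1 - specificity
(no extra cost by default; endoscopic biopsy is confirmatory in-session).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet
from .states import SURV_PREFIX, TREATABLE_PRECANCER, ExpandedSpace

START_AGES = (40, 45, 50, 55)
END_AGE = 70
INTERVALS = (1, 2, 5, 10, 15, "once")
FOLLOW_UP_INTERVALS = (5, 10, 15, "once")  # no published follow-up arm for i1/i2


@dataclass(frozen=True)
class ScreeningStrategy:
    """One row of the strategy grid."""

    start_age: int
    interval: int | str          # years, or "once"
    follow_up: bool
    end_age: int = END_AGE

    def __post_init__(self) -> None:
        if self.start_age > self.end_age:
            raise ValueError("start_age must be <= end_age")
        if self.interval not in INTERVALS:
            raise ValueError(f"unsupported interval {self.interval!r}")
        if self.follow_up and self.interval not in FOLLOW_UP_INTERVALS:
            raise ValueError(f"no follow-up variant for interval {self.interval!r}")

    @property
    def code(self) -> str:
        tag = "in" if self.interval == "once" else f"i{self.interval}"
        return f"y{self.start_age}_{'f' if self.follow_up else 'nf'}_{tag}"

    @classmethod
    def from_code(cls, code: str) -> "ScreeningStrategy":
        try:
            y, fu, i = code.split("_")
            interval: int | str = "once" if i == "in" else int(i.removeprefix("i"))
            return cls(int(y.removeprefix("y")), interval, fu == "f")
        except (ValueError, AttributeError) as e:
            raise ValueError(f"malformed strategy code {code!r}") from e


def enumerate_strategies() -> list[ScreeningStrategy]:
    """The full 40-strategy grid (the no-screening reference is implicit)."""
    out = []
    for start in START_AGES:
        for interval in INTERVALS:
            out.append(ScreeningStrategy(start, interval, follow_up=False))
        for interval in FOLLOW_UP_INTERVALS:
            out.append(ScreeningStrategy(start, interval, follow_up=True))
    return out


def build_schedule(s: ScreeningStrategy) -> tuple[int, ...]:
    """Ages at which screening is offered: start, start+interval, ... <= 70."""
    if s.interval == "once":
        return (s.start_age,)
    return tuple(range(s.start_age, s.end_age + 1, s.interval))


# ---------------------------------------------------------------------------
# detection management
# ---------------------------------------------------------------------------

ACTION_TREAT_REVERT = "treat_and_revert"      # SD/CIS, HGIN -> post-treatment
ACTION_TREAT_EARLY = "treat_early_cancer"     # early cancer -> post-treatment
ACTION_TAG_ADVANCED = "treat_advanced_screen_detected"
ACTION_SURVEIL = "surveil"                    # low-grade lesion, follow-up arms
ACTION_NONE = "none"


@dataclass(frozen=True)
class ManagementPolicy:
    """Action applied to each screen-detectable grade on detection."""

    actions: dict[str, str]
    surveillance_interval: int = 1  # years between follow-up endoscopies

    def action_for(self, state_name: str) -> str:
        try:
            return self.actions[state_name]
        except KeyError:
            raise KeyError(f"management policy has no action for state {state_name!r}")


def default_management(space, follow_up: bool) -> ManagementPolicy:
    actions: dict[str, str] = {}
    for s in space:
        if not s.screen_detectable:
            continue
        if s.name in TREATABLE_PRECANCER:
            actions[s.name] = ACTION_TREAT_REVERT
        elif s.grade == "precancer":
            actions[s.name] = ACTION_SURVEIL if follow_up else ACTION_NONE
        elif s.grade == "early_cancer":
            actions[s.name] = ACTION_TREAT_EARLY
        elif s.grade == "advanced_cancer":
            actions[s.name] = ACTION_TAG_ADVANCED
    return ManagementPolicy(actions)


@dataclass(frozen=True)
class Policy:
    """A strategy bound to its schedule and detection management."""

    strategy: ScreeningStrategy
    schedule: tuple[int, ...]
    management: ManagementPolicy

    @property
    def follow_up(self) -> bool:
        return self.strategy.follow_up


def make_policy(strategy: ScreeningStrategy, space) -> Policy:
    return Policy(strategy, build_schedule(strategy),
                  default_management(space, strategy.follow_up))


# ---------------------------------------------------------------------------
# rounds
# ---------------------------------------------------------------------------

@dataclass
class RoundReport:
    """Per-round tallies (cohort fractions) and undiscounted costs (CNY per
    cohort member, i.e. multiply by cohort size for totals)."""

    attendance: float = 0.0
    false_positives: float = 0.0
    detections: dict[str, float] = field(default_factory=dict)
    detected_advanced: dict[str, float] = field(default_factory=dict)  # organ -> fraction
    screening_cost: float = 0.0
    treatment_cost: float = 0.0

    @property
    def total_detected(self) -> float:
        return sum(self.detections.values())


def apply_screening_round(v: np.ndarray, params: ParameterSet, policy: Policy,
                          exp: ExpandedSpace) -> tuple[np.ndarray, RoundReport]:
    """One population screening round applied to the expanded state vector.

    Mass is conserved: detections move between live states only.  Lesions
    already under surveillance are not re-invited (their endoscopy arrives
    through the follow-up round).  Advanced detection applies to the
    duration-1 tunnel only — older tunnels represent cancers already
    diagnosed; the detected fraction is tagged for "(screening)" costing by
    the cohort engine, which also charges the undetected remainder at the
    clinical "(no screening)" cost.
    """
    cs = params.screening_compliance
    se = params.sensitivity
    sp = params.specificity
    c_endo = params.cost_of("screening_total")
    new = v.copy()
    rep = RoundReport()
    post_idx = exp.index["post_treatment"]

    for i in range(exp.n):
        base = exp.base_state(i)
        if base.grade == "death" or exp.is_surveilled(i):
            continue
        attending = cs * v[i]
        if attending <= 0.0:
            continue
        rep.attendance += attending
        rep.screening_cost += attending * c_endo
        if not base.screen_detectable:
            rep.false_positives += attending * (1.0 - sp)
            rep.screening_cost += attending * (1.0 - sp) * params.false_positive_cost
            continue
        # advanced tunnels: only the newly-entered duration-1 copy is
        # undiagnosed and hence screen-detectable
        if base.grade == "advanced_cancer" and not exp.names[i].endswith("_d1"):
            continue
        detected = attending * se
        if detected <= 0.0:
            continue
        action = policy.management.action_for(base.name)
        rep.detections[base.name] = rep.detections.get(base.name, 0.0) + detected
        if action == ACTION_TREAT_REVERT:
            new[i] -= detected
            new[post_idx] += detected
            rep.treatment_cost += detected * params.cost_of(f"treat_{base.organ}_sd_cis")
        elif action == ACTION_TREAT_EARLY:
            # resection cures; the treatment cost was charged at state entry
            new[i] -= detected
            new[post_idx] += detected
        elif action == ACTION_TAG_ADVANCED:
            rep.detected_advanced[base.organ] = \
                rep.detected_advanced.get(base.organ, 0.0) + detected
        elif action == ACTION_SURVEIL:
            new[i] -= detected
            new[exp.surv_index(base.name)] += detected
        elif action != ACTION_NONE:
            raise ValueError(f"unknown management action {action!r}")
    return new, rep


def apply_follow_up_round(v: np.ndarray, params: ParameterSet, policy: Policy,
                          exp: ExpandedSpace) -> tuple[np.ndarray, RoundReport]:
    """Annual surveillance endoscopy of the lesions enrolled in follow-up.

    A compliance fraction of surveilled mass attends; attenders whose lesion
    has progressed to a resectable grade (severe dysplasia/CIS, HGIN) are
    detected with the endoscope's sensitivity and treated.
    """
    if not policy.follow_up:
        raise ValueError(f"strategy {policy.strategy.code} has no follow-up arm")
    cf = params.follow_up_compliance
    se = params.sensitivity
    c_endo = params.cost_of("screening_total")
    new = v.copy()
    rep = RoundReport()
    post_idx = exp.index["post_treatment"]

    for i in range(exp.n):
        if not exp.is_surveilled(i) or v[i] <= 0.0:
            continue
        base = exp.base_state(i)
        attending = cf * v[i]
        rep.attendance += attending
        rep.screening_cost += attending * c_endo
        if base.name in TREATABLE_PRECANCER:
            detected = attending * se
            rep.detections[base.name] = rep.detections.get(base.name, 0.0) + detected
            new[i] -= detected
            new[post_idx] += detected
            rep.treatment_cost += detected * params.cost_of(f"treat_{base.organ}_sd_cis")
    return new, rep
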