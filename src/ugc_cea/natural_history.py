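"""Deterministic annual-cycle cohort propagation through the natural history.

The cohort is advanced as occupancy fractions (no microsimulation): each
cycle, a stochastic one-step operator moves mass between expanded states.
Competing risks follow a fixed, documented ordering — age-specific
other-cause death is applied first, then disease transitions (or the
duration-specific advanced-cancer death probability) act on the survivors at
their full annual probabilities.  Cycle ``t`` corresponds to attained age
``age_start + t``; mortality is looked up at attained age with no silent
extrapolation.

Screening and follow-up rounds, when a policy is supplied, are applied at
the start of a cycle, before the natural-history transition.  Treatment
costs for cancer are charged once per case: early cancer at state entry,
advanced cancer at diagnosis (screen-detected newly-entered mass at the
"(screening)" cost, the clinically-presenting remainder at the
"(no screening)" cost).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import screening as scr
from .params import ParameterSet
from .states import ExpandedSpace

CONSERVATION_TOL = 1e-9


def assemble_cycle_matrix(params: ParameterSet, age: int,
                          exp: ExpandedSpace | None = None) -> np.ndarray:
    """Row-stochastic one-cycle operator at the given attained age."""
    exp = exp or ExpandedSpace(params.state_space)
    lo, hi = params.age_span
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside model span {params.age_span}")
    q_oc = params.mortality.other_cause_at(age)
    n = exp.n
    M = np.zeros((n, n))
    other_death = exp.index["other_death"]
    ugc_death = exp.index["ugc_death"]
    table = params.transitions

    for i in range(n):
        base = exp.base_state(i)
        if base.grade == "death":
            M[i, i] = 1.0
            continue
        M[i, other_death] = q_oc
        live = 1.0 - q_oc
        if base.grade == "advanced_cancer":
            k = int(exp.names[i].rsplit("_d", 1)[1])
            q_d = params.mortality.duration_series(base.organ)[k - 1]
            M[i, ugc_death] += live * q_d
            nxt = exp.index[f"{base.name}_d{min(k + 1, 6)}"]
            M[i, nxt] += live * (1.0 - q_d)
            continue
        row = table.row(base.name)
        stay = 1.0
        surveilled = exp.is_surveilled(i)
        for target, p in row.items():
            t_state = params.state_space[target]
            if surveilled and t_state.pre_intramucosal:
                j = exp.surv_index(target)   # surveilled lesions stay enrolled
            else:
                j = exp.entry_index(target)
            M[i, j] += live * p
            stay -= p
        M[i, i] += live * stay
    return M


def advance_cohort(v: np.ndarray, M: np.ndarray) -> np.ndarray:
    """One annual transition of the occupancy vector."""
    if v.shape[0] != M.shape[0] or M.shape[0] != M.shape[1]:
        raise ValueError(f"dimension mismatch: v{v.shape} vs M{M.shape}")
    return v @ M


def _entry_flows(v: np.ndarray, M: np.ndarray, targets: list[int],
                 internal: set[int]) -> float:
    """Mass flowing into ``targets`` from outside ``internal`` this cycle."""
    src = np.array([i for i in range(len(v)) if i not in internal])
    return float(v[src] @ M[np.ix_(src, targets)].sum(axis=1))


@dataclass
class CohortTrace:
    """Per-cycle occupancy and event/cost tallies of one cohort run.

    ``occupancy[t]`` is the start-of-cycle vector at age ``ages[t]`` after
    any screening/follow-up round (this is the vector utilities accrue on);
    ``final`` is the vector after the last transition.  Costs are
    undiscounted CNY per cohort member; event tallies are cohort fractions.
    """

    exp: ExpandedSpace
    ages: np.ndarray
    occupancy: np.ndarray          # (n_cycles, n_states)
    final: np.ndarray
    cost_screening: np.ndarray     # per cycle
    cost_follow_up: np.ndarray
    cost_treatment: np.ndarray
    new_cases: dict[str, np.ndarray]      # organ -> per-cycle entry flow into cancer
    ugc_deaths: np.ndarray
    other_deaths: np.ndarray
    detections: np.ndarray         # screen + follow-up true positives per cycle
    reports: list = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    def check_conservation(self, tol: float = CONSERVATION_TOL) -> None:
        sums = self.occupancy.sum(axis=1)
        worst = float(np.max(np.abs(sums - 1.0)))
        if worst > tol:
            raise AssertionError(f"occupancy conservation violated: max |sum-1| = {worst:.3e}")

    def total_cost_per_cycle(self) -> np.ndarray:
        return self.cost_screening + self.cost_follow_up + self.cost_treatment

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle occupancy (cycle, age, state, occupancy)."""
        recs = [
            {"cycle": t, "age": int(self.ages[t]), "state": name, "occupancy": self.occupancy[t, j]}
            for t in range(self.n_cycles)
            for j, name in enumerate(self.exp.names)
        ]
        return pd.DataFrame.from_records(recs)

    def events_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cycle": np.arange(self.n_cycles), "age": self.ages,
            "ugc_deaths": self.ugc_deaths, "other_deaths": self.other_deaths,
            "screen_detections": self.detections,
            "cost_screening": self.cost_screening,
            "cost_follow_up": self.cost_follow_up,
            "cost_treatment": self.cost_treatment,
        })
        for organ, flows in self.new_cases.items():
            df[f"new_cases_{organ}"] = flows
        return df


def run_cohort(params: ParameterSet, policy: scr.Policy | None = None,
               cycle_matrices: list[np.ndarray] | None = None) -> CohortTrace:
    """Propagate the cohort from entry to the end of the horizon.

    With ``policy=None`` this is the pure natural history (the no-screening
    arm).  ``cycle_matrices`` allows reusing the per-age operators across
    strategies evaluated under the same parameters.  Propagation is fully
    deterministic.
    """
    exp = ExpandedSpace(params.state_space)
    lo, hi = params.age_span
    ages = np.arange(lo, hi + 1)
    n_cycles = len(ages)
    if cycle_matrices is None:
        cycle_matrices = [assemble_cycle_matrix(params, int(a), exp) for a in ages]

    organs = sorted({s.organ for s in params.state_space if s.grade == "early_cancer"})
    cancer_idx: dict[str, list[int]] = {}
    cancer_internal: dict[str, set[int]] = {}
    d1_idx: dict[str, int] = {}
    for organ in organs:
        idx = [i for i in range(exp.n)
               if exp.base_state(i).organ == organ
               and exp.base_state(i).grade in ("early_cancer", "advanced_cancer")]
        cancer_idx[organ] = idx
        cancer_internal[organ] = set(idx)
        adv = next(s.name for s in params.state_space
                   if s.organ == organ and s.grade == "advanced_cancer")
        d1_idx[organ] = exp.index[f"{adv}_d1"]
    ugc_death = exp.index["ugc_death"]
    other_death = exp.index["other_death"]

    v = exp.initial_vector(params.initial_distribution)
    occ = np.zeros((n_cycles, exp.n))
    cost_scr = np.zeros(n_cycles)
    cost_fu = np.zeros(n_cycles)
    cost_tr = np.zeros(n_cycles)
    detections = np.zeros(n_cycles)
    new_cases = {o: np.zeros(n_cycles) for o in organs}
    ugc_d = np.zeros(n_cycles)
    oth_d = np.zeros(n_cycles)
    reports: list = []

    for t in range(n_cycles):
        age = int(ages[t])
        # duration-1 advanced occupancy at cycle start = last cycle's entries,
        # still undiagnosed and awaiting their (single) treatment charge
        chargeable = {o: v[d1_idx[o]] for o in organs}
        detected_adv = {o: 0.0 for o in organs}

        if policy is not None and age in policy.schedule:
            v, rep = scr.apply_screening_round(v, params, policy, exp)
            cost_scr[t] += rep.screening_cost
            cost_tr[t] += rep.treatment_cost
            detections[t] += rep.total_detected
            for o, m in rep.detected_advanced.items():
                detected_adv[o] = m
            reports.append((t, "screening", rep))
        if policy is not None and policy.follow_up \
                and t % policy.management.surveillance_interval == 0:
            v, rep = scr.apply_follow_up_round(v, params, policy, exp)
            cost_fu[t] += rep.screening_cost
            cost_tr[t] += rep.treatment_cost
            detections[t] += rep.total_detected
            reports.append((t, "follow_up", rep))

        # advanced-cancer diagnosis costing: screen-detected fraction at the
        # "(screening)" price, clinical presentation of the rest this cycle
        for o in organs:
            det = min(detected_adv[o], chargeable[o])
            cost_tr[t] += det * params.cost_of(f"treat_{o}_advanced_screen")
            cost_tr[t] += (chargeable[o] - det) * params.cost_of(f"treat_{o}_advanced_clinical")

        occ[t] = v
        M = cycle_matrices[t]
        ugc_d[t] = float(v @ M[:, ugc_death]) - v[ugc_death]
        oth_d[t] = float(v @ M[:, other_death]) - v[other_death]
        for o in organs:
            flow = _entry_flows(v, M, cancer_idx[o], cancer_internal[o])
            new_cases[o][t] = flow
            # early-cancer treatment charged once, at state entry (all arms)
            early = next(s.name for s in params.state_space
                         if s.organ == o and s.grade == "early_cancer")
            early_j = exp.index[early]
            src = [i for i in range(exp.n) if i not in cancer_internal[o]]
            early_flow = float(v[src] @ M[src, early_j])
            cost_tr[t] += early_flow * params.cost_of(f"treat_{o}_early")
        v = advance_cohort(v, M)

    trace = CohortTrace(exp=exp, ages=ages, occupancy=occ, final=v,
                        cost_screening=cost_scr, cost_follow_up=cost_fu,
                        cost_treatment=cost_tr, new_cases=new_cases,
                        ugc_deaths=ugc_d, other_deaths=oth_d,
                        detections=detections, reports=reports)
    trace.check_conservation()
    return trace


def tally_events(trace: CohortTrace, cohort_size: int = 1) -> dict:
    """Cumulative cases, deaths and life-years over the horizon.

    ``cases`` counts first entries into early- or advanced-cancer states;
    ``life_years`` sums live occupancy over cycles (undiscounted).
    """
    live = trace.occupancy[:, trace.exp.live_mask()].sum(axis=1)
    by_organ = {o: float(f.sum()) * cohort_size for o, f in trace.new_cases.items()}
    return {
        "cases": sum(by_organ.values()),
        "cases_by_organ": by_organ,
        "ugc_deaths": float(trace.ugc_deaths.sum()) * cohort_size,
        "other_deaths": float(trace.other_deaths.sum()) * cohort_size,
        "life_years": float(live.sum()) * cohort_size,
        "screen_detections": float(trace.detections.sum()) * cohort_size,
    }
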