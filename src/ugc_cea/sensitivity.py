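"""Deterministic and probabilistic sensitivity analysis.

One-way sweeps re-evaluate every strategy with a single parameter moved
across its range (everything else at base), feeding a tornado table (entries
ranked by the spread of the base-case-optimal strategy's net monetary
benefit across the parameter's endpoints) and threshold location (bisection
for the parameter value at which the argmax-NMB strategy switches).

The PSA draws full parameter sets from the published distributions —
parameters jointly and independently sampled, transition probabilities held
fixed — evaluates every strategy per draw, and summarises decision
uncertainty as cost-effectiveness acceptability curves: per willingness-to-
pay, the fraction of draws in which each strategy attains the highest net
monetary benefit (ties split equally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cea, economics
from .params import DEFAULT_WTP, ParameterSet, sample_parameter_set
from .screening import ScreeningStrategy

DEFAULT_PSA_ITERATIONS = 1000
#: default λ grid: 0 to 3x per-capita GDP in ¥5,000 steps
DEFAULT_WTP_STEP = 5000.0


def _outcomes(results: list[economics.EconResult]) -> list[cea.StrategyOutcome]:
    return [cea.StrategyOutcome(r.code, r.cost, r.qalys) for r in results]


def one_way_sweep(params: ParameterSet, name: str, values,
                  strategies: list[ScreeningStrategy] | None = None) -> pd.DataFrame:
    """Re-evaluate all strategies at each value of one parameter."""
    if name not in params.named_values():
        raise KeyError(f"unknown parameter {name!r}")
    frames = []
    for x in values:
        ps = params.set_value(name, x)
        res = economics.evaluate_all(ps, strategies)
        df = economics.results_frame(res)
        df.insert(0, "value", float(x))
        df.insert(0, "parameter", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    nmb_low: float
    nmb_high: float

    @property
    def spread(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def tornado_table(params: ParameterSet, names: list[str] | None = None,
                  wtp: float | None = None,
                  strategies: list[ScreeningStrategy] | None = None,
                  baseline: str = "no_screening") -> list[TornadoEntry]:
    """One-way endpoint sweeps ranked by NMB spread.

    The metric is the net monetary benefit (vs the baseline arm) of the
    base-case optimal strategy, re-evaluated at each parameter endpoint.
    """
    wtp = params.wtp if wtp is None else wtp
    reg = params.named_values()
    if names is None:
        names = [n for n, pv in reg.items() if pv.high > pv.low]
    base_res = economics.evaluate_all(params, strategies)
    base_out = _outcomes(base_res)
    base_ref = next(o for o in base_out if o.code == baseline)
    opt_code = cea.optimal_strategy(base_out, wtp, base_ref).code

    entries = []
    for name in sorted(names):
        pv = reg[name]
        ends = {}
        for tag, x in (("low", pv.low), ("high", pv.high)):
            out = _outcomes(economics.evaluate_all(params.set_value(name, x), strategies))
            ref = next(o for o in out if o.code == baseline)
            opt = next(o for o in out if o.code == opt_code)
            ends[tag] = cea.net_monetary_benefit(opt, wtp, ref)
        entries.append(TornadoEntry(name, pv.low, pv.high, ends["low"], ends["high"]))
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter, "low": e.low, "high": e.high,
        "nmb_low": e.nmb_low, "nmb_high": e.nmb_high, "spread": e.spread,
    } for e in entries])


@dataclass
class ThresholdResult:
    parameter: str
    switch_value: float
    optimal_below: str
    optimal_above: str
    multiple_switches: bool = False


def threshold_locate(params: ParameterSet, name: str,
                     wtp: float | None = None,
                     strategies: list[ScreeningStrategy] | None = None,
                     baseline: str = "no_screening",
                     tolerance: float = 1e-3,
                     coarse_points: int = 9) -> ThresholdResult | None:
    """Bisection for the parameter value where the optimal strategy switches.

    A coarse scan over the range brackets argmax-NMB changes; the lowest
    bracket is bisected to ``tolerance`` (absolute, in the parameter's
    units).  Returns ``None`` when the optimum is constant over the range;
    flags multiplicity when the scan sees more than one switch.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    reg = params.named_values()
    if name not in reg:
        raise KeyError(f"unknown parameter {name!r}")
    pv = reg[name]
    if pv.high <= pv.low:
        return None
    wtp = params.wtp if wtp is None else wtp

    def optimum(x: float) -> str:
        out = _outcomes(economics.evaluate_all(params.set_value(name, x), strategies))
        ref = next(o for o in out if o.code == baseline)
        return cea.optimal_strategy(out, wtp, ref).code

    grid = np.linspace(pv.low, pv.high, coarse_points)
    opts = [optimum(x) for x in grid]
    brackets = [(grid[i], grid[i + 1], opts[i], opts[i + 1])
                for i in range(len(grid) - 1) if opts[i] != opts[i + 1]]
    if not brackets:
        return None
    lo, hi, below, above = brackets[0]
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if optimum(mid) == below:
            lo = mid
        else:
            hi = mid
            above = optimum(hi)
    return ThresholdResult(name, 0.5 * (lo + hi), below, above,
                           multiple_switches=len(brackets) > 1)


def run_psa(params: ParameterSet, n: int = DEFAULT_PSA_ITERATIONS, seed: int = 0,
            strategies: list[ScreeningStrategy] | None = None) -> pd.DataFrame:
    """Monte-Carlo PSA: ``n`` sampled parameter sets, every strategy evaluated.

    One root seed spawns independent per-iteration child streams, so results
    are reproducible and insensitive to iteration order.  Returns a long
    table (iteration, strategy, cost, qalys).
    """
    if n < 1:
        raise ValueError("need at least one PSA iteration")
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    rows = []
    for it in range(n):
        ps = sample_parameter_set(params, int(child_seeds[it]))
        for r in economics.evaluate_all(ps, strategies):
            rows.append({"iteration": it, "strategy": r.code,
                         "cost": r.cost, "qalys": r.qalys})
    return pd.DataFrame(rows)


def default_wtp_grid(wtp: float, step: float = DEFAULT_WTP_STEP) -> np.ndarray:
    return np.arange(0.0, 3.0 * wtp + step, step)


def compute_ceac(psa: pd.DataFrame, wtp_grid=None,
                 wtp: float = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA outcomes.

    For each willingness-to-pay λ, the probability a strategy is optimal is
    the fraction of iterations in which it attains the maximum net monetary
    benefit (λ·QALYs − cost; the baseline cancels in an argmax, ties split
    equally).  Returns a long table (wtp, strategy, probability).
    """
    if psa.empty:
        raise ValueError("PSA table is empty")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(DEFAULT_WTP if wtp is None else wtp)
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")

    cost = psa.pivot(index="iteration", columns="strategy", values="cost")
    qaly = psa.pivot(index="iteration", columns="strategy", values="qalys")
    C, Q = cost.to_numpy(), qaly.to_numpy()
    n_iter = C.shape[0]
    rows = []
    for lam in wtp_grid:
        nmb = lam * Q - C
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        prob = share.sum(axis=0) / n_iter
        for j, code in enumerate(cost.columns):
            rows.append({"wtp": float(lam), "strategy": code, "probability": float(prob[j])})
    return pd.DataFrame(rows)
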