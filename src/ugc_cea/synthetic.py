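"""Synthetic natural-history inputs for the upper-GI screening model.

The transition probabilities, initial state distribution and mortality
tables behind the published cohort results are not printed; this module
generates structurally faithful stand-ins so every pipeline stage runs and
is testable end to end.  The generated tables make no claim of clinical
accuracy — they exercise the model's structure: bidirectional transitions
before intramucosal carcinoma, one-way progression after, age-increasing
background mortality, and 5-year-survival-derived advanced-cancer death.

Defaults emulate the study conditions: a closed cohort of 100,000 entering
at age 40 with ~97-98% healthy occupancy and small precancer fractions (as
detected in 40-44-year-olds), Gompertz-like background mortality rising from
~3 per 1,000 at 40 to ~5.5 per 100 at 80, and advanced-stage 5-year survival
around 20-25% per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults as d
from .params import MortalityTable, ParameterSet, TransitionTable
from .states import StateSpace, default_state_space

__all__ = ["SyntheticSpec", "default_state_space", "synth_transition_table",
           "synth_mortality_table", "synth_initial_distribution",
           "synth_parameter_set"]


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic natural-history generator.

    ``progression`` / ``regression`` / ``onset`` multiply the forward,
    backward, and healthy->lesion annual probabilities; ``jitter_sd`` is the
    SD of seeded lognormal noise applied per edge so different seeds yield
    different (but structurally identical) tables.
    """

    seed: int = 0
    progression: float = 1.0
    regression: float = 1.0
    onset: float = 1.0
    jitter_sd: float = 0.05
    mortality_at_40: float = 0.003
    mortality_at_80: float = 0.055
    advanced_survival_5yr: dict[str, float] = field(
        default_factory=lambda: {"esophagus": 0.20, "cardia": 0.20, "gastric": 0.25})

    def __post_init__(self) -> None:
        if min(self.progression, self.regression, self.onset) < 0:
            raise ValueError("intensities must be non-negative")


# baseline annual probabilities (before intensity scaling and jitter):
# (from, to, kind) with kind in {onset, forward, backward}
_EDGES = [
    ("healthy", "eso_mild_dysplasia", "onset", 0.0040),
    ("healthy", "cardia_im", "onset", 0.0030),
    ("healthy", "gastric_cag", "onset", 0.0060),
    # esophagus ladder
    ("eso_mild_dysplasia", "eso_moderate_dysplasia", "forward", 0.060),
    ("eso_moderate_dysplasia", "eso_severe_dysplasia_cis", "forward", 0.050),
    ("eso_severe_dysplasia_cis", "eso_early", "forward", 0.120),
    ("eso_early", "eso_advanced", "forward", 0.350),
    ("eso_mild_dysplasia", "healthy", "backward", 0.080),
    ("eso_moderate_dysplasia", "eso_mild_dysplasia", "backward", 0.060),
    ("eso_severe_dysplasia_cis", "eso_moderate_dysplasia", "backward", 0.040),
    # cardia ladder
    ("cardia_im", "cardia_lgin", "forward", 0.050),
    ("cardia_lgin", "cardia_hgin", "forward", 0.050),
    ("cardia_hgin", "cardia_early", "forward", 0.120),
    ("cardia_early", "cardia_advanced", "forward", 0.350),
    ("cardia_im", "healthy", "backward", 0.050),
    ("cardia_lgin", "cardia_im", "backward", 0.060),
    ("cardia_hgin", "cardia_lgin", "backward", 0.040),
    # gastric ladder
    ("gastric_cag", "gastric_im", "forward", 0.060),
    ("gastric_im", "gastric_lgin", "forward", 0.040),
    ("gastric_lgin", "gastric_hgin", "forward", 0.040),
    ("gastric_hgin", "gastric_early", "forward", 0.120),
    ("gastric_early", "gastric_advanced", "forward", 0.350),
    ("gastric_cag", "healthy", "backward", 0.050),
    ("gastric_im", "gastric_cag", "backward", 0.040),
    ("gastric_lgin", "gastric_im", "backward", 0.050),
    ("gastric_hgin", "gastric_lgin", "backward", 0.040),
]

_INITIAL_LESIONS = {
    # lesion fractions at cohort entry (ages 40-44 detection pattern):
    # low grades common, high grades rare, cancer very rare
    "eso_mild_dysplasia": 0.0060, "eso_moderate_dysplasia": 0.0025,
    "eso_severe_dysplasia_cis": 0.0008,
    "cardia_im": 0.0040, "cardia_lgin": 0.0015, "cardia_hgin": 0.0004,
    "gastric_cag": 0.0070, "gastric_im": 0.0035, "gastric_lgin": 0.0012,
    "gastric_hgin": 0.0004,
    "eso_early": 0.0001, "cardia_early": 0.0001, "gastric_early": 0.0002,
}


def synth_transition_table(spec: SyntheticSpec) -> TransitionTable:
    """Seeded annual transition table honouring the progression topology."""
    rng = np.random.default_rng(spec.seed)
    scale = {"onset": spec.onset, "forward": spec.progression, "backward": spec.regression}
    probs: dict[str, dict[str, float]] = {}
    for frm, to, kind, p in _EDGES:
        jitter = float(np.exp(rng.normal(0.0, spec.jitter_sd))) if spec.jitter_sd > 0 else 1.0
        q = min(p * scale[kind] * jitter, 1.0)
        probs.setdefault(frm, {})[to] = q
    # post-treatment follows the healthy state's onset transitions
    probs["post_treatment"] = dict(probs["healthy"])
    for frm, row in probs.items():
        total = sum(row.values())
        if total > 1.0:
            raise ValueError(f"synthetic intensities give row sum {total:.3f} > 1 for {frm!r}")
    return TransitionTable(probs)


def synth_mortality_table(spec: SyntheticSpec,
                          ages: tuple[int, int] = (40, 90)) -> MortalityTable:
    """Exponential-in-age background mortality plus advanced survival inputs."""
    lo, hi = ages
    b = np.log(spec.mortality_at_80 / spec.mortality_at_40) / 40.0
    other = {a: float(min(spec.mortality_at_40 * np.exp(b * (a - 40)), 1.0))
             for a in range(lo, hi + 1)}
    # small age-rising UGC background series (reporting only; deaths in the
    # model come from the advanced-cancer duration series)
    ugc = {a: float(min(2e-4 * np.exp(0.06 * (a - 40)), 1.0)) for a in range(lo, hi + 1)}
    return MortalityTable(other_cause=other, ugc=ugc,
                          advanced_survival_5yr=dict(spec.advanced_survival_5yr))


def synth_initial_distribution(space: StateSpace) -> dict[str, float]:
    dist = dict(_INITIAL_LESIONS)
    dist[space.healthy] = 1.0 - sum(dist.values())
    return dist


def synth_parameter_set(spec: SyntheticSpec | None = None) -> ParameterSet:
    """Complete ParameterSet: synthetic tables + published base-case scalars."""
    spec = spec or SyntheticSpec()
    space = default_state_space()
    ps = ParameterSet(
        state_space=space,
        transitions=synth_transition_table(spec),
        initial_distribution=synth_initial_distribution(space),
        mortality=synth_mortality_table(spec),
        utilities=d.default_utilities(),
        costs=d.default_costs(),
        test=d.default_test_characteristics(),
        compliance=d.default_compliance(),
        discount_rate=d.default_discount_rate(),
    )
    ps.validate()
    return ps
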