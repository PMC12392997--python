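"""Health-state definitions and the expanded (tunnel/surveillance) state space.

The natural-history model tracks three disease ladders — esophagus, cardia and
stomach — from low-grade precancerous lesions through early (intramucosal)
cancer to advanced cancer, alongside a single healthy state, a post-treatment
state for endoscopically cured lesions, and two absorbing death states
(upper-GI-cancer death and death from any other cause).

Before intramucosal carcinoma a lesion may progress, regress, or return to
healthy; after that point progression is one-way.  Advanced cancer carries
duration-dependent annual death probabilities, which requires duration-indexed
"tunnel" copies (years 1..5 since entry, then a constant 6+ bucket).  Lesions
enrolled in endoscopic surveillance (the follow-up arms) are tracked in
parallel copies of the pre-intramucosal states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORGANS = ("esophagus", "cardia", "gastric")

#: grade labels, ordered by severity along a ladder
GRADES = ("healthy", "precancer", "early_cancer", "advanced_cancer",
          "post_treatment", "death")

N_TUNNEL = 6  # durations 1..5 plus the constant 6+ bucket
SURV_PREFIX = "surv_"


@dataclass(frozen=True)
class StateDef:
    """One health state of the base (un-expanded) Markov model."""

    name: str
    organ: str              # esophagus | cardia | gastric | none
    grade: str              # one of GRADES
    pre_intramucosal: bool = False
    screen_detectable: bool = False

    def __post_init__(self) -> None:
        if self.organ not in ORGANS + ("none",):
            raise ValueError(f"unknown organ {self.organ!r} for state {self.name!r}")
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r} for state {self.name!r}")
        if self.pre_intramucosal and self.grade != "precancer":
            raise ValueError(
                f"state {self.name!r}: pre_intramucosal is only valid for precancer grades")


@dataclass(frozen=True)
class StateSpace:
    """Ordered collection of base states with structural helpers."""

    states: tuple[StateDef, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError("duplicate state names")
        if sum(s.grade == "healthy" for s in self.states) != 1:
            raise ValueError("state space must contain exactly one healthy state")
        if sum(s.grade == "death" for s in self.states) < 2:
            raise ValueError("state space needs >=2 absorbing death states")

    def __iter__(self):
        return iter(self.states)

    def __getitem__(self, name: str) -> StateDef:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.states)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def healthy(self) -> str:
        return next(s.name for s in self.states if s.grade == "healthy")

    @property
    def death_states(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states if s.grade == "death")

    @property
    def disease_states(self) -> tuple[str, ...]:
        """The organ-specific lesion/cancer states (16 in the default space)."""
        return tuple(s.name for s in self.states
                     if s.grade in ("precancer", "early_cancer", "advanced_cancer"))

    def of_grade(self, *grades: str) -> tuple[str, ...]:
        return tuple(s.name for s in self.states if s.grade in grades)

    @property
    def pre_intramucosal_states(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states if s.pre_intramucosal)


def default_state_space() -> StateSpace:
    """The bundled 16-disease-state space of the combined upper-GI model.

    Esophagus: mild dysplasia -> moderate dysplasia -> severe dysplasia/CIS
    -> early EC -> advanced EC.  Cardia: intestinal metaplasia -> LGIN ->
    HGIN -> early CC -> advanced CC.  Stomach: chronic atrophic gastritis ->
    IM -> LGIN -> HGIN -> early GC -> advanced GC.  Plus healthy,
    post-treatment, and two death states.
    """
    pre = dict(grade="precancer", pre_intramucosal=True, screen_detectable=True)
    early = dict(grade="early_cancer", screen_detectable=True)
    adv = dict(grade="advanced_cancer", screen_detectable=True)
    return StateSpace(states=(
        StateDef("healthy", "none", "healthy"),
        StateDef("eso_mild_dysplasia", "esophagus", **pre),
        StateDef("eso_moderate_dysplasia", "esophagus", **pre),
        StateDef("eso_severe_dysplasia_cis", "esophagus", **pre),
        StateDef("eso_early", "esophagus", **early),
        StateDef("eso_advanced", "esophagus", **adv),
        StateDef("cardia_im", "cardia", **pre),
        StateDef("cardia_lgin", "cardia", **pre),
        StateDef("cardia_hgin", "cardia", **pre),
        StateDef("cardia_early", "cardia", **early),
        StateDef("cardia_advanced", "cardia", **adv),
        StateDef("gastric_cag", "gastric", **pre),
        StateDef("gastric_im", "gastric", **pre),
        StateDef("gastric_lgin", "gastric", **pre),
        StateDef("gastric_hgin", "gastric", **pre),
        StateDef("gastric_early", "gastric", **early),
        StateDef("gastric_advanced", "gastric", **adv),
        StateDef("post_treatment", "none", "post_treatment"),
        StateDef("ugc_death", "none", "death"),
        StateDef("other_death", "none", "death"),
    ))


#: states whose screen detection triggers immediate endoscopic resection
#: (severe dysplasia / carcinoma in situ and high-grade neoplasia)
TREATABLE_PRECANCER = {
    "eso_severe_dysplasia_cis": "esophagus",
    "cardia_hgin": "cardia",
    "gastric_hgin": "gastric",
}


@dataclass
class ExpandedSpace:
    """Index layout of the expanded state vector used for cohort propagation.

    Expansion rules applied to a base :class:`StateSpace`:

    * every advanced-cancer state becomes ``N_TUNNEL`` duration-indexed
      tunnel copies ``<name>_d1 .. _d5, _d6`` (the d6 bucket is 6+ years);
    * every pre-intramucosal state gains a surveillance copy
      ``surv_<name>`` used by the follow-up arms;
    * all other states map one-to-one.
    """

    base: StateSpace
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.names = []
        self._base_of: list[str] = []   # base-state name behind each expanded index
        for s in self.base:
            if s.grade == "advanced_cancer":
                for k in range(1, N_TUNNEL + 1):
                    self.names.append(f"{s.name}_d{k}")
                    self._base_of.append(s.name)
            else:
                self.names.append(s.name)
                self._base_of.append(s.name)
        for s in self.base:
            if s.pre_intramucosal:
                self.names.append(SURV_PREFIX + s.name)
                self._base_of.append(s.name)
        self.index = {n: i for i, n in enumerate(self.names)}

    # -- structural queries -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.names)

    def base_state(self, i: int) -> StateDef:
        return self.base[self._base_of[i]]

    def entry_index(self, base_name: str) -> int:
        """Expanded index where mass entering ``base_name`` lands
        (duration-1 tunnel for advanced states)."""
        s = self.base[base_name]
        if s.grade == "advanced_cancer":
            return self.index[f"{base_name}_d1"]
        return self.index[base_name]

    def tunnel_indices(self, base_name: str) -> list[int]:
        return [self.index[f"{base_name}_d{k}"] for k in range(1, N_TUNNEL + 1)]

    def surv_index(self, base_name: str) -> int:
        return self.index[SURV_PREFIX + base_name]

    def is_surveilled(self, i: int) -> bool:
        return self.names[i].startswith(SURV_PREFIX)

    @property
    def death_indices(self) -> list[int]:
        return [self.index[n] for n in self.base.death_states]

    @property
    def live_indices(self) -> np.ndarray:
        dead = set(self.death_indices)
        return np.array([i for i in range(self.n) if i not in dead])

    def live_mask(self) -> np.ndarray:
        m = np.ones(self.n, dtype=bool)
        m[self.death_indices] = False
        return m

    def initial_vector(self, distribution: dict[str, float]) -> np.ndarray:
        """Map a base-state initial distribution onto the expanded vector."""
        v = np.zeros(self.n)
        for name, frac in distribution.items():
            v[self.entry_index(name)] += frac
        return v
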