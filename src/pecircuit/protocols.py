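"""Stimulus protocols: sensorimotor phases, training paradigms, input routing
and simulated optogenetic perturbations.

A "visual" drive v and a "motor prediction" drive m (both scalar, piecewise
constant, in 1/s) are organized into phases: baseline (v = m = 0), feedback
(v = m > 0, fully predicted sensation), feedback mismatch (m > v, predicted
sensation absent) and playback (v > m, unpredicted sensation). Routing of v
and m onto the populations is controlled by an :class:`InputConfiguration`.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .circuit_model import DriveVectors
from .connectivity import PopulationSizes
from .errors import ConfigurationError

__all__ = [
    "InputConfiguration",
    "Phase",
    "StimulusSequence",
    "generate_training_sequence",
    "make_test_triplet",
    "route_inputs",
    "apply_opto",
    "default_background",
    "OPTO_INACTIVATE",
    "OPTO_ACTIVATE",
]

OPTO_INACTIVATE = -8.0  # 1/s, added to the targeted population's drive
OPTO_ACTIVATE = 5.0  # 1/s

# background drives used with plastic networks [1/s]
PLASTIC_BACKGROUND = {"x_E": 28.0, "x_D": 0.0, "x_P": 2.0, "x_S": 2.0, "x_V": 2.0}

PARADIGMS = ("QT", "RT", "CT")
PHASE_KINDS = ("baseline", "feedback", "mismatch", "playback", "independent")


@dataclass(frozen=True)
class InputConfiguration:
    """Routing of visual (v) and motor (m) drives onto the populations.

    V_E, V_P : PC somata / PV neurons receive v
    M_P : PV neurons receive m
    f_SOM_visual : fraction f of SOM neurons receiving v (the rest get m)
    f_VIP_visual : fraction of VIP neurons receiving v; defaults to (1 - f)
        so that the standard single-parameter sweep couples the two
        populations, but can be set independently (e.g. SOM 90% / VIP 50%)
    dendrite_motor : PC apical dendrites receive m

    The default is the standard configuration: PC somata, PV and all SOM
    neurons get v; dendrites and all VIP neurons get m.
    """

    V_E: int = 1
    V_P: int = 1
    M_P: int = 0
    f_SOM_visual: float = 1.0
    f_VIP_visual: float | None = None
    dendrite_motor: bool = True

    def __post_init__(self) -> None:
        for name in ("V_E", "V_P", "M_P"):
            if getattr(self, name) not in (0, 1):
                raise ConfigurationError(f"{name} must be 0 or 1")
        if not 0.0 <= self.f_SOM_visual <= 1.0:
            raise ConfigurationError("f_SOM_visual must lie in [0, 1]")
        if self.f_VIP_visual is not None and not 0.0 <= self.f_VIP_visual <= 1.0:
            raise ConfigurationError("f_VIP_visual must lie in [0, 1]")


@dataclass(frozen=True)
class Phase:
    """One piecewise-constant stimulus phase. v, m in 1/s, duration in ms."""

    kind: str
    v: float = 0.0
    m: float = 0.0
    duration: float = 1000.0

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise ConfigurationError(f"unknown phase kind {self.kind!r}")
        if self.duration <= 0:
            raise ConfigurationError("phase duration must be positive")
        if self.v < 0 or self.m < 0:
            raise ConfigurationError("v and m must be nonnegative")
        ok = {
            "baseline": self.v == 0 and self.m == 0,
            "feedback": self.v == self.m and self.v > 0,
            "mismatch": self.m > self.v,
            "playback": self.v > self.m,
            "independent": True,
        }[self.kind]
        if not ok:
            raise ConfigurationError(
                f"(v={self.v}, m={self.m}) inconsistent with kind {self.kind!r}")


@dataclass
class StimulusSequence:
    """Ordered list of phases plus the seed that generated it."""

    phases: list[Phase]
    rng_seed: int | None = None

    def __iter__(self):
        return iter(self.phases)

    def __len__(self) -> int:
        return len(self.phases)

    @property
    def kinds(self) -> list[str]:
        return [p.kind for p in self.phases]

    def to_json(self) -> str:
        return json.dumps({"rng_seed": self.rng_seed,
                           "phases": [asdict(p) for p in self.phases]})

    @classmethod
    def from_json(cls, text: str) -> "StimulusSequence":
        obj = json.loads(text)
        return cls([Phase(**p) for p in obj["phases"]], obj.get("rng_seed"))


def generate_training_sequence(
    paradigm: str,
    n_stimuli: int,
    stim_max: float = 7.0,
    rng_seed: int | None = 0,
    stim_duration: float = 1000.0,
    baseline_duration: float = 1000.0,
    playback_m_frac: float = 0.0,
) -> StimulusSequence:
    """Training stimulus sequence for one of the three paradigms.

    QT (quasi-natural): alternating feedback (v = m = s) and playback
    (v = s, m = ``playback_m_frac * s``) stimuli, s ~ U[0, stim_max] per
    stimulus; the default playback carries no motor prediction at all.
    RT (random gain): v and m drawn independently from U[0, stim_max].
    CT (coupled): feedback stimuli only.

    Every stimulus is preceded by a baseline phase; ``n_stimuli`` counts the
    non-baseline phases.
    """
    if paradigm not in PARADIGMS:
        raise ConfigurationError(f"unknown paradigm {paradigm!r}; choose from {PARADIGMS}")
    if n_stimuli <= 0:
        raise ConfigurationError("n_stimuli must be positive")
    rng = np.random.default_rng(rng_seed)
    phases: list[Phase] = []
    for i in range(n_stimuli):
        phases.append(Phase("baseline", duration=baseline_duration))
        if paradigm == "QT":
            s = float(rng.uniform(0.0, stim_max))
            if i % 2 == 0:
                phases.append(_stim_phase(s, s, stim_duration))
            else:
                phases.append(_stim_phase(s, playback_m_frac * s, stim_duration))
        elif paradigm == "RT":
            v = float(rng.uniform(0.0, stim_max))
            m = float(rng.uniform(0.0, stim_max))
            phases.append(Phase("independent", v=v, m=m, duration=stim_duration))
        else:  # CT
            s = float(rng.uniform(0.0, stim_max))
            phases.append(_stim_phase(s, s, stim_duration))
    return StimulusSequence(phases, rng_seed)


def _stim_phase(v: float, m: float, duration: float) -> Phase:
    if v == m:
        kind = "baseline" if v == 0 else "feedback"
    elif m > v:
        kind = "mismatch"
    else:
        kind = "playback"
    return Phase(kind, v=v, m=m, duration=duration)


def make_test_triplet(strength: float, mm_v: float = 0.0, pb_m: float = 0.0,
                      duration: float = 1000.0) -> StimulusSequence:
    """The feedback / mismatch / playback test: [BL, FB, BL, MM, BL, PB].

    ``mm_v`` and ``pb_m`` allow partial mismatches (v = mm_v <= m in MM,
    m = pb_m <= v in PB) for response sweeps; defaults are the full
    conditions. At ``mm_v == strength`` (or ``pb_m == strength``) the phase
    degenerates to feedback and is labeled accordingly.
    """
    if strength <= 0:
        raise ConfigurationError("test stimulus strength must be positive")
    if not (0 <= mm_v <= strength) or not (0 <= pb_m <= strength):
        raise ConfigurationError("partial-mismatch drives must lie in [0, strength]")
    bl = Phase("baseline", duration=duration)
    return StimulusSequence([
        bl, Phase("feedback", v=strength, m=strength, duration=duration),
        bl, _stim_phase(mm_v, strength, duration),
        bl, _stim_phase(strength, pb_m, duration),
    ])


def som_vip_split(config: InputConfiguration, sizes: PopulationSizes) -> tuple[int, int]:
    """Number of SOM / VIP units assigned to the visual group.

    The first ``ceil(f * N_SOM)`` SOM units and the first
    ``ceil(f_VIP * N_VIP)`` VIP units receive v; the remainder receive m.
    """
    f = config.f_SOM_visual
    f_vip = (1.0 - f) if config.f_VIP_visual is None else config.f_VIP_visual
    return (math.ceil(f * sizes.N_SOM), math.ceil(f_vip * sizes.N_VIP))


def route_inputs(config: InputConfiguration, phase: Phase,
                 background: DriveVectors, sizes: PopulationSizes) -> DriveVectors:
    """Add the phase's v/m drives to the background according to the routing
    configuration. Unit-to-group assignment for the fractional SOM/VIP split
    is fixed (leading units form the visual group)."""
    d = background.copy()
    v, m = phase.v, phase.m
    d.x_E += config.V_E * v
    if config.dendrite_motor:
        d.x_D += m
    d.x_P += config.V_P * v + config.M_P * m
    n_som_v, n_vip_v = som_vip_split(config, sizes)
    d.x_S[:n_som_v] += v
    d.x_S[n_som_v:] += m
    d.x_V[:n_vip_v] += v
    d.x_V[n_vip_v:] += m
    return d


def apply_opto(drives: DriveVectors, population: str, mode: str | None) -> DriveVectors:
    """Add an optogenetic offset to every unit of one interneuron population.

    Inactivation adds -8 1/s, activation +5 1/s, entering the external drive
    before rate rectification (so partial inactivation is possible).
    ``mode=None`` is the identity (control condition)."""
    if mode is None or mode == "none":
        return drives.copy()
    if population not in ("PV", "SOM", "VIP"):
        raise ConfigurationError(f"unknown population {population!r}")
    if mode not in ("inactivate", "activate"):
        raise ConfigurationError(f"unknown opto mode {mode!r}")
    offset = OPTO_INACTIVATE if mode == "inactivate" else OPTO_ACTIVATE
    d = drives.copy()
    target = {"PV": d.x_P, "SOM": d.x_S, "VIP": d.x_V}[population]
    target += offset
    return d


def default_background(config: InputConfiguration | None,
                       sizes: PopulationSizes) -> DriveVectors:
    """Background drives for plastic networks (x_E = 28, x_D = 0, others 2)."""
    return DriveVectors.from_scalars(**PLASTIC_BACKGROUND, sizes=sizes.as_tuple())
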