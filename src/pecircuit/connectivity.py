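"""Random network construction.

Connections are drawn with fixed in-degree: every neuron of a given type
receives exactly ``k = round(N_pre * p)`` synapses for each afferent pathway,
with partners chosen uniformly at random without replacement (self-connections
excluded within a population). Each realized weight is the pathway's mean
strength divided by the in-degree, so the summed afferent weight equals the
configured mean and population rates are independent of network size.

Inhibitory weights are stored as nonnegative magnitudes and enter the rate
equations with minus signs (Dale's principle by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from . import theory

__all__ = [
    "PopulationSizes",
    "ConnectivitySpec",
    "WeightSet",
    "PATHWAYS",
    "DEFAULT_PROBS",
    "build_network",
    "default_nonplastic_weights",
    "default_plastic_weights",
    "enforce_dale",
]

# pathway -> (postsynaptic population, presynaptic population);
# "D" is the PC dendritic compartment (postsynaptic only)
PATHWAYS: dict[str, tuple[str, str]] = {
    "EP": ("E", "P"),  # PV -> PC soma
    "DE": ("D", "E"),  # PC -> PC dendrite (recurrent excitation)
    "DS": ("D", "S"),  # SOM -> PC dendrite
    "PE": ("P", "E"),
    "PP": ("P", "P"),
    "PS": ("P", "S"),
    "PV": ("P", "V"),
    "SE": ("S", "E"),
    "SV": ("S", "V"),
    "VE": ("V", "E"),
    "VS": ("V", "S"),
}

# connection probabilities (experimental literature); absent pathways omitted
DEFAULT_PROBS: dict[str, float] = {
    "EP": 0.60,
    "DE": 0.10,
    "DS": 0.55,
    "PE": 0.45,
    "PP": 0.50,
    "PS": 0.60,
    "PV": 0.50,
    "SE": 0.35,
    "SV": 0.50,
    "VE": 0.10,
    "VS": 0.45,
}

# fixed mean strengths shared by all network variants
FIXED_MEANS: dict[str, float] = {"DE": 0.42, "SE": 1.0, "SV": 0.61, "VE": 1.0, "VS": 0.5}

# plastic pathways under the standard (backprop / local) training setups
DEFAULT_PLASTIC: frozenset[str] = frozenset({"EP", "DS", "PS", "PV"})


@dataclass(frozen=True)
class PopulationSizes:
    """Population counts; defaults follow the 70 PC / 10+10+10 interneuron
    composition of mouse V1 layer 2/3."""

    N_PC: int = 70
    N_PV: int = 10
    N_SOM: int = 10
    N_VIP: int = 10

    def __post_init__(self) -> None:
        if min(self.N_PC, self.N_PV, self.N_SOM, self.N_VIP) <= 0:
            raise ConfigurationError("population sizes must be positive")

    def n(self, pop: str) -> int:
        return {"E": self.N_PC, "D": self.N_PC, "P": self.N_PV,
                "S": self.N_SOM, "V": self.N_VIP}[pop]

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.N_PC, self.N_PV, self.N_SOM, self.N_VIP)

    @classmethod
    def scaled(cls, factor: float) -> "PopulationSizes":
        d = cls()
        return cls(*(int(round(factor * x)) for x in d.as_tuple()))


@dataclass
class ConnectivitySpec:
    """Connection probabilities and mean strengths per pathway.

    ``mean_w`` entries are nonnegative magnitudes; signs are structural.
    ``uniform_init`` pathways have each realized connection drawn from
    ``U(init_range) * mean / k`` instead of the exact ``mean / k``.
    """

    prob: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROBS))
    mean_w: dict[str, float] = field(default_factory=dict)
    plastic: frozenset[str] = frozenset()
    uniform_init: frozenset[str] = frozenset()
    init_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        for pw, p in self.prob.items():
            if pw not in PATHWAYS:
                raise ConfigurationError(f"unknown pathway {pw!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability for {pw} outside [0, 1]")
        for pw, w in self.mean_w.items():
            if w < 0:
                raise ConfigurationError(f"mean strength for {pw} must be >= 0")


def in_degree(n_pre: int, p: float) -> int:
    """Fixed in-degree: round-half-away-from-zero of N_pre * p."""
    return int(np.floor(n_pre * p + 0.5))


@dataclass
class WeightSet:
    """All synaptic weight matrices, stored as nonnegative magnitudes.

    Shapes are (N_post, N_pre). ``masks`` holds the immutable zero pattern of
    each pathway; ``plastic`` names the learnable pathways.
    """

    w_EP: np.ndarray
    w_DE: np.ndarray
    w_DS: np.ndarray
    w_PE: np.ndarray
    w_PP: np.ndarray
    w_PS: np.ndarray
    w_PV: np.ndarray
    w_SE: np.ndarray
    w_SV: np.ndarray
    w_VE: np.ndarray
    w_VS: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    plastic: frozenset[str] = frozenset()

    def matrix(self, pathway: str) -> np.ndarray:
        return getattr(self, f"w_{pathway}")

    def mask(self, pathway: str) -> np.ndarray:
        return self.masks[pathway]

    def effective(self) -> dict[str, float]:
        """Population-summed weights: mean over postsynaptic neurons of the
        summed afferent magnitude, one scalar per pathway (the mean-field
        collapse used by the analytic constraints)."""
        return {pw: float(self.matrix(pw).sum(axis=1).mean()) for pw in PATHWAYS}

    def copy(self) -> "WeightSet":
        return WeightSet(
            **{f"w_{pw}": self.matrix(pw).copy() for pw in PATHWAYS},
            masks={pw: m.copy() for pw, m in self.masks.items()},
            plastic=self.plastic,
        )

    @property
    def sizes(self) -> PopulationSizes:
        return PopulationSizes(self.w_DE.shape[0], self.w_EP.shape[1],
                               self.w_DS.shape[1], self.w_PV.shape[1])


def _draw_block(n_post: int, n_pre: int, p: float, mean: float, uniform: bool,
                init_range: tuple[float, float], self_excluded: bool,
                rng: np.random.Generator, pathway: str) -> tuple[np.ndarray, np.ndarray]:
    w = np.zeros((n_post, n_pre))
    mask = np.zeros((n_post, n_pre), dtype=bool)
    if p == 0.0:
        return w, mask
    k = in_degree(n_pre, p)
    if k < 1:
        raise ConfigurationError(
            f"pathway {pathway}: in-degree round({n_pre}*{p}) = 0; "
            "increase the population size or probability")
    n_avail = n_pre - 1 if self_excluded else n_pre
    if k > n_avail:
        raise ConfigurationError(
            f"pathway {pathway}: in-degree {k} exceeds available partners {n_avail}")
    for i in range(n_post):
        cand = np.delete(np.arange(n_pre), i) if self_excluded else np.arange(n_pre)
        pre = rng.choice(cand, size=k, replace=False)
        mask[i, pre] = True
        if uniform:
            lo, hi = init_range
            w[i, pre] = rng.uniform(lo * mean, hi * mean, size=k) / k
        else:
            w[i, pre] = mean / k
    return w, mask


def build_network(sizes: PopulationSizes, spec: ConnectivitySpec,
                  rng_seed: int | np.random.Generator = 0) -> WeightSet:
    """Draw a random fixed-in-degree network from a connectivity spec.

    Pathways with probability 0 (or absent from ``spec.prob``) come out as
    all-zero blocks. Pathways named in ``spec.uniform_init`` get per-connection
    uniform initial strengths; all others get the exact ``mean / k``.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    mats: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for pw, (post, pre) in PATHWAYS.items():
        p = spec.prob.get(pw, 0.0)
        mean = spec.mean_w.get(pw, 0.0)
        self_excluded = PATHWAYS[pw][0].replace("D", "E") == PATHWAYS[pw][1]
        w, mask = _draw_block(sizes.n(post), sizes.n(pre), p, mean,
                              pw in spec.uniform_init, spec.init_range,
                              self_excluded, rng, pw)
        mats[f"w_{pw}"] = w
        masks[pw] = mask
    return WeightSet(**mats, masks=masks, plastic=spec.plastic)


def _constrained_pv_weights(input_config, w_PP: float, w_EP: float) -> tuple[float, float]:
    mf = theory.MeanFieldNetwork(
        w_EP=w_EP, w_PP=w_PP, w_SV=FIXED_MEANS["SV"], w_VS=FIXED_MEANS["VS"],
        V_E=input_config.V_E, V_P=input_config.V_P, M_P=input_config.M_P,
    )
    return theory.solve_constraints(mf)


def default_nonplastic_weights(input_config, sizes: PopulationSizes | None = None,
                               rng_seed: int = 0, w_VE: float = FIXED_MEANS["VE"],
                               ) -> WeightSet:
    """Non-plastic network with the fixed mean strengths, wPP selected by
    whether PCs receive visual input, and (wPS, wPV) from the analytic
    E/I-balance constraints. Raises on Dale-violating configurations."""
    sizes = sizes or PopulationSizes()
    w_EP, w_DS, w_PE = 2.8, 3.5, 1.5
    w_PP = 0.1 if input_config.V_E else 1.5
    w_PS, w_PV = _constrained_pv_weights(input_config, w_PP, w_EP)
    means = dict(FIXED_MEANS, VE=w_VE, EP=w_EP, DS=w_DS, PE=w_PE, PP=w_PP,
                 PS=w_PS, PV=w_PV)
    spec = ConnectivitySpec(mean_w=means)
    return build_network(sizes, spec, rng_seed)


# initial means for plastic networks, by whether PCs receive visual input
_PLASTIC_MEANS_VISUAL = {"EP": 1.75, "DS": 0.35, "PE": 2.5, "PP": 0.5,
                         "PS": 0.3, "PV": 0.6}
_PLASTIC_MEANS_NOVISUAL = {"EP": 1.75, "DS": 0.35, "PE": 1.2, "PP": 1.5,
                           "PS": 0.3, "PV": 0.6}


def default_plastic_weights(input_config, sizes: PopulationSizes | None = None,
                            rng_seed: int = 0, plastic_pe: bool = False,
                            w_VE: float = FIXED_MEANS["VE"]) -> WeightSet:
    """Plastic network with all initial connections drawn from
    ``U(0.5 w, 1.5 w) / k``. ``plastic_pe`` additionally marks the PC->PV
    pathway as learnable (the homeostatic-PV rule variant)."""
    sizes = sizes or PopulationSizes()
    init = _PLASTIC_MEANS_VISUAL if input_config.V_E else _PLASTIC_MEANS_NOVISUAL
    means = dict(FIXED_MEANS, VE=w_VE, **init)
    plastic = DEFAULT_PLASTIC | ({"PE"} if plastic_pe else set())
    spec = ConnectivitySpec(mean_w=means, plastic=frozenset(plastic),
                            uniform_init=frozenset(PATHWAYS))
    return build_network(sizes, spec, rng_seed)


def enforce_dale(weights: WeightSet) -> WeightSet:
    """Clip all magnitudes at zero (in place) and re-apply the zero pattern.

    Called after every plasticity step so no negative magnitude is ever
    persisted."""
    for pw in PATHWAYS:
        w = weights.matrix(pw)
        np.maximum(w, 0.0, out=w)
        w[~weights.masks[pw]] = 0.0
    return weights
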