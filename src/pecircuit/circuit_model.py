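"""Rate dynamics of the layer-2/3 microcircuit.

Excitatory pyramidal cells (PCs) are two-compartment rate units: a somatic
compartment with rheobase ``theta`` and an apical dendrite that can emit a
calcium event (a threshold-triggered extra current) and whose net input is
rectified before it reaches the soma, so an excess of dendritic inhibition
cannot hyperpolarize the somatic rate. PV, SOM and VIP interneurons are
rectified linear point neurons with a fast time constant.

All rates are in 1/s, all times in ms; synaptic "currents" are expressed in
rate units (the rate-to-current gain ``gain_g`` is only applied in analysis
when currents are reported in pA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "PCParams",
    "InterneuronParams",
    "NetworkState",
    "DriveVectors",
    "Traces",
    "somatic_synaptic_input",
    "dendritic_synaptic_input",
    "calcium_event",
    "total_somatic_input",
    "rate_derivatives",
    "integrate",
    "simulate_phases",
]

DT_MIN = 0.05  # ms
DT_MAX = 2.0  # ms


@dataclass
class PCParams:
    """Two-compartment pyramidal-cell parameters.

    tau_E : somatic rate time constant [ms]
    theta : rheobase [1/s]
    lambda_D, lambda_E : fraction of current leaking away from dendrite / soma
    c_amp : calcium-event amplitude [1/s]
    theta_c : calcium-event threshold on the total dendritic input [1/s]
    gain_g : rate-to-current gain [1/(pA*s)]; used only for pA readouts
    dendritic_rectification : if False, the dendrite-to-soma rectification is
        disabled (model variant without the dendritic nonlinearity)
    strict_calcium_threshold : Heaviside convention at threshold; True means
        H(0) = 0, i.e. a calcium event needs strictly suprathreshold input
    """

    tau_E: float = 60.0
    theta: float = 14.0
    lambda_D: float = 0.27
    lambda_E: float = 0.31
    c_amp: float = 7.0
    theta_c: float = 28.0
    gain_g: float = 0.07
    dendritic_rectification: bool = True
    strict_calcium_threshold: bool = True

    def __post_init__(self) -> None:
        if self.tau_E <= 0:
            raise ConfigurationError("tau_E must be positive")
        if not (0.0 <= self.lambda_D <= 1.0 and 0.0 <= self.lambda_E <= 1.0):
            raise ConfigurationError("lambda_D and lambda_E must lie in [0, 1]")
        if self.c_amp < 0:
            raise ConfigurationError("c_amp must be nonnegative")
        if self.theta_c <= 0:
            raise ConfigurationError("theta_c must be positive")
        if self.gain_g <= 0:
            raise ConfigurationError("gain_g must be positive")


@dataclass
class InterneuronParams:
    """Interneuron rate time constant [ms]; shared by PV, SOM and VIP."""

    tau_I: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_I <= 0:
            raise ConfigurationError("tau_I must be positive")


@dataclass
class NetworkState:
    """Firing rates of all populations at time ``t`` [ms]; rates in 1/s."""

    r_E: np.ndarray
    r_P: np.ndarray
    r_S: np.ndarray
    r_V: np.ndarray
    t: float = 0.0

    @classmethod
    def zeros(cls, n_pc: int, n_pv: int, n_som: int, n_vip: int) -> "NetworkState":
        return cls(
            r_E=np.zeros(n_pc),
            r_P=np.zeros(n_pv),
            r_S=np.zeros(n_som),
            r_V=np.zeros(n_vip),
        )

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.r_E.copy(), self.r_P.copy(), self.r_S.copy(), self.r_V.copy(), self.t
        )


@dataclass
class DriveVectors:
    """Per-neuron external drives [1/s]: background plus routed v/m plus any
    optogenetic offset. ``x_E`` targets PC somata, ``x_D`` PC dendrites."""

    x_E: np.ndarray
    x_D: np.ndarray
    x_P: np.ndarray
    x_S: np.ndarray
    x_V: np.ndarray

    @classmethod
    def from_scalars(
        cls,
        x_E: float,
        x_D: float,
        x_P: float,
        x_S: float,
        x_V: float,
        sizes: tuple[int, int, int, int],
    ) -> "DriveVectors":
        n_pc, n_pv, n_som, n_vip = sizes
        return cls(
            x_E=np.full(n_pc, float(x_E)),
            x_D=np.full(n_pc, float(x_D)),
            x_P=np.full(n_pv, float(x_P)),
            x_S=np.full(n_som, float(x_S)),
            x_V=np.full(n_vip, float(x_V)),
        )

    def copy(self) -> "DriveVectors":
        return DriveVectors(*(getattr(self, f).copy() for f in ("x_E", "x_D", "x_P", "x_S", "x_V")))


def _check_matvec(w: np.ndarray, r: np.ndarray, name: str) -> None:
    if w.ndim != 2 or w.shape[1] != r.shape[0]:
        raise ConfigurationError(
            f"{name}: weight shape {w.shape} not conformable with rate vector "
            f"of length {r.shape[0]}"
        )


def somatic_synaptic_input(x_E: np.ndarray, r_P: np.ndarray, w_EP: np.ndarray) -> np.ndarray:
    """Net synaptic input to PC somata: external drive minus PV inhibition.

    Not rectified here; rectification happens at the rate nonlinearity.
    """
    _check_matvec(w_EP, r_P, "somatic_synaptic_input")
    return x_E - w_EP @ r_P


def dendritic_synaptic_input(
    x_D: np.ndarray,
    r_S: np.ndarray,
    r_E: np.ndarray,
    w_DS: np.ndarray,
    w_DE: np.ndarray,
) -> np.ndarray:
    """Net synaptic input to PC dendrites: motor prediction, minus SOM
    inhibition, plus recurrent PC excitation."""
    _check_matvec(w_DS, r_S, "dendritic_synaptic_input")
    _check_matvec(w_DE, r_E, "dendritic_synaptic_input")
    return x_D - w_DS @ r_S + w_DE @ r_E


def calcium_event(I_D0: np.ndarray, pc: PCParams) -> np.ndarray:
    """Calcium-event current: ``c_amp`` where the total dendritic input
    exceeds ``theta_c``, else zero."""
    if pc.strict_calcium_threshold:
        above = I_D0 > pc.theta_c
    else:
        above = I_D0 >= pc.theta_c
    return np.where(above, pc.c_amp, 0.0)


def total_somatic_input(
    I_E_syn: np.ndarray, I_D_syn: np.ndarray, c: np.ndarray, pc: PCParams
) -> np.ndarray:
    """Total somatic input: rectified dendritic contribution (synaptic input
    plus calcium event) scaled by ``lambda_D``, plus the somatic synaptic
    input scaled by ``1 - lambda_E``."""
    bracket = I_D_syn + c
    if pc.dendritic_rectification:
        bracket = np.maximum(bracket, 0.0)
    return pc.lambda_D * bracket + (1.0 - pc.lambda_E) * I_E_syn


def _derivatives(
    r_E: np.ndarray,
    r_P: np.ndarray,
    r_S: np.ndarray,
    r_V: np.ndarray,
    weights,
    drives: DriveVectors,
    pc: PCParams,
    inh: InterneuronParams,
):
    """Core right-hand side. Returns derivatives and dendritic diagnostics."""
    I_E_syn = drives.x_E - weights.w_EP @ r_P
    I_D_syn = drives.x_D - weights.w_DS @ r_S + weights.w_DE @ r_E
    I_D0 = pc.lambda_E * I_E_syn + (1.0 - pc.lambda_D) * I_D_syn
    c = calcium_event(I_D0, pc)
    I = total_somatic_input(I_E_syn, I_D_syn, c, pc)
    d_rE = (-r_E + np.maximum(I - pc.theta, 0.0)) / pc.tau_E

    net_P = drives.x_P + weights.w_PE @ r_E - weights.w_PP @ r_P \
        - weights.w_PS @ r_S - weights.w_PV @ r_V
    net_S = drives.x_S + weights.w_SE @ r_E - weights.w_SV @ r_V
    net_V = drives.x_V + weights.w_VE @ r_E - weights.w_VS @ r_S
    d_rP = (-r_P + net_P) / inh.tau_I
    d_rS = (-r_S + net_S) / inh.tau_I
    d_rV = (-r_V + net_V) / inh.tau_I

    # derivative zeroing at the rectification boundary: a silent unit with
    # negative net drive stays silent
    d_rP = np.where((r_P <= 0.0) & (d_rP < 0.0), 0.0, d_rP)
    d_rS = np.where((r_S <= 0.0) & (d_rS < 0.0), 0.0, d_rS)
    d_rV = np.where((r_V <= 0.0) & (d_rV < 0.0), 0.0, d_rV)
    d_rE = np.where((r_E <= 0.0) & (d_rE < 0.0), 0.0, d_rE)
    return d_rE, d_rP, d_rS, d_rV, I_E_syn, I_D_syn, I_D0, c


def rate_derivatives(state: NetworkState, weights, drives: DriveVectors,
                     pc: PCParams | None = None,
                     inh: InterneuronParams | None = None):
    """Time derivatives of all population rates [1/s per ms].

    PC somata follow a rectified threshold-linear law with rheobase ``theta``;
    interneurons are rectified linear units. Derivatives are zeroed at the
    r = 0 boundary when the net drive is negative so rates never go negative.
    """
    pc = pc or PCParams()
    inh = inh or InterneuronParams()
    d = _derivatives(state.r_E, state.r_P, state.r_S, state.r_V,
                     weights, drives, pc, inh)
    return d[:4]


@dataclass
class Traces:
    """Recorded rate and current traces. ``time`` in ms, rates in 1/s.

    Rate arrays have shape (n_samples, n_neurons); dendritic diagnostics
    (``I_E_syn``, ``I_D_syn``, ``I_D0``, ``calcium``) refer to PCs.
    """

    time: np.ndarray
    r_E: np.ndarray
    r_P: np.ndarray
    r_S: np.ndarray
    r_V: np.ndarray
    I_E_syn: np.ndarray
    I_D_syn: np.ndarray
    I_D0: np.ndarray
    calcium: np.ndarray

    @staticmethod
    def concatenate(parts: Sequence["Traces"]) -> "Traces":
        return Traces(*(np.concatenate([getattr(p, f.name) for p in parts])
                        for f in Traces.__dataclass_fields__.values()))  # type: ignore[arg-type]


def _rk2_step(r_E, r_P, r_S, r_V, weights, drives, pc, inh, dt):
    """One Heun step; states clamped nonnegative after each stage."""
    k1 = _derivatives(r_E, r_P, r_S, r_V, weights, drives, pc, inh)
    e1 = np.maximum(r_E + dt * k1[0], 0.0)
    p1 = np.maximum(r_P + dt * k1[1], 0.0)
    s1 = np.maximum(r_S + dt * k1[2], 0.0)
    v1 = np.maximum(r_V + dt * k1[3], 0.0)
    k2 = _derivatives(e1, p1, s1, v1, weights, drives, pc, inh)
    h = 0.5 * dt
    r_E = np.maximum(r_E + h * (k1[0] + k2[0]), 0.0)
    r_P = np.maximum(r_P + h * (k1[1] + k2[1]), 0.0)
    r_S = np.maximum(r_S + h * (k1[2] + k2[2]), 0.0)
    r_V = np.maximum(r_V + h * (k1[3] + k2[3]), 0.0)
    return r_E, r_P, r_S, r_V


def _validate_dt(dt: float, allow_any_dt: bool) -> None:
    if not allow_any_dt and not (DT_MIN <= dt <= DT_MAX):
        raise ConfigurationError(
            f"dt={dt} ms outside the supported window [{DT_MIN}, {DT_MAX}] ms "
            "(pass allow_any_dt=True to override)"
        )


def _weight_args(weights):
    return (weights.w_EP, weights.w_DE, weights.w_DS, weights.w_PE,
            weights.w_PP, weights.w_PS, weights.w_PV, weights.w_SE,
            weights.w_SV, weights.w_VE, weights.w_VS)


def _param_args(pc: PCParams, inh: InterneuronParams):
    return (pc.tau_E, pc.theta, pc.lambda_D, pc.lambda_E, pc.c_amp,
            pc.theta_c, bool(pc.dendritic_rectification),
            bool(pc.strict_calcium_threshold), inh.tau_I)


def integrate(
    state: NetworkState,
    weights,
    drives: DriveVectors,
    dt: float = 0.1,
    duration: float = 1000.0,
    record_every: float = 1.0,
    pc: PCParams | None = None,
    inh: InterneuronParams | None = None,
    allow_any_dt: bool = False,
    engine: str = "auto",
) -> tuple[NetworkState, Traces]:
    """Integrate the network with Heun's method (2nd-order Runge-Kutta).

    ``state`` is advanced in place-semantics-free fashion: the returned state
    is a new object at time ``state.t + duration``. Rates are clamped at zero
    after every stage. Diagnostics are sampled every ``record_every`` ms.

    ``engine`` selects the inner loop: "numpy" forces the reference
    implementation, "auto" uses the jitted kernel when numba is available
    (bit-identical math; a regression test asserts agreement).
    """
    _validate_dt(dt, allow_any_dt)
    pc = pc or PCParams()
    inh = inh or InterneuronParams()

    from . import _kernels
    if engine == "auto" and _kernels.HAVE_NUMBA:
        return _integrate_kernel(state, weights, drives, dt, duration,
                                 record_every, pc, inh)

    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    n_rec = n_steps // rec_stride

    r_E, r_P, r_S, r_V = (state.r_E.copy(), state.r_P.copy(),
                          state.r_S.copy(), state.r_V.copy())
    time = np.empty(n_rec)
    out_E = np.empty((n_rec, r_E.size))
    out_P = np.empty((n_rec, r_P.size))
    out_S = np.empty((n_rec, r_S.size))
    out_V = np.empty((n_rec, r_V.size))
    out_IE = np.empty((n_rec, r_E.size))
    out_ID = np.empty((n_rec, r_E.size))
    out_ID0 = np.empty((n_rec, r_E.size))
    out_c = np.empty((n_rec, r_E.size))

    j = 0
    for i in range(1, n_steps + 1):
        r_E, r_P, r_S, r_V = _rk2_step(r_E, r_P, r_S, r_V, weights, drives, pc, inh, dt)
        if i % rec_stride == 0:
            _, _, _, _, IE, ID, ID0, c = _derivatives(
                r_E, r_P, r_S, r_V, weights, drives, pc, inh)
            time[j] = state.t + i * dt
            out_E[j] = r_E
            out_P[j] = r_P
            out_S[j] = r_S
            out_V[j] = r_V
            out_IE[j] = IE
            out_ID[j] = ID
            out_ID0[j] = ID0
            out_c[j] = c
            j += 1

    new_state = NetworkState(r_E, r_P, r_S, r_V, t=state.t + n_steps * dt)
    traces = Traces(time[:j], out_E[:j], out_P[:j], out_S[:j], out_V[:j],
                    out_IE[:j], out_ID[:j], out_ID0[:j], out_c[:j])
    return new_state, traces


def _integrate_kernel(state, weights, drives, dt, duration, record_every, pc, inh):
    from . import _kernels

    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    n_rec = n_steps // rec_stride
    r_E, r_P, r_S, r_V = (state.r_E.copy(), state.r_P.copy(),
                          state.r_S.copy(), state.r_V.copy())
    n_E, n_P, n_S, n_V = r_E.size, r_P.size, r_S.size, r_V.size
    time = np.empty(n_rec)
    out = {k: np.empty((n_rec, n)) for k, n in
           (("r_E", n_E), ("r_P", n_P), ("r_S", n_S), ("r_V", n_V),
            ("I_E_syn", n_E), ("I_D_syn", n_E), ("I_D0", n_E), ("calcium", n_E))}
    dummy_mask = np.empty((0, 0), dtype=np.bool_)
    dummy_vecE = np.zeros(n_E)
    dummy_vecP = np.zeros(n_P)
    dummy_pm = np.empty((0, 0))
    acc = np.zeros(n_E)
    acc_p = np.zeros(n_P)
    j = _kernels.run_phase(
        r_E, r_P, r_S, r_V, *_weight_args(weights),
        drives.x_E, drives.x_D, drives.x_P, drives.x_S, drives.x_V,
        *_param_args(pc, inh), dt, n_steps,
        _kernels.VARIANT_NONE, 1, 0.0, 0.0, 0.0, 0.0, 0.0,
        dummy_vecE, dummy_vecP, dummy_mask, dummy_mask, dummy_mask,
        dummy_mask, dummy_mask, dummy_pm,
        False, False, False, False, False,
        rec_stride, time, out["r_E"], out["r_P"], out["r_S"], out["r_V"],
        out["I_E_syn"], out["I_D_syn"], out["I_D0"], out["calcium"],
        state.t, acc, acc_p)
    new_state = NetworkState(r_E, r_P, r_S, r_V, t=state.t + n_steps * dt)
    traces = Traces(time[:j], *(out[k][:j] for k in
                                ("r_E", "r_P", "r_S", "r_V", "I_E_syn",
                                 "I_D_syn", "I_D0", "calcium")))
    return new_state, traces


def simulate_phases(
    weights,
    drive_list: Sequence[tuple[DriveVectors, float]],
    state: NetworkState | None = None,
    dt: float = 0.1,
    record_every: float = 1.0,
    pc: PCParams | None = None,
    inh: InterneuronParams | None = None,
) -> tuple[NetworkState, Traces, list[tuple[float, float]]]:
    """Run a sequence of (drives, duration [ms]) segments, carrying state.

    Returns the final state, concatenated traces, and the (start, end) time
    window of each segment.
    """
    if state is None:
        n_pc = weights.w_DE.shape[0]
        state = NetworkState.zeros(n_pc, weights.w_EP.shape[1],
                                   weights.w_DS.shape[1], weights.w_PV.shape[1])
    parts: list[Traces] = []
    windows: list[tuple[float, float]] = []
    for drives, duration in drive_list:
        t0 = state.t
        state, tr = integrate(state, weights, drives, dt=dt, duration=duration,
                              record_every=record_every, pc=pc, inh=inh)
        parts.append(tr)
        windows.append((t0, state.t))
    return state, Traces.concatenate(parts), windows
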