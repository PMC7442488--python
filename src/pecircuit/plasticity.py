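"""Experience-dependent inhibitory plasticity and the training loop.

All rules share the form  dw ∝ ±(post − baseline) · pre  and act only on
existing connections (the zero pattern is immutable); magnitudes are clipped
at zero after every update so Dale's principle always holds.

Three rule variants set the weights onto PV neurons:

``backprop``
    SOM->PV and VIP->PV weights follow an approximation of a backpropagation
    of error: the update is driven by the mean deviation from baseline of the
    PCs each PV neuron inhibits.
``local_recurrent``
    The backprop error is replaced by a locally available proxy, the
    deviation of the excitatory recurrent drive onto the PV neuron from its
    target value (accurate when PC->PV connectivity is dense; a
    feedback-alignment-style approximation).
``pv_homeostatic``
    For configurations in which PCs receive no direct visual input, PV
    neurons themselves can be held at a target rate: SOM->PV and VIP->PV
    follow a homeostatic inhibitory rule and PC->PV an anti-Hebbian rule.

In every variant, PV->PC-soma weights follow an inhibitory Hebbian rule that
establishes the PC baseline rate, and SOM->PC-dendrite weights grow with the
rectified dendritic activity so the motor prediction arriving at the apical
dendrite is cancelled.

Learning rates are expressed per millisecond of simulated time; the rule
right-hand sides are accumulated every integration step and applied every
``update_interval`` ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .circuit_model import (DriveVectors, InterneuronParams, NetworkState,
                            PCParams, _rk2_step, integrate)
from .connectivity import WeightSet, enforce_dale
from .errors import ConfigurationError, DivergenceError
from .protocols import (InputConfiguration, StimulusSequence,
                        default_background, route_inputs)

logger = logging.getLogger(__name__)

__all__ = [
    "PlasticityConfig",
    "TrainResult",
    "update_wEP",
    "update_wDS",
    "update_wPX_backprop",
    "update_wPX_local",
    "update_wPX_homeostatic",
    "update_wPE_antihebbian",
    "measure_baselines",
    "train",
]

RULE_VARIANTS = ("backprop", "local_recurrent", "pv_homeostatic")


@dataclass
class PlasticityConfig:
    """Learning rule selection, rates and training-loop controls.

    Learning rates are per ms of simulated time and sized so that the weight
    change per 1-s stimulus stays well below the weight scale. ``rho_E0`` /
    ``rho_P0`` start from the measured pre-training baseline rates (5 s
    settling run), per neuron; with ``baseline_mode="running"`` (default)
    they are re-measured in every interleaved baseline phase so the rule
    targets track the evolving baseline operating point, while ``"fixed"``
    freezes them at their initial values. ``epsilon`` [1/s] eases the effect
    of strong dendritic onset responses in the SOM->dendrite rule.
    """

    rule_variant: str = "backprop"
    eta_EP: float = 1e-6
    eta_DS: float = 1e-6
    eta_PX: float = 1e-6
    eta_PE: float = 1e-6
    rho_E0: np.ndarray | None = None
    rho_P0: np.ndarray | None = None
    epsilon: float = 0.1
    update_interval: float = 1.0
    dt: float = 1.0
    rate_cap: float = 500.0
    convergence_tol: float = 0.01
    convergence_tol_neuron: float = 0.01
    convergence_window: int = 200
    baseline_mode: str = "running"  # "running" or "fixed"
    fixed_wPV: float | None = None  # freeze VIP->PV at this summed magnitude

    def __post_init__(self) -> None:
        if self.rule_variant not in RULE_VARIANTS:
            raise ConfigurationError(
                f"unknown rule variant {self.rule_variant!r}; choose from {RULE_VARIANTS}")
        for name in ("eta_EP", "eta_DS", "eta_PX", "eta_PE"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.epsilon < 0:
            raise ConfigurationError("epsilon must be nonnegative")
        if self.baseline_mode not in ("running", "fixed"):
            raise ConfigurationError("baseline_mode must be 'running' or 'fixed'")


# ---------------------------------------------------------------------------
# individual update rules (return raw weight deltas on the existing mask)

def update_wEP(r_E, rho_E0, r_P, mask, eta):
    """Inhibitory Hebbian rule for PV -> PC soma: more inhibition when the
    PC fires above its baseline, gated by presynaptic PV activity."""
    return eta * np.outer(r_E - rho_E0, r_P) * mask


def update_wDS(A, epsilon, r_S, mask, eta):
    """SOM -> PC dendrite rule driven by the rectified dendritic activity
    ``A = [I_D_syn + c]_+``; decays slowly (via ``-epsilon``) when silent."""
    return eta * np.outer(A - epsilon, r_S) * mask


def update_wPX_backprop(r_E, rho_E0, r_pre, post_mean, mask, eta):
    """Backprop-like rule for SOM/VIP -> PV: driven by the mean baseline
    deviation of the PCs each PV neuron projects to.

    ``post_mean`` is the (N_PV, N_PC) row-normalized indicator of each PV
    neuron's postsynaptic PCs (rows of all zeros for PV neurons with no
    postsynaptic targets, whose afferents are then frozen)."""
    err = post_mean @ (rho_E0 - r_E)
    return eta * np.outer(err, r_pre) * mask


def update_wPX_local(r_E, rho_E0, w_PE, r_pre, mask, eta):
    """Local approximation: the error signal is the deviation of the
    excitatory recurrent drive onto the PV neuron from its target."""
    delta_E_rec = w_PE @ (rho_E0 - r_E)
    return eta * np.outer(delta_E_rec, r_pre) * mask


def update_wPX_homeostatic(r_P, rho_P0, r_pre, mask, eta):
    """Homeostatic inhibitory rule for SOM/VIP -> PV: holds PV at target."""
    return eta * np.outer(r_P - rho_P0, r_pre) * mask


def update_wPE_antihebbian(r_P, rho_P0, r_E, mask, eta):
    """Anti-Hebbian rule for PC -> PV, establishing the PV target rate."""
    return eta * np.outer(rho_P0 - r_P, r_E) * mask


# ---------------------------------------------------------------------------

def measure_baselines(weights: WeightSet, background: DriveVectors,
                      pc: PCParams, inh: InterneuronParams,
                      duration: float = 5000.0, dt: float = 1.0,
                      state: NetworkState | None = None):
    """Settle the network at background drives and return the per-neuron
    baseline rates (rho_E0, rho_P0) together with the settled state."""
    sizes = weights.sizes
    state = state or NetworkState.zeros(*sizes.as_tuple())
    state, tr = integrate(state, weights, background, dt=dt, duration=duration,
                          record_every=duration / 10, pc=pc, inh=inh)
    return state.r_E.copy(), state.r_P.copy(), state


@dataclass
class TrainResult:
    """Trained weights plus per-stimulus history and periodic checkpoints."""

    weights: WeightSet
    rho_E0: np.ndarray
    rho_P0: np.ndarray
    history: dict
    state: NetworkState
    converged: bool
    n_stimuli_run: int


def train(
    weights: WeightSet,
    input_config: InputConfiguration,
    sequence: StimulusSequence,
    config: PlasticityConfig | None = None,
    pc: PCParams | None = None,
    inh: InterneuronParams | None = None,
    background: DriveVectors | None = None,
    checkpoint_every: int = 100,
) -> TrainResult:
    """Run the training loop: integrate the rate dynamics through the
    stimulus sequence and apply the selected plasticity rules.

    Weight magnitudes are clipped at zero after every update. The loop stops
    early once, over the last ``convergence_window`` stimuli, the running
    mean of the PC-population |ΔR/R| falls below ``convergence_tol`` AND
    the worst single PC's running-mean |ΔR/R| falls below
    ``convergence_tol_neuron`` (the method's target is every PC at
    baseline, and a population average can mask a few stragglers). Raises
    :class:`DivergenceError` if any population mean rate exceeds
    ``rate_cap``.
    """
    config = config or PlasticityConfig()
    pc = pc or PCParams()
    inh = inh or InterneuronParams()
    weights = weights.copy()
    sizes = weights.sizes
    background = background or default_background(input_config, sizes)
    dt = config.dt

    if config.fixed_wPV is not None:
        mask = weights.masks["PV"]
        k = mask.sum(axis=1)
        weights.w_PV[:] = 0.0
        weights.w_PV[mask] = np.repeat(config.fixed_wPV / k, k)
        weights = WeightSet(**{f"w_{pw}": weights.matrix(pw) for pw in weights.masks},
                            masks=weights.masks,
                            plastic=weights.plastic - {"PV"})

    rho_E0, rho_P0 = config.rho_E0, config.rho_P0
    if rho_E0 is None or rho_P0 is None:
        m_E, m_P, state = measure_baselines(weights, background, pc, inh, dt=dt)
        rho_E0 = m_E if rho_E0 is None else rho_E0
        rho_P0 = m_P if rho_P0 is None else rho_P0
    else:
        state = NetworkState.zeros(*sizes.as_tuple())
        state, _ = integrate(state, weights, background, dt=dt, duration=2000.0,
                             record_every=2000.0, pc=pc, inh=inh)
    rho_E0 = np.array(rho_E0, dtype=float)
    rho_P0 = np.array(rho_P0, dtype=float)
    if np.any(rho_E0 <= 0):
        logger.warning("some PCs have zero pre-training baseline rate; "
                       "their ΔR/R is undefined")

    plastic = weights.plastic
    masks = {pw: weights.masks[pw].astype(float) for pw in ("EP", "DS", "PS", "PV", "PE")}
    # per-PV mean over postsynaptic PCs (columns of w_EP); empty sets frozen
    post = (weights.masks["EP"].T).astype(float)
    counts = post.sum(axis=1)
    if np.any(counts == 0):
        logger.warning("%d PV neurons have no postsynaptic PCs; their "
                       "incoming SOM/VIP weights are frozen", int((counts == 0).sum()))
    post_mean = np.divide(post, np.maximum(counts, 1.0)[:, None])
    post_mean[counts == 0] = 0.0

    upd_stride = max(1, int(round(config.update_interval / dt)))
    variant = config.rule_variant
    r_E, r_P, r_S, r_V = state.r_E, state.r_P, state.r_S, state.r_V

    from . import _kernels
    use_kernel = _kernels.HAVE_NUMBA
    variant_code = {"backprop": _kernels.VARIANT_BACKPROP,
                    "local_recurrent": _kernels.VARIANT_LOCAL,
                    "pv_homeostatic": _kernels.VARIANT_HOMEO}[variant]
    bool_masks = {pw: weights.masks[pw] for pw in ("EP", "DS", "PS", "PV", "PE")}
    flags = tuple(pw in plastic for pw in ("EP", "DS", "PS", "PV", "PE"))
    no_rec = (0, np.empty(0), np.empty((0, r_E.size)), np.empty((0, r_P.size)),
              np.empty((0, r_S.size)), np.empty((0, r_V.size)),
              np.empty((0, r_E.size)), np.empty((0, r_E.size)),
              np.empty((0, r_E.size)), np.empty((0, r_E.size)))

    hist_kind: list[str] = []
    hist_s: list[float] = []
    hist_drr: list[float] = []
    hist_drr_vec: list[np.ndarray] = []
    checkpoints: list[dict] = []
    converged = False
    n_run = 0
    valid = rho_E0 > 0

    for phase in sequence.phases:
        drives = route_inputs(input_config, phase, background, sizes)
        n_steps = int(round(phase.duration / dt))
        half = n_steps // 2
        acc = np.zeros_like(r_E)
        acc_P = np.zeros_like(r_P)
        n_acc = n_steps - half
        if use_kernel:
            from .circuit_model import _param_args, _weight_args
            _kernels.run_phase(
                r_E, r_P, r_S, r_V, *_weight_args(weights),
                drives.x_E, drives.x_D, drives.x_P, drives.x_S, drives.x_V,
                *_param_args(pc, inh), dt, n_steps,
                variant_code, upd_stride,
                config.eta_EP, config.eta_DS, config.eta_PX, config.eta_PE,
                config.epsilon, rho_E0, rho_P0,
                bool_masks["EP"], bool_masks["DS"], bool_masks["PS"],
                bool_masks["PV"], bool_masks["PE"], post_mean,
                *flags, *no_rec, state.t, acc, acc_P)
        else:
            for step in range(1, n_steps + 1):
                r_E, r_P, r_S, r_V = _rk2_step(r_E, r_P, r_S, r_V, weights,
                                               drives, pc, inh, dt)
                if step % upd_stride == 0:
                    scale = upd_stride * dt
                    I_E_syn = drives.x_E - weights.w_EP @ r_P
                    I_D_syn = drives.x_D - weights.w_DS @ r_S + weights.w_DE @ r_E
                    I_D0 = pc.lambda_E * I_E_syn + (1.0 - pc.lambda_D) * I_D_syn
                    c = np.where(I_D0 > pc.theta_c, pc.c_amp, 0.0)
                    A = np.maximum(I_D_syn + c, 0.0)
                    if "EP" in plastic:
                        weights.w_EP += scale * update_wEP(
                            r_E, rho_E0, r_P, masks["EP"], config.eta_EP)
                    if "DS" in plastic:
                        weights.w_DS += scale * update_wDS(
                            A, config.epsilon, r_S, masks["DS"], config.eta_DS)
                    if variant == "backprop":
                        if "PS" in plastic:
                            weights.w_PS += scale * update_wPX_backprop(
                                r_E, rho_E0, r_S, post_mean, masks["PS"], config.eta_PX)
                        if "PV" in plastic:
                            weights.w_PV += scale * update_wPX_backprop(
                                r_E, rho_E0, r_V, post_mean, masks["PV"], config.eta_PX)
                    elif variant == "local_recurrent":
                        if "PS" in plastic:
                            weights.w_PS += scale * update_wPX_local(
                                r_E, rho_E0, weights.w_PE, r_S, masks["PS"], config.eta_PX)
                        if "PV" in plastic:
                            weights.w_PV += scale * update_wPX_local(
                                r_E, rho_E0, weights.w_PE, r_V, masks["PV"], config.eta_PX)
                    else:  # pv_homeostatic
                        if "PS" in plastic:
                            weights.w_PS += scale * update_wPX_homeostatic(
                                r_P, rho_P0, r_S, masks["PS"], config.eta_PX)
                        if "PV" in plastic:
                            weights.w_PV += scale * update_wPX_homeostatic(
                                r_P, rho_P0, r_V, masks["PV"], config.eta_PX)
                        if "PE" in plastic:
                            weights.w_PE += scale * update_wPE_antihebbian(
                                r_P, rho_P0, r_E, masks["PE"], config.eta_PE)
                    enforce_dale(weights)
                if step > half:
                    acc += r_E
                    acc_P += r_P
        state = NetworkState(r_E, r_P, r_S, r_V, t=state.t + n_steps * dt)
        if max(r_E.mean(), r_P.mean(), r_S.mean(), r_V.mean()) > config.rate_cap:
            raise DivergenceError(
                f"population rate exceeded {config.rate_cap} 1/s at t={state.t} ms "
                f"(phase {phase.kind}); mean rates: E={r_E.mean():.1f}, "
                f"P={r_P.mean():.1f}, S={r_S.mean():.1f}, V={r_V.mean():.1f}")

        if phase.kind == "baseline":
            if config.baseline_mode == "running":
                # the rule targets track the evolving baseline operating point
                rho_E0[:] = acc / max(n_acc, 1)
                rho_P0[:] = acc_P / max(n_acc, 1)
                valid = rho_E0 > 0
            continue
        n_run += 1
        mean_rate = acc / max(n_acc, 1)
        drr_vec = np.zeros_like(rho_E0)
        drr_vec[valid] = np.abs(
            (mean_rate[valid] - rho_E0[valid]) / rho_E0[valid])
        drr = float(drr_vec[valid].mean()) if valid.any() else 0.0
        hist_kind.append(phase.kind)
        hist_s.append(max(phase.v, phase.m))
        hist_drr.append(drr)
        hist_drr_vec.append(drr_vec)
        if n_run % checkpoint_every == 0:
            checkpoints.append({"n_stimuli": n_run, "t_ms": state.t,
                                "effective": weights.effective(),
                                "mean_rates": (float(r_E.mean()), float(r_P.mean()),
                                               float(r_S.mean()), float(r_V.mean())),
                                "mean_abs_drr": drr})
        w = config.convergence_window
        if n_run >= w and float(np.mean(hist_drr[-w:])) < config.convergence_tol:
            worst = float(np.mean(hist_drr_vec[-w:], axis=0).max())
            if worst < config.convergence_tol_neuron:
                converged = True
                break

    history = {"kind": hist_kind, "strength": np.asarray(hist_s),
               "mean_abs_drr": np.asarray(hist_drr), "checkpoints": checkpoints}
    return TrainResult(weights, rho_E0, rho_P0, history, state, converged, n_run)
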