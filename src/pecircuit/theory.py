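"""Analytic results for the linearized, homogeneous circuit.

Negative prediction-error (nPE) neurons exist when excitatory, inhibitory,
disinhibitory and dis-disinhibitory pathways cancel for fully predicted
(feedback) and unpredicted-but-present (playback) stimuli. For the
three-interneuron circuit, and assuming the PC dendrite is sufficiently
inhibited in those phases, the cancellation reduces to two constraints on the
SOM->PV and VIP->PV population weights:

    w_PS = V_P + w_VS * M_P - (1 + w_PP) / w_EP * V_E
    w_PV = M_P + w_SV * V_P - w_SV * (1 + w_PP) / w_EP * V_E
         = w_SV * w_PS + (1 - w_SV * w_VS) * M_P

where V_X, M_X in {0, 1} flag whether population X receives visual or motor
input. This module solves these constraints, inverts the baseline fixed point
for background drives, and provides an exact linear steady-state solver used
as an oracle for the nonlinear simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit_model import DriveVectors, PCParams
from .errors import BranchInconsistencyError, DaleViolationError

__all__ = [
    "MeanFieldNetwork",
    "BackgroundInputs",
    "solve_constraints",
    "solve_background_inputs",
    "linear_steady_state",
    "find_steady_state",
    "check_balance",
]


@dataclass
class MeanFieldNetwork:
    """Population-summed (effective) weights of the homogeneous circuit,
    input-routing flags, and the PC parameters entering the linearization."""

    w_EP: float = 2.8
    w_DS: float = 3.5
    w_DE: float = 0.42
    w_PE: float = 1.5
    w_PP: float = 0.1
    w_PS: float = 0.0
    w_PV: float = 0.0
    w_SE: float = 1.0
    w_SV: float = 0.61
    w_VE: float = 1.0
    w_VS: float = 0.5
    V_E: int = 1
    V_P: int = 1
    M_P: int = 0
    pc: PCParams = field(default_factory=PCParams)


def solve_constraints(mf: MeanFieldNetwork) -> tuple[float, float]:
    """Solve the E/I-balance constraints for (w_PS, w_PV).

    Both printed forms of the w_PV expression are evaluated and must agree to
    1e-12 (they are algebraically identical). A negative solution means the
    requested input configuration cannot be balanced with Dale-compliant
    inhibitory weights and raises :class:`DaleViolationError`.
    """
    if mf.w_EP <= 0:
        raise DaleViolationError("w_EP must be positive to solve the constraints")
    gamma = (1.0 + mf.w_PP) / mf.w_EP
    w_PS = mf.V_P + mf.w_VS * mf.M_P - gamma * mf.V_E
    w_PV = mf.M_P + mf.w_SV * mf.V_P - mf.w_SV * gamma * mf.V_E
    w_PV_alt = mf.w_SV * w_PS + (1.0 - mf.w_SV * mf.w_VS) * mf.M_P
    if abs(w_PV - w_PV_alt) > 1e-12 * max(1.0, abs(w_PV)):
        raise AssertionError(
            f"the two forms of the w_PV constraint disagree: {w_PV} vs {w_PV_alt}")
    if w_PS < 0 or w_PV < 0:
        raise DaleViolationError(
            f"configuration V_E={mf.V_E}, V_P={mf.V_P}, M_P={mf.M_P} with "
            f"w_PP={mf.w_PP}, w_EP={mf.w_EP} requires negative weights "
            f"(w_PS={w_PS:.4f}, w_PV={w_PV:.4f})")
    return float(w_PS), float(w_PV)


@dataclass
class BackgroundInputs:
    """Constant background drives [1/s] realizing a baseline operating point."""

    x_E: float
    x_D: float
    x_P: float
    x_S: float
    x_V: float

    def as_drives(self, sizes) -> DriveVectors:
        return DriveVectors.from_scalars(self.x_E, self.x_D, self.x_P,
                                         self.x_S, self.x_V, sizes.as_tuple())


def solve_background_inputs(
    mf: MeanFieldNetwork,
    target_rates: tuple[float, float, float, float] = (1.0, 2.0, 2.0, 4.0),
) -> BackgroundInputs:
    """Invert the baseline (v = m = 0) fixed point for the background drives.

    Assumes all units are in the linear regime and the PC dendrite is
    rectified-silent (net dendritic input <= 0 and below the calcium
    threshold); both assumptions are verified at the solution, with x_D = 0.
    """
    r_E, r_P, r_S, r_V = target_rates
    if min(target_rates) <= 0:
        raise BranchInconsistencyError("target rates must be positive (linear regime)")
    pc = mf.pc
    x_V = r_V - mf.w_VE * r_E + mf.w_VS * r_S
    x_S = r_S - mf.w_SE * r_E + mf.w_SV * r_V
    x_P = r_P - mf.w_PE * r_E + mf.w_PP * r_P + mf.w_PS * r_S + mf.w_PV * r_V
    I_E_syn = (r_E + pc.theta) / (1.0 - pc.lambda_E)
    x_E = I_E_syn + mf.w_EP * r_P
    # verify the assumed dendritic branch
    I_D_syn = -mf.w_DS * r_S + mf.w_DE * r_E
    I_D0 = pc.lambda_E * I_E_syn + (1.0 - pc.lambda_D) * I_D_syn
    if I_D_syn > 0:
        raise BranchInconsistencyError(
            f"baseline dendritic input {I_D_syn:.3f} > 0 contradicts the assumed "
            "rectified-silent dendrite; re-solve with the open-dendrite branch")
    if I_D0 >= pc.theta_c:
        raise BranchInconsistencyError(
            f"baseline dendritic input {I_D0:.3f} reaches the calcium threshold")
    return BackgroundInputs(float(x_E), 0.0, float(x_P), float(x_S), float(x_V))


def _assemble_linear_system(weights, drives, pc, active, dendrite_open, calcium_on):
    n_E = weights.w_DE.shape[0]
    n_P = weights.w_EP.shape[1]
    n_S = weights.w_DS.shape[1]
    n_V = weights.w_PV.shape[1]
    n = n_E + n_P + n_S + n_V
    sl_E = slice(0, n_E)
    sl_P = slice(n_E, n_E + n_P)
    sl_S = slice(n_E + n_P, n_E + n_P + n_S)
    sl_V = slice(n_E + n_P + n_S, n)
    A = np.eye(n)
    b = np.zeros(n)
    lam_D, lam_E = pc.lambda_D, pc.lambda_E
    c_vec = np.where(calcium_on, pc.c_amp, 0.0)

    # PC rows: r = I - theta, with I depending on the dendritic branch
    A[sl_E, sl_P] += (1.0 - lam_E) * weights.w_EP
    b[sl_E] = (1.0 - lam_E) * drives.x_E - pc.theta
    opn = np.asarray(dendrite_open, dtype=float) * np.ones(n_E)
    A[sl_E, sl_E] -= (opn[:, None] * lam_D) * weights.w_DE
    A[sl_E, sl_S] += (opn[:, None] * lam_D) * weights.w_DS
    b[sl_E] += opn * lam_D * (drives.x_D + c_vec)

    # interneuron rows: r = net input
    A[sl_P, sl_E] -= weights.w_PE
    A[sl_P, sl_P] += weights.w_PP
    A[sl_P, sl_S] += weights.w_PS
    A[sl_P, sl_V] += weights.w_PV
    b[sl_P] = drives.x_P
    A[sl_S, sl_E] -= weights.w_SE
    A[sl_S, sl_V] += weights.w_SV
    b[sl_S] = drives.x_S
    A[sl_V, sl_E] -= weights.w_VE
    A[sl_V, sl_S] += weights.w_VS
    b[sl_V] = drives.x_V

    # clamped (silent) units: r = 0 replaces the dynamical row
    act = np.asarray(active, dtype=bool) * np.ones(n, dtype=bool)
    for i in np.flatnonzero(~act):
        A[i] = 0.0
        A[i, i] = 1.0
        b[i] = 0.0
    return A, b, (sl_E, sl_P, sl_S, sl_V)


def linear_steady_state(
    weights,
    drives: DriveVectors,
    pc: PCParams | None = None,
    active=True,
    dendrite_open=False,
    calcium_on=False,
    tol: float = 1e-9,
):
    """Exact steady state of the piecewise-linear circuit for a given
    rectification-branch assignment.

    ``active`` marks units in the linear regime (scalar or length-N bool
    array over the concatenated [E, P, S, V] order), ``dendrite_open`` marks
    PCs whose dendritic bracket is positive, ``calcium_on`` PCs with an
    active calcium event. Returns ``(rates, consistent)`` where ``rates`` is
    a dict of population rate vectors and ``consistent`` says whether the
    solution respects the assumed assignment.
    """
    pc = pc or PCParams()
    A, b, (sl_E, sl_P, sl_S, sl_V) = _assemble_linear_system(
        weights, drives, pc, active, dendrite_open, calcium_on)
    try:
        r = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise BranchInconsistencyError(f"singular linear system: {exc}") from exc
    r_E, r_P, r_S, r_V = r[sl_E], r[sl_P], r[sl_S], r[sl_V]

    n = r.size
    act = np.asarray(active, dtype=bool) * np.ones(n, dtype=bool)
    opn = np.asarray(dendrite_open, dtype=bool) * np.ones(r_E.size, dtype=bool)
    ca = np.asarray(calcium_on, dtype=bool) * np.ones(r_E.size, dtype=bool)

    I_E_syn = drives.x_E - weights.w_EP @ r_P
    I_D_syn = drives.x_D - weights.w_DS @ r_S + weights.w_DE @ r_E
    I_D0 = pc.lambda_E * I_E_syn + (1.0 - pc.lambda_D) * I_D_syn
    c_vec = np.where(ca, pc.c_amp, 0.0)
    bracket = I_D_syn + c_vec
    I_total = pc.lambda_D * np.where(opn, bracket, 0.0) + (1.0 - pc.lambda_E) * I_E_syn

    net = np.concatenate([
        I_total - pc.theta,
        drives.x_P + weights.w_PE @ r_E - weights.w_PP @ r_P
        - weights.w_PS @ r_S - weights.w_PV @ r_V,
        drives.x_S + weights.w_SE @ r_E - weights.w_SV @ r_V,
        drives.x_V + weights.w_VE @ r_E - weights.w_VS @ r_S,
    ])
    consistent = (
        bool(np.all(r[act] >= -tol))
        and bool(np.all(net[~act] <= tol))
        and bool(np.all(bracket[opn] >= -tol))
        and bool(np.all(bracket[~opn] <= tol))
        and bool(np.all(I_D0[ca] > pc.theta_c - tol))
        and bool(np.all(I_D0[~ca] <= pc.theta_c + tol))
    )
    rates = {"r_E": np.maximum(r_E, 0.0), "r_P": np.maximum(r_P, 0.0),
             "r_S": np.maximum(r_S, 0.0), "r_V": np.maximum(r_V, 0.0)}
    return rates, consistent


def find_steady_state(weights, drives: DriveVectors, pc: PCParams | None = None,
                      max_iter: int = 60):
    """Search rectification-branch assignments by fixed-point iteration:
    solve the linear system for the current assignment, then update each
    unit's branch from the solution, until the assignment is self-consistent.

    Returns ``(rates, consistent)``; ``consistent`` is False if no
    self-consistent assignment was found within ``max_iter`` sweeps.
    """
    pc = pc or PCParams()
    n_E = weights.w_DE.shape[0]
    n = n_E + weights.w_EP.shape[1] + weights.w_DS.shape[1] + weights.w_PV.shape[1]
    active = np.ones(n, dtype=bool)
    dendrite_open = np.zeros(n_E, dtype=bool)
    calcium_on = np.zeros(n_E, dtype=bool)
    rates = None
    for _ in range(max_iter):
        rates, ok = linear_steady_state(weights, drives, pc, active,
                                        dendrite_open, calcium_on)
        if ok:
            return rates, True
        r_E, r_P, r_S, r_V = (rates["r_E"], rates["r_P"], rates["r_S"], rates["r_V"])
        I_E_syn = drives.x_E - weights.w_EP @ r_P
        I_D_syn = drives.x_D - weights.w_DS @ r_S + weights.w_DE @ r_E
        I_D0 = pc.lambda_E * I_E_syn + (1.0 - pc.lambda_D) * I_D_syn
        new_ca = I_D0 > pc.theta_c
        c_vec = np.where(new_ca, pc.c_amp, 0.0)
        new_open = (I_D_syn + c_vec) > 0
        I_total = (pc.lambda_D * np.maximum(I_D_syn + c_vec, 0.0)
                   + (1.0 - pc.lambda_E) * I_E_syn)
        net = np.concatenate([
            I_total - pc.theta,
            drives.x_P + weights.w_PE @ r_E - weights.w_PP @ r_P
            - weights.w_PS @ r_S - weights.w_PV @ r_V,
            drives.x_S + weights.w_SE @ r_E - weights.w_SV @ r_V,
            drives.x_V + weights.w_VE @ r_E - weights.w_VS @ r_S,
        ])
        active = net > 0
        dendrite_open, calcium_on = new_open, new_ca
    return rates, False


def background_for_weights(weights, target_rates=(1.0, 2.0, 2.0, 4.0)):
    """Background drives that put a (non-plastic) network at the standard
    baseline operating point, from its population-summed effective weights."""
    eff = weights.effective()
    mf = MeanFieldNetwork(
        w_EP=eff["EP"], w_DS=eff["DS"], w_DE=eff["DE"], w_PE=eff["PE"],
        w_PP=eff["PP"], w_PS=eff["PS"], w_PV=eff["PV"], w_SE=eff["SE"],
        w_SV=eff["SV"], w_VE=eff["VE"], w_VS=eff["VS"])
    return solve_background_inputs(mf, target_rates)


def check_balance(weights, input_config, strength: float = 7.0,
                  pc: PCParams | None = None) -> dict:
    """Deviation of a (learned) weight set from the analytic balance.

    Collapses the weight set to population-summed effective weights, compares
    (w_PS, w_PV) to the constraint solution implied by the learned w_EP and
    w_PP, and reports the residual dendritic activity (the rectified dendritic
    input that survives SOM inhibition) in feedback and playback phases.
    Deviations are reported, never raised: an unbalanced network is a valid
    input.
    """
    from . import protocols  # runtime import to avoid a module cycle
    from .circuit_model import simulate_phases

    pc = pc or PCParams()
    eff = weights.effective()
    mf = MeanFieldNetwork(
        w_EP=eff["EP"], w_DS=eff["DS"], w_DE=eff["DE"], w_PE=eff["PE"],
        w_PP=eff["PP"], w_SE=eff["SE"], w_SV=eff["SV"], w_VE=eff["VE"],
        w_VS=eff["VS"], V_E=input_config.V_E, V_P=input_config.V_P,
        M_P=input_config.M_P, pc=pc)
    try:
        w_PS_star, w_PV_star = solve_constraints(mf)
        dev = {
            "w_PS": _rel_dev(eff["PS"], w_PS_star),
            "w_PV": _rel_dev(eff["PV"], w_PV_star),
        }
        analytic = {"w_PS": w_PS_star, "w_PV": w_PV_star}
    except DaleViolationError as exc:
        dev, analytic = {"w_PS": np.nan, "w_PV": np.nan}, {"error": str(exc)}

    background = protocols.default_background(input_config, weights.sizes)
    residuals = {}
    for kind, v, m in (("feedback", strength, strength), ("playback", strength, 0.0)):
        phase = protocols.Phase(kind, v=v, m=m)
        drives = protocols.route_inputs(input_config, phase, background, weights.sizes)
        _, tr, _ = simulate_phases(weights, [(drives, 1000.0)], dt=0.5, pc=pc)
        A = np.maximum(tr.I_D_syn[-1] + tr.calcium[-1], 0.0)
        residuals[kind] = float(A.mean())
    return {"learned": {"w_PS": eff["PS"], "w_PV": eff["PV"]},
            "analytic": analytic, "relative_deviation": dev,
            "dendritic_residual": residuals}


def _rel_dev(value: float, target: float) -> float:
    if target == 0.0:
        return float(abs(value))
    return float(abs(value - target) / abs(target))
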