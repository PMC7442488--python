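"""Jitted inner loops for integration and training.

The math here mirrors :mod:`pecircuit.circuit_model` (Heun integration with
per-stage nonnegativity clamps) and :mod:`pecircuit.plasticity` exactly; a
regression test asserts agreement with the pure-numpy path. When numba is
unavailable the package transparently falls back to numpy.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

# plasticity variant codes
VARIANT_NONE = 0
VARIANT_BACKPROP = 1
VARIANT_LOCAL = 2
VARIANT_HOMEO = 3


@njit(cache=False)
def _rhs(rE, rP, rS, rV, wEP, wDE, wDS, wPE, wPP, wPS, wPV, wSE, wSV, wVE, wVS,
         xE, xD, xP, xS, xV, tauE, theta, lamD, lamE, camp, thc, rect, strict,
         tauI, dE, dP, dS, dV):
    IE = xE - np.dot(wEP, rP)
    ID = xD - np.dot(wDS, rS) + np.dot(wDE, rE)
    for i in range(rE.shape[0]):
        id0 = lamE * IE[i] + (1.0 - lamD) * ID[i]
        if strict:
            c = camp if id0 > thc else 0.0
        else:
            c = camp if id0 >= thc else 0.0
        br = ID[i] + c
        if rect and br < 0.0:
            br = 0.0
        inp = lamD * br + (1.0 - lamE) * IE[i] - theta
        if inp < 0.0:
            inp = 0.0
        d = (-rE[i] + inp) / tauE
        if rE[i] <= 0.0 and d < 0.0:
            d = 0.0
        dE[i] = d
    netP = xP + np.dot(wPE, rE) - np.dot(wPP, rP) - np.dot(wPS, rS) - np.dot(wPV, rV)
    netS = xS + np.dot(wSE, rE) - np.dot(wSV, rV)
    netV = xV + np.dot(wVE, rE) - np.dot(wVS, rS)
    for i in range(rP.shape[0]):
        d = (-rP[i] + netP[i]) / tauI
        if rP[i] <= 0.0 and d < 0.0:
            d = 0.0
        dP[i] = d
    for i in range(rS.shape[0]):
        d = (-rS[i] + netS[i]) / tauI
        if rS[i] <= 0.0 and d < 0.0:
            d = 0.0
        dS[i] = d
    for i in range(rV.shape[0]):
        d = (-rV[i] + netV[i]) / tauI
        if rV[i] <= 0.0 and d < 0.0:
            d = 0.0
        dV[i] = d


@njit(cache=False)
def _dendritic_diagnostics(rE, rP, rS, wEP, wDE, wDS, xE, xD, lamD, lamE,
                           camp, thc, strict, IE, ID, ID0, cvec):
    IE[:] = xE - np.dot(wEP, rP)
    ID[:] = xD - np.dot(wDS, rS) + np.dot(wDE, rE)
    for i in range(rE.shape[0]):
        ID0[i] = lamE * IE[i] + (1.0 - lamD) * ID[i]
        if strict:
            cvec[i] = camp if ID0[i] > thc else 0.0
        else:
            cvec[i] = camp if ID0[i] >= thc else 0.0


@njit(cache=False)
def run_phase(rE, rP, rS, rV,
              wEP, wDE, wDS, wPE, wPP, wPS, wPV, wSE, wSV, wVE, wVS,
              xE, xD, xP, xS, xV,
              tauE, theta, lamD, lamE, camp, thc, rect, strict, tauI,
              dt, n_steps,
              variant, upd_stride,
              etaEP, etaDS, etaPX, etaPE, eps,
              rhoE, rhoP, mEP, mDS, mPS, mPV, mPE, post_mean,
              pEP, pDS, pPS, pPV, pPE,
              rec_stride, rec_t, rec_rE, rec_rP, rec_rS, rec_rV,
              rec_IE, rec_ID, rec_ID0, rec_c, t0, acc_rE, acc_rP):
    """Integrate one phase of ``n_steps`` Heun steps with constant drives.

    ``variant`` selects the plasticity rules (0 = frozen weights); updates
    are applied every ``upd_stride`` steps, scaled by the elapsed time.
    Traces are recorded every ``rec_stride`` steps (0 disables recording).
    ``acc_rE`` / ``acc_rP`` accumulate PC / PV rates over the second half
    of the phase (used for response histories and the running baseline).
    Returns the number of recorded samples.
    """
    nE = rE.shape[0]
    nP = rP.shape[0]
    nS = rS.shape[0]
    nV = rV.shape[0]
    dE = np.empty(nE)
    dP = np.empty(nP)
    dS = np.empty(nS)
    dV = np.empty(nV)
    dE2 = np.empty(nE)
    dP2 = np.empty(nP)
    dS2 = np.empty(nS)
    dV2 = np.empty(nV)
    e1 = np.empty(nE)
    p1 = np.empty(nP)
    s1 = np.empty(nS)
    v1 = np.empty(nV)
    IE = np.empty(nE)
    ID = np.empty(nE)
    ID0 = np.empty(nE)
    cvec = np.empty(nE)
    half = n_steps // 2
    j = 0
    for step in range(1, n_steps + 1):
        _rhs(rE, rP, rS, rV, wEP, wDE, wDS, wPE, wPP, wPS, wPV, wSE, wSV,
             wVE, wVS, xE, xD, xP, xS, xV, tauE, theta, lamD, lamE, camp,
             thc, rect, strict, tauI, dE, dP, dS, dV)
        for i in range(nE):
            e1[i] = max(rE[i] + dt * dE[i], 0.0)
        for i in range(nP):
            p1[i] = max(rP[i] + dt * dP[i], 0.0)
        for i in range(nS):
            s1[i] = max(rS[i] + dt * dS[i], 0.0)
        for i in range(nV):
            v1[i] = max(rV[i] + dt * dV[i], 0.0)
        _rhs(e1, p1, s1, v1, wEP, wDE, wDS, wPE, wPP, wPS, wPV, wSE, wSV,
             wVE, wVS, xE, xD, xP, xS, xV, tauE, theta, lamD, lamE, camp,
             thc, rect, strict, tauI, dE2, dP2, dS2, dV2)
        h = 0.5 * dt
        for i in range(nE):
            rE[i] = max(rE[i] + h * (dE[i] + dE2[i]), 0.0)
        for i in range(nP):
            rP[i] = max(rP[i] + h * (dP[i] + dP2[i]), 0.0)
        for i in range(nS):
            rS[i] = max(rS[i] + h * (dS[i] + dS2[i]), 0.0)
        for i in range(nV):
            rV[i] = max(rV[i] + h * (dV[i] + dV2[i]), 0.0)

        if variant != VARIANT_NONE and step % upd_stride == 0:
            scale = upd_stride * dt
            _dendritic_diagnostics(rE, rP, rS, wEP, wDE, wDS, xE, xD, lamD,
                                   lamE, camp, thc, strict, IE, ID, ID0, cvec)
            if pEP:
                for i in range(nE):
                    e = scale * etaEP * (rE[i] - rhoE[i])
                    for jj in range(nP):
                        if mEP[i, jj]:
                            w = wEP[i, jj] + e * rP[jj]
                            wEP[i, jj] = w if w > 0.0 else 0.0
            if pDS:
                for i in range(nE):
                    a = ID[i] + cvec[i]
                    if a < 0.0:
                        a = 0.0
                    e = scale * etaDS * (a - eps)
                    for jj in range(nS):
                        if mDS[i, jj]:
                            w = wDS[i, jj] + e * rS[jj]
                            wDS[i, jj] = w if w > 0.0 else 0.0
            if variant == VARIANT_BACKPROP or variant == VARIANT_LOCAL:
                err = np.empty(nP)
                if variant == VARIANT_BACKPROP:
                    for i in range(nP):
                        acc = 0.0
                        for k in range(nE):
                            acc += post_mean[i, k] * (rhoE[k] - rE[k])
                        err[i] = acc
                else:
                    for i in range(nP):
                        acc = 0.0
                        for k in range(nE):
                            acc += wPE[i, k] * (rhoE[k] - rE[k])
                        err[i] = acc
                if pPS:
                    for i in range(nP):
                        e = scale * etaPX * err[i]
                        for jj in range(nS):
                            if mPS[i, jj]:
                                w = wPS[i, jj] + e * rS[jj]
                                wPS[i, jj] = w if w > 0.0 else 0.0
                if pPV:
                    for i in range(nP):
                        e = scale * etaPX * err[i]
                        for jj in range(nV):
                            if mPV[i, jj]:
                                w = wPV[i, jj] + e * rV[jj]
                                wPV[i, jj] = w if w > 0.0 else 0.0
            elif variant == VARIANT_HOMEO:
                if pPS:
                    for i in range(nP):
                        e = scale * etaPX * (rP[i] - rhoP[i])
                        for jj in range(nS):
                            if mPS[i, jj]:
                                w = wPS[i, jj] + e * rS[jj]
                                wPS[i, jj] = w if w > 0.0 else 0.0
                if pPV:
                    for i in range(nP):
                        e = scale * etaPX * (rP[i] - rhoP[i])
                        for jj in range(nV):
                            if mPV[i, jj]:
                                w = wPV[i, jj] + e * rV[jj]
                                wPV[i, jj] = w if w > 0.0 else 0.0
                if pPE:
                    for i in range(nP):
                        e = scale * etaPE * (rhoP[i] - rP[i])
                        for jj in range(nE):
                            if mPE[i, jj]:
                                w = wPE[i, jj] + e * rE[jj]
                                wPE[i, jj] = w if w > 0.0 else 0.0

        if step > half:
            for i in range(nE):
                acc_rE[i] += rE[i]
            for i in range(nP):
                acc_rP[i] += rP[i]
        if rec_stride > 0 and step % rec_stride == 0:
            _dendritic_diagnostics(rE, rP, rS, wEP, wDE, wDS, xE, xD, lamD,
                                   lamE, camp, thc, strict, IE, ID, ID0, cvec)
            rec_t[j] = t0 + step * dt
            for i in range(nE):
                rec_rE[j, i] = rE[i]
                rec_IE[j, i] = IE[i]
                rec_ID[j, i] = ID[i]
                rec_ID0[j, i] = ID0[i]
                rec_c[j, i] = cvec[i]
            for i in range(nP):
                rec_rP[j, i] = rP[i]
            for i in range(nS):
                rec_rS[j, i] = rS[i]
            for i in range(nV):
                rec_rV[j, i] = rV[i]
            j += 1
    return j
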