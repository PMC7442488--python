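"""Response analysis: ΔR/R phase responses, prediction-error-neuron
classification, somatic current decomposition, and optogenetic fingerprints.

The classification statistic is ΔR/R = (r − r_BL) / r_BL, with r the rate
averaged over the last part of a phase (the first 500 ms are excluded so
transient onset/offset responses do not enter). A PC is a negative
prediction-error (nPE) neuron when ΔR/R exceeds +20% in the mismatch phase
while staying within ±10% in feedback and playback; a positive
prediction-error (pPE) neuron is the playback-selective mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit_model import (DriveVectors, InterneuronParams, NetworkState,
                            PCParams, Traces, simulate_phases)
from .connectivity import WeightSet
from .errors import ConfigurationError
from .protocols import (InputConfiguration, StimulusSequence, apply_opto,
                        default_background, make_test_triplet, route_inputs)

__all__ = [
    "TripletResult",
    "CurrentDecomposition",
    "phase_response",
    "classify_pcs",
    "normalize_responses",
    "current_decomposition",
    "run_sequence",
    "run_triplet",
    "mismatch_sweep",
    "fingerprint",
]

LABELS = ("nPE", "pPE", "baseline", "suppressed_MM", "other")
ONSET_EXCLUSION_MS = 500.0


def _window_mean(traces: Traces, window: tuple[float, float],
                 onset_exclusion: float) -> np.ndarray:
    t0, t1 = window
    if t1 - t0 > onset_exclusion:
        t0 = t0 + onset_exclusion
    sel = (traces.time > t0) & (traces.time <= t1)
    if not np.any(sel):
        raise ConfigurationError(f"window ({t0}, {t1}) contains no samples")
    return traces.r_E[sel].mean(axis=0)


def phase_response(traces: Traces,
                   phase_windows: dict[str, tuple[float, float]],
                   baseline_windows: list[tuple[float, float]],
                   onset_exclusion: float = ONSET_EXCLUSION_MS) -> pd.DataFrame:
    """Per-PC ΔR/R for each named phase window.

    ``phase_windows`` maps phase names (e.g. "FB", "MM", "PB") to (start,
    end) times in ms; rates are averaged after excluding the first
    ``onset_exclusion`` ms of each window. The baseline rate is the average
    over all ``baseline_windows``. Neurons with zero baseline rate are
    flagged undefined and excluded from labeling.
    """
    r_bl = np.mean([_window_mean(traces, w, onset_exclusion)
                    for w in baseline_windows], axis=0)
    defined = r_bl > 0
    data = {"baseline": r_bl, "defined": defined}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, window in phase_windows.items():
            r = _window_mean(traces, window, onset_exclusion)
            drr = np.where(defined, (r - r_bl) / np.where(defined, r_bl, 1.0), np.nan)
            data[f"dRR_{name}"] = drr
    return pd.DataFrame(data)


def classify_pcs(table: pd.DataFrame, up: float = 0.20, band: float = 0.10) -> pd.DataFrame:
    """Attach mutually exclusive labels to a ΔR/R table.

    nPE: MM > +up, FB and PB within ±band. pPE: PB > +up, FB and MM within
    ±band. baseline: all three within ±band. suppressed_MM: MM < −up with FB
    and PB within ±band. Everything else: other. Neurons with undefined
    ΔR/R get an empty label.
    """
    fb, mm, pb = (table["dRR_FB"], table["dRR_MM"], table["dRR_PB"])
    in_fb, in_mm, in_pb = (fb.abs() < band, mm.abs() < band, pb.abs() < band)
    label = np.full(len(table), "other", dtype=object)
    label[(mm > up) & in_fb & in_pb] = "nPE"
    label[(pb > up) & in_fb & in_mm] = "pPE"
    label[in_fb & in_mm & in_pb] = "baseline"
    label[(mm < -up) & in_fb & in_pb] = "suppressed_MM"
    label[~table["defined"].to_numpy()] = ""
    out = table.copy()
    out["label"] = label
    return out


def normalize_responses(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each neuron's phase responses by its maximum absolute response,
    mapping them into [−1, 1] with baseline at 0. All-zero rows stay zero."""
    cols = [c for c in table.columns if c.startswith("dRR_")]
    out = table.copy()
    peak = out[cols].abs().max(axis=1)
    scale = np.where(peak > 0, peak, 1.0)
    out[cols] = out[cols].div(scale, axis=0)
    return out


@dataclass
class CurrentDecomposition:
    """Somatic current decomposition per PC, in pA (rate units / gain_g).

    ``excitatory`` counts the external somatic drive plus the rectified
    dendritic contribution; ``inhibitory`` the PV-induced somatic current;
    ``net = excitatory - inhibitory``; ``dendritic_net`` is the (signed)
    dendritic input including calcium events.
    """

    time: np.ndarray
    excitatory: np.ndarray
    inhibitory: np.ndarray
    net: np.ndarray
    dendritic_net: np.ndarray

    def window_mean(self, window: tuple[float, float]) -> dict[str, np.ndarray]:
        sel = (self.time > window[0]) & (self.time <= window[1])
        return {f: getattr(self, f)[sel].mean(axis=0)
                for f in ("excitatory", "inhibitory", "net", "dendritic_net")}


def current_decomposition(traces: Traces, weights: WeightSet,
                          pc: PCParams | None = None) -> CurrentDecomposition:
    """Decompose the somatic input of every PC into excitation and
    inhibition, converted to pA with the rate-to-current gain."""
    pc = pc or PCParams()
    inh_rate = traces.r_P @ weights.w_EP.T  # w_EP · r_P over time
    x_E = traces.I_E_syn + inh_rate
    bracket = traces.I_D_syn + traces.calcium
    if pc.dendritic_rectification:
        bracket_pos = np.maximum(bracket, 0.0)
    else:
        bracket_pos = bracket
    exc = (1.0 - pc.lambda_E) * x_E + pc.lambda_D * bracket_pos
    inh = (1.0 - pc.lambda_E) * inh_rate
    g = pc.gain_g
    return CurrentDecomposition(traces.time, exc / g, inh / g, (exc - inh) / g,
                                bracket / g)


def run_sequence(weights: WeightSet, input_config: InputConfiguration,
                 sequence: StimulusSequence,
                 background: DriveVectors | None = None,
                 dt: float = 0.1, opto: tuple[str, str] | None = None,
                 pc: PCParams | None = None, inh: InterneuronParams | None = None,
                 state: NetworkState | None = None):
    """Simulate a stimulus sequence (optionally under an optogenetic
    manipulation applied throughout) and return (traces, windows, kinds)."""
    sizes = weights.sizes
    background = background if background is not None else default_background(
        input_config, sizes)
    drive_list = []
    for phase in sequence.phases:
        drives = route_inputs(input_config, phase, background, sizes)
        if opto is not None:
            drives = apply_opto(drives, *opto)
        drive_list.append((drives, phase.duration))
    _, traces, windows = simulate_phases(weights, drive_list, state=state,
                                         dt=dt, pc=pc, inh=inh)
    return traces, windows, sequence.kinds


@dataclass
class TripletResult:
    """Traces and ΔR/R table from a feedback/mismatch/playback test run."""

    traces: Traces
    windows: list[tuple[float, float]]
    kinds: list[str]
    table: pd.DataFrame

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def fraction(self, label: str) -> float:
        n = int(self.table["defined"].sum())
        return float((self.table["label"] == label).sum()) / max(n, 1)


_KIND_TO_COL = {"feedback": "FB", "mismatch": "MM", "playback": "PB"}


def run_triplet(weights: WeightSet, input_config: InputConfiguration,
                background: DriveVectors | None = None, strength: float = 7.0,
                mm_v: float = 0.0, pb_m: float = 0.0, dt: float = 0.1,
                opto: tuple[str, str] | None = None,
                baseline_table: pd.DataFrame | None = None,
                pc: PCParams | None = None, inh: InterneuronParams | None = None,
                ) -> TripletResult:
    """Run the BL/FB/BL/MM/BL/PB test and classify all PCs.

    ``baseline_table`` substitutes externally measured baseline rates for the
    ΔR/R denominator (used to express responses under an optogenetic
    manipulation relative to the unmanipulated baseline).
    """
    seq = make_test_triplet(strength, mm_v=mm_v, pb_m=pb_m)
    traces, windows, kinds = run_sequence(weights, input_config, seq,
                                          background=background, dt=dt,
                                          opto=opto, pc=pc, inh=inh)
    # columns are positional: a fully partial "mismatch" (mm_v == strength)
    # degenerates to a feedback phase but still fills the MM column
    phase_windows = {"FB": windows[1], "MM": windows[3], "PB": windows[5]}
    baseline_windows = [w for k, w in zip(kinds, windows) if k == "baseline"]
    table = phase_response(traces, phase_windows, baseline_windows)
    if baseline_table is not None:
        r_bl = baseline_table["baseline"].to_numpy()
        defined = r_bl > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            for col in phase_windows:
                r = table[f"dRR_{col}"] * table["baseline"] + table["baseline"]
                table[f"dRR_{col}"] = np.where(defined, (r - r_bl) / r_bl, np.nan)
        table["baseline"] = r_bl
        table["defined"] = defined
    table = classify_pcs(table)
    return TripletResult(traces, windows, kinds, table)


def mismatch_sweep(weights: WeightSet, input_config: InputConfiguration,
                   background: DriveVectors | None = None, strength: float = 7.0,
                   deltas: np.ndarray | None = None, dt: float = 0.1,
                   pc: PCParams | None = None) -> pd.DataFrame:
    """Sweep partial mismatches: the mismatch phase runs at (v = s − Δ,
    m = s) and the playback phase at (v = s, m = s − Δ) for each Δ. Returns
    the PC-population mean ΔR/R per condition."""
    if deltas is None:
        deltas = np.arange(1.0, strength + 0.5)
    rows = []
    for d in np.asarray(deltas, dtype=float):
        res = run_triplet(weights, input_config, background=background,
                          strength=strength, mm_v=strength - d,
                          pb_m=strength - d, dt=dt, pc=pc)
        rows.append({"delta": d,
                     "dRR_MM": float(res.table["dRR_MM"].mean()),
                     "dRR_PB": float(res.table["dRR_PB"].mean())})
    return pd.DataFrame(rows)


OPTO_GRID = tuple((pop, mode) for pop in ("PV", "SOM", "VIP")
                  for mode in ("inactivate", "activate"))


def fingerprint(weights: WeightSet, input_config: InputConfiguration,
                background: DriveVectors | None = None, strength: float = 7.0,
                opto_grid=OPTO_GRID, dead_band: float = 0.10, dt: float = 0.1,
                pc: PCParams | None = None) -> pd.DataFrame:
    """Optogenetic fingerprint of an nPE circuit.

    Runs the test triplet under each (population, mode) manipulation and
    reports, per phase, whether the mean ΔR/R of the control-classified nPE
    population increases, decreases or stays within a dead-band relative to
    the control run. Manipulated ΔR/R is computed against the control
    baseline rates. Deterministic given the weights.
    """
    control = run_triplet(weights, input_config, background=background,
                          strength=strength, dt=dt, pc=pc)
    is_npe = (control.table["label"] == "nPE").to_numpy()
    if not is_npe.any():
        is_npe = control.table["defined"].to_numpy()
    rows = []
    for pop, mode in opto_grid:
        res = run_triplet(weights, input_config, background=background,
                          strength=strength, dt=dt, opto=(pop, mode),
                          baseline_table=control.table, pc=pc)
        for col in ("FB", "MM", "PB"):
            delta = float(res.table[f"dRR_{col}"][is_npe].mean()
                          - control.table[f"dRR_{col}"][is_npe].mean())
            change = ("none" if abs(delta) <= dead_band
                      else "increase" if delta > 0 else "decrease")
            rows.append({"population": pop, "mode": mode, "phase": col,
                         "delta_dRR": delta, "change": change})
    return pd.DataFrame(rows)
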