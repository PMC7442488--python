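# pecircuit

Rate-based models of **negative prediction-error (nPE) neurons** in mouse
V1 layer 2/3, for computational neuroscientists studying predictive coding
in cortical microcircuits. The package simulates a network of
two-compartment pyramidal cells (PCs) and PV, SOM and VIP interneurons in
which inhibitory synaptic plasticity balances excitation and inhibition so
that PCs stop responding to predicted sensory input and fire only when a
motor-based prediction is not met.

## The model in brief

PC somata follow `tau_E dr/dt = -r + [I - Theta]_+` with

    I = lambda_D [I_D_syn + c]_+ + (1 - lambda_E) I_E_syn,

where `I_E_syn = x_E - w_EP r_P` (external drive minus PV inhibition),
`I_D_syn = x_D - w_DS r_S + w_DE r_E` (motor prediction, SOM inhibition,
recurrence) and `c` is a threshold-triggered dendritic calcium current.
Interneurons are rectified linear units. During "quasi-natural" training
(alternating feedback phases, v = m, and playback phases, v > m = 0),
inhibitory Hebbian rules on PV→PC and SOM→dendrite synapses and
backprop-like (or biologically plausible local / homeostatic) rules on
SOM/VIP→PV synapses drive every PC toward its baseline rate. The resulting
multi-pathway E/I balance is characterized analytically by

    w_PS = V_P + w_VS M_P - (1 + w_PP)/w_EP V_E,
    w_PV = w_SV w_PS + (1 - w_SV w_VS) M_P,

which the `theory` module solves for any routing of visual (V) and motor
(M) input. A PC counts as nPE when ΔR/R = (r − r_BL)/r_BL exceeds +20%
in the mismatch phase and stays within ±10% in feedback and playback.

See `docs/methods.md` for parameters, numerical choices and limitations.

## Worked example

```python
import pecircuit as pz
from pecircuit import analysis, protocols

config = pz.InputConfiguration()            # PC soma/PV/SOM visual, dendrite/VIP motor
weights = pz.default_plastic_weights(config, rng_seed=1)
sequence = protocols.generate_training_sequence("QT", n_stimuli=3000, rng_seed=11)
result = pz.train(weights, config, sequence)
print(result.converged, result.n_stimuli_run)

triplet = analysis.run_triplet(result.weights, config, strength=7.0)
print(triplet.table["label"].value_counts())
print(triplet.table[["dRR_FB", "dRR_MM", "dRR_PB"]].mean().round(3))
```

prints (about a minute on one core):

```
True 1409
label
nPE    70
Name: count, dtype: int64
dRR_FB    0.047
dRR_MM    0.714
dRR_PB   -0.005
```

All 70 PCs are classified as nPE neurons after 1409 training stimuli: they
stay at baseline during feedback and playback (|ΔR/R| ≪ 10%) and fire ~70%
above baseline during mismatch. `theory.check_balance(result.weights,
config)` confirms the learned SOM→PV and VIP→PV weights land on the
analytic balance solution.

A CLI mirrors the library:

```bash
pecircuit theory                    # constraint table for all input configurations
pecircuit preset emergence          # train the default network, report nPE counts
pecircuit preset opto-fingerprints  # optogenetic fingerprint grid
pecircuit sweep --fractions 1.0,0.5,0.0   # SOM/VIP input-fraction sweep
```

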