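# ftsts

Spiking-network simulation of **Forced Temporal Spike-Time Stimulation
(FTSTS)** — a family of charge-balanced stimulation protocols that control
the synchronization of excitatory–inhibitory (E–I) networks not by masking
pathological rhythms while the stimulator is on, but by steering
spike-timing-dependent plasticity (STDP) so the network *stays* in the
desired state after the stimulator is switched off.  The intended audience
is computational neuroscientists studying desynchronizing brain-stimulation
strategies (deep-brain-stimulation models for Parkinson's disease and
epilepsy) and anyone needing a compact, reproducible E–I + STDP testbed.

## The model in brief

Leaky integrate-and-fire neurons (80% excitatory),

&nbsp;&nbsp;τ_m dv/dt = −v + Z + μ + σ√τ_m χ(t) + V_stim(t),

coupled E→I and I→E through delayed difference-of-exponential synapses with
drive Z = ±(J/C)·ΣS.  E-to-I couplings are plastic under trace-based pair
STDP (LTD-dominant: a_LTP = 1, a_LTD = −1.1, τ_LTP = 20 ms, τ_LTD = 22 ms),
which makes the mean E-to-I weight J·W bistable: a high attractor at
290 mV where the network oscillates synchronously, and a low attractor at
10 mV where it fires asynchronously.  Synchrony is measured by the Kuramoto
order parameter R of the excitatory population, computed from spike-time
phases.

FTSTS delivers biphasic ±U_stim pulse pairs to the two populations with a
fixed lag, forcing the inhibitory (postsynaptic) population to fire just
before the excitatory (presynaptic) one: every cycle depresses E-to-I
weights through the post-before-pre branch of the STDP window.  Once the
mean weight is pushed across the basin boundary the stimulator turns off
and the network's own plasticity finishes the job — long-lasting
desynchronization.  Swapping the two waveforms potentiates instead and
resynchronizes.  The package also implements coordinated-reset (CR)
scheduling, the hybrid FTSTS-CR, per-pulse amplitude jitter, heterogeneous
membrane time constants, partially inseparable populations, anti-Hebbian
plasticity on I-to-E synapses, and a symmetric inter-spike-interval
plasticity rule with an offset-pulse FTSTS variant.

## Worked example

Desynchronize a (desk-scaled) 2,000-neuron network from the synchronous
attractor, stimulating until the mean E-to-I weight falls to 75 mV:

```sh
simulate scenario desync_2000 --seed 3
```

prints

```json
{
  "scenario": "desync_2000",
  "seed": 3,
  "scale": 0.2,
  "final_weight_mV": 74.05428690850083,
  "regime": "asynchronous-basin",
  "stop_time_ms": 19959.9,
  "stim_duration_ms": 17959.9,
  "period_T_ms": null,
  "pre_R": 0.5159791210807556,
  "post_R": 0.04096544049907531
}
```

Reading: after a 2 s synchronous baseline (windowed R ≈ 0.52), ~18 s of
FTSTS (U_stim = 100 mV, T_stim = 1 ms, T_neutral = 10 ms) depress the mean
E-to-I weight from 290 mV to the 75 mV stop threshold
(`stop_time_ms`); the protocol switches off, the weight stays in the
asynchronous basin (`final_weight_mV`, `regime`), and five seconds later
the excitatory population's order parameter sits at the asynchronous floor
(`post_R` ≈ 0.04) — the desynchronization outlives the stimulation.

`simulate list` shows all thirteen published-experiment scenarios
(bistability, two-neuron mechanism, desynchronization and
resynchronization at 2,000 and 10,000 neurons, robustness variants, CR vs
FTSTS-CR, dual plasticity, symmetric rule, LTP-dominant network);
`simulate run --config FILE` runs a YAML/TOML configuration and writes
`spikes.csv`, `weights.csv`, `sync.csv` and a re-run manifest.

Python API:

```python
from ftsts import run_scenario
result, summary = run_scenario("resync_2000", seed=0, scale=0.2)
```

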