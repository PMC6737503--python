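# Methods

## The model

The package simulates recurrent excitatory–inhibitory (E–I) networks of
leaky integrate-and-fire neurons under stimulation protocols that harness
spike-timing-dependent plasticity (STDP) to move the network between a
synchronous and an asynchronous state.

**Membrane dynamics.** Each neuron obeys

    tau_m dv/dt = -v + Z(t) + mu + sigma*sqrt(tau_m)*chi(t) + V_stim(t)

with threshold 20 mV, reset 0 mV and no refractory period.  Defaults
(2,000-neuron network, 80% excitatory): tau_m = 10 ms, mu_E = 20.8 mV
(suprathreshold — excitatory neurons are intrinsically tonic with period
tau_m ln 26 ≈ 32.6 ms), mu_I = 18 mV (subthreshold — inhibitory neurons
fire only when driven), sigma_E = 1 mV, sigma_I = 3 mV.

**Noise discretization.** The equations are integrated with fixed-step
Euler at dt = 0.1 ms.  The stochastic baseline term is integrated like the
deterministic terms — multiplied by dt/tau_m — giving a per-step noise
standard deviation of sigma·dt/sqrt(tau_m).  This is a deliberate choice
over the Euler–Maruyama discretization (sigma·sqrt(dt/tau_m), 3.2× larger
at these values): under the larger noise the synchronous network state
that the whole method is built around is unstable (R stays below 0.1 even
from a synchronized start and the high weight attractor disappears),
whereas under the fixed-step reading the documented bistability emerges.
A consequence is that the effective noise is tied to dt; dt is therefore a
model constant, not a numerical knob (the deterministic dynamics are
dt-robust — halving dt changes the single-neuron firing period by <1%).

**Synapses.** Spikes are delivered after a 5 ms conduction delay into a
two-stage linear filter (rise and decay constants 1 ms); the drive to a
target population is Z = ±(J/C)·ΣS, positive for excitatory and negative
for inhibitory sources, with C = 0.3·N_tot for the between-population
projections (C = 10·N_target in the two-neuron configuration, C = N_tot
for the optional recurrent E–E/I–I projections).  J_IE is not published
separately, only the weight range J_IE·W_IE ∈ [10, 290] mV; we set
J_IE = 100 mV (equal to J_EI) so the dimensionless coupling spans
[0.1, 2.9]; every reported weight is the product J·W in mV, so this choice
only fixes an internal scale.

**Plasticity.** E-to-I synapses follow trace-based pair STDP: each
neuron carries an exponential trace (pre: tau_LTP = 20 ms; post:
tau_LTD = 22 ms) incremented by A_0 = 0.005 at its spikes; at a
postsynaptic spike each incoming synapse changes by eta·a_LTP·pre_trace,
at a presynaptic spike by eta·a_LTD·post_trace (eta = 0.25, a_LTP = 1,
a_LTD = −1.1: depression dominates by 10%).  Traces are decayed to the
current step *before* they are sampled and incremented *after*, which
makes the accumulated update exactly equal to the sum of the pair kernel
over all spike pairs (verified to 1e-9 relative in the tests) and leaves
simultaneous pairs without effect.  Weights are hard-clipped to
[10, 290] mV / J after every update.  Variants: anti-Hebbian
(a_LTP = −1.1, a_LTD = 1; used on plastic I-to-E synapses), LTP-dominant
(a_LTP = 1.01, a_LTD = −1, both windows 20 ms; no bistability), and a
symmetric inter-spike-interval rule ΔW = c_P·e^(−|ISI|/tau_P) −
c_D·e^(−|ISI|/tau_D) (c_P = 0.038, c_D = 0.02, tau_P = 10 ms,
tau_D = 25 ms; potentiation below the zero crossing at ≈10.70 ms,
depression above).  The symmetric rule fires one update per spike on
either side of a synapse against the last opposite-side spike
(nearest-spike pairing; all-to-all pairing would double count a rule
written on a single ISI).

**Synchrony.** The Kuramoto order parameter R(t) of the excitatory
population, with per-neuron phases interpolated linearly between
consecutive spikes.  Phases are undefined before a neuron's first and
after its last spike; such neurons are excluded and the phasor mean is
renormalized by the valid count (counting them as phase 0 would bias R
upward during silence).  Scalar comparisons use 1-s windowed means: the
last second before protocol onset ("pre") and a 1-s window starting 5 s
after protocol offset ("post").  R has a finite-size floor of order
1/sqrt(N_E) for fully asynchronous firing.

## Stimulation protocols

**FTSTS.** Charge-balanced biphasic voltage pulses (+U for T_stim, then
−U for T_stim, then a T_neutral gap) delivered population-wide.  The
follower population receives the same pulse delayed by T_stim, so the
leader fires during its +U phase and the follower one pulse-width later:
the forced spike lag is T_stim.  We deliberately do not use sign-mirrored
waveforms (V_E = −V_I): closed-form LIF arithmetic shows that a leading
−U phase leaves the follower so hyperpolarized that no published
amplitude could force it across threshold within T_stim, and in
simulation the mirrored arrangement desynchronizes ~3× slower than
reported because the excitatory population is then only rephased, not
forced.  With the desynchronize polarity the inhibitory (postsynaptic)
population leads — post-before-pre firing, net depression of ~0.1 mV of
J·W per synapse per cycle — and the 2,000-neuron network crosses from the
high attractor to the 75 mV stop threshold in ~18 s of stimulation.
Swapping the waveforms (synchronize polarity) forces pre-before-post and
potentiation.  A non-zero T_offset (used with the symmetric rule) anchors
the excitatory pulse at the cycle start and places the inhibitory pulse
T_offset later, so the forced ISI equals T_offset; the published offsets
(5 ms for potentiation, 11 ms with a 24 ms cycle for depression) sit on
either side of the symmetric rule's 10.70 ms zero crossing, and both
cross-pairings within a cycle then fall on the intended side.

**Amplitude jitter.** Per-cycle amplitudes drawn from
Normal(U_stim, variance U_stim/10) (variance as printed), truncated at 0;
the two pulses of a cycle share the amplitude.

**CR and FTSTS-CR.** Each population is split uniformly at random into
n_sub = 4 subpopulations.  Each period T (estimated at run time as the
first off-zero peak of the population-rate autocorrelation over the
pre-stimulation window, ~32 ms for the default synchronous network, or
supplied explicitly) contains n_sub slots of width T/n_sub; each slot
stimulates one excitatory and one inhibitory subpopulation, with fresh
independent uniform slot orderings drawn each period.  Plain CR delivers a
single positive rectangular pulse (amplitude U_stim, width T_stim) per
slot; FTSTS-CR delivers the full FTSTS biphasic pair to the selected E/I
subpopulation pair, forcing post-before-pre within the pair.  T_neutral
in the CR context describes the designed per-slot footprint
(2·T_stim + T_neutral ≈ T/n_sub); scheduling is driven by T alone.

**Partial inseparability.** A stated fraction of each population, drawn
once per run, receives the sum of both populations' waveforms.

**Stop rules.**  The protocol switches off permanently when the sampled
mean E-to-I weight crosses a threshold in the stated direction (75 mV
falling for desynchronization of the 2,000-neuron network, 25 mV for the
10,000-neuron network, 125 mV rising for resynchronization); the
simulation then continues unstimulated.

## Integration loop and engines

Per step, in fixed order: synaptic drive from the current filter state;
membrane update with stimulus and noise; threshold detection and reset;
trace decay; plasticity updates for this step's spikes; trace increments
and spike-time bookkeeping; delayed spike delivery and filter update;
weight sampling (10 ms default) with the stop rule.  The default engine
is a Numba-compiled loop; a pure-NumPy reference engine performs the same
arithmetic in the same order and is asserted bit-identical on pair-STDP
networks in the test-suite (the symmetric rule matches to 1e-9, the only
difference being transcendental evaluation inside vs. outside the
compiled code).  Runs are bit-reproducible from the configuration seed,
which spawns independent streams for connectivity, initial conditions
(membrane potentials uniform on [v_reset, v_threshold)), membrane noise,
and protocol randomness.

## Desk scaling

Full-size simulations (2,000–10,000 neurons, tens to hundreds of
simulated seconds) are expensive, so the test-suite and the acceptance
script run desk-scaled networks: populations shrunk by a factor (0.2 for
2,000-neuron scenarios → 400 neurons; 0.1 for the 10,000-neuron scenario
→ 1,000 neurons) while the per-neuron in-degree is preserved by raising
the connection probability and the C normalizers keep their full-scale
values.  This preserves both the mean synaptic drive and its fluctuation
statistics; side-by-side checks at full scale reproduce the desk-scale
steady-state R (0.54 vs 0.56 at the high attractor) and weight drift.
What desk scaling does not preserve is the finite-size floor of R
(~0.06 at 320 excitatory neurons vs ~0.025 at 1,600).

## What the simulations do and do not show

The generator-free, fully synthetic setting means every result is a
property of the stated model, not of biological data: conduction
heterogeneity, conductance-based synapses, spatial structure and any
non-stationarity of real circuits are out of scope.  Passing tests show
that the implementation reproduces the model's documented behavior —
bistable weight dynamics, long-lasting desynchronization after
weight-targeted stimulation, robustness to pulse jitter, parameter
heterogeneity and partial population overlap — under the published
parameters.

## Known discrepancies (kept, not tuned away)

With the printed parameters read faithfully, four published quantities do
not reproduce; we keep the faithful reading and let the corresponding
acceptance checks fail rather than adjust parameters toward them:

1. **Basin boundary.**  The measured synchronous/asynchronous boundary
   lies near 165 mV, not 100 mV.  Readings of the drive normalizer that
   lower it (e.g. C scaled by the source population) overshoot to
   ~65 mV and break the desynchronization experiments instead (a 75 mV
   stop would resynchronize).  Consequently, resynchronization runs that
   stop at 125 mV relax back to the low attractor, and the post-window R
   stays near the asynchronous floor instead of reaching 0.6.
2. **Low-basin convergence speed.**  Below ~100 mV the inhibitory
   population is nearly silent (mu_I = 18 mV is subthreshold and the
   E-to-I drive is weak), so the weight drifts toward the 10 mV attractor
   at only ~0.05 mV/s; "run to plateau" therefore reports ~49 mV from a
   50 mV start rather than 10 mV.
3. **Steady-state synchrony.**  The synchronous attractor yields windowed
   R ≈ 0.55 (both desk and full scale) against a reported 0.75.
4. **Coordinated-reset pacing.**  FTSTS-CR reaches the 75 mV stop in
   ~170 s and plain CR in ~210 s (reported: ~60 s and ~100 s); their
   ordering, the mechanism, and the long-lasting effect all reproduce.
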