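# Methods

## Scientific setting

Purkinje cells (PCs), the inhibitory output neurons of the cerebellar
cortex, converge onto glutamatergic projection neurons of the cerebellar
nuclei (CbN).  Measured unitary PC→CbN conductances in juvenile mice are
highly variable — right-skewed with mean 52.9 nS and coefficient of
variation (CV) 1.0 before corrections — rather than uniform as older models
assumed.  `cbnsim` implements the computational half of that study: it
synthesises PC spike trains and conductances with the measured statistics,
drives a conductance-based integrate-and-fire CbN neuron with them, and
quantifies how input size variability shapes rate coding, spike timing,
synchrony sensitivity and pause responses.

## Model components

### Unitary conductance sizes

The raw juvenile size distribution is modelled as a lognormal calibrated to
mean 52.9 nS and CV 1.0 exactly (closed-form moment matching), which
reproduces the right skew of the measured histogram.  The published
histogram itself is not tabulated in text form, so the shape family is a
modelling choice; a user-supplied empirical multiset (CSV, one raw
conductance in nS per row) takes precedence when provided and is resampled
with replacement.  Because the mean and CV are matched, the shot-noise
variance of the summed conductance — which is what drives the postsynaptic
neuron — depends on the family only through higher moments.

Simulated amplitudes are the raw draws corrected for steady-state synaptic
depression (× 0.4) and for the high-chloride recording internal (÷ 2.3),
giving a corrected mean of 9.2 nS.  Populations are drawn one input at a
time until the cumulative corrected amplitude reaches the target total
(200 nS unless stated); the overshooting draw is kept and the realised
total recorded, so realised totals slightly exceed the nominal one (the
reference simplified population likewise sums to 208 nS against a nominal
200).  For ensembles whose *definition* fixes the total — e.g. "populations
containing one 37 nS input with a 200 nS total" — the remainder is drawn to
its budget and rescaled to meet the total exactly
(`experiments.conditioned_population`), since there the total is a stated
condition rather than a stopping rule.

### Interspike intervals

PC firing is modelled by lognormal ISI distributions whose standard
deviation follows the empirical linear relation

    sd = −0.00154 + 0.583 · mean      (seconds)

with the lognormal shape parameters (μ, σ) set by moment matching on
(mean, sd).  The relation has a positive root at 0.583/0.00154 ≈ 378.6
spikes/s; rates at or above it are rejected.  No explicit refractory period
is imposed: at physiological rates the lognormal mass near zero is
negligible (P(ISI < 1 ms) < 1% at 83 Hz, asserted by test), and that gap is
itself what produces the refractory trough in autocorrelograms and the
pre-spike disinhibition window in summed conductances.  A memoryless
exponential (Poisson) ISI model serves as the refractory-free control.
Spike trains are cumulative sums of i.i.d. ISI draws truncated at the
requested duration.

### Conductance synthesis

Unitary synaptic events are biexponential kernels
k(t) = A·N·(e^(−t/τd) − e^(−t/τr)), peak-normalised so max k = A (the
standard conductance-clamp convention; the published rise/decay times are
treated as the biexponential time constants).  Inhibition uses
τr = 0.1 ms, τd = 2.5 ms; excitation uses τr = 0.28 ms, τd = 1.06 ms,
A = 0.4 nS, delivered as one aggregate Poisson stream at the printed total
events-per-second rate (20,000–25,000 /s depending on protocol).  Kernels
are truncated at 10·τd (discarded tail < 10⁻⁴ of the integral); the kernel
integral is exposed so Campbell's-theorem oracles
(mean = Σᵢ Aᵢ·rateᵢ·∫k) stay valid if the convention is changed.
Traces are sampled at dt = 0.02 ms by default (≤ τr/5 of the fastest
rise).  An alternative unnormalised-kernel convention was evaluated and
rejected: it displaces every reproduced simulation quantity far outside the
published values in the opposite direction.

### CbN neuron

A single-compartment passive membrane with threshold:

    Cm dV/dt = gE(t)(VE − V) + gI(t)(VI − V) + gL(VL − V)

VE = 0 mV, VI = −75 mV; a spike is emitted when V reaches θ = −50 mV, the
voltage is clamped at Vr = −60 mV for the absolute refractory period t_ref
(2 ms, or 1 ms in the pause protocol) and integration then resumes.  The
"inactive" refractory state is realised as a clamp at Vr; only the
post-refractory initial condition matters for the dynamics, so this choice
is behaviourally equivalent to freezing the voltage.  Named presets carry
the per-protocol parameters:

| preset | Cm (pF) | gL (nS) | VL (mV) | t_ref (ms) | exc events/s |
|---|---|---|---|---|---|
| fig2 | 50 | 8.8 | −40 | 2 | 20,000 |
| fig4 (= fig5, fig6) | 200 | 5 | −10 | 2 | 23,650 |
| fig8 | 70 | 20 | −49.9 | 1 | 23,650 |
| fig8-uniform | 70 | 20 | −49.9 | 1 | 25,000 |

Integration is a per-step exponential update toward the instantaneous
equilibrium V∞ = (gL·VL + gE·VE + gI·VI)/(gL+gE+gI), exact for
piecewise-constant conductances and free of stiffness error at the 0.1 ms
synaptic rise.  Threshold crossings are resolved at step granularity (no
sub-step interpolation); halving dt changes stochastic-input rates by well
under 2% (asserted by test).  In the constant-conductance limit the rate
has the closed form 1/(τ·ln((V∞−Vr)/(V∞−θ)) + t_ref), τ = Cm/(gL+gE+gI),
used throughout as an independent oracle (simulator agreement within 1% at
dt = 0.02 ms).

### Correlogram analysis

Cross-correlograms accumulate target spikes around each reference spike
over a 20 ms window, binned at 0.1 ms (0.5 ms for pause PSTHs; bin widths
are not published and are configurable).  Both a rate normalisation
(counts/(n_ref·Δt)) and a probability-per-bin normalisation (counts/n_ref)
are carried; reference spikes closer than the histogram extent to either
record edge are dropped, and the outermost bins receive full coverage.
The baseline is the mean rate over lags [−10, −5] ms (the flattest
pre-event region; configurable).  Summary metrics: e = fractional
elevation of the pre-spike maximum over [−5, 0) ms; i = fractional
suppression of the post-spike minimum over [0, +5] ms; t½ = time from the
trough to half-recovery, measured on a 3-bin boxcar-smoothed rate.  The
window extents and smoothing width are design choices (the published
definitions are graphical) and are recorded in exported metadata.

### Synchrony and pauses

Synchronised inputs share one spike train: grouping k inputs is exactly
equivalent to one input of their summed amplitude, and the conductance
pipeline preserves that equivalence bit-for-bit.  Pauses delete spikes in
[onset, onset+width) windows (2 ms wide, every 20/50/100 ms) without
re-drawing subsequent ISIs; overlapping windows are merged.  Pause PSTHs
are normalised to the mean rate in the 5 ms before onset, and the peak is
read at the peak time of the 100%-paused condition.

## Protocol scales

The original simulations ran up to 160,000 s per cell.  Desk-scale defaults
keep each protocol within minutes on one CPU while holding correlogram
standard errors below ~10% of baseline: 2,000 s/cell (per-input
correlograms), 10 s/cell (rate-vs-CV populations, as published),
100 s/condition (rate-code sweeps, as published), 200 s/condition
(synchrony), 1,600 s/condition (pauses).  Long runs are processed in 50 s
chunks with exact carry-over of the membrane state and kernel tails, so
memory is flat in duration and results are bit-reproducible for a fixed
master seed, configuration and chunk length (the chunk length partitions
the excitatory Poisson stream).  Seeding uses one master `SeedSequence`
with independent child streams per input and per stage.

## What the generator does and does not emulate

The synthetic inputs reproduce the measured size statistics (mean, CV,
skew), the ISI mean–sd relation with its refractory-like structure, full
(100%) synchrony, clean 2 ms pauses, and stationary Poisson excitatory
drive.  They do not emulate: serial ISI correlations or rate modulation of
real PC firing; partial or jittered synchrony; short-term plasticity
dynamics (depression is a static factor); dendritic or multi-compartment
effects; or intrinsic pacemaker currents of CbN neurons (deliberately
absent — the point of the model is that synaptically driven fluctuations
suffice).  Passing tests therefore demonstrate the fidelity of the
conductance-to-spiking transformation under these idealised inputs, not a
complete account of in vivo firing.

## Numerical and degenerate-case choices

dt = 0.02 ms default, integer-ratio resampling of traces only; a 1 s
burn-in is discarded from all rates and trace statistics (replacing the
experimental conductance-CV ramp-in, which is out of scope); conductance
traces flag CV as undefined (NaN) when the mean is zero; correlograms with
a non-positive baseline refuse to compute metrics; in draw-until-total the
overshooting draw is kept; duplicate pause windows merge; empty spike
trains are legal and yield zero conductance.

## Known limitations

Reproduced quantitative values for the stochastic protocols sit ~10–20%
below the published single-example figures (e.g. rate-code endpoints
≈109/29 vs 126/35 spikes/s).  The published values derive from individual
cells/draws whereas the package reports ensemble means, and two conventions
the source does not print — the kernel normalisation and the exact shape of
the size distribution — bound the achievable agreement.  All published
orderings and monotonicities (metric growth with input size, rate with
conductance CV, synchrony/pause effects with total affected amplitude,
fold-change decrease with pause interval, uniform > nonuniform relative
pause response) reproduce robustly at desk scale.
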