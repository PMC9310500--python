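# Methods

## Model

Each of the N = 78 regions is a two-population lumped neural mass in the
Lopes da Silva / Zetterberg lineage of alpha-rhythm models. Synaptic
integration is linear: every pathway convolves its presynaptic pulse density
with a bi-exponential kernel `h(t) = A (e^{-at} - e^{-bt})`, `0 < a < b`,
i.e. the second-order system `y'' + (a+b)y' + ab·y = A(b-a)x(t)`. Four
kernel filters per mass: external drive → pyramidal (EPSP), long-range input
→ pyramidal (EPSP), local inhibition → pyramidal (IPSP, stored with positive
amplitude and subtracted), and pyramidal → inhibitory (EPSP). The only
nonlinearity is the logistic pulse-density function
`sigm(V) = G / (1 + e^{-q(V - Vd)})`; there is no inhibitory-to-inhibitory
coupling and no local excitatory-to-excitatory loop. External input is
`P + noise·σ₀·ξ` with `ξ ~ N(0,1)` i.i.d. per sample per mass; negative
samples are not clipped (they enter a linear filter). Long-range input is the
plain sum of neighbours' delayed pulse densities times the global gain S (no
degree normalisation by default; a normalised mode exists but is off).

### Parameters (defaults = control condition)

| name | meaning | default | unit |
|------|---------|---------|------|
| t (dt) | sample time | 0.002 | s |
| P | mean drive pulse density | 550 | s⁻¹ |
| noise | drive fluctuation level | 1.0 | – |
| σ₀ | drive fluctuation base scale | 200 | s⁻¹ |
| A1, a1, b1 | EPSP amplitude/shape | 1.6, 55, 605 | mV, s⁻¹, s⁻¹ |
| A2, a2, b2 | IPSP amplitude/shape | 32, 27.5, 55 | mV, s⁻¹, s⁻¹ |
| g, q | sigmoid rate and steepness | 25, 0.34 | s⁻¹, mV⁻¹ |
| Vd1, Vd2 | excitatory/inhibitory thresholds | 7, 7 | mV |
| C1, C2 | E→I and I→E local couplings | 32, 3 | – |
| S | global coupling gain | 1.5 | – |
| T | inter-mass delay | 0.002 (= 1 sample) | s |
| sigmoid_scale | saturation convention | 2 (asymptote 2g) | – |

The sigmoid saturation convention is genuinely ambiguous in this model
family (asymptote `g` vs `2g`); both are implemented via
`NeuralMassParams.sigmoid_scale`. The default is the `2g` convention: with
the calibrated stand-in connectome it is the convention under which the
direction table reproduces (notably the uniformly higher total power of the
disease-like scenarios), whereas the plain-`g` convention fails the 2B
total-power direction. Parameter overrides per scenario are registered
verbatim (1A: Vd1 7→6/8; 1B: a1,b1 55,605→48,540 / 62,670; 1C: S 1.5→2.0/1.0;
2A: Vd2 7→8/6; 2B: a2,b2 27.5,55→40,70 / 17.5,35; 2C: C2 3→2/4). An
alternate contrast-1B (`1B_contrast_text`, a1=42, b1=670) is registered
because the values are printed inconsistently at the source; it takes no part
in scoring.

## Numerics

Kernel filters advance by an exact impulse-invariant exponential update of
the two modal components (`z1' = -a z1 + A x`, `z2' = -b z2 + A x`,
`y = z1 - z2`), treating each input sample as an impulse of area `h·x[n]` at
step size `h = dt/substeps` (default 4 sub-steps, h = 0.5 ms). The discrete
output therefore equals the `h`-scaled convolution with the closed-form
kernel to machine precision, and the update is unconditionally stable — the
fast EPSP decay (b = 605 s⁻¹, time constant 1.65 ms) poses no step-size
constraint. Within one dt the external drive and the delayed long-range
input are held constant while the local E↔I feedback refreshes every
sub-step. The delay is an integer ring buffer at dt resolution; non-integer
T/dt is rejected rather than interpolated. Initial state: all filter states
zero, pulse densities at sigm(0); a 2 s transient (1000 samples) is
discarded before any analysis. Default runs retain 4096 samples (8.192 s at
500 Hz).

Randomness: mass *i* of a run with seed *s* draws from
`numpy.random.default_rng([s, i])`, so noise streams are independent across
masses, identical between network and single-mass runs (S = 0 decoupling
equivalence is exact per seed), and invariant to the number of masses or
iterations. Batch iteration *k* uses seed `base_seed + k`. No global RNG
state exists anywhere; identical seeds give bit-identical output.

## Spectral estimation

Per channel: full-epoch periodogram, linear detrend, rectangular window,
`scaling="spectrum"` — chosen so the one-sided spectrum sums *exactly* to the
variance of the detrended signal (Parseval), which anchors the total-power
measure; a taper or segment averaging can be selected per call but trades
away that exactness. Resolution at the defaults is 500/4096 ≈ 0.122 Hz.
Band intervals are half-open `[low, high)` so the partition
{0.5–4, 4–8, 8–10, 10–13, 13–30, 30–45, 45–48} sums to exactly 1; delta and
gamma are computed but excluded from headline comparisons. Peak frequency is
the spectral argmax within a closed search range, default 4–13 Hz
(configurable — a 6–13 Hz variant also circulates for posterior dominant
rhythms), ties broken toward the lower frequency. Whole-brain values average
per-channel measures within an iteration, then across iterations; spike
density is the time-and-region mean of E(t).

## Direction classification

Scenario batches are labelled against the control batch on neuronal activity
(spike density), total power, and a composite oscillatory outcome. Sign
labels use an "unchanged" band of ±2 pooled standard errors by default —
dispersion-based rather than a fixed magnitude, since Monte-Carlo model
output is deliberately not significance-tested (any power can be bought with
iterations). The oscillatory rule, applied in order: theta up and peak not
up → *slower*; theta up and peak up → *mixed*; theta down → *faster*; theta
unchanged → *faster* if alpha2+beta rose, *slower* if the peak fell, else
*unchanged*. The rule is an operationalisation of a visual classification;
it is a pluggable strategy whose parameters are carried in every report.
Concordance is scored against the embedded reference direction table; the
contrast-1A oscillatory entry is accepted either way because the source
reports it inconsistently. The Welch unequal-variance t-test (scipy, with
Welch–Satterthwaite df) serves the group-statistics path for per-subject
values; simulated batches are never tested this way.

## Stand-in connectome and calibration

The anatomical matrix used in the original study (a DTI-derived binary
78-region cortical network) is not publicly deposited, so the default
connectome is a generated stand-in: a connected Watts–Strogatz small-world
graph with 78 nodes, mean degree 16 (density ≈ 0.21) and rewiring
probability 0.1, regenerated until connected and seeded. Random and ring
lattice topologies, dense-CSV and edge-list file input are also supported.

Mean degree, the sigmoid convention and the noise base scale σ₀ jointly set
the network's operating point. They were calibrated once, as a set, to the
qualitative regime the model family is built for: the control network must
produce an irregular, non-epileptiform alpha rhythm sitting *just below* the
transition to a strong slow (theta-range) collective oscillation, because
all disease-relevant behaviour lives near that transition — excitatory
insults push the network into it (theta rise, peak drop, total-power rise),
inhibitory-gain insults pull away from it, and IPSP shortening (2B) instead
accelerates the rhythm into alpha2. At the defaults (degree 16, 2g, σ₀ =
200 s⁻¹) the direction table reproduces across independent connectome
realisations and master seeds; at markedly weaker coupling the contrast
scenarios gain spurious theta from the noise floor, and at stronger coupling
or much weaker noise the control itself falls into the slow regime. The
single known systematic departure from the reference directions is scenario
1B's activity sign: with the fixed kernel normalisation, enlarging the EPSP
raises the kernel's DC gain on the direct drive path *and* on the E→I→E loop,
and the direct path wins at every operating point we probed, giving a small
spike-density *increase* where the reference records a small decrease. The
other ten activity signs, all twelve total-power signs and the oscillatory
labels reproduce.

## Surrogate data

The surrogate-group generator emulates only the spectral contrast used by
the statistics path, not MEG physics: each channel is low-passed white noise
(the floor) plus narrowband components made by driving second-order
resonators (`iirpeak`, Q = 25, linewidth ≈ 0.4 Hz at 10 Hz) with white
noise — an alpha component at the group's peak frequency and, in group B, a
theta component carrying the fraction `theta_shift` of the alpha power.
Subjects differ by a log-normal amplitude factor (σ = 0.2); groups default
to 18 + 18 subjects with five 4096-sample epochs each. It contains no
beamformer leakage, sensor noise structure, 1/f slope changes or subject
covariates, so passing statistical-power checks here says the *pipeline*
(epoch IO → spectra → per-subject aggregation → Welch test) behaves
correctly, not that real MEG effects of this size would be detected at the
same rate.

## Problem sizes

Default analyses use 10 Monte-Carlo iterations per scenario with 4096
retained samples, the spike-density convention; spectra-only batch defaults
of 50 iterations are provided as constants. The statistical-power check runs
100 seeded repetitions of an 18-vs-18 comparison with 2 channels per subject
— the channel count narrows only within-subject averaging noise, not the
group effect, and keeps the check inexpensive. The acceptance script and the
test suite each complete in minutes on one CPU at these sizes.

## Known limitations

* The exact equations of the original implementation are not printed in its
  main text; the kernel/sigmoid closed forms here follow the model family's
  standard forms and are pluggable. Absolute spike-density and power values
  are therefore not comparable to the original figures — only directions
  and regimes are.
* Homogeneous parameters across regions; no activity-dependent degeneration,
  regional heterogeneity, hub-targeted lesions or fitting to empirical data.
* Scenario 1B's neuronal-activity direction departs from the reference (see
  calibration section).
* The stand-in connectome matches the original's size and binary symmetric
  reciprocal structure, not its exact anatomy; results are checked for
  robustness across realisations but depend on the near-transition operating
  point.
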