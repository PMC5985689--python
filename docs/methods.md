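# Model and methods

`sacsim` simulates the decision the oculomotor system makes at every
moment of fixation: keep the eyes still, or launch a saccade.  The model
couples a one-dimensional neural-field map of the superior colliculus
(SC) to a mutually inhibitory omnipause/burst-neuron (OPN/BN) trigger in
the brainstem and a cerebellar (fastigial) stop circuit, closes the
visual loop through an oculomotor plant with a 50-ms feedback delay, and
adds spatiotemporally correlated noise to the map.  Saccades of any
size — including fixational microsaccades — arise from one mechanism:
whenever the centre of activity of the SC map moves far enough off the
rostral pole, the brainstem trigger flips from the fixation state (OPN
firing, BNs silent) to the saccade state (OPN silent, one side's BNs
firing).

## Collicular map

The two colliculi are collapsed into one signed map of 101 neurons
spanning [−5, +5] mm, rightward eccentricities at positive coordinates.
Retinal eccentricity `D` (deg) maps to tissue coordinate
`d = B·ln((D + A)/A)` (mm), with `A = 3°`, `B = 1.4 mm`, extended to
both directions by odd symmetry.  Each neuron is a leaky integrator
(`τ_SC = 5 ms`) of its inputs with logistic activation
`a(u) = F/(1 + e^{−β_u u})`, `F = 500 spikes/s`, `β_u = 0.1`.  Lateral
connectivity is a Mexican hat,
`w_ij = (A_w + C)·e^{−dist²/2σ_SC²} − C` with `A_w = C = 1`,
`σ_SC = 0.5 mm`: short-range excitation, global inhibition.  Under
these constants the map operates as a winner-take-all field whose
stable state is a single saturated hill ~1.2 mm wide; cortical bias,
noise and the cerebellar reset move the hill, and because the lattice
is discrete the hill's resting position is quantized at roughly half
the 0.1-mm neuron spacing.  This quantization is visible downstream as
a ~0.1–0.25° granularity of motor commands and is the dominant
accuracy limit of the closed loop.

A burst layer thresholds the buildup layer at `burst_threshold`
(300 spikes/s = 0.6·F, boundary inclusive).  Descending drives:

* to the OPN — the buildup layer weighted by `1 − |d|/S` (strongest
  from the rostral pole);
* to each side's BNs — the burst layer weighted by distance from the
  pole, summed per side and divided by the whole-map burst total plus
  `buildup_fraction = 0.05` of the buildup total, so the command encodes
  the *location* of activity rather than its amount.

The mm-valued centre-of-activity command is converted back to degrees
through the exact inverse magnification before it reaches the brainstem
and cerebellum.  This undoes the logarithmic compression of the map, so
a single set of downstream gains produces accurate saccades across
amplitudes; we read this conversion as part of the topography-to-rate
code transformation of the SC→BN projection.

Each side's BNs then receive the *net* rectified command
`max(c_own − c_opposite, 0)`.  Without this crossed inhibition a hill
centred exactly on the pole would drive both sides with ~0.35° each,
which exceeds the trigger's release threshold — the OPN could never
resume after a saccade.  With it, centred activity yields zero net
drive to both sides, and only a genuine imbalance moves the eyes.

## Brainstem trigger

One OPN and three BNs per side (LLIBN, MLEBN, MLIBN), each a leaky
integrator (`τ_BN = 1 ms`) with saturating rate
`B(x) = B_m(1 − e^{−(x−e0)/b})`, rectified at zero; `B_m = 800
spikes/s`, `b = 8`, `e0 = 0`.  The OPN (tonic bias 50, plus the
rostrally weighted SC drive scaled by `k_opn = 0.009`) inhibits all six
BNs; the IBNs inhibit the OPN (`w_LLIBN_OPN = 10`) and the three
contralateral BNs (`W_IBN_BN = 0.1`).  The OPN→LLIBN weight is weak
(0.0015) and OPN→MLEBN/MLIBN strong (0.2), so a modest SC command can
lift the LLIBN, whose strong projection then silences the OPN — a
Schmitt trigger with measured switch-up threshold ≈ 0.22 command units
and release threshold ≈ 0.01 at defaults.  The OPN's saturation is a
separate parameter (`opn_max_rate`, default 800) so that lowering the
BN gain — the PSP manipulation — weakens the burst neurons without
weakening the omnipause neuron.

The SC command enters the LLIBNs with gain `k_llibn = 5.5` (trigger
sensitivity: fluctuations ≳ 0.24° of net command flip the circuit) and
the medium-lead neurons with gain `k_bn = 1` (movement drive).  Two
separate gains are needed because the trigger must react to ~0.2°
commands while the MLEBN rate must stay in the near-linear range of
`B(x)` so that saccade duration grows only weakly with amplitude and a
single cerebellar calibration stops all sizes accurately.

## Cerebellar stop and reset

Per movement direction the fastigial circuit integrates an efference
copy of the MLEBN rate through two cascaded leaky stages
(`T_cblm1 = T_cblm2 = 20 ms`, efference gain 0.013): over a ~20-ms
saccade the cascade integrates displacement; afterwards it leaks back
to zero.  With command `c` and estimate `e`,

    late  = max(F1·e − F2·c, 0)       F1 = 0.1, F2 = 0.03
    early = max(F3·c − F4·e, 0)       F3 = 1,   F4 = 0.13

The late burst switches on as the displacement estimate overtakes the
command, and is routed two ways: a *choke* (gain 2·10⁴) that silences
the medium-lead BNs of the moving side, and a rostral reset (gain 10⁶
times the summed late bursts) that excites map neurons within 0.5 mm of
the pole and inhibits the rest, snapping the hill back to centre.
Because the estimate decays over tens of milliseconds after the burst
ends, the choke and reset outlast the movement — a refractory period
that bridges the 50-ms window during which the retinal error is still
stale.  This is why no discrete "reset at saccade end" is needed: the
leak both empties the integrator for the next saccade and enforces the
refractory.  A `crossed_choke` switch routes each late burst to the
anatomically crossed side instead; in this collapsed one-dimensional
model the two routings are behaviourally equivalent.

## Cortical drive and noise

The frontal eye fields contribute a Gaussian hill of excitation
(`σ_FEF = 0.5 mm`) at the collicular location of the target error, with
a saturating eccentricity gain `2000 + 10000·(1 − e^{−|err|/2°})`: weak
for small errors (small residual errors do not deterministically evoke
correction) yet strong enough to relocate the hill for real target
steps.  The basal ganglia contribute the complementary surround
inhibition `−15000·(1 − e^{−Δ²/2σ_BG²})`, `σ_BG = 1 mm`.  The absolute
scales are free constants of this implementation, chosen so the hill
relocates to a 2° target within ~30 ms while the recurrent field still
dominates moment-to-moment stability.

Noise is an Ornstein–Uhlenbeck field: one white source per neuron,
mixed spatially with a Gaussian kernel (`σ_noise = 0.2 mm`, rows
L2-normalized so every neuron has identical stationary variance) and
filtered temporally (`τ_noise = 20 ms`) with the exact discrete OU
update, so the stationary SD equals `noise_gain` at any step size.
`noise_gain = 850` (input units) is the one free amplitude; it is
calibrated so default fixation yields 1–2 microsaccades/s with median
magnitude ≪ 1°.  The field is zeroed at each saccade onset (OPN
silencing), preventing a persistent fluctuation from launching
staircases; the RNG stream is not touched, so a run is reproducible
from its seed.

## Plant and engine

The net MLEBN drive is scaled by `velocity_gain = 0.62 (deg/s)/(sp/s)`
into a velocity command; a neural integrator forms the step, and the
pulse (plus a 10% slide component low-passed at 50 ms) compensates the
first-order plant (`τ_plant = 150 ms`) so the eye tracks the integrator
with minimal post-saccadic drift.  The plant constants are not part of
the published model and are chosen for physiological peak velocities
(~25 deg/s at 0.5°, ~100 deg/s at 2°) and durations (20–40 ms).

All continuous states (101 map neurons, 7 brainstem neurons, 4
cerebellar stages, 3 plant states) advance jointly with a fixed-step
third-order Bogacki–Shampine scheme at `dt = 1 ms` (forward Euler
available for debugging).  Discrete elements update once per step: the
visual delay ring buffer (50 samples), the noise draw, and the noise
reset at OPN silencing.  Quartering the step changes a noise-free 2°
saccade's amplitude by <2%.

## Experiment presets

Each condition edits at most two parameters of the healthy model:

| preset | edits | expected signature |
|---|---|---|
| `single_saccade_2deg` | noise off; target step 2° | one saccade, 2° ± 10% |
| `fixation_default` | none | 1–2 microsaccades/s, median ≪ 1° |
| `sc_inactivation` | null output of map neurons in (0.4, 1.0] mm | rate ↓, fixation shifted |
| `pd` | noise ×2 | rate ↑, slope unchanged |
| `psp` | noise ×4, `B_m` 800→300 | magnitude ↑, slope ↓ |
| `sca` | `F1` ×0.5 | macrosaccadic oscillations |

The scaling factors are implementation choices tuned once to produce
the qualitative clinical orderings; they are ordinary parameters and
can be changed in configuration.  Ataxia is modelled on `F1` because
that gain scales the whole stop signal (choke *and* rostral reset);
reducing the choke alone leaves the rostral stop intact and produces no
oscillations.  The inactivation window spares the innermost 0.4 mm:
nulling from 0 mm outward removes one side of the fixation hill
entirely, leaving an uncancellable net command from the intact side and
a pathological ~20/s jerk pattern, which is not what focal rostral
inactivation produces experimentally.

## Event analysis

Saccades are detected by a velocity threshold (5 deg/s on a 5-sample
Savitzky–Golay derivative) sustained ≥ 3 ms; a dual-threshold pass then
extends each event's boundaries while the speed stays above one fifth
of the threshold, so the movement's slow settling tail counts toward
its amplitude, and events closer than 10 ms are merged.  Thresholds are
low because simulated inter-saccadic traces are nearly noiseless (the
model has no ocular drift or tremor).
Square-wave jerks are opposite-direction consecutive pairs within
0.5 s and magnitude ratio in [0.5, 2]; macrosaccadic oscillations are
runs of ≥ 3 alternating events, each ≥ 0.5° ("macro") and within 0.5 s
of its predecessor.  The main-sequence slope is the least-squares slope
through the origin of peak velocity against magnitude.  The detector is
built for these clean simulated traces, not for noisy recordings of
real eyes.

## What the simulations do and do not show

The synthetic conditions emulate the *mechanism* of saccadic triggering
and its failure modes, not any particular dataset: there is no ocular
drift or tremor, no vertical component, no binocular geometry, and the
noise lumps all physiological sources into one collicular input.
Passing tests therefore demonstrate internal consistency of the trigger
hypothesis (hysteresis, mutual exclusion, normalization, condition
orderings), not quantitative agreement with any patient recording.
Absolute rates and magnitudes under the disease presets depend on the
free gain constants; only their orderings against matched-seed controls
are meaningful.

## Numerical and design notes

* Problem sizes: unit tests run 0.2–1-s loops; statistical checks use
  three 100-s fixation runs and five 30-s runs per condition, enough
  for stable medians at 1–2 events/s.
* The hill's lattice pinning quantizes command outcomes; closed-loop
  amplitude accuracy at the tested sizes (0.5°, 1°, 2°, 3°) is 1–7%,
  with residual errors below the corrective-saccade threshold, so
  target steps yield exactly one saccade.
* Burst-layer boundary is inclusive (`a ≥ threshold` bursts); ties in
  the winner-take-all field are broken by any asymmetry of the input
  (tests use an explicit 1e−6 seed).
* Degenerate inputs: zero-duration runs, even neuron counts, negative
  time constants and out-of-map inactivation windows are rejected at
  validation; non-finite states abort a run naming the first bad
  component and step.
* `w_MLIBN_OPN` exists (default 0) for the anatomically suggested
  MLIBN→OPN projection that the published weight table omits; enabling
  it strengthens OPN suppression during saccades without changing the
  trigger threshold ordering.
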