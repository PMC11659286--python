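# Methods

This note documents the models, algorithms, parameter choices and known
limitations of pneumotrace.  It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic trace model

### Breath waveform

A breath cycle is a positive half-sine inspiration of duration
Ti = 0.35·TT followed by an expiratory lobe `−c·sin(π·u^k)` (u = elapsed
fraction of Te).  The stretch `k ≈ 2.46` and amplitude `c ≈ 0.76·amp`
are solved once from two constraints:

1. **area balance** — each cycle integrates to zero (inspired volume =
   expired volume, as in an AC-coupled flow or chamber-pressure signal),
   so high-pass filtering cannot shift the baseline or the onsets;
2. **slope continuity through the onset** — the expiratory tail meets
   the next inspiration with the same slope, so the breath onset is a
   steep, unbiased zero crossing under any zero-phase filter.

Both properties exist to make ground truth meaningful: the programmed
onset *is* the signal's zero crossing, to machine precision on clean
traces.  Cycle periods and amplitudes are jittered with truncated
Gaussian multipliers (CV defaults 0.08 and 0.10, typical of quiet
rodent breathing).  Sighs replace a breath's amplitude with
`sigh_amp_factor × amp_mean` and apneas append a quiescent pause so the
breath's onset-to-onset interval equals `apnea_ibi_factor × TT`; both
factors must be ≥ 2 so every programmed event satisfies the detector's
definitions by construction.  Event counts are exact per-session quotas
(`round(rate/100 × n_breaths)`) with random positions, so rate-recovery
tests compare integers, not Poisson draws.

Default conditions: adult sessions at 150 breaths/min, 2% amplitude
noise, 0.5 sighs and 0.5 apneas per 100 breaths; neonatal baselines at
120 breaths/min with a cardiac oscillation (6% of breath amplitude, 450
beats/min) superimposed and a dedicated cardiac channel emitted
alongside (heart rate is recorded as its own trace in neonatal
sessions).  Adult sessions default to 100 Hz sampling, neonatal to
200 Hz — enough to resolve the 4–12 Hz cardiac band.

### Gas channels

Chamber O2/CO2 follow first-order washout toward each period's inflow
fraction with time constant τ = chamber volume / flow rate (default
450 mL at 198 mL/min, τ ≈ 2.3 min).  Oxygen's steady state is depressed
by `VO2/flow` — the exact flow-through mass balance the analysis stage
inverts.  CO2 production by the animal is not modeled (the analysis
never uses chamber CO2 quantitatively, only for switch detection).  The
five-period adult protocol defaults to 20 min per period: room air
(20.95% O2), 5% CO2 / 21% O2 hypercapnia, room air, 10% O2 hypoxia,
room air.  Ventilatory responses are rendered as step changes at the
switch: hypercapnia ×1.35 rate and ×1.50 amplitude, hypoxia ×1.25 and
×1.10 — magnitudes in the range typical of adult mouse chemoreflexes;
they exist so percent-change contrasts have a known sign and rough
size, not to reproduce any particular animal.

The anoxic mixture for neonatal challenges is rendered as 3% CO2 / 97%
N2 (configurable).

### Autoresuscitation sessions

Each challenge renders eupnea during the programmed induction window,
silence from apnea onset, gasps (isolated 1.5×-amplitude cycles) at the
programmed intervals, and — for recovering trials — eupnea resuming
after the last gasp, paced by the instantaneous rate curve
`VF(t) = floor + (base − floor)(1 − e^{−t/τ})` measured from the first
gasp.  Heart rate steps to its floor at apnea onset and recovers along
its own exponential from the first gasp; the cardiac phase is the
integral of the instantaneous HR, so the rendered oscillation embodies
the programmed curve exactly.  Ground-truth latencies are the
closed-form inversions of these exponentials.  The next challenge
follows 300 s (5 min) after the first gasp.  The terminal trial renders
gasps without recovery and an HR decay to zero.  There is no mortality
mechanism beyond the `recovers` flag.

## Breath detection

The breath channel is zero-phase band-pass filtered: the high-pass
stage subtracts a centered moving-average baseline of width
1/highpass_hz (default 10 s) — an IIR high-pass at 0.1 Hz rings for
~10 s at the record edges and would corrupt the first and last breaths
— and the low-pass stage is a 4th-order Butterworth at 20 Hz.

Cycles are delimited by a hysteresis pair of thresholds ±h, with
h = 0.25 × a robust reference amplitude (median of lobe peaks above one
quarter of their 99th percentile — robust against thousands of small
cardiac lobes during long apneas).  All thresholds are relative, so
detection is invariant to channel gain.  Onsets are refined to
sub-sample precision:

* **contiguous breathing** — the interpolated zero crossing between the
  expiratory tail and the inspiratory rise (the waveform crosses zero
  exactly once there, steeply);
* **onsets out of silence** (post-apnea breaths, gasps) — zero
  crossings adjacent to a silent baseline are located by noise, so the
  inspiratory rise between h/2 and the lobe peak is fit with a bounded
  half-sine (the classic model of inspiratory flow) and the onset is
  the fitted foot.

Candidate cycles shorter than `min_tt` (0.1 s) are merged; lobes that
never reach h are absorbed into the preceding cycle.  The expiratory
offset is the zero crossing where the lobe durably returns to baseline;
for contiguous breaths the residual gap to the next onset (shallow-tail
noise) is absorbed into Te unless it is a genuine pause (> 50% of the
cycle), so Ti + Te tiles gap-free spans exactly.

Measured on the generator (100 sessions × 60 s, adult defaults):
onset recall = precision = 1.0 within one sample period at 5% noise;
≈ 0.98 at 15% noise (`scripts/acceptance.py` recomputes these).

## Calm breaths and events

"Calm" is operationalized as: within a centered 21-breath rolling
window, TT and amplitude each within [1/2, 2] × the window median, and
not inside a movement-artifact span (0.5 s local RMS > 3 × session
median RMS).  On metronomic data every breath is calm; sighs and
stretched-IBI outliers are excluded automatically.  The window median
makes the rule scale-free and deterministic.

Apneas and sighs use inclusive ≥ 2× thresholds against the mean IBI /
amplitude of *calm* breaths, computed per gas epoch (a session-wide
mean would mis-scale thresholds across conditions, since hypercapnia
and hypoxia shift both rate and depth).  Events are independent calls;
no exclusion rule links them.  Rates are exact count ratios per 100
breaths; the square-root convenience column anticipates the analysis
transform but the statistics stage applies its own.

## Heartbeats and recovery latencies

Heartbeats are peaks of the 4–12 Hz (240–720 beats/min) band-passed
cardiac channel (the dedicated channel when present, else the breath
channel), with a refractory period of 0.6 × the running median
inter-beat interval and parabolic sub-sample peak refinement.  The HR
series is 60 / the median-filtered (5-beat) inter-beat interval,
interpolated onto a uniform 10 Hz grid; grid points more than 5 s from
any beat are undefined (NaN) — needed during asystole-like gaps, not an
error.  On constant-HR synthetic data the baseline estimate is within
1 beat/min of truth at 240–600 beats/min.

Ventilatory frequency for recovery tracking is 60 / interbreath
interval (gasps included) on the same grid, set to zero inside
breathless gaps longer than 3 × the apnea gap.

Recovery latency is the first grid crossing of
`fraction × baseline`, refined by linear interpolation, measured from
the first gasp (the start of the recovery period); an alternative
origin can be passed via `t0`.  Reported latencies are HR → 63% and
VF → 50% (both other combinations are also computed), and decoupling is
their difference as an exact column identity.  Survival of a trial
requires both reported latencies to be defined before the next
challenge.

Apnea induction uses a terminal-apnea gap of 10 s of breathlessness —
the cessation threshold is configuration, not biology, and must exceed
any programmed gasp latency to be meaningful.  Gasps require ≥ 0.5 ×
baseline amplitude and ≥ 1 s of preceding quiescence.  "Gasp frequency"
is emitted both as the inter-gasp interval in seconds and its
reciprocal in gasps/min, since either reading appears in the field.

## Tidal volume

VT = inject_volume × (deflection ratio) × C, with C the Drorbaugh–Fenn
barometric correction evaluated at body temperature linearly
interpolated between the pre- and post-session rectal temperatures.
Saturated water vapor pressure uses the Antoine equation.  Without a
calibration injection, VT is reported in signal units with a
`vt_calibrated = False` flag rather than guessed.

## Adult epochs and metabolics

Switch times come from markers when present, else from the first
halfway crossing of the chamber gas toward its new target.  The
"initial reflex" window is the first 120 s after the chamber reaches
90% of the target (breathing during the transit is at an undefined
stimulus); "steady state" is the last 300 s of the period; room-air
analysis windows are the last 300 s of each room-air period.  All
windows are configurable and logged.  Condition summaries require ≥ 20
calm breaths, otherwise the epoch is omitted with a logged reason.
VO2 = flow × (FiO2 − FeO2) / weight is a steady-state mass balance;
during reflex windows the chamber is still equilibrating, so reflex
VO2 values carry transient bias and negative values are surfaced (never
clipped) as a calibration red flag.  Percent change references each
challenge's steady state to the immediately preceding room-air window
(hypercapnia → first room air, hypoxia → second), and is invariant to
per-gram versus absolute units.

## Statistics

Outcomes are analyzed on a per-outcome transform (inspiratory duration
and tidal volume and event rates on sqrt; expiratory/cycle duration,
frequency, ventilation, VO2 and VE/VO2 on log10), or by automatic
selection maximizing residual normal-QQ correlation with near-ties
broken toward raw.  The model is a linear mixed-effects fit (REML,
statsmodels MixedLM) with group × sex fixed effects and a random
intercept per animal; a singular random-effect fit falls back to OLS
with a prominent warning — in the balanced two-group case the Tukey
p-value then reduces exactly to the pooled-variance t-test.

Pairwise contrasts over the design cells use the studentized-range
distribution on |t|·√2 with a Satterthwaite-type degrees of freedom:
the between-animal and within-animal contributions to the cell-mean
difference variance are weighted by their own df (n_animals − n_cells
and N − n_animals).  The df method is named in every report header so
results are comparable across implementations.  Tukey-adjusted p-values
are clamped to be ≥ the unadjusted p.  The type-I error of the full
stack, measured by simulation at the package's default null design (8
animals/cell, ICC ≈ 0.33, 5 observations/animal), sits near the nominal
0.05; `scripts/acceptance.py` recomputes it on 500 replicates.

Degenerate inputs: exactly constant outcomes yield zero contrasts with
p = 1; log10 is refused (naming rows) on non-positive data; automatic
transform selection skips inapplicable candidates.

## What passing tests do and do not show

The generator's waveform is far cleaner than real plethysmography: no
drift, no humidity or temperature artifacts, no sniffing bouts, no
chamber resonance, Gaussian noise only, and cardiogenic oscillations
that are purely sinusoidal.  Perfect onset recovery at 5% noise
therefore validates the algorithmic contract (thresholds, refinement,
bookkeeping), not field performance on noisy animals.  Similarly, VO2
recovery validates the mass-balance inversion, not analyzer drift
handling; and the statistics simulations validate calibration under the
generative model that matches the fitted model's assumptions.
Windowing conventions (reflex/steady-state extents, terminal-apnea gap,
gasp isolation) are deliberate operationalizations and are exposed in
configuration; analyses of real data may need them retuned.

## Problem sizes used in validation

Acceptance-scale runs use 60 s adult sessions at 100 Hz (×100 seeds),
five-trial neonatal sessions at 200 Hz with the standard 300 s
recovery hold, 50-seed respirometry recovery, and 500 null + 100
effect-recovery mixed-model replicates — sizes chosen so the full
validation pass completes in minutes on a single CPU while every rate
is estimated from ≥ 10^4 events where it matters (breath detection).
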