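# Methods

## The oscillator model

Each cell is a Poincaré (amplitude–phase) oscillator,

    dr/dt   = λ r (A0 − r)
    dφ/dt   = 2π/τᵢ + σ_φ ξ(t),

the minimal planar limit-cycle model that reproduces the qualitative
repertoire of skeletal-tissue clock recordings: damped population rhythms
from desynchronizing cells, phase- and dose-dependent resetting by brief
stimuli, the type 1 → type 0 resetting transition as stimulus strength
crosses the limit-cycle radius, amplitude resynchronization of dispersed
populations, and entrainment by periodic forcing. No mechanistic
transcription–translation feedback model is attempted; the package's
subject is the analysis pipeline, and the Poincaré oscillator is the
standard chronobiology formalism whose behaviour the pipeline must
quantify correctly.

Radial relaxation does not feed back on phase, so an instantaneous
Cartesian displacement is the complete description of a stimulus: the new
phase is the polar angle of the displaced state (the origin maps to phase
0 by convention). Phase 0 is the reporter peak; the observable per cell
is `obs_baseline + obs_gain · r cos φ` plus Gaussian observation noise,
and the population trace is the mean over cells.

### Default ensemble parameters

| parameter | default | units | rationale |
|---|---|---|---|
| n_cells | 100 | – | smallest population whose mean trace has explant-like smoothness; finite-N phase noise ≈ 0.5 h |
| tau_h | 24.0 | h | circadian reference period |
| tau_sd_h | 0.5 | h | with σ_φ, halves ensemble amplitude in 4–6 cycles (see below) |
| relax_rate λ | 0.15 | 1/h | amplitude perturbations relax within ~1/4 cycle |
| limit_radius A0 | 1.0 | a.u. | sets the amplitude scale |
| phase_noise σ_φ | 0.1 | rad/√h | see damping calibration |
| obs_baseline / obs_gain | 2.0 / 1.0 | signal units | keeps the observable positive (baseline ≥ 1.5·gain·A0) |
| obs_noise_sd | 0.02 | signal units | photon-noise-like jitter, small next to the rhythm |
| dt_h | 0.05 | h | fixed-step explicit integration; events applied between steps |

**Damping calibration.** Unstimulated synchronized ensembles should decay
to below half their starting cycle amplitude within 4–6 cycles, the decay
seen in undisturbed explant recordings. For Gaussian phase dispersion the
ensemble amplitude factor is exp(−σ²(t)/2) with
σ²(t) = (2π σ_τ t/τ²)² + σ_φ² t; the defaults σ_τ = 0.5 h,
σ_φ = 0.1 rad/√h give a factor ≈ 0.45 at t = 120 h. (Weaker constants
sometimes quoted for this kind of model, e.g. σ_τ = 0.25 with σ_φ = 0.05,
leave ~80% of the amplitude after five cycles and do not produce the
stated behaviour; the behavioural target was kept and the constants set
to meet it.)

Integration is a fixed-step explicit scheme in polar coordinates
(dt = 0.05 h). The system is non-stiff; a fixed step keeps runs exactly
reproducible for a given seed, which adaptive steppers do not guarantee.
Every stochastic routine takes an explicit seed and no global RNG state
is used.

## Stimulus calibration

Dose maps to kick magnitude through a saturating Michaelis-type transfer
function ε(d) = ε_max·d/(d+K) with a fixed kick direction; the tissue
experiments report dose–response outputs, not the transfer function, so
the constants are fitted by grid search against behavioural endpoints and
shipped as package defaults:

* **Osmotic** (`ε_max = 1.93`, `K = 300 mOsm`, direction `−1.5010 rad`):
  fitted so a +400 mOsm instantaneous kick at the mid-descending phase
  (6 h after peak) of the deterministic oscillator produces a 9.5 h phase
  delay, while +200 mOsm stays below the limit-cycle radius
  (ε(200) = 0.77 A0), making resetting at that dose type 1 — both
  endpoints of the hyperosmotic explant experiments. The closed-form kick
  geometry (`skeletime.calibration.fit_osmotic_calibration`) reproduces
  the fit.
* **Loading** (`ε_max = 0.85`, `K = 0.5 MPa`, direction `−0.40 rad`):
  fitted by simulation so the five-day in-vivo loading protocol (below)
  advances the clock by ~8 h against sedentary controls. The direction is
  mildly off-radial: a bout at the reporter peak mostly boosts amplitude
  with minimal shift, while repeated bouts at the trough walk the phase
  forward — the phase dependence the loading experiments show.

**Sustained stimuli.** A stimulus held for some duration acts as a
constant Cartesian drive delivering ε(d) *per hour of application*; a 1 h
compression bout is therefore equivalent to one instantaneous kick, and
the 12 h on-half of a 12:12 loading cycle delivers 12× that impulse.
(The alternative convention — spreading a single kick's impulse over the
whole on-half — makes a 12 h sustained load as weak as a 1 h bout; under
it the single-oscillator locking map barely contracts in three forced
days and antiphase schedules cannot produce antiphasic rhythms, contrary
to the cultured-cell experiment the scenario emulates.)

**Stimulus phase categories** {peak, mid-descending, trough,
mid-ascending} map to {0, 6, 12, 18} h after the reporter peak.

**Schedule presets**: `single_pulse`, `phase_series` (one schedule per
category), `daily_pulses`, `antiphase_12_12` (two square waves offset
12 h, 3 days), `osmotic_cycles`, `treadmill_in_vivo` (five daily 45-min
loading bouts at the trough category — the in-vivo stimulus is modelled
as discrete daily bouts, one per running day, rather than sustained
forcing; which of the two the biology implements is unknown, and discrete
bouts match the 45-min protocol directly).

## Analysis conventions

* **Detrending** subtracts (optionally divides by) a centred trapezoid-
  weighted moving average spanning exactly `window_h` (default 24 h);
  half-weighted endpoints make the average of a full-period cosine vanish
  identically on a uniform grid, so detrending is idempotent on circadian
  components. Half a window is trimmed at each edge, never padded.
  Subtraction is the default because it keeps amplitude in signal units,
  which the %-of-reference-peak metric downstream relies on.
* **Cosinor**: linear sin/cos parameterization; amplitude ≥ 0, acrophase
  in [0, period) as hours after the reference time at which the fitted
  curve peaks; zero-amplitude F test with (2, n−3) df. The damped variant
  multi-starts from a 1 h period grid on [18, 30] h; ties on RSS break
  toward smaller |damping|, then period closer to 24 h.
* **Phase shifts** are wrapped to (−12, +12] with advances positive. The
  baseline-extrapolation method compares pre-event and post-event
  fixed-period cosinor acrophases, excluding a 12 h post-stimulus
  transient (config-exposed); the control-referenced method uses a
  parallel recording's acrophase as the prediction.
* **Peak amplitude** is the detrended peak height (peak-to-midline); peak
  detection smooths with a 4 h window and enforces ≥ 16 h peak
  separation, keeping the higher peak on conflicts.
* **PTC winding**: new phase = (old + shift) mod 24, unwrapped along
  sorted old phases with shortest-path jumps; the winding number is the
  net number of cycles traversed over one full turn. Type 1 ⇔ W = 1,
  type 0 ⇔ W = 0. Classification requires ≥ 6 phases and refuses
  near-half-cycle jumps (noisy 4-point curves cannot fix W).
* **Responder rule**: a cell responds iff the detrended height of its
  first peak within 30 h after treatment strictly exceeds the height of
  its reference (default: highest; alternative: last) peak within 30 h
  before. Fractions come with exact Clopper–Pearson CIs; undefined calls
  are excluded from the denominator and reported.
* **Rhythmic genes**: strict "> 50 counts in at least one sample" filter
  (a per-timepoint-mean reading is available; the two coincide for
  one-replicate designs), log2(CPM+1) normalization, per-gene fixed-24 h
  cosinor rhythmicity with two tiers (raw p < 0.05; BH q < 0.05). The
  rhythmicity p is the zero-amplitude F-test p, or a time-label
  permutation p when requested — one well-defined in-repo test rather
  than a re-implementation of multi-method meta-integration software.
* **Differential response** is Welch's t on log2 CPM with BH adjustment —
  a deliberately simple stand-in for a negative-binomial GLM framework.
  It needs ≥ 2 replicates per group and has usable genome-wide power only
  from ~6 replicates (moderated NB tests achieve this at 3); the
  synthetic designs used in tests provide 6.
* **Phase projection**: genes are z-scored across reference timepoints,
  query samples z-scored with the reference moments, and each query is
  assigned the reference timepoint with maximal Pearson correlation —
  the directly testable core of reference-timecourse PCA projections.

## What the generator emulates — and what it does not

The synthetic ensembles reproduce damped population oscillations,
phase/dose-dependent resetting, entrainment and resynchronization, with
calibrated endpoints matching the printed tissue results (9.5 h maximal
osmotic delay, ~8 h loading advance, type-1 resetting at +200 mOsm,
osmolarity-compensated ~24 h period, 12 h antiphase separation). They do
not model transcription–translation feedback, tissue mechanics, the
MPa→mOsm conversion, inter-cell coupling, or the slow baseline drifts
and luminescence decay of real Lumicycle traces (single-cell simulations
add an exponential observation decay of 0.004–0.008/h to emulate
fluorophore bleaching). Passing tests therefore demonstrate that the
*pipeline* measures what it claims on data with known truth — not that
the oscillator is a faithful biophysical model of chondrocytes.

Single-cell populations treat "responders" as cells receiving a radial
amplitude boost (default 2.5 A0, relaxation 0.03/h for cell runs): a
fixed-direction kick on cells at random phases would *lower* the next
peak of about half of them, so no peak-height rule could recover such
labels; the radial boost is the per-cell amplitude response that the
strict post>pre rule is designed to detect. With the default noise this
recovers generator truth for ≥ 90% of cells.

The count generator draws negative-binomial counts (variance
μ + 0.1 μ²) around log2-cosine profiles, amplitude 1 log2 unit for
rhythmic genes, uniform acrophases, library-size factors in [0.7, 1.3],
and a responsive subset stepping by ±2 log2 units from t ≥ 4 h.

## Problem sizes and numerics

Default runs use 100-cell ensembles, 0.05 h steps and 5–8 day recordings;
an end-to-end scenario completes in seconds and the full test suite in
well under a minute on one CPU. The treadmill comparison averages six
simulated explants per arm before estimating the shift, mirroring the
per-group averaging of the tissue experiment (single explant pairs carry
~1.3 h of finite-ensemble phase noise; six-explant means reduce this to
~0.5 h), and the reported endpoint is the mean over two such replicate
experiments. Degenerate inputs are refused loudly: rank-deficient cosinor
designs, non-monotone time grids, windows too short for the detrend
width, all-undefined responder sets, empty post-filter count matrices.

## Known limitations

* The kick direction is global per stimulus kind; cell-type-specific
  resetting geometries would need per-population calibrations.
* The Welch DE stand-in is underpowered at wet-lab replicate counts; it
  is adequate for the synthetic designs here, not a DESeq2 replacement.
* Winding classification assumes a reasonably dense, low-noise PRC;
  4-point experimental PRCs return "undetermined" by design.
* The damped-cosinor SE comes from the asymptotic J'J approximation and
  ignores residual autocorrelation, so it is optimistic on densely
  sampled simulator output.
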