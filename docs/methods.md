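# Methods

## The experiment being emulated

A pre-cued unimanual tapping task.  Each 4 s trial: fixation dot
(500 ms), a directional cue (150 ms) announcing a left/right tap to the
near, middle or far target — or a no-go symbol — then a go signal
1000 ms after cue onset.  Blocks of 63 trials (4 min 12 s) keep target
width fixed; widths of 1, 2 and 4 cm are paired with amplitudes
`A = W·2^ID/2` so that the same three difficulty levels ID ∈ {2, 3, 4}
bits recur at every width.  The seven cue types (2 hands × 3 distances
+ no-go) each fill exactly 1/7 of every block (9 repetitions).  This
geometry only partially confounds ID with amplitude (9 cells, 3 ID
levels, 5 distinct amplitudes), which is what lets regressions on ID
and on amplitude be distinguished.

## Synthetic-data generator

One master seed spawns per-subject `numpy.random.SeedSequence` children
(in subject order); each subject spawns four sub-streams in the fixed
order *parameters, behaviour, eeg, measures*.  Identical config + seed
therefore reproduces every output bit for bit, and e.g. behavioural
draws never perturb EEG noise.

**Behaviour.**  `MT ~ N(a + b·ID, σ_MT)` with `a = 211` ms,
`b = 68` ms/bit, `σ_MT = 40` ms, plus a per-subject intercept
(SD 15 ms).  RT is ID-independent: `N(355, 60)` ms plus a subject
intercept (SD 20 ms) and a right-hand advantage drawn per subject as
`N(15, 20)` ms (half added to left-hand, half subtracted from
right-hand RTs).  Values are clamped at two sample periods; miss and
wrong-target flags are Bernoulli draws with per-cell rates of 0.1–2.0 %
(largest for the small-width far target) and 0.1–0.2 % respectively.
Trial times are stored exactly; event markers round them to the sample
grid, so marker-derived times differ by under one sample.

**Continuous EEG/EOG** (per subject, μV): 15 scalp channels covering
every analysed site, plus bipolar VEOG/HEOG, at 500 Hz (the recording
parameters are not externally constrained; 500 Hz is a conventional
choice and configurable).  Each channel carries independent 1/f (4 μV
RMS) + white (4 μV RMS) noise; EOG channels carry a larger 6 + 6 μV
floor.  Artifacts: VEOG blinks as 200 μV Gaussian bumps (SD 60 ms) from
a 0.15 Hz Poisson process; HEOG gaze steps per action trial (sigmoid
rise centred 300 ms post-go, return at ~900 ms).  The *full* EOG
signals propagate to every scalp channel with fixed coefficients
(vertical: 0.30 frontally falling to 0.05 occipitally; horizontal:
antisymmetric ±0.03–0.10 laterally), which is exactly the generative
model regression-based ocular correction assumes.

Four deterministic components are added per action trial.  Shapes are
free; only analysis-window means are contract-bound:

| component | shape | channels | window mean |
|---|---|---|---|
| posterior N2/P3b | Gaussian bump, centre 340 ms, SD 45 ms | Pz, P1, P2, POz, PO3, PO4 (+reduced CPz/Oz/Cz) | −2.3 + 1.6·ID μV over 310–370 ms post-cue |
| CNV | ramp 400 ms → go onset, released over 300 ms | Cz, FCz, CPz, C1, C2 (+reduced neighbours) | ID-independent (−5 μV peak); absent on no-go |
| lateralized motor potential | ramp from lift−300 ms, released over 200 ms | contralateral C1/C3 or C2/C4 | ID-independent (−2 μV) |
| gaze step | sigmoid rise/fall | HEOG | −133 − 3.8·A μV over 250–450 ms post-go, sign-mirrored by target side |

Each component also gets a per-subject random intercept (SDs 0.8, 1.0,
0.5, 8 μV).  Templates are normalised numerically so their mean over
the analysis window is exactly 1 before scaling.

**Measure-level simulator.**  `simulate_measures` draws the
per-subject × condition window measures directly from the same
statistical model (law mean + subject intercept + Gaussian measurement
noise with per-measure SDs 0.5/0.8/0.4/4 μV).  It exists so that
properties of the *regression stage* — the ID/amplitude dissociations
and the CNV/LRP nulls — can be checked over 100 seeds in seconds; the
continuous-EEG path is exercised at study size in the same suites.
These per-measure SDs approximate the empirical subject-level scatter
the full pipeline produces at default noise.

**What the generator does not emulate**: electrode geometry or volume
conduction beyond fixed propagation coefficients, saccade dynamics
(main-sequence velocity profiles), alpha rhythms or other structured
oscillations, latency variability of the ERP components across
subjects, non-stationary noise, or the practice block.  Passing tests
therefore show the *pipeline arithmetic* is right under realistic
noise levels — not that the pipeline is robust to every pathology of
real recordings.

## Preprocessing

Order: ocular correction → segmentation → filtering → rejection →
baseline → averaging (configurable, since only the segmentation-first
part of that order is externally fixed).

* **Ocular correction (Gratton–Coles).**  Fitted on cue-locked raw
  epochs: each trial minus its condition average, then per EEG channel
  `b = cov(EOG_res, EEG_res)/var(EOG_res)` pooled over trials and
  samples.  Vertical EOG is fitted first; the horizontal coefficients
  are fitted on vertically-deflated residuals; application subtracts
  both from the continuous data (EOG channels untouched).  A single
  combined coefficient per EOG channel is used (no separate
  blink/saccade classes) — the simplest published variant.  The fit is
  oracle-checked against an independent least-squares solution.
* **Filtering.**  0.05 Hz high-pass and 60 Hz low-pass, 24 dB/octave as
  4th-order Butterworth, zero-phase by default (so the effective
  roll-off doubles; `zero_phase=False` gives a causal pass).  The
  low-pass uses `sosfiltfilt`.  The high-pass is applied as the
  squared-magnitude Butterworth response in the frequency domain: at a
  0.05 Hz cutoff the biquad poles sit so close to the unit circle that
  time-domain forward-backward filtering leaves numerical transients
  lasting seconds (verified directly), while the frequency-domain form
  is the ideal filtfilt limit and is exact at DC.
* **Epoch windows** (0-based samples, half-open [start, end) ms):
  cue-locked [−300, 1500) with baseline [−200, 0); go-locked
  [−200, 2000) with baseline [−200, 0) — long enough that the full gaze
  transient lies inside the segment, since high-pass filtering a
  segment that truncates the step mid-plateau attenuates the 250–450 ms
  window mean by tens of percent; lift-locked [−800, 200) with baseline
  [−800, −600) (no pre-cue interval is inside a response-locked window,
  and all response-locked quantities are difference measures that
  cancel any common offset).
* **Rejection.**  An epoch is rejected iff peak-to-peak strictly
  exceeds 100 μV on any *EEG* channel (the offending channel is
  recorded).  EOG channels are excluded by default: per-trial gaze
  steps of 140–260 μV are part of the design, and including EOG would
  discard every far-target trial; `include_eog=True` restores the
  stricter rule.
* **Averaging** is the arithmetic mean over accepted epochs per
  condition; empty conditions are an error naming the condition.

## Behavioural reduction

Trimming removes trials with RT or MT < 100 ms (strict), then — in a
single pass per subject × hand × width × ID cell, with mean/SD computed
over the floor-survivors including the candidate — trials deviating
strictly more than 2 SD in RT or MT.  No iteration and no leave-one-out
(a very small cell with one gross outlier can therefore retain it; at
study sizes the rule behaves conventionally, trimming ~5–8 %).
Miss/wrong-target trials are excluded from the MT regressions but
counted in the error table.  Condition means average first within
subject, then over subjects, hands pooled (the MT hand difference is
itself tested with a paired t-test and is null by construction).

## Statistics

Closed-form simple OLS; `F = (r²/(1−r²))·(n−2)` with df (1, n−2) and a
perfect fit reported as r² = 1, F = ∞, p clamped to the smallest
positive float.  Regressions are fitted on the 9 pooled condition
means; a subject-level fit over 17 subjects would quote df (1, 16) —
both conventions are noted in the report.  Slope CIs use the
residual-based standard error; the CNV/LRP "null" criterion is the 95 %
slope CI covering zero.  The paired t-test flags zero within-pair
variance as degenerate (t = 0, p = 1 for identical arrays; t = ±∞
otherwise).

## File formats

EDF (16-bit) for continuous data with symmetric integer physical bounds
against digital ±32767, making the value mapping exactly proportional;
the writer fixes the header date so identical data give byte-identical
files, and reading goes through MNE's independent EDF parser.  Events
and behaviour are TSV (UTF-8, unix newlines, "." decimal); epochs are
stored as flat `.npz` with a JSON metadata entry; configs and reports
are JSON with a SHA-256 config digest for provenance.

## Problem sizes and known limitations

The behavioural analyses run the full 17-subject × 12-block study; the
continuous-EEG analyses run 17 subjects × 2 blocks with per-subject
block widths rotated so the group covers all 9 cells (with 12 blocks
the rotation reduces to 4 blocks per width).  The 100-seed dissociation
and null checks run the behavioural pipeline in full and the ERP checks
at measure level (see above).  The N2/P3b window is 310–370 ms
(an alternative 310–350 ms reading exists; the window is a config
knob).  The zero-phase high-pass slightly overshoots sustained steps
(~2–4 % on the gaze measure) — visible as LHEOG slopes marginally
steeper than the generating −3.8 μV/cm.  Scalp topography rendering,
source localization, ICA, and effective-width (We) analyses are out of
scope.
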