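# Methods

This note documents the models, parameters and numerical choices behind
`reflexgait`, what the synthetic generator does and does not emulate, and
the limitations a user should know before applying the pipeline to real
recordings.

## Measures and their definitions

All kinematic quantities are computed from paw contact/liftoff event
times and horizontal positions in the treadmill frame (SI units).

- Cycle duration: successive contacts of the same limb; stance: contact
  to liftoff; swing: cycle − stance (the decomposition is exact by
  construction and asserted exactly in the tests).
- Stride length: `|x_contact − x_liftoff| + belt_speed × swing`. At
  steady state on a treadmill this equals `belt_speed × cycle duration`.
- Step length: horizontal distance between the leading and trailing limb
  at stance onset of the leading limb, taken as an absolute value. The
  trailing paw's position between events is interpolated: backward at
  belt speed during stance, linearly from liftoff position to next
  contact position during swing (the event-level analogue of measuring
  from video).
- Phase interval: contact-time offset of the coupled limb divided by the
  reference limb's cycle duration, × 360, kept in [0, 360) rather than
  folded onto [0, 180] so distributions remain circular. Reference limb:
  left forelimb, except the homologous hindlimb coupling (left hindlimb).
- Gap interval: step length / reference stride length × 360; homologous
  couplings only.
- Symmetry index: `|θ − 180| / 180 × 100` (%), the relative deviation
  from perfect left-right symmetry; mirror-symmetric about 180°.

## Circular statistics

Mean direction and resultant length r come from the mean unit vector; a
vanishing resultant (r < 1e−12) flags the mean direction as undefined.
Rayleigh's test uses `z = n r²` with the standard finite-sample
approximation

    p = exp( sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n) ),   R = n r,

as used in the common circular-statistics toolboxes. The Watson–Williams
test uses

    F = (1 + 3/(8 κ̂)) · (N − k)(ΣR_i − R) / ((k − 1)(N − ΣR_i)),

with κ̂ from the standard piecewise inverse of A1(κ) at the weighted mean
resultant length; p from F(k−1, N−k). Warnings are raised when the
common-concentration assumption is doubtful (weighted r̄ < 0.45, group
n < 5); identical angles in every group make the denominator vanish and
raise an error. Two analysis levels are provided: raw cycles per subject,
and group level (circular mean per subject first, then statistics across
subjects).

## Reflex quantification

Cycles are delimited by successive reference onsets. The default
reference is the contact event of the reference limb (the limb carrying
the configured reference muscle, the stimulated hindlimb's sartorius by
convention); an EMG-burst-onset reference is a documented alternative,
but contact events are exact, shared between generator and analyzer, and
avoid a detector-dependent constant phase shift. Cycles are tagged
stimulated (S) when a stimulus falls in `[onset, next onset)`, control
(C) when they carry no stimulus and do not follow an S cycle, excluded
otherwise — post-stimulation cycles never enter the baseline.

The blEMG is the mean full-wave-rectified control cycle in normalized
time (200 points), summarized in 10 equal bins. The bin means are the
bins of the averaged trace; for equal-length normalized cycles this is
identical to averaging per-cycle bin means.

Detection is automated (visual inspection guided by confidence intervals
is not reproducible): for each (muscle, phase bin) with at least 4
stimuli, the rectified post-stimulus segments (80 ms) of stimulated
cycles are averaged and compared with *phase-matched* control segments —
every control cycle probed at the same within-cycle phases as the actual
stimuli. The confidence band is the two-sided 97.5% t-interval for a mean
of n_stim segments, using the *within-phase* cycle-to-cycle variance
(the deterministic envelope differences between probed phases are shared
by the stimulated average and must not widen the band). Both trace sets
are smoothed with a 2 ms moving average for detection only; integration
uses the raw averages, because smoothing biases integrals near sharp
envelope transitions. A response opens when the stimulated average stays
outside the band for ≥ 3 ms inside the 7–60 ms search window; onset =
first sample outside, offset = return into the band, sign = side of exit.
A relative band floor (1e−4 of the control-trace maximum) guards the
degenerate zero-variance (noise-free) case. With these settings the
per-cell false-positive rate on null injections is ≈ 2% (bounded at 5% in
the acceptance suite).

Latency classes: P/N1 7–18 ms, P/N2 19–34 ms, P/N3 35–60 ms; responses in
non-stimulated limbs with onsets ≤ 18 ms are short-latency (the minimal
spino-bulbo-spinal loop latency in the cat is 18 ms). Onsets in the
1 ms gaps between printed windows are assigned to the nearer window and
flagged. Onsets < 7 ms are rejected as stimulus artifact.

Net reflex value: `(∫stim − ∫blEMG)/∫blEMG` over the response window
(trapezoidal), with the blEMG taken over the same window, so excitation
is positive and the value is invariant to rescaling both traces (the
rationale for the division: responses are measured relative to motor-pool
excitability). Integrated baselines below a floor give NaN with a
warning. Ten-bin profiles integrate every bin over one *identical*
window per (muscle, latency family) — the median detected onset/offset —
so phases without a detectable deflection contribute their near-zero net
value rather than a missing one.

Normalization divides each muscle's net values by the maximum *signed*
value across all four conditions and bins (× 100). This is what lets the
modulation index — largest minus smallest normalized response over the
10 phases of a condition — exceed 100% when inhibitory and excitatory
responses coexist; normalizing by the maximum magnitude instead is
available behind `normalization="abs_max"`.

Activity windows: the activity period of a muscle is the longest
circularly contiguous run of blEMG bins above baseline + 25% of the
bin-mean range; mid-activity and mid-inactivity windows are the period
midpoints ± 7.5% of the cycle.

## Group statistics

The one-factor repeated-measures ANOVA uses the classical within-subject
partition (F = MS_levels / MS_subject×levels), listwise dropping of
incomplete subjects, and no sphericity correction by default (a
Greenhouse–Geisser correction, ε from the double-centered covariance, is
available behind `correction="gg"`). Pairwise comparisons are paired
two-sided t tests with raw p values — deliberately uncorrected, on the
argument that multiplicity corrections inflate type II error; the caller
gates them on a significant main effect. Normality is assumed (a
Shapiro–Wilk diagnostic on the residuals is logged, never enforced).
Left- and right-nerve datasets are pooled as separate rows (up to two per
subject), keeping only rows whose response was actually evoked. Treating
two same-animal datasets as independent rows is statistically
questionable but is the analysis convention being reimplemented; it is
kept as-is and noted here as a caveat.

## The synthetic generator

The generator emulates a cat on a split-belt treadmill under the four
conditions: tied 0.4/0.4 (`tied_slow`), tied 0.8/0.8 (`tied_fast`) and
split 0.4 vs 0.8 m/s with the reference (left) side slow (`split_slow`)
or fast (`split_fast`).

- Cycle duration: `1.30 − 0.75 × mean belt speed` s (1.0 s at 0.4 m/s,
  0.7 s at 0.8 m/s), reproducing tied_slow > split > tied_fast; per-cycle
  CV 3%.
- Duty factor: `0.72 − 0.22 × limb belt speed` (0.63 slow, 0.54 fast), so
  the slow side has longer stance and the fast side longer swing during
  split-belt walking.
- Coupling: the left forelimb is the master oscillator; other limbs are
  placed by von Mises draws around the condition's phase targets
  (homologous ≈ 180°, homolateral 90°, diagonal consistent with their
  sum). Concentrations make tied_fast tightest and the split conditions
  most dispersed, with spatial (gap) dispersion always larger than
  temporal — the qualitative dispersion ordering reported for cats.
  Gap targets: 180° tied; 270°/90° (mirror images) for split. Per-cycle
  gap draws are realized *exactly* by placing the reference limb's
  contact positions (reference placement constrains nothing else, since
  strides depend only on belt travel).
- EMG: each muscle is a raised-cosine burst over its activity window
  (fraction of its limb's cycle) on a resting tone of 0.05 a.u., times
  (1 + 15% multiplicative noise), plus 0.02 a.u. additive noise, clipped
  at zero — the signal stands for full-wave rectified EMG. The envelope
  is extrapolated one cycle beyond the event span so the recording is in
  steady state at its edges.
- Stimulation: trains (echoing three 0.2 ms pulses at 300 Hz, 1.2× motor
  threshold) every 2–4 cycles (uniform over {2, 3, 4}) at a within-cycle
  delay uniform over the cycle, so all 10 phase bins are populated
  (~n_cycles/3 stimuli). The delay distribution is an assumption; the
  experimental delays were varied but their distribution is not
  recoverable. Stimulus times are snapped to the EMG sample grid, as when
  a stimulator is triggered by the acquisition clock.
- Evoked responses: raised-cosine bumps added at a configurable onset
  latency and duration, with amplitude `profile[phase bin] × local clean
  envelope mean over the bump support`. This multiplicative reflex-gain
  model makes the net reflex value (which divides by the blEMG) recover
  the injected profile itself: on a noise-free session the recovered
  profile equals the injection up to a positive scale (asserted to
  1e−9), and at the default noise (strongest-response SNR ≈ 5–6, ≥ 12
  stimuli per bin) the recovery correlation exceeds 0.9. The default
  injections place one response at the center of each latency window
  (12/26/47 ms); the stimulated-limb soleus receives inhibition during
  its stance activity and excitation during its inactive phases, the
  configuration that drives modulation indexes above 100%.

What the generator does **not** emulate: motor-unit interference
structure (real EMG is a signed, colored interference signal, not an
envelope with Gaussian noise), stimulus artifacts, movement artifacts or
electrode drift, irregular stepping episodes, burst-shape variability
beyond amplitude noise, and any supraspinal adaptation across the
session. Passing the recovery tests therefore demonstrates correctness
of the *analysis chain*, not robustness to every artifact of real
recordings — in particular, real response detection near the 7 ms bound
may face stimulus artifacts that the generator never produces.

## Problem sizes and numerical choices

Tests and the acceptance script run sessions of 120–600 cycles at
1–2 kHz (the analysis requires ≥ 1 kHz; the generator's default is 5 kHz,
a typical digitization rate) — sizes chosen so every phase bin holds
enough stimuli for stable averages. Detection uses at most ~300 control
segments per cell, subsampling control *cycles* (never probed phases, to
keep phase weights equal). Noise-free recovery holds to float precision
because generator and analyzer share the same window-to-sample mapping
and integration rule. Determinism: one seeded NumPy generator drives all
randomness; identical config + seed gives bit-identical sessions, and
report tables embed a configuration hash so re-runs are byte-identical.

## Known limitations

- The automated detector is a stated surrogate for the original visual
  scoring; its onset estimates are biased late by up to ~2–3 ms for
  responses barely clearing the band.
- The gap/phase measures assume at most one coupled-limb contact per
  reference cycle; grossly arrhythmic gait would need pre-cleaning.
- The Watson–Williams test assumes comparable concentrations; for very
  dispersed split-belt gap data the permutation alternative used as the
  test oracle is the safer inference.
- Step lengths are unsigned; a limb crossing past its homolog reads the
  same as trailing it.
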