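# reflexgait

Analysis of phase- and task-dependent cutaneous reflexes and interlimb
coordination during tied- and split-belt quadrupedal locomotion.

When a cutaneous nerve of the paw (superficial peroneal or superficial
radial) is stimulated during walking, the evoked EMG responses in muscles
of all four limbs depend on *when* in the locomotor cycle the stimulus
arrives (phase-dependent modulation) and on the locomotor task (e.g.
left-right asymmetric split-belt walking). `reflexgait` implements the
complete quantitative chain used to study this in cats on a split-belt
treadmill, for researchers in motor-control neurophysiology who need a
tested, reusable implementation:

- **Gait kinematics** from paw contact/liftoff events: cycle, stance and
  swing durations; stride length `|x_contact − x_liftoff| + belt speed ×
  swing`; step length between leading and trailing limb at stance onset.
- **Interlimb coordination** as circular data: phase intervals
  `Δt/T_ref × 360°` (180° = strict alternation), gap intervals
  `step/stride × 360°` for homologous pairs, symmetry indexes
  `|θ − 180°|/180° × 100`, mean direction and resultant length *r*,
  Rayleigh's test (`z = n r²`), and the Watson–Williams test between
  conditions.
- **Reflex quantification**: cycles tagged stimulated/control/excluded,
  the baseline locomotor EMG (blEMG — mean rectified control-cycle EMG in
  10 phase bins), stimulus-triggered averages per phase bin, automated
  response detection against a pointwise 97.5% confidence band of
  phase-matched controls, latency classification (P1/N1 7–18 ms,
  P2/N2 19–34 ms, P3/N3 35–60 ms), the net reflex value
  `(∫stim − ∫blEMG)/∫blEMG`, per-muscle normalization to the maximum
  across the four conditions, and the modulation index (largest minus
  smallest response over the 10 phases; > 100 % when excitation and
  inhibition coexist).
- **Group statistics**: one-factor repeated-measures ANOVA, uncorrected
  pairwise comparisons, pooling of left/right nerve datasets.
- **A synthetic session generator** producing four-limb gait events, EMG
  envelopes, stimulus trains (every 2–4 cycles) and injected reflex
  responses with known ground truth, so the whole pipeline is testable
  end to end without any recordings.

## Worked example

```python
import reflexgait as rg

bundle = rg.generate_session(rg.condition_config("tied_slow", seed=1, n_cycles=120))
report = rg.run_pipeline(bundle)

s = rg.circ_mean_r(report["coupling_angles"][("forelimb", "phase")])
z, p = rg.rayleigh_test(s)
print(f"forelimb phase: mean {s.mean_direction:.1f} deg, r = {s.r:.3f}, "
      f"Rayleigh z = {z:.1f}, p = {p:.2e}, n = {s.n}")
cols = ["muscle", "limb", "relation", "bin", "latency_class", "onset_ms", "net_value"]
print(report["reflex"].responses[cols].head(4).to_string(index=False))
```

prints

```
forelimb phase: mean 180.8 deg, r = 0.982, Rayleigh z = 115.6, p = 2.78e-83, n = 120
muscle limb   relation  bin latency_class  onset_ms  net_value
   SOL   LH homonymous    1            N1      13.4  -0.183048
   SOL   LH homonymous    6            P1      14.6   0.345114
    TA   LH homonymous    6            P1      13.4   0.367343
    TA   LH homonymous    9            P1      15.4   0.231418
```

The homologous forelimbs alternate strictly (mean phase ≈ 180°) with very
consistent step-by-step phasing (r close to 1; Rayleigh rejects
uniformity). The stimulated-hindlimb soleus shows a short-latency
inhibition (N1, onset ≈ 13 ms, net value −0.18 = 18 % below its baseline
EMG) when stimulated during stance (bin 1) and a short-latency excitation
(P1, +35 %) during swing (bin 6) — phase-dependent reflex reversal.

The same chain is available from the shell:

```sh
reflexgait generate --seed 1 --out study
reflexgait analyze --study study --out report --plots
reflexgait report --report report
```

`report/` then holds per-condition kinematics/coordination tables,
response tables, normalized responses, modulation indexes, a coordination
summary JSON (Rayleigh and pairwise Watson–Williams results) and a
manifest with the configuration hash for byte-identical re-runs.

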