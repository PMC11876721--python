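# topoperm

Topographic permutation statistics for event-related potentials (ERPs):
point-by-point TANOVA on the global dissimilarity index, duration-based
multiple-comparison control (global duration statistics, GDS), GFP
normalisation, and permutation effect sizes — together with a fully
seedable simulator of the cued repetition-probability (S1–S2) study
design, so every statistical stage can be validated against known ground
truth without any EEG recording.

## Who this is for

ERP researchers analysing multi-channel scalp data who want
reference-free, electrode-selection-free statistics: instead of picking
channels and testing amplitudes, TANOVA compares entire scalp maps
between conditions at every timepoint and calibrates both the test and
its multiple-comparison correction from within-subject permutations.

## The statistics

For a scalp map **v** over *N* electrodes, **global field power** is the
spatial standard deviation

GFP(v) = sqrt( (1/N) Σᵢ (vᵢ − v̄)² ),

and the **global dissimilarity index** between two maps is

GDI(a, b) = sqrt( (1/N) Σᵢ (aᵢ − bᵢ)² ),

which equals GFP(a − b) for average-referenced maps. **TANOVA** tests,
at each timepoint, the GDI between the grand-mean maps of an
experimental factor's levels (for a 2×2 interaction, the RMS of the
grand-mean double-difference map) against a null distribution built by
reassigning each participant's condition maps to conditions within that
participant; p = (1 + #{perm ≥ observed}) / (1 + n_perm). **GDS**
converts each permutation's statistic series into its own p-value
series, takes the longest sub-α run per permutation, and declares an
observed run of consecutive significant timepoints reliable only if it
is strictly longer than the 95th percentile of those null run lengths —
controlling the family-wise error rate over the whole epoch. Effect
sizes per surviving window are partial η² (share of the windowed
contrast field's sum of squares explained by the group-mean contrast),
the deterministic conversion d = 2·sqrt(η² / (1 − η²)), and a
permutation z-score normalised by sqrt(p₁·p₂·N).

The simulated design is the cued repetition-probability paradigm: pairs
of stimuli (S1, S2) from one of three categories, where the S1
subcategory cues the probability (75% vs. 25%) that S2 repeats S1,
crossing repetition × expectation with exact cell counts
(180/180/60/60 per 480-trial category block; 1440 trials in total),
20% target trials, and 64-channel average-referenced epochs from
−150 to 850 ms.

## Worked example

```python
import topoperm as tp

montage = tp.ring_montage(32)
topo = tp.make_topography(montage, ["ch05", "ch21"], 0.3)
effect = tp.EffectSpec("n250r", "repetition_main", topo,
                       window_ms=(200, 300), amplitude=3.0)
noise = tp.NoiseSpec(trial_noise_sd=1.0, subject_amplitude_sd=0.3)
data, times = tp.simulate_condition_erps(20, [effect], noise, montage, seed=11)
stack = tp.ErpStack(data, tuple(f"S{i:02d}" for i in range(20)),
                    tp.CELL_LABELS, times, montage.channel_labels)

result = tp.run_factorial_analysis(stack, "words",
                                   tp.AnalysisConfig(n_perm=1000, seed=11))
for name in ("repetition_main", "expectation_main", "interaction"):
    print(name, result.surviving_windows(name))
for es in result.effect_sizes:
    print(f"{es.effect} {es.window_ms}: eta2 = {es.partial_eta2:.2f}, "
          f"d = {es.cohen_d:.2f}")
```

prints

```
repetition_main [(210.0, 290.0)]
expectation_main []
interaction []
repetition_main (210.0, 290.0): eta2 = 0.90, d = 6.04
```

A repetition effect injected at 200–300 ms is recovered as a single
GDS-surviving window (210–290 ms — the raised-cosine envelope leaves the
outermost samples too weak to detect), the two null effects stay empty,
and the effect size over the surviving window is reported with both the
η²→d conversion and the permutation z route.

The same stages are available from the shell:

```bash
topoperm simulate --config config.yaml --seed 7 --out data/
topoperm analyze --data data/ --out results/ --n-perm 1000 --seed 7
topoperm report --results results/ --out figures/
```

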