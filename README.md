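# painhfa

Analysis of tonic thermal pain encoding in human intracranial (sEEG)
recordings: broadband high-frequency activity (HFA, 70–150 Hz)
extraction, sliding-window generalized linear mixed-effects models of
binary and graded pain reports, and permutation-based significance
testing — plus a synthetic-study generator so the entire pipeline runs
and validates with known ground truth, no patient data required.

## The problem

During a tonic pain task, a participant holds a hand on a
thermoelectric surface for 10 s at a temperature adapted to their pain
threshold, then reports whether the stimulus was painful (yes/no) and
rates it 0–10. The scientific question is *where and when* the
amplitude of broadband high-gamma activity — a proxy for local
population firing — carries information about those reports. The
statistical obstacles are that electrode coverage differs across
patients, stimulus temperature confounds everything, and effects are
expected only in particular time windows around stimulus onset and
offset.

## The model

For each brain region (atlas labels collapsed to gyri, e.g.
`Amyg_L_2_1 → Amyg`; regions kept only with ≥3 patients sampling gray
matter), each trial event (hand-on, hand-off) and each 500 ms window
stepping by 250 ms, the mean z-scored HFA amplitude A enters

```
y ~ 1 + A + (1 + A | temperature) + (1 + A | patient)
```

with a binomial (logit) family for the binary report and a gaussian
family for the 0–10 rating. Random intercepts and slopes absorb
between-temperature and between-patient variation, so the fixed effect
β measures what HFA says about the report *beyond* the stimulus itself.
Significance comes from a permutation test: responses are shuffled
within patient and the model refit (1000 permutations by default); the
real t-statistic is significant when outside the central 95% of the
pseudo-t null, with two-sided p = 2·max(c, 1)/n_perm (floor 0.002 at
1000 permutations).

HFA is computed per epoch as a zero-phase 4th-order Butterworth
bandpass (70–150 Hz), Hilbert-envelope magnitude, 300 ms moving
average, and z-scoring against the −3..−2 s pre-event baseline, after
common-median referencing, fixed-threshold artifact rejection
(60 Hz power, slope, variance, saturation, robust peak outliers) and
downsampling to 500 Hz.

## Worked example

Simulate a small study in which the inferior temporal gyrus (ITG)
carries a 1.5 z-unit HFA effect around stimulus onset while two other
regions are null, then run the sliding-window harness:

```python
import painhfa as ph

study = ph.simulate_study(
    n_patients=6,
    region_counts={"ITG": 6, "MTG": 6, "Hipp": 6},
    trials_per_patient=20,
    channels_per_region={"ITG": 3},
    effects={("ITG", "hand_on", (0, 1000)): 1.5},
    seed=42,
)
results = ph.analyze_study(study, events=("hand_on",),
                           families=("binomial",), n_perm=200, seed=0)
print(results[["region", "window_start", "window_end",
               "beta", "t_real", "p_value", "significant"]]
      .round(3).to_string(index=False))
```

prints

```
region  window_start  window_end  beta  t_real  p_value  significant
  Hipp        -250.0       250.0 0.094   0.708     0.46        False
  Hipp           0.0       500.0 0.104   0.727     0.48        False
  Hipp         250.0       750.0 0.101   0.761     0.40        False
  Hipp         500.0      1000.0 0.076   0.607     0.55        False
   ITG        -250.0       250.0 0.675   2.016     0.01         True
   ITG           0.0       500.0 1.324   2.888     0.01         True
   ITG         250.0       750.0 0.962   3.524     0.01         True
   ITG         500.0      1000.0 0.681   2.552     0.01         True
   MTG        -250.0       250.0 0.090   0.516     0.65        False
   MTG           0.0       500.0 0.151   0.536     0.43        False
   MTG         250.0       750.0 0.071   0.422     0.77        False
   MTG         500.0      1000.0 0.127   0.794     0.58        False
```

Every ITG window is flagged (p = 0.01 is the floor at 200 effective
permutations) while the null regions sit near t ≈ 0. Reading the ITG
coefficient the way the binomial model's slope is interpreted,
`ph.coefficient_to_percent(0.675)` → a one z-unit HFA increase
corresponds to a 67.5% increase in the proportion of "yes" responses
(a linear approximation to the logit slope).

The same workflow is available from the shell:

```
painhfa simulate --config cfg.yaml --seed 42 --out data/
painhfa summarize-regions --data data/ --out regions.tsv
painhfa analyze --data data/ --out results.tsv --n-perm 1000 --seed 0
painhfa report --results results.tsv --out figs/
```

`report` renders the region × window t-statistic heatmaps with
significant cells outlined, and exports every matrix as TSV.

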