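# latemp

**Lateralized temperature analysis for emotion research.**

`latemp` implements a complete analysis pipeline for experiments that ask
whether emotional state lateralizes body temperature — specifically, whether
the right-minus-left difference in tympanic membrane temperature (TMT)
carries information about emotional valence that peripheral skin temperature
(the wrist) does not. It is aimed at affective-computing and
psychophysiology researchers who record bilateral temperature at ~20 Hz
during block-designed emotion-induction sessions (four target emotions —
fear, sadness, joy, love — each with repeated 120-s labeled segments from a
small within-subject sample).

Because raw recordings from such studies are rarely public, the package
ships a synthetic-data generator that reproduces the *statistical* structure
of the design — participant-level baselines, slow drift, AR(1) noise, 20-Hz
sensor noise, sparse movement-spike artifacts, and a valence-dependent shift
planted on the latent right–left tympanic difference — so every stage of the
pipeline is testable end to end.

## What it computes

1. **Preprocessing.** Each channel is averaged into 1-s bins, then cleaned
   with a difference-thresholding rule: first differences farther than
   5 standard deviations from their mean are zeroed and the signal is
   reintegrated from its first sample. Right-minus-left series are cut into
   labeled trial samples.

2. **Cluster-based permutation testing.** With baseline-corrected
   per-participant condition means `x[i, j, k]` (participant, condition,
   time), a pointwise statistic is computed at every second:
   a paired *t* for the valence contrast (df = n − 1) or a one-way
   repeated-measures *F* across the four emotions (df = (c − 1, (n − 1)(c − 1))).
   Runs of consecutive supra-threshold seconds form clusters whose mass is
   the summed statistic; the null distribution takes the largest absolute
   cluster mass from each of 1000 random within-participant relabelings
   (a space of (c!)^n patterns), controlling family-wise error over time.
   Cluster *p* is the proportion of null masses ≥ the observed mass
   (reported both as printed and with the (b+1)/(m+1) correction).

3. **Features and classification.** Each 120-s sample is sliced into 20-s
   windows at a 10-s stride (11 windows); each window contributes mean,
   min, max, and Shannon entropy (10-bin histogram, bits), giving a
   44-dimensional vector that is min–max scaled within participant.
   Valence (chance 50%) and four-emotion (chance 25%) decoding are
   evaluated with leave-one-participant-out cross-validation using Gaussian
   naive Bayes, an RBF-kernel SVM (C = 0.5), and a (300, 300, 300) MLP, and
   per-participant accuracies are compared to chance with a one-sample
   *t*-test.

## Worked example

```python
import latemp

design = latemp.StudyDesign()                      # 10 participants, 2 experiments
effects = latemp.EffectSpec()                      # -0.3 degC on right-left TMT, 70-85 s
recordings, trials, ratings = latemp.generate_experiment(design, effects, seed=1)
samples = latemp.preprocess_dataset(recordings, trials)

tymp = [s for s in samples if s.site == "tympanic" and s.experiment == "exp1"]
result = latemp.cluster_test(tymp, grouping="valence", n_permutations=1000, seed=1)
print(f"threshold t({result.stats.df[0]}) = {result.stats.threshold:.2f}")
for c in result.significant_clusters:
    print(f"cluster {c.start_s}-{c.end_s} s  mass {c.mass:.1f}  p = {c.p_value:.3f}")

vectors = latemp.normalize_within_participant(
    [latemp.build_feature_vector(s) for s in tymp]
)
for r in latemp.run_task(vectors, task="valence", seed=1):
    print(f"{r.classifier:8s} {100*r.mean:5.1f} +- {100*r.sd:4.1f} %   "
          f"t({len(r.per_participant_accuracy)-1}) = {r.t_statistic:.2f}, p = {r.p_value:.4f}")
```

Output:

```
threshold t(9) = 2.26
cluster 72-83 s  mass 106.4  p = 0.004
gnb      100.0 +-  0.0 %   t(9) = inf, p = 0.0000
svm_rbf  100.0 +-  0.0 %   t(9) = inf, p = 0.0000
mlp      100.0 +-  0.0 %   t(9) = inf, p = 0.0000
```

The planted −0.3 °C valence effect (negative emotions lower right–left TMT
inside 70–85 s) is recovered as a significant cluster at 72–83 s — the
cosine-tapered onset keeps the earliest, weakest seconds below threshold —
and valence is decoded perfectly from tympanic features under these
low-noise defaults. Wrist channels, which carry no effect by default, show
neither (see the tests). Note the degenerate `sd = 0` case: with every fold
at 100%, the one-sample *t* against chance is infinite and *p* is reported
as 0.

The same stages are available from the shell:

```bash
latemp simulate --out data/ --seed 1
latemp preprocess --in data/ --out work/
latemp cluster-test --samples work/samples.csv --grouping valence \
    --site tympanic --experiment exp1 --n-perm 1000 --seed 1 --out result.json
latemp features --samples work/samples.csv --out features.csv
latemp classify --features features.csv --task valence --site tympanic \
    --seed 1 --out cv.json
latemp run --seed 1 --out report_dir      # the whole pipeline + report.md
```

## Data formats

`latemp simulate` / `write_dataset` produce plain CSV:

- `recordings.csv` — long format: `participant, experiment, site
  (tympanic|wrist), side (left|right), time_s, value_c` at 20 Hz.
- `trials.csv` — `participant, experiment, block, sub_block, emotion,
  valence, start_s, end_s` (one row per labeled 120-s segment).
- `ratings.csv` — `participant, experiment, emotion, sub_block` plus the
  eight 1–9 rating items (anger, disgust, fear, sadness, amusement,
  inspiration, joy, tenderness).
- `config.json` — the `StudyDesign`/`EffectSpec` used.

Derived files: `samples.csv` (one row per sample-second of right−left
difference), `features.csv` (`f001..f044` per sample), and JSON results
whose schema mirrors the result dataclasses.

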