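# damscore

Pose-to-ethogram scoring of rodent maternal behavior from home-cage video.

Maternal care in laboratory rats — nest attendance, nursing postures,
licking/grooming of pups — is a central phenotype in developmental and
behavioral neuroscience, and scoring it by hand is the bottleneck.
`damscore` takes the output of markerless pose estimation (per-frame
keypoint coordinates with detection likelihoods for a dam tracked with 32
body points and her pups tracked identity-free with 9 points each) and
produces frame-level annotations of seven maternal behaviors plus
per-video behavior summaries. It covers everything downstream of the
pose-estimation networks:

1. **pose_io** — reads the three-row-header pose CSV dialect for the dam,
   raw multi-animal pup detections (native pickled "full" detections or a
   portable JSON dialect), and BORIS-style interval annotations; assigns
   identity-free pup detections to fixed slots by descending confidence
   and joins everything into one flat per-frame table.
2. **features** — computes a 218-column kinematic feature matrix
   (172 dam, 19 pup, 27 joint features across eight categories:
   location, convex-hull areas, keypoint angles, keypoint probabilities,
   movement, pup area, pup probabilities, dam–pup distances). Occlusion
   is handled by likelihood weighting or thresholding (p ≥ 0.5), never by
   outlier interpolation. Rolling mean/sum/std windows span 0.1/1/2 s;
   dam–pup distances also use 30- and 60-minute rolling pup centroids
   that bridge long litter occlusions.
3. **classify** — one binary random forest per behavior
   (100–1500 trees, Gini, √d candidate features, stratified 20 % test
   split, no class rebalancing), with the discrimination threshold chosen
   from the precision–recall curve (smallest threshold maximising F1,
   manual override supported). Follows a Model/Results design:
   `BehaviorClassifier(...).fit()` returns a `BehaviorClassifierResults`
   with the fitted forest, threshold, test scores and `summary()`.
4. **behavior_metrics** — run-length bout segmentation (a single positive
   frame is a bout), optional minimum-bout smoothing and gap merging, and
   per-video totals: total duration, percent time, bout count, mean bout
   duration, exported long-format for cohort statistics.
5. **explain** — permutation-importance ranks (1 = most important)
   averaged per feature category, and exact additive tree attributions
   (base rate + per-feature contributions = predicted probability) sampled
   on 150 behavior-present / 150 behavior-absent frames and summed by
   category.
6. **synthetic** — a seeded in-silico session generator (scripted
   behavior bouts driving posture templates, episodic pup occlusion,
   coordinate noise) that emits every input format the pipeline reads, so
   the whole chain is testable without any recording.

For classification, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R); a frame is scored positive when the forest's probability
is ≥ the behavior's discrimination threshold. Behaviors are not mutually
exclusive (nursing co-occurs with nest attendance by definition).

## Worked example

Train a nest-attendance classifier on ten simulated hour-style sessions
and score a held-out session:

```python
from damscore.synthetic import default_scenario, simulate_session
from damscore.pipeline import session_features, build_training_table
from damscore.classify import BehaviorClassifier, RFHyperparams, evaluate
from damscore.behavior_metrics import labels_to_bouts, summarize_video

train = [simulate_session(default_scenario(i)) for i in range(10)]
X, Y, _ = build_training_table(train)
res = BehaviorClassifier(X, Y["nest_attendance"], "nest_attendance",
                         RFHyperparams(n_trees=100, seed=0)).fit()
print(res.summary())

held = simulate_session(default_scenario(99))
fm, truth = session_features(held)
probs, labels = res.predict(fm)
s = evaluate(labels, truth["nest_attendance"])
print(f"held-out: precision {s.precision:.3f} recall {s.recall:.3f} F1 {s.f1:.3f}")
bouts = labels_to_bouts(labels, fps=held.meta.fps, behavior="nest_attendance")
print(summarize_video(bouts, held.meta, behaviors=("nest_attendance",)).table.round(2))
```

prints

```
Behavior classifier: nest_attendance
============================================
frames                       18000
positive fraction            0.376
trees                          100
min leaf                         1
seed                             0
manifest version                 1
threshold                    0.625  (max_f1)
test precision               0.993
test recall                  0.997
test F1                      0.995

held-out: precision 0.982 recall 1.000 F1 0.991
                 total_duration_s  percent_time  bout_count  mean_bout_s
behavior
nest_attendance              24.0          40.0           3          8.0
```

The summary block reports the training size, the positive base rate of
the behavior, the selected discrimination threshold and the scores on the
held-out 20 % test split; the bout table says the dam spent 24 s (40 % of
the 60 s session) on the nest across 3 bouts averaging 8 s.

The same steps are available from the shell:

```
damscore simulate --seed 3 --out fixtures/
damscore join --dam fixtures/dam_pose.csv --detections fixtures/pup_detections_full.pickle \
              --fps 30 --max-pups 12 --out joined.csv
damscore extract joined.csv --fps 30 --px-per-mm 2.0 --out features.csv
```

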