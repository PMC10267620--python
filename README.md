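# timedecode

Time-resolved multivariate decoding of epoched EEG with cluster-based
permutation inference — plus a synthetic-data generator that makes the
whole pipeline verifiable end to end.

## The problem

In delayed match-to-sample experiments, the strength of a stimulus
feature's neural representation can be tracked by training classifiers on
EEG scalp topographies at every timepoint. Comparing *how long* a feature
stays decodable across conditions — e.g. whether the stimulus remained on
screen (perception) or vanished (working memory), and whether the feature
was task-relevant — requires (a) a decoding score whose chance level is
exactly 0, (b) inference that respects the strong temporal autocorrelation
of decoding time series, and (c) a control ruling out systematic eye
movements as the information source. `timedecode` packages all three for
researchers running such analyses on epoched, artifact-cleaned EEG + gaze
recordings.

## The method

Per participant and condition, correct trials are binned into K = 4
equal-count stimulus classes, equalised, and averaged within class into 3
cross-validation fold exemplars ("pseudo-trials"). At each training time
*t*, one-versus-all linear SVMs (one per class) are fitted on the
(n_folds−1)·K training exemplars and applied to the held-out fold at every
testing time *t′*, giving signed distances to bound *d(k, c, t, t′)*.
Scores are z-scored per classifier, multiplied by the true-class label
(±1), and averaged over classifiers:

> s(t, t′) = (1/K) Σ_c sign(k, c) · z(d(k, c, t, t′)),  sign(k, c) = +1 iff k = c

so chance = 0 and s > 0 means correct-class evidence. The matrix s(t, t′)
is the temporal generalization matrix; its diagonal is the decoding time
series. The fold partition is redrawn `n_shuffles` times.

Group inference is nonparametric: per-timepoint one-sample t values are
thresholded (two-sided α = 0.05), maximal suprathreshold runs form
clusters with mass Σt, and the largest mass is compared against a
permutation null — sign-flipping whole evaluation score series
(within-condition, preserving autocorrelation) or swapping conditions for
half the participants (between-condition, statistic |M_A − M_B|). Gaze
decoding reuses the identical machinery on 2-D eye position as a confound
control.

The hot loop — millions of 8-sample × 20-feature SVM fits — runs through a
batched dual coordinate-descent solver validated against scikit-learn in
the test suite.

## A worked example

`examples/03_group_cluster_inference.py` simulates 12 participants with
ground-truth sustained representation durations of 1200 ms
(short-availability relevant) vs 650 ms (long-availability relevant),
decodes both conditions and runs the cluster tests:

```
short-availability relevant: p = 0.0020, reject = True, largest cluster 0-1180 ms (mass 1096.6)
long-availability relevant: p = 0.0020, reject = True, largest cluster 0-640 ms (mass 802.4)
short vs long availability: mass difference = 294.2, p = 0.1497, reject = False
```

Both conditions decode far above chance (p = .002 is the add-one floor at
500 permutations), and the significant clusters end at 1180 and 640 ms —
recovering the planted 1200/650 ms durations to one or two samples. The
between-condition test is the harder contrast; at this half-size group it
stays short of significance, while at the full 24-participant design (the
power study below) it rejects in the large majority of runs. The other example
scripts cover the generator (`01`), single-participant TGMs (`02`) and the
gaze confound control (`04`).

A thin CLI chains the stages on native on-disk containers:

```bash
timedecode simulate --preset paper-shaped --out raw/ --seed 1
timedecode preprocess --in raw/ --out prep/
timedecode decode --in prep/ --out dec/ --condition short-sf --seed 1
timedecode stats --test within --scores-a dec/ --out result/
timedecode report result/
```

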