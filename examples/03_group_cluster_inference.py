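"""Group-level cluster-based permutation inference on decoding time series.

Simulates a small group, decodes the two feature-relevant conditions, then
runs the within-condition sign-flip test (is decoding above chance, and
until when?) and the between-condition cluster-mass-difference test (do
short and long availability differ?).
"""

from timedecode import (
    AnalysisConfig,
    between_condition_test,
    decode_condition,
    group_from_tensors,
    iter_dataset,
    paper_shaped_config,
    preprocess_pipeline,
    within_condition_test,
)

cfg = AnalysisConfig(n_shuffles=2)
syn = paper_shaped_config(n_participants=12, rng_seed=4)

tensors = {"short": [], "long": []}
for i, (rec, _, table) in enumerate(iter_dataset(syn)):
    rec, table = preprocess_pipeline(rec, table, cfg, select=False)
    for avail in tensors:
        tensors[avail].append(
            decode_condition(rec, table, avail, "sf", cfg, seed=i,
                             mode="diagonal", train_window_ms=(0, 2000))
        )

groups = {a: group_from_tensors(t) for a, t in tensors.items()}
for avail, group in groups.items():
    res = within_condition_test(group, cfg, seed=1, n_permutations=500)
    lc = res.largest_cluster
    span = f"{lc.start_ms:.0f}-{lc.end_ms:.0f} ms" if lc else "none"
    print(f"{avail}-availability relevant: p = {res.p_value:.4f}, "
          f"reject = {res.reject}, largest cluster {span} "
          f"(mass {res.observed_max_mass:.1f})")

bt = between_condition_test(groups["short"], groups["long"], cfg, seed=2,
                            n_permutations=500)
print(f"short vs long availability: mass difference = "
      f"{bt.observed_max_mass:.1f}, p = {bt.p_value:.4f}, reject = {bt.reject}")
print("the short-availability cluster extends well past the long one, "
      "tracking the generative sustained durations (1200 vs 650 ms); the "
      "between-condition test is more demanding — at this half-size group "
      "(12 participants) it may not reach significance, while the "
      "full-design power study (scripts/acceptance.py, 24 participants) "
      "rejects in the large majority of runs")
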