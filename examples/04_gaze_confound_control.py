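"""Eye-movement confound control: decode the stimulus class from gaze alone.

Simulates a participant whose gaze becomes class-informative only late in
the trial (1400 ms), decodes both EEG and gaze with the shared machinery,
and shows the temporal dissociation that rules gaze artifacts out as the
source of early EEG decoding.
"""

import numpy as np

from timedecode import (
    AnalysisConfig,
    decode_condition,
    decode_gaze,
    gaze_baseline,
    iter_dataset,
    paper_shaped_config,
    preprocess_pipeline,
)

cfg = AnalysisConfig(n_shuffles=2)
syn = paper_shaped_config(
    n_participants=1, n_trials_per_condition=96,
    gaze_coupling_amplitude=0.3, rng_seed=6,
)
rec, gaze, table = next(iter(iter_dataset(syn)))

rec_p, table_p = preprocess_pipeline(rec, table, cfg, select=False)
eeg = decode_condition(rec_p, table_p, "long", "sf", cfg, seed=0,
                       mode="diagonal", train_window_ms=(0, 2800))
gz = decode_gaze(gaze_baseline(gaze, cfg.baseline_window_ms), table,
                 "long", "sf", cfg, seed=0, train_window_ms=(0, 2800))

print("mean signed score (0 = chance) per window:")
print(f"{'window':>14s} {'EEG':>8s} {'gaze':>8s}")
for lo in range(0, 2800, 700):
    me = eeg.scores[:, (eeg.train_times >= lo) & (eeg.train_times < lo + 700)].mean()
    mg = gz.scores[:, (gz.train_times >= lo) & (gz.train_times < lo + 700)].mean()
    print(f"{lo:6d}-{lo + 700:4d} ms {me:+8.3f} {mg:+8.3f}")
print("EEG carries class information early (transient + 650 ms sustained "
      "signal); gaze only after the injected 1400 ms coupling — so early "
      "EEG decoding cannot be an eye-movement artifact")
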