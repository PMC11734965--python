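"""Simulate listener groups and summarize their scores like the study.

Thirty synthetic listeners (15 NH + 15 HI) respond to the full 54-condition
grid; scores are averaged over repetitions per subject, then summarized with
condition means, Cohen's d and Bonferroni-adjusted pairwise comparisons.
"""

import pandas as pd

from binsim import behavior, stimuli

REPS = 3  # study used 10; 3 keeps this example quick
frames = []
for group in ("NH", "HI"):
    listeners = behavior.make_listener_group(group, 15, seed=2)
    grid = stimuli.build_condition_grid(groups=(group,), listeners_per_group=15,
                                        repetitions=REPS, master_seed=2)
    for li, listener in enumerate(listeners):
        results = [behavior.respond(listener, t, float(t.snr))
                   for t in grid[(group, li)]]
        frames.append(behavior.results_frame(results, f"{group}{li:02d}"))
df = pd.concat(frames, ignore_index=True)

out = behavior.summarize(df, factor="snr")
means = (df.groupby(["group", "snr"])["sentence_correct"].mean()
         .unstack(0).round(3))
print("proportion sentences correct by group and SNR:")
print(means.to_string())
print()
print("pairwise SNR comparisons (subject means, Bonferroni-adjusted):")
print(out["pairwise"].round(4).to_string(index=False))
print()
print("HI scores sit below NH at every SNR and both groups improve with SNR,")
print("mirroring the qualitative group ordering of the behavioral data.")
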