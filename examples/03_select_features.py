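"""Compare the three selection methods on a simulated cohort.

M1 tests discrete states (Kruskal-Wallis, all three pairwise comparisons),
M2 keeps fixed numbers of principal components per signal, and M3 — the
transition method — runs Shapiro-gated paired tests across the three
emotional state transitions.  Both M1 and M3 then discard features whose
|Pearson r| with an already-kept feature exceeds 0.9.
"""

import transfeat as tf
from transfeat.selection import discrete_select, pca_reduce, transition_select
from transfeat.simulate import SessionTimeline

# Halved protocol keeps this example fast; the structure is unchanged.
layout = [("relax", 60.0), ("neutral", 120.0), ("relax", 60.0),
          ("negative", 120.0), ("relax", 60.0), ("positive", 120.0)]
segs, t = [], 0.0
for label, dur in layout:
    segs.append((label, t, t + dur))
    t += dur

cfg = tf.CohortSimConfig(n_subjects=8, seed=3, timeline=SessionTimeline(segs))
fm = tf.extract_feature_matrix(tf.simulate_cohort(cfg))

m3 = transition_select(fm)
m1 = discrete_select(fm)
_, pca_report = pca_reduce(fm)

print(f"M3 (transition method) final subset, {len(m3.final_subset)} features:")
print("  " + ", ".join(m3.final_subset))
print(f"M1 (discrete states) final subset, {len(m1.final_subset)} features:")
print("  " + ", ".join(m1.final_subset))
print("M2 (PCA) explained variance of the first component per signal:")
for sig, rep in pca_report.items():
    print(f"  {sig}: {rep['explained_variance_ratio'][0]:.2f}")

feat = "HR_ECG"
print(f"\n{feat} p-values across transitions (M3):")
for pair, p in m3.decisions[feat].p_values.items():
    test = m3.decisions[feat].tests[pair]
    print(f"  {pair}: p = {p:.2e} ({test})")
# p < 0.05 in all three transitions is required for preliminary selection.
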