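"""Extract the 39-feature sliding-window matrix from one simulated subject.

Preprocessing: 1-40 Hz zero-phase band-pass + 50 Hz notch for ECG/BVP,
4-Hz resampling + convex tonic/phasic decomposition for GSR; then all 39
features over 60-s windows sliding in 1-s steps within each segment.
"""

import transfeat as tf

subject = tf.simulate_cohort(tf.CohortSimConfig(n_subjects=1, seed=7))[0]
fm = tf.extract_feature_matrix([subject])

print(f"feature matrix: {fm.shape[0]} windows x {fm.shape[1] - 4} features")
print("windows per segment:")
print(fm.groupby(['segment', 'label']).size().to_string())
# A 240-s picture block yields 181 windows of 60 s at 1-s steps.

print("\nper-state means of three stress-sensitive features:")
emo = fm[fm.label.isin(['neutral', 'negative', 'positive'])]
print(emo.groupby('label')[['HR_ECG', 'MEANPA_BVP', 'NUMP_GSR']]
      .mean().round(2).to_string())
# Expected physiology: HR up, pulse amplitude down and more SCR events
# per window in the negative (stress) state.
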