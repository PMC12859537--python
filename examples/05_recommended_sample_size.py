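"""Find, by simulation, the development sample size at which MLE attains
an expected calibration slope of 0.9 in the main scenario.

A target expected shrinkage of 0.9 is the usual criterion for limiting
overfitting when planning a risk-prediction study. The search bisects on
n, estimating the median validation CS of MLE from Monte-Carlo replicates
at each candidate size (common random numbers across candidates).
"""

import shrinktune as st

scn = st.main_scenario()
n_rec = st.find_recommended_n(scn, target_cs=0.9, nsim=150, seed=40,
                              bracket=(400, 1600), nval=10_000)
print(f"recommended n for expected CS 0.9: {n_rec}")
print("(roughly 900 for C=0.7, prevalence 0.5 with 12 candidate predictors; "
      "at this\nlight replication the search lands within ~10% of that, and "
      "a stricter target\nCS would require a larger n)")
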