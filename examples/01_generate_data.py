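"""Generate a synthetic development dataset and check it hits its targets.

The main scenario has 12 multivariate-normal predictors (5 true, 7 noise;
correlations 0.1 within the true block, 0.05 within the noise block), a
logistic outcome with slopes k*(0.5, 0.3, 0.3, 0.25, 0.25, 0, ..., 0),
prevalence 0.5 and true C-statistic 0.7.
"""

import shrinktune as st

scn = st.main_scenario()  # beta0 = 0, k = 0.93
ds = st.generate_dataset(scn, n=50_000, seed=1)

print(f"n = {ds.n}, p = {ds.p}")
print(f"event fraction        : {ds.y.mean():.3f}   (target 0.5)")
print(f"C-stat of true probs  : {st.c_statistic(ds.y, ds.true_prob):.3f}"
      "   (target 0.70)")

# calibrate (beta0, k) from scratch instead of trusting the defaults
beta0, k = st.calibrate_dgm(scn, seed=2)
print(f"recalibrated beta0, k : {beta0:.3f}, {k:.3f}   (k near 0.93)")

# datasets round-trip through plain CSV (outcome column 'y')
ds_small = st.generate_dataset(scn, n=200, seed=3)
print("head of the data frame (Dataset.to_csv writes exactly this):")
print(ds_small.to_frame().head(3).round(3).to_string(index=False))
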