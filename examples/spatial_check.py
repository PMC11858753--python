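"""Check country random intercepts for spatial clustering with Moran's I.

Fits the hierarchical duration model to a simulated meta-table, extracts
the posterior-mean country intercepts, and tests them against country
coordinates using inverse-distance spatial weights. Because the
simulator places country effects independently of geography, Moran's I
should sit near its null expectation of -1/(n-1) with a large p-value.
"""

from circasleep import (
    McmcConfig,
    StudyGenParams,
    fit_sleep_model,
    generate_study_table,
    morans_i,
)

table = generate_study_table(StudyGenParams(seed=3))
fit = fit_sleep_model(table, mcmc=McmcConfig(seed=3))

intercepts = fit.random_intercepts()
coords = table.groupby("country")[["latitude", "longitude"]].mean()
merged = intercepts.merge(coords, on="country")

res = morans_i(
    merged["intercept"].to_numpy(),
    merged["latitude"].to_numpy(),
    merged["longitude"].to_numpy(),
    n_permutations=9999,
    seed=3,
)
print(f"Moran's I = {res.I:.4f}  (null expectation {res.expected_I:.4f}, "
      f"p = {res.p_value:.3f}, n = {res.n_units} countries)")
print("no spatial clustering of country effects" if res.p_value > 0.05
      else "country effects cluster in space")
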