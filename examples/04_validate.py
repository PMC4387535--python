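"""Two-step validation of a fitted map: 10% holdout and internal checks.

Refits on 90% of the clusters and scores the held-out 10% (MPE / MAE /
RMSE / Pearson r), then computes leave-one-out conditional predictive
ordinates and the standardized-residual semivariogram with 99-permutation
envelopes on the full fit.
"""

import numpy as np

import u5mbg as m

grid = m.RasterGrid(3.0, 4.0, 0.33, 30, 30)
stack = m.gen_covariate_stack(grid, seed=1)
truth = m.STGPModel(beta={"intercept": 0.18, "accessibility": 0.02},
                    sigma2=2e-3, kappa=np.sqrt(8.0) / 3.0, nugget=1.5e-3,
                    rho=0.0)
clusters, _ = m.simulate_survey(stack, truth, n_clusters=300, n_waves=1, seed=4)

train, test = m.holdout_split(clusters, fraction=0.10, seed=0)
fit_train = m.fit(train, stack, ["accessibility"], m.FitConfig(n_starts=2))
X_test = np.column_stack([
    np.ones(len(test)),
    stack.values_at(test["lon"].to_numpy(), test["lat"].to_numpy(),
                    ["accessibility"])])
mu, _ = m.predict_points(fit_train, X_test,
                         test[["lon", "lat"]].to_numpy(dtype=float),
                         test["time"].to_numpy(dtype=float),
                         include_nugget=True)
hm = m.holdout_metrics(test["p_under5"].to_numpy(), mu)
print(f"holdout n={len(test)}  MPE {hm.mpe:+.5f}  MAE {hm.mae:.4f}  "
      f"RMSE {hm.rmse:.4f}  r {hm.pearson_r:.3f}")

fit_full = m.fit(clusters, stack, ["accessibility"], m.FitConfig(n_starts=2))
cpo = m.loo_cpo(fit_full)
print(f"CPO: min {cpo.min():.3f}, median {np.median(cpo):.3f} "
      "(low values flag poorly predicted clusters)")

resid = m.loo_residuals(fit_full)
sv = m.residual_semivariogram(resid, clusters[["lon", "lat"]].to_numpy(float),
                              n_bins=10, n_perm=99, seed=0)
inside = np.mean((sv.gamma >= sv.lower) & (sv.gamma <= sv.upper))
print(f"semivariogram bins inside permutation envelopes: {inside:.0%}")
# A flat semivariogram inside the envelopes means the model absorbed the
# spatial structure; MAE/RMSE quantify out-of-sample accuracy.
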