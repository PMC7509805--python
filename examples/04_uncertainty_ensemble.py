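"""Propagate measurement and model uncertainty with a Monte-Carlo ensemble.

Each draw perturbs every reflectance pair within its sensor's
radiometric bound (up to +-7/5/3% for L5/L7/L8), refits the
cross-sensor calibration, draws the spline smoothing parameter from
[0.68, 0.72], and rebuilds every annual NDVI_max.  Statistics are
summarised by the median and the 2.5th/97.5th percentiles.
"""

from tundragreen import ensemble as ens
from tundragreen import synthetic as syn

sites = syn.generate_sites(40, frac_greening=0.37, frac_browning=0.05, seed=30)
obs = syn.simulate_observations(sites, range(1985, 2017), seed=31)

e = ens.run_ensemble(obs, n_sims=20, master_seed=32, sites=sites)
print(f"{e.n_sims} draws, {len(e.failures)} failures")

summary = ens.summarize(e, lambda t: float(t["ndvimax"].mean()),
                        name="network-mean NDVI_max")
print(f"{summary.statistic}: {summary.median:.3f} "
      f"[{summary.ci_low:.3f}, {summary.ci_high:.3f}] (95% MC CI)")
print("The CI width reflects radiometric bounds, calibration refits, and")
print("spar variation; it collapses to zero when those sources are disabled.")
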