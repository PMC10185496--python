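"""Full statistical pipeline on a synthetic spawning dataset.

Generates a spawning table with known genus-specific lit shifts, runs
classification -> filtering -> positive transform -> spatial Poisson
mixed model, and compares the recovered per-genus lit-unlit shifts with
the generating truth.  A recovered difference near the configured shift
(e.g. -3 days for Porites) shows the pipeline estimates the ALAN effect
without bias from the regional intercepts, latitude trend, or spatial
autocorrelation it also has to absorb.
"""

import numpy as np

from moontrigger import (GeneratorConfig, ModelSpec, apply_filters, buffer_mean,
                         classify_exposure, fit_glmm, generate_dataset,
                         genus_shift_table, positive_transform)
from moontrigger.io import SPAWNING_COLUMNS

cfg = GeneratorConfig(seed=11)
sites, raster, traits, obs, truth = generate_dataset(cfg)

df = obs.rename(columns=SPAWNING_COLUMNS)
df["in_situ"] = df.pop("o_n").str.lower().eq("in situ")
crit = np.array([buffer_mean(raster, la, lo)
                 for la, lo in zip(df["latitude"], df["longitude"])])
df, audit_cls = classify_exposure(df, crit, dict(zip(traits.species, traits.lower_depth_m)))
df, audit = apply_filters(df)
df["dsst"] = 0.0
df["dkd490"] = 0.0
df["dfe"] = df["latitude"].abs()
df["y"], transform = positive_transform(df["dosrtnf"])

print(f"{len(df)} observations retained (filter audit: {audit})")
fit = fit_glmm(ModelSpec(fixed_terms=("ALAN", "Genus", "DfE", "Ecoregion", "ALAN:Genus")),
               df, transform)
print(f"log-likelihood {fit.loglik:.1f}, AIC {fit.aic:.1f}, "
      f"Pearson dispersion {fit.dispersion:.2f}, "
      f"Matern sigma^2 {fit.sigma2:.3f}, range {fit.rho_km:.0f} km\n")

tab = genus_shift_table(fit, df)
tab["truth_days"] = tab["genus"].map({g: v["delta_days"] for g, v in truth["genera"].items()})
print(tab[["genus", "difference_days", "ci95_lo", "ci95_hi", "truth_days"]]
      .round(2).to_string(index=False))
print("\ndifference_days is the modeled lit-minus-unlit shift in days from full moon;")
print("negative values mean lit corals spawn closer to the full moon.")
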