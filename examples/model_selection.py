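"""AIC model selection and likelihood-ratio tests on synthetic data.

Enumerates every marginality-respecting nested version of the global
fixed-effect structure (194 models for the full term set; a reduced set
is used here to keep the run short), ranks them by AIC, then interrogates
the genus-specific ALAN effect with a likelihood-ratio test.  Data are
generated with a strong ALAN x Genus interaction, so the top-ranked
models should retain it and the LRT should reject its removal.
"""

import numpy as np

from moontrigger import (GeneratorConfig, ModelSpec, enumerate_nested, fit_glmm,
                         generate_dataset, lrt, positive_transform, select_model)
from moontrigger.io import SPAWNING_COLUMNS

print(f"global model enumeration size (marginality enforced): "
      f"{len(enumerate_nested())} models")

cfg = GeneratorConfig(seed=5, n_obs=1200, n_sites=30)
sites, raster, traits, obs, truth = generate_dataset(cfg)
df = obs.rename(columns=SPAWNING_COLUMNS)
df["in_situ"] = True
df["exposure"] = np.where(df["site_id"].isin(sites.site_id[sites.lit]), "Lit", "Unlit")
df["dsst"] = 0.0
df["dkd490"] = 0.0
df["dfe"] = df["latitude"].abs()
df["y"], transform = positive_transform(df["dosrtnf"])

terms = ("ALAN", "Genus", "DfE", "ALAN:Genus", "ALAN:DfE")
tab = select_model(df, global_terms=terms, transform=transform)
print(f"\n{len(tab)} nested models ranked by AIC (top 5):")
print(tab.head(5)[["terms", "k", "aic", "delta_aic", "akaike_weight"]]
      .round(3).to_string(index=False))

full = fit_glmm(ModelSpec(fixed_terms=("ALAN", "Genus", "ALAN:Genus")), df, transform)
nested = fit_glmm(ModelSpec(fixed_terms=("ALAN", "Genus")), df, transform)
chi2, dof, p = lrt(nested, full)
print(f"\nLRT for ALAN:Genus: chi2 = {chi2:.2f}, df = {dof}, p = {p:.2g}")
print("A small p confirms the lit shift differs between genera, as generated.")
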