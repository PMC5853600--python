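# lightresponse

Bayesian analysis of chlorophyll-fluorescence light-response curves, built
for comparing photosynthetic performance between experimental treatments —
for example wild-type *Chlamydomonas* against a pyrenoid-less mutant whose
carbon-concentrating mechanism is disabled, across light-acclimation and
CO₂ regimes.

## The models

PSII operating efficiency φ_II as a function of actinic intensity *I*
(µmol photons m⁻² s⁻¹) follows an exponential-saturation model in two
equivalent parameterisations:

    φ_II(I) = φ_m · (I_k / I) · (1 − e^(−I/I_k))              (efficiency form)
    φ_II(I) = ETR_max / (a_II · I) · (1 − e^(−I/I_k))         (electron-transport form)

with φ_m the maximum PSII operating efficiency, I_k the light-saturation
intensity, ETR_max = a_II·φ_m·I_k the maximum electron transport rate, and
a_II = 0.84 × 0.5 = 0.42 the assumed fraction of incident photons absorbed
and allocated to PSII.  Efficiencies convert to electron transport rates as
ETR = φ_II · I · a_II.  Total electron flow follows the same saturation
directly in rate units, TEF(I) = TEF_max·(1 − e^(−I/I_k)), and
non-photochemical quenching follows a Hill dose-response
NPQ(I) = NPQ_max·Iⁿ/(I₅₀ⁿ + Iⁿ).

Each treatment is fitted independently by random-walk Metropolis MCMC on
log-transformed parameters with a Gaussian likelihood whose standard
deviation is an extra nuisance parameter, and flat (improper) priors on the
log scale.  Posterior chains yield 95% credible bands for the mean response
in ETR units, and pairwise treatment comparisons via the posterior
difference Δ = θ_A − θ_B: the probability P(Δ ≤ 0) is 0.5 when there is no
difference, and values below 0.025 (or above 0.975) flag a significant one.

## Worked example

```python
import numpy as np
from lightresponse import (LightResponseRegressor, default_scenario, generate,
                           param_difference, credible_band)

data = generate(default_scenario(), kinds=("phi_ii",), seed=42)
wt  = data[data.treatment == "WT_SL_air"]
pyr = data[data.treatment == "pyr_SL_air"]

def fit(d, seed):
    X = d["intensity"].to_numpy().reshape(-1, 1)
    return LightResponseRegressor(model="phi_ii", seed=seed).fit(X, d["response"])

reg_wt, reg_pyr = fit(wt, 0), fit(pyr, 1)
print(reg_wt.summary_.round(3))
res = param_difference(reg_wt.chain_, reg_pyr.chain_, "etr_max", seed=2)
print(f"P(dETR_max<=0) = {res.p_leq_zero:.5f}  "
      f"95% CI = ({res.ci95[0]:.1f}, {res.ci95[1]:.1f})  significant = {res.significant}")
```

prints

```
              mean     sd     q2.5   median    q97.5
parameter
etr_max     30.872  0.761   29.463   30.841   32.470
i_k        155.488  5.116  146.062  155.273  166.187
sigma        0.016  0.002    0.013    0.016    0.019
P(dETR_max<=0) = 0.00000  95% CI = (12.5, 16.1)  significant = True
```

The wild-type posterior recovers the generating values (ETR_max = 30,
I_k = 150) within uncertainty, and the genotype difference in ETR_max
(truth 12 µmol e⁻ m⁻² s⁻¹ under standard light in air) is decisively
detected: essentially no posterior mass on Δ ≤ 0, with a 95% credible
interval of roughly 12–16.  `credible_band` converts a chain into
per-intensity 95% bands of the mean ETR response for plotting.

The same workflow is available from the shell:

```
lightresponse simulate --out data.csv --seed 0
lightresponse fit --input data.csv --out-dir fits --seed 1
lightresponse compare --draws-dir fits --pair WT_SL_air:pyr_SL_air \
    --parameter etr_max --out comparisons.csv
```

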