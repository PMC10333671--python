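"""Drivers of the three specialization responses via mixed models.

Fits richness (Poisson, log link), ln Simpson and sqrt d' (Gaussian) on
standardized climate variables, guild and reproductive mode, with crossed
random intercepts for forest and mycobiont species; reports type-III Wald
tests, Nakagawa R2, VIF and Moran's I.
"""

from symbiospec.io import RunConfig
from symbiospec.pipeline import run_synthetic_pipeline

results = run_synthetic_pipeline(RunConfig(seed=1))

for response, fit in results["glmm"].items():
    print(f"\n=== {response} ({fit['family']}, "
          f"transform={fit['transformation']}, n={fit['n']}) ===")
    print(f"  R2 marginal {fit['r2_marginal']:.2f} | "
          f"conditional {fit['r2_conditional']:.2f}")
    print(f"  random variances: "
          + ", ".join(f"{k}={v:.4f}" for k, v in fit["random_variances"].items()))
    top = max(fit["anova_type3"], key=lambda r: r["chi2"])
    print(f"  strongest fixed term: {top['term']} "
          f"(chi2={top['chi2']:.2f}, df={top['df']}, p={top['p_value']:.3f})")
    print(f"  Moran's I on residuals: I={fit['morans_i']['I']:.3f}, "
          f"p={fit['morans_i']['p_value']:.3f}")
# A large conditional-vs-marginal gap for d' indicates mycobiont identity
# (the species random intercept) explains most of that index's variation.
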