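"""Rebuild a solubility model from (synthetic) data, end to end.

Generates the study-design grid (9 donors x 4 temperatures x 5 pressures)
from the three-variable generating law with realistic noise, holds out two
donors for external validation, refits by OLS, and runs the Williams-plot
applicability-domain analysis.  The refitted coefficients should agree with
the generating ones within a few standard errors, and the held-out donors
should validate nearly as well as the training set.
"""

from desqspr import (
    SynthSpec,
    build_design,
    external_validation,
    fit_ols,
    reference_eeig02d,
    split_by_hbd,
    synth_generate,
    williams_ad,
)

spec = SynthSpec(seed=2026)
dataset = synth_generate(spec)
train, test = split_by_hbd(dataset, ["Furfuryl alcohol", "Diethylene glycol"])
lookup = reference_eeig02d()

X, y = build_design(train, lookup)
fit = fit_ols(X, y)
print(f"n(train) = {fit.n}, n(test) = {len(test)}")
print(f"{'term':10s} {'fitted':>9s} {'SE':>8s} {'truth':>8s}")
for term, truth in [("lnP", spec.a), ("T", spec.b), ("EEig02d", spec.c),
                    ("intercept", spec.d)]:
    print(f"{term:10s} {fit.coef[term]:9.4f} {fit.se[term]:8.4f} {truth:8.4f}")
print(f"R2 = {fit.r2:.4f}, Q2_LOO = {fit.q2_loo:.4f}, "
      f"S = {fit.s:.4f}, AARD(ln) = {fit.aard_ln:.2f}%")

X_test, y_test = build_design(test, lookup)
ext = external_validation(fit, X_test, y_test)
print(f"external: R2 = {ext['r2']:.4f}, RMSE = {ext['rmse']:.4f}, "
      f"AARD(ln) = {ext['aard_ln']:.2f}%")

ad = williams_ad(fit, X, y)
flagged = sum(f != "in-domain" for f in ad.flags)
print(f"applicability domain: h* = {ad.h_star:.3f}, "
      f"{flagged}/{fit.n} points outside the domain")
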