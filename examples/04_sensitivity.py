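"""Global sensitivity analysis and location-independent uncertainty bands.

First-order Sobol indices identify the inputs driving the variance of the
unattenuated impact force F*, the skeletal force F and ARF0; the inputs
whose indices sum past 80% are 'sensitive', and measurement uncertainty is
propagated through the extreme bin-mean outputs over their grid.
"""

import numpy as np

import femrisk as fr
from femrisk.domain import GeneralTruncNormSpec, TruncatedNormalSpec

# --- F*: body-floor impact model -------------------------------------------
specs = fr.impact_force_specs()
res = fr.saltelli_first_order(fr.unattenuated_force_model(), specs, N=100_000, seed=1)
print("first-order indices of F*:", {k: f"{v:.3f}" for k, v in res.indices.items()})
sensitive = fr.select_sensitive(res)
print("sensitive inputs (80% rule):", sensitive)

# propagate measurement uncertainty through the canonical (m, theta_f) pair
# (their indices sum to ~0.80, right at the screening threshold)
sample = fr.lh_sample(100_000, list(specs.values()), seed=2, names=list(specs)).matrix
Y = fr.unattenuated_force_model()(sample)
cols = [list(specs).index(k) for k in ("m", "theta_f")]
band = fr.uncertainty_band(
    Y, sample[:, cols], {"m": 4.10, "theta_f": 3.70}, bins=10, angular=[False, True]
)
print(f"bin-mean extrema: {band.y_max:.0f} N / {band.y_min:.0f} N; propagated uncertainty ~{band.s_tilde:.0f} N")
print("(measurement errors of 4.1 kg in mass and 3.7 deg in fall angle translate to this force uncertainty)\n")

# --- F: ground-skeleton force-transfer model --------------------------------
res_f = fr.saltelli_first_order(
    fr.skeletal_force_model(), fr.impact_force_specs(include_eta_I=True), N=100_000, seed=3
)
sub = {k: res_f.indices[k] for k in ("m", "H", "eta_I")}
print("indices of F (m, H, eta_I):", {k: f"{v:.3f}" for k, v in sub.items()})
print("sensitive inputs:", fr.select_sensitive(sub))
print("(the impact attenuation coefficient dominates the skeletal-force uncertainty)\n")

# --- ARF0: multiscale model --------------------------------------------------
model = fr.arf0_population_model(fr.FallStochasticModel(), N_falls=1024, seed=4)
arf_specs = {
    "m": TruncatedNormalSpec(63.75 - 3 * 13.2, 63.75 + 3 * 13.2),
    "H": TruncatedNormalSpec(1.58 - 3 * 0.062, 1.58 + 3 * 0.062),
    "S": GeneralTruncNormSpec(2800.0, 1000.0, 390.0, 6330.0),
}
corr = np.array([[1.0, 0.429, 0.264], [0.429, 1.0, 0.294], [0.264, 0.294, 1.0]])
res_a = fr.correlated_first_order(model, arf_specs, corr, N=8192, seed=5)
print("indices of ARF0 (m, H, <S>):", {k: f"{v:.3f}" for k, v in res_a.indices.items()})
print("sensitive inputs:", fr.select_sensitive(res_a))
print("(bone strength alone explains the bulk of the risk variance)")
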