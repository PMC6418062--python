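"""Predict one subject's current absolute risk of femoral fracture (ARF0).

Builds a subject, generates a surrogate side-fall strength surface, runs the
Monte-Carlo fall simulation at the verified settings (N = 10^4 falls, M = 33
impact orientations) and prints the per-fall fracture probability P and ARF0.
"""

import numpy as np

import femrisk as fr

subject = fr.Subject("demo", m=62.6, H=1.58, age=75)
print(f"subject: mass {subject.m} kg, height {subject.H} m, BMI {subject.bmi:.1f} kg/m^2")
print(f"soft-tissue attenuation eta_ST = {fr.eta_st_from_bmi(subject.bmi):.3f}")

# surrogate femoral strength over impact orientations (mean 2500 N here)
rng = np.random.default_rng(0)
surface = fr.synthesize_surface(subject, fr.SurfaceGenParams(), rng, mean_strength=2500.0)
s_min, s_max, s_mean = fr.surface_stats(surface)
print(f"strength surface: min {s_min:.0f} N, max {s_max:.0f} N, mean {s_mean:.0f} N")

fall_model = fr.FallStochasticModel()  # the default truncated-normal fall distributions
P = fr.fall_fracture_probability(subject, fall_model, surface, N=10_000, seed=42)
arf0 = fr.arf0_from_p(P)  # annual fall rate 0.65 by default
print(f"\nper-fall fracture probability P = {P:.3f}")
print(f"ARF0 = {arf0:.1f}%  (probability of >=1 hip fracture within the year)")
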