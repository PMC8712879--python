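"""Personalize the global conductivity to a clinical QRS duration.

Mimics per-patient model tailoring: given a measured mean QRS duration,
find the single conductivity scale g whose simulated mean QRSd matches it.
The demonstration first simulates a "clinical" target with a known ground
truth, then recovers it.
"""

from crtpredict import build_ventricles, default_torso, place_pacing_sites
from crtpredict.personalization import QRSdSimulator, fit_conductivity

mesh = build_ventricles(edge_length=5.0)
torso = default_torso()
pacing = place_pacing_sites(mesh)
sources = [(pacing.rv_site, 0.0), (pacing.lv_site, 0.0)]  # BiV, zero delay

sim = QRSdSimulator(mesh, sources, torso)
g_true = 0.8
target = sim.mean_qrsd(g_true)
print(f"ground truth g* = {g_true}  ->  simulated mean QRSd "
      f"= {target:.1f} ms (the 'clinical' target)")

result = fit_conductivity(mesh, sources, torso, target,
                          simulator=sim, mode="biv")
print(f"fitted g = {result.g:.4f} (recovery error "
      f"{abs(result.g - g_true) / g_true:.2%})")
print(f"implied along-fiber velocity v_f = {result.v_f:.3f} mm/ms")
print(f"|mean QRSd - target| at optimum = {result.objective:.3f} ms "
      f"after {result.n_evaluations} forward evaluations; "
      f"converged = {result.converged}")
print("fibrosis stays at 1% of the fitted conductivity and scar stays "
      "inexcitable throughout the fit")
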