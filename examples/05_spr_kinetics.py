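"""Fit 1:1 Langmuir kinetics to a synthetic SPR sensorgram.

A sensorgram with a 30 min association phase and a 13 min dissociation
phase is simulated from known rates plus 1% Gaussian noise, then globally
fitted; the fit recovers ka, kd and the affinity KA = ka/kd.
"""

from aptaselect import (
    SimulationSpec,
    binding_affinity,
    datasets,
    fit_sensorgram,
    simulate_sensorgram,
)

spec = SimulationSpec(ka=1e5, kd=1e-3, concentration=1e-8, noise_sd=0.01, seed=7)
sg = simulate_sensorgram(spec)
fit = fit_sensorgram(sg)

print(f"truth : ka = {spec.ka:.3g} 1/(M s), kd = {spec.kd:.3g} 1/s")
print(
    f"fitted: ka = {fit.params.ka:.3g} +/- {fit.stderr['ka']:.2g}, "
    f"kd = {fit.params.kd:.3g} +/- {fit.stderr['kd']:.2g}"
)
print(f"KA = ka/kd = {fit.KA:.3g} 1/M")

print("\npublished affinities recomputed from the fitted rate constants:")
for _, row in datasets.load_kinetics().iterrows():
    ka = row["ka_1e3_per_M_s"] * 1e3
    kd = row["kd_1e-3_per_s"] * 1e-3
    print(f"  {row['name']:10s} KA = {binding_affinity(ka, kd) / 1e6:.2f} x1e6 1/M")
# On noiseless data the fit recovers the rates to <0.1%; at 1% noise both
# rates come back within a few percent.
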