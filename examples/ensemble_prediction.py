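"""Predict a pKa from several reference solvents at once.

A species measured in water, acetonitrile and DMSO gives three independent
routes to its methanol pKa. In a perfectly consistent world they agree
exactly (spread ~ 0); with measurement noise the ensemble mean damps the
error of any single reference and the spread estimates the disagreement.
"""

from pkashift import SimulationSpec, fit_delta, predict_ensemble, simulate
from pkashift.curation import curate

spec = SimulationSpec(
    n_species=30,
    solvents={"acetonitrile": 10.0, "dmso": -6.0, "methanol": -0.5},
    noise_sd=0.3,
    seed=5,
)
world = simulate(spec)

# fit the shifts first (water is the anchor at 0)
deltas = {"water": 0.0}
for solvent in spec.solvents:
    datapoints, _ = curate(world.measurements, world.species, world.solvation, solvent)
    deltas[solvent] = fit_delta(datapoints, world.ctx).delta_hat

measurements = {}
for m in world.measurements:
    measurements.setdefault(m.species_id, []).append((m.solvent, m.pka))

species = world.species[0]
refs = [(s, p) for s, p in measurements[species.species_id] if s != "methanol"]
pred = predict_ensemble(species, "methanol", refs, world.solvation, deltas, world.ctx)

truth = world.ground_truth["true_pkas"][species.species_id]["methanol"]
print(f"species {species.species_id} ({species.ionization_class.value}), target: methanol")
for solvent, value in pred.per_reference:
    print(f"  via {solvent:>13}: predicted pKa = {value:6.2f}")
print(f"  combined (mean): {pred.combined_pka:6.2f}  spread (SD) = {pred.spread:.2f}")
print(f"  true value:      {truth:6.2f}")
print()
print("The spread across references is a consistency diagnostic: large spread")
print("flags a reference measurement on an inconsistent acidity scale.")
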