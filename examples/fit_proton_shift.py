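"""Fit per-solvent proton shifts on a synthetic benchmark.

Builds a small world of 40 acids and bases with known proton transfer
energies (acetonitrile +10, DMSO -6, methanol -0.5 kcal/mol), adds 0.5 pKa
units of measurement noise, then curates and fits each solvent.
"""

from pkashift import SimulationSpec, fit_delta, simulate, summarize_fits
from pkashift.curation import curate

spec = SimulationSpec(
    n_species=40,
    acid_fraction=0.5,
    solvents={"acetonitrile": 10.0, "dmso": -6.0, "methanol": -0.5},
    noise_sd=0.5,
    seed=42,
)
world = simulate(spec)

fits = []
for solvent, true_delta in spec.solvents.items():
    datapoints, report = curate(world.measurements, world.species, world.solvation, solvent)
    fit = fit_delta(datapoints, world.ctx)
    fits.append(fit)
    print(f"{solvent:>13}: delta = {fit.delta_hat:6.2f} kcal/mol (true {true_delta:+.1f}), "
          f"N = {fit.n_points}, RMSE = {fit.rmse:.2f} pKa")

print()
print(summarize_fits(fits).to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
print("Each fitted delta estimates the proton transfer free energy from water")
print("into that solvent; RMSE/MAE are the per-point pKa prediction errors at")
print("the fitted shift. With 0.5 pKa noise the shift is recovered to ~0.1 kcal/mol.")
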