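# Methods

## Model

The transfer of an acid dissociation equilibrium from a reference solvent
(water, denoted †) into a target solvent S is written as a thermodynamic
cycle over the solvation free energies of every participating species.
With c ≡ ln(10)·R·T,

- acids (AH ⇌ A⁻ + H⁺): pKa(S) = pKa(ref) + (δ + ΔΔG†(A⁻) − ΔΔG†(AH)) / c
- bases (BH⁺ ⇌ B + H⁺): pKa(S) = pKa(ref) + (δ − ΔΔG†(BH⁺) + ΔΔG†(B)) / c

where ΔΔG†(Z) = ΔG_solv(Z, S) − ΔG_solv(Z, ref). The sign convention is
load-bearing and is asserted throughout the tests: the anion transfer
energy is added, the cation transfer energy subtracted. The arbitrary
reference state of the underlying solvation energies cancels in ΔΔG
provided both solvents use the same convention; the package assumes this
and cannot detect a violation.

δ is the proton's transfer free energy from the reference solvent into S.
It is treated as a per-solvent regression parameter δ_H† because no
continuum solvation model yields it reliably. Each datapoint's residual

    f_i(δ) = pKa_ref,i − pKa_exp,i + (δ + g_i)/c

(g_i the class-dependent combination of solute transfer energies) is
affine in δ with slope 1/c, so minimizing Σ f_i² has the closed form
δ̂ = mean_i r_i with r_i = c·(pKa_exp,i − pKa_ref,i) − g_i. The closed form
is exact and deterministic; a brute-force grid search over the same
objective exists in the package purely as an independent verification
oracle and is never used for fitting. An optional least-absolute-deviation
mode (δ̂ = weighted median of r_i) is provided for robustness but is not
the default: the squared loss is the defining objective. Points are
unweighted by default; a weights hook exists in `fit_delta`.

At the optimum the residual mean is exactly zero, the objective is
strictly convex, and adding a constant k to every g_i shifts δ̂ by exactly
−k — these are the invariants the property tests pin down.

## Joint multi-solvent fitting

When measurements exist between arbitrary solvent pairs, every solvent S
carries an unknown δ_S relative to an anchor solvent (water, δ ≡ 0 by the
definition of the reference). A datapoint between solvents a and b
contributes a residual linear in (δ_b − δ_a), giving an ordinary linear
least-squares system with design-matrix entries ±1 after scaling by c,
solved by `numpy.linalg.lstsq`. Solvents with no path to the anchor in the
datapoint graph are not identifiable and are rejected by a BFS
connectivity check. When all datapoints share the anchor as reference the
system is diagonal and the joint solution reproduces the per-solvent fits
exactly (tested). The per-solvent statistics reported for a joint fit pool
every datapoint whose target is that solvent, evaluated at the joint
solution. No per-pair weighting is applied; an inverse-variance scheme
would be the natural refinement if reference solvents of very different
data quality are mixed.

## Ensemble prediction

A species measured in several solvents admits one prediction per
reference: pKa(b) = pKa(a) + ((δ_b − δ_a) + g_ab)/c. The combined value is
the unweighted mean of the per-reference predictions (median optional);
since the model is linear, averaging predictions and averaging energy
corrections before conversion are identical for the mean. The spread
(population SD across references) is the consistency diagnostic: exactly
zero in a self-consistent world, and non-zero when a reference solvent's
acidity scale carries an anchor offset that the fitted shifts did not
absorb. No solvent blacklist is hard-coded; callers exclude unreliable
references by omitting them or via the `trusted` flags.

## Curation

Filters applied when assembling fit-ready datapoints for a target solvent,
in order: duplicate merging, trust flags, charge filter, reference
coverage, solvation coverage. Duplicate (species, solvent) measurements
within 0.4 pKa units of each other (default, configurable) are replaced by
their arithmetic mean with concatenated provenance; duplicates spanning
more than the tolerance are all dropped and logged as conflicts, since a
spread that large usually means the values sit on different acidity scales
and no average is meaningful. Species whose ion form carries |charge| ≥ 2
are outside the single-proton transfer model and are removed both at CSV
ingest and during curation, always with an explicit per-species reason.
Zwitterions are not excluded by this rule: the criterion is the net charge
of the ionic form, not internal charge separation. Datasets smaller than
`min_points` (default 10) or missing an ionization class produce warnings,
never failures — some solvents genuinely have no measured bases. Every
input measurement is accounted for as kept, merged, removed or conflicted,
and curation is idempotent.

## Error metrics

RMSE and MAE of the pKa residuals (predicted − experimental; positive =
overprediction) and two R² variants: the squared Pearson correlation
(default in summaries, the quantity a parity plot suggests) and the
coefficient of determination about the parity line 1 − SS_res/SS_tot,
which additionally penalizes constant offsets. Both are reported because
published error tables rarely state which definition they use; summary
CSVs carry the choice in the column metadata. RMSE ≥ MAE always
(power-mean inequality, property-tested).

The `report` path compares fitted shifts with a packaged table of
experimental proton transfer free energies derived under different
extrathermodynamic assumptions (TATB, cluster-pair approximation,
regression-based). Agreement there is the external sanity check on
interpreting δ_H† as a physical transfer energy rather than a lumped
error term.

## Synthetic benchmark generator

The generator emulates the structure of a curated multi-solvent dataset:
n_species acid/base records (default 50, half acids), aqueous pKa drawn
uniformly on [2, 12], per-form solvation free energies drawn per solvent
from Gaussians with mean −5 (sd 2) kcal/mol for neutrals and −60 (sd 5)
kcal/mol for singly charged ions — magnitudes typical of small organics,
though only between-solvent differences ever enter the model, so these
locations are inert. Non-aqueous pKa values follow the transfer relation
exactly for known per-solvent shifts, then acquire:

- Gaussian noise (default sd 0.5 pKa units) on the non-reference
  measurements. Noise is placed on pKa, not energies, because
  experimental scatter is quoted in pKa units; an energy-noise mode
  exists. Reference-solvent (aqueous) values are noiseless, so the
  closed-form standard error of the fitted shift is exactly c·σ/√N —
  the recovery tests use this.
- an optional per-solvent anchor offset (pKa units), emulating a
  mis-anchored acidity scale. In the noiseless limit it biases δ̂ by
  exactly c·offset and leaves residuals untouched: scale errors and the
  proton transfer energy are observationally confounded in this model.
- an optional ion_bias (kcal/mol): the solvation table handed to the
  modeler reports ionic solvation energies shifted by +b in non-reference
  solvents while measurements follow the unbiased truth. Because the
  anion enters the relation with + and the cation with −, the induced
  prediction error is oppositely signed for acids and bases: the residual
  clouds separate by exactly 2b/c and a class-balanced fit splits the
  difference. This reproduces, at desk scale, the characteristic
  acid/base separation that a charge-dependent solvation-model error
  imprints on a parity plot.

All randomness flows through one `numpy` generator seeded from the spec;
fixtures are byte-identical per seed (floats serialized via `repr`).

What passing on synthetic data does **not** show: the generator contains
no homoconjugation, ion pairing, conformer effects or functional-group-
dependent solvation error beyond the additive bias — on real data those
appear as structured residuals the model cannot explain, and performance
is then limited by data and solvation-model quality rather than by the
regression machinery validated here.

## Numerical choices and conventions

- T = 298 K by default, configurable; R = 1.98720425864083e-3
  kcal·mol⁻¹·K⁻¹, so c(298 K) ≈ 1.36356 kcal/mol.
- Internal energy unit is kcal/mol; kJ/mol is accepted at I/O with an
  explicit per-row unit declaration and converted on ingest (÷4.184).
- The grid oracle breaks ties toward the smaller δ and refuses an optimum
  on the grid boundary (the bracket is then suspect).
- Solvent names are normalized case-insensitively through a small alias
  map (MeCN → acetonitrile, ...); unknown names pass through verbatim.
- CSV schema violations are collected per line and raised together; a
  validation failure exits the CLI with status 2.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
100 randomized datasets of up to 100 points for oracle agreement, 200
seeds × 50 species for recovery statistics, 30–40 species for the exact
identities. These sizes put the Monte-Carlo standard errors well below
the asserted tolerances while keeping the whole suite in seconds.

## Known limitations

- δ_H† conflates the proton transfer energy with systematic solvation
  error and scale-anchor error; the package quantifies the signatures of
  these confounders but cannot separate them from data alone.
- No uncertainty quantification beyond residual statistics (no bootstrap
  confidence intervals on δ̂).
- Joint-fit weighting across heterogeneous reference solvents is uniform.
- Structure identifiers (SMILES/InChI) are carried as opaque strings and
  never validated chemically.
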