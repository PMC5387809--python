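# Methods

## Chromosome encoding and GA operators

The search space is the 24-nt variable region of a 32-nt aptamer; the
constant flanks (5′-TTTTT, TTT-3′) are identical in every candidate and are
excluded from the chromosome because constant positions carry no
information. Each base maps to two bits, most-significant bit first —
A→00, T→01, G→10, C→11 — giving a 48-bit chromosome. The bit order within
a base is a convention of this package (any fixed order works); it is
recorded here and the encoding is exactly invertible, which the tests check
exhaustively for short regions and by property testing at full length.

One generation step draws ordered parent pairs with replacement (uniformly,
or proportionally to a non-negative fitness such as a QCM signal), applies
crossover at `n_crossover_points` cut positions, and optionally per-bit
mutation. Cuts default to *bit* boundaries because the operators act on the
binary coding: a cut between the two bits of one base can create a base
present in neither parent at that position. A `base_boundary_cuts` option
restricts cuts to whole bases, under which the per-position parental
invariant holds at base level. Mutation defaults to rate 0; it exists
because some published second-generation offspring carry bases that no
parent has at those positions, so a pure reproduction+crossover model
cannot explain them — the provenance checker (`explain_offspring`)
quantifies exactly this: it exhaustively searches ordered parent pairs and
placements of at most `max_cut_points` base-level cuts and reports the
minimum number of unexplained positions, with every minimal explanation
listed (reproduction, i.e. zero cuts, sorted first). Duplicate offspring
are permitted by default, matching observed candidate pools in which an
offspring reproduces a parent verbatim.

All stochastic operations draw from a single seeded NumPy generator, so a
generation is reproducible bit-for-bit from its config.

## Secondary-structure screen

The elimination criterion is purely structural: a candidate whose
dot-bracket string contains no brackets (every base unpaired) is removed.
When an externally computed minimum free energy (MFE) accompanies the
structure, an MFE of exactly 0 together with brackets present is flagged
but *not* removed — the criterion is the dot-bracket content, and in the
reference tables the two conditions coincide anyway. Ingestion normalizes
period-like Unicode glyphs (e.g. '…') to ASCII dots, a printing artifact
of typeset tables, and transliterates U→T since the structures come from
RNA-oriented folding servers applied to DNA.

The built-in folder is a Nussinov base-pair-maximization dynamic program:
allowed pairs default to Watson–Crick A·T and G·C (G·T wobble optional),
minimum hairpin loop 3 nt (the conventional minimal size), and the
traceback deterministically prefers the leftmost pairing partner on ties so
results are stable across runs. It is an auxiliary combinatorial screen:
it neither computes free energies nor reproduces thermodynamic
predictions, and external MFE values are always ingested, never
recomputed. Its pair counts are verified against exhaustive enumeration of
all nested pairings on short random sequences.

## Docking-score ranking

Docking itself is out of scope; score tables are inputs. Ranking uses the
ZRANK column exclusively, ascending, because a lower ZRANK energy predicts
a better complex; ZDOCK scores are carried for reporting only. Rows marked
"N.A." (candidates that never reached docking) are excluded from ranking.
Ties break lexicographically by name for determinism; the only observed tie
is an identical sequence appearing in two tables. Rank concordance between
an experimental and a simulated ordering is Spearman's ρ computed directly
from the rank pairs (the rankings are permutations, so no tie correction
applies); an independent statistics library reproduces the value in tests.

## QCM analytics

The Sauerbrey relation Δf = −2 f₀² Δm / (A √(μρ)) is applied with crystal
constants A = 0.196 cm², ρ = 2.684 g/cm³, μ = 2.947×10¹¹ g/(cm·s²). The
fundamental frequency f₀ is instrument-specific and must always be passed
explicitly (7.995 MHz is typical for the 8 MHz crystal class and is
exported as a documented constant, never silently assumed). Replicate
frequency changes are stored as magnitudes of frequency *drops*; summaries
use the sample standard deviation (n−1). Fold changes divide a candidate's
mean signal by the benchmark aptamer's mean. Analyte molarity conversion
defaults to a 33,000 g/mol molecular weight for PSA (configurable).

## SPR kinetic fitting

The sensorgram model is the 1:1 first-order Langmuir system given in the
README, continuous at the association/dissociation boundary (R₀ is the
association value at t₀). The fit is bounded nonlinear least squares over
(k_a, k_d, R_max) jointly on both phases, run in log₁₀ parameter space
because the rates span decades, from three log-spaced multi-starts
(10³/10⁻², 10⁵/10⁻³, 10⁷/10⁻⁴ for ka/kd) to guard against local minima;
residuals are weighted equally across phases. Standard errors come from
the Gauss–Newton curvature (JᵀJ) at the optimum via the delta method.
K_A = k_a/k_d is attached exactly.

Identifiability: at very low analyte concentration (k_a·C ≪ k_d, as for a
2 ng/ml protein at these affinities) the association phase determines only
k_obs ≈ k_d and the product R_max·k_a, so k_a and R_max are individually
near-unidentifiable from a single concentration. The fitter flags such
fits (`poorly_identified`, with the Jacobian condition number as the
diagnostic) and emits a warning rather than failing.

## Synthetic data

The sensorgram generator emulates the acquisition protocol of the target
assay — 30 min association, 13 min dissociation, 1 Hz sampling, analyte at
10⁻⁸ M by default — with additive homoscedastic Gaussian noise, the
simplest model consistent with the smooth curves such instruments produce.
It does not emulate drift, bulk refractive-index jumps at phase
boundaries, mass-transport limitation, or heterogeneous binding, so
parameter-recovery results bound performance on idealized data only, not
on real sensorgrams. Random populations draw bases i.i.d. uniformly. The
motif-count fitness oracle exists solely to make selection pressure
observable in an end-to-end GA test; it is not a binding-affinity model.
Recovery checks use a fit on data generated by the same model family
(a self-consistency design): noiseless recovery of both rates to <0.1 %
and a median relative error below 5 % at 1 % noise over 20 seeded
replicates.

## Problem sizes and numerical choices

Property tests sample 500 random sequences of length ≤ 10 for the folder
oracle, 20 seeded replicates for noisy kinetic recovery, and 10⁴-scale
draws for binomial checks (3σ bands); the provenance search is exhaustive
over 4 parents × ≤1 cut × 23 positions. Least-squares tolerances are set
to 10⁻¹⁴ (xtol/ftol/gtol) so the noiseless recovery is limited by the
optimizer, not the data. All tests and the acceptance script run in
seconds on one CPU.

## Known limitations

- No thermodynamic folding, pseudoknots or suboptimal ensembles; the
  built-in folder maximizes pair counts only.
- No docking, rescoring or pose handling; scores are external inputs.
- The kinetic model is strict 1:1 Langmuir — no mass-transport-limited or
  bivalent variants, and no refractive-index-to-coverage calibration.
- The exact operator settings that produced the published candidate pools
  (crossover fraction, any mutation) are not recoverable from the source
  tables; the provenance checker measures, rather than assumes, how far
  each printed offspring is from a pure crossover explanation.
- The source tables print one surface coverage in ng/mm² where the others
  are ng/cm²; the ingested fixture preserves the printed numbers and units
  and the discrepancy is noted in the loader's docstring, not resolved.
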