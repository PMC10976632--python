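# Methods

## The reduced model

The package operates on the three prolyl peptide-bond dihedrals
(ω₂, ω₃, ω₇) of a three-proline peptide, not on Cartesian coordinates.
The per-residue potential is the physical prolyl torsion term: four
dihedrals co-rotate rigidly with the peptide bond (offsets 0°, 180°,
180°, 0° for Cα–C–N–Cα, O–C–N–Cα, O–C–N–H, Cα–C–N–H on a planar peptide
unit), each contributing `V[1 + cos(2Φ − 180°)]`. Under two-fold
multiplicity the four terms coincide, so the per-bond profile is
`4V[1 + cos(2ω − 180°)]`: equal-depth minima at 0° and 180° and a barrier
of exactly `8V` at ±90° — 20 kcal·mol⁻¹ at the physical force constant
V = 2.5 kcal·mol⁻¹. The amplitude convention (V, not 2V) is fixed by this
barrier identity.

Within the reduced model the eight octant states would be degenerate, so
a state-coupling term stands in for the solvated-peptide environment
that makes the states inequivalent: each octant state s carries an energy
offset `c_s` switched on by a product of smooth periodic weights,
`w_T(ω) = sin²(ω/2)` per trans letter and its complement per cis letter.
The weights of the eight states sum to one everywhere, so the coupling is
a smooth, periodic interpolation of the offsets over the three-torus, and
the total energy is finite everywhere. `c_TTT = 0` is the reference.

**Quadrature oracle.** State probabilities are computed by midpoint
quadrature of `exp(−U/kT)` on an octant-aligned tensor grid (default 120
points per axis, required to be a multiple of 4 so ±90° fall on bin
edges). Because every octant contains the same well shape sampled on the
same relative grid, quadrature errors cancel in the probability ratios;
refining 120 → 240 points changes the probabilities by ~10⁻¹⁶ in
practice, far inside the 10⁻⁶ contract asserted in the tests.

**Calibration.** `calibrate_model` starts from `c_s = G_target(s)` and
iterates `c_s += G_target(s) − G_quadrature(s)`. Because the Boltzmann
weight of each well sits deep inside its octant (thermal width ≈ 5° at
300 K against a 90° half-width), the switching weight is ≈ 1 where it
matters and the iteration contracts geometrically; convergence to 0.002
kcal·mol⁻¹ (contract: 0.01) typically takes 3–5 iterations. Constants:
k_B = 0.0019872 kcal·mol⁻¹·K⁻¹, T = 300 K default, angles in degrees on
[−180°, 180°).

## Sampling

Dynamics is Metropolis Monte Carlo, not molecular dynamics: one sweep
proposes one wrapped-Gaussian move (σ = 20°) per angle per replica. This
is exactly Boltzmann for each replica Hamiltonian and is all the reduced
model needs. The replica ladder scales the torsion force constant
linearly from 2.5 kcal·mol⁻¹ (replica 1) to 0 (replica 12); the one-fold
trans-penalizing bias (V = 1 kcal·mol⁻¹, phase 180°) is identical in all
replicas — the scheme's defining feature, which balances cis/trans
occupation so that even octants 5–6 kcal·mol⁻¹ above all-trans are
sampled with percent-level biased probability. Neighbor exchanges follow
the Metropolis criterion on the energy cross-difference, which for this
ladder reduces to `β(V_a − V_b)(T(x_b) − T(x_a))` with `T` the unit-V
torsion sum; attempts alternate between even and odd pairs every 250
sweeps, and accepted swaps exchange configurations. The inner loop is
compiled with numba; `mc_propagate` is the plain single-chain reference
implementation used to verify the stationary distribution against the
quadrature oracle.

Exchange acceptance is reported, not asserted: it is model dependent
(0.26–0.94 across the ladder in the default recovery run, highest where
both configurations sit in wells and `T ≈ 0`).

## Unbiasing and free energies

Replica-1 frames are binned into a 50³ histogram (7.2° bins). Each bin is
multiplied by `exp(+β U_bias(bin center))` and the result renormalized;
the additive free-energy constants of the biased and unbiased ensembles
are absorbed by the normalization. Evaluating the bias at bin centers
rather than bin averages shifts the reconstructed density by < 1 % of the
peak (verified against quadrature densities, which are bin-averaged with
a 4× oversampled subgrid precisely so that histogram comparisons are
like-for-like).

Octant probabilities are composite-Simpson tensor integrals over the
±90° windows. With 50 bins, ±90° are exact bin centers; those bins enter
both adjacent octants as shared boundary ordinates (an even split). For
other bin counts the boundary ordinate is linearly interpolated between
the two straddling centers. The eight raw integrals are renormalized to
unit sum — on a noisy histogram the alternating Simpson coefficients
would otherwise leave a per-mille-level defect. Free energies are
`−kT ln P` with G(TTT) = 0; empty octants give +∞ with a warning, never
a smoothed value. The cis→trans sign convention is
`ΔG = −kT ln(P_trans/P_cis) = G_trans − G_cis` (negative = trans
favored), pinned by the reference value +0.89 kcal·mol⁻¹ for
Pro7 | Pro2=C, Pro3=T, the one cis-favoring conditional.

Errors are standard errors of the mean over statistics recomputed on five
equal contiguous frame blocks. No multi-replica estimator (WHAM/MBAR) is
used: only replica 1 is unbiased.

## Reference table and its internal consistency

`reference_state_table` chains the reported conditional free energies
into the eight-state table (CTT = 4.09, TCT = 2.06, CTC = CTT − 0.89,
TTC = CTC − 1.58, TCC = TTC + 1.86, CCT = CTT + 0.09, CCC = CTC + 2.54;
all kcal·mol⁻¹ relative to TTT). The inputs are two-decimal printed
values, so chained entries can deviate from directly reported ones by up
to ~0.02 kcal·mol⁻¹ (CCC: 5.74 vs 5.75; TCT vs the Boltzmann inversion
of the reported probabilities: 0.004). These cross-checks are exposed by
`ReferenceTable.consistency_checks` and asserted in the tests. A known
tension in the source values is left as-is: the CTT probability route
(−kT ln(0.19/89.99) ≈ 3.67) disagrees with the conditional route (4.09);
CTT has ~50 % relative probability error, both routes are implemented,
and neither is corrected.

## Synthetic data

The i.i.d. sampler draws from the quadrature-tabulated density
(inverse-CDF on a 200³ grid commensurate with the 50-bin analysis, with
in-bin jitter); it is the primary test path for the unbiasing estimators
because it isolates their correctness from sampler mixing. Geometry
fixtures plant hydrogen-bond occupancies per state (defaults: the
production state-filtered frame counts and the β-turn Ser6–Arg9
occupancies 30.8/7.2/4.3/10.7 % in TTT/TCT/CTT/CCT), NOE channels with
closed-form effective distances, and cluster structure (three
well-separated centers over two informative features plus twenty noise
features). Everything planted is recorded in a ground-truth record and
recovered exactly (occupancies) or deterministically (rankings, cluster
counts) by the tests.

What the fixtures do *not* emulate: solvent, atomistic geometry, MD
kinetics, and force-field realism. Quantities of the real solvated
peptide that depend on those — transition rates in ns⁻¹, the biased state
percentages, the Pearson correlations of a specific trajectory, per-NOE
violation magnitudes, MMGBSA energetics — are outside what passing tests
demonstrate; the tests validate the estimators and the recovery of
model-true quantities, not the chemistry.

## Recovery study and problem sizes

`recovery_study` calibrates to the reference table, runs 12 replicas for
1.6×10⁷ sweeps (saving every 40th sweep → 4×10⁵ replica-1 frames,
discarding the first 2 % as burn-in), unbiases, and reports P(TTT) and
the two headline conditionals with five-block SEMs. The run length was
chosen so the block SEM of P(TTT) is a few tenths of a percentage point
and that of the rare-CTT conditional ≈ 0.1–0.3 kcal·mol⁻¹: the slow mode
is the diffusion of configurations down the 12-level ladder (one pair
attempt per 500 sweeps per pair), and CTT — at 0.1 % unbiased and ~0.3 %
biased occupancy — is the statistics-limiting state, exactly as its large
relative error in the reference data suggests. The run takes about two
minutes on one CPU. Unit tests use much shorter runs with
self-consistent 3·SE tolerances.

## Known limitations

* The coupling term is a modeling device: its offsets reproduce octant
  free energies, not any physical interaction surface between residues.
* Boundary bins of octant integrals are split by linear interpolation;
  for well-separated states (the design regime) the density there is
  ~e⁻³⁰ of the peak and the choice is immaterial.
* `cluster_conformations` and `rank_features` wrap scikit-learn
  (HDBSCAN, RandomForestClassifier); only `min_cluster_size`, class
  weighting and the seed are pinned — remaining hyperparameters follow
  scikit-learn defaults and are documented, not asserted.
* Transition rates default to 90° labeling (every frame assigned); the
  45° convention is available via the `halfwidth` flag, with no
  transition scored across unassigned gaps.
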