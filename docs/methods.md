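# Methods

This note documents the models, conventions, and numerical choices behind
`chemevol`, and what the synthetic-data generators do and do not emulate.

## Synthetic data: the conditions the generators encode

The generators produce inputs with the statistical structure the downstream
analyses assume, at a scale matching the study design the package targets:
48 species, three independent experiments, ~30 defense compounds, four-point
dilution series per extract.

**Trees.** `simulate_tree` draws a pure-birth (Yule) tree conditioned on the
tip count, extends all tips by the memoryless waiting time to the next
(uncut) speciation event (without this the youngest cherry has zero pendant
edges and the Brownian covariance is singular), enforces exact
ultrametricity, and rescales to unit root depth. Only relative branch
lengths matter for K, PGLS, ND and ES, so unit depth loses no generality.

**Traits.** `simulate_traits` draws Brownian tips as L·z with L the Cholesky
factor of V(tree) (covariance σ²V), or iid normal tips for the signal-free
("white") model. The distribution behind "randomly generated" calibration
traits is genuinely open; both generators are provided and the calibration
defaults to iid normal, the stricter null for tree-based tests.

**Profiles.** `simulate_profiles` realizes the combining model itself:
y = μ_c + β_e + u_sc + w_sce + ε, with per-compound means μ_c ~ N(4, 1) on
the log scale, experiment offsets defaulting to (0, +0.5, −0.5), the main
random effect u_sc Brownian-structured along the tree per compound (rate
σ² = 1; switchable to iid), cell noise SD 0.3, replicate noise SD 0.2, two
replicates per cell. Raw-scale intensities are exp(y) − 0.1 (floored at 0)
so the log(x + 0.1) transform inverts the simulation exactly in the
noiseless limit.

**Feature tables.** For every nonzero species×compound, the generator emits
the [M+H]⁺/[M+Na]⁺ parental pair (per-compound Na/H response ratio drawn in
[0.3, 2] so either adduct can dominate), the protonated genin and its
one-water-loss fragment, the outer-sugar-loss fragment for di-glycosides,
and, for glucosinolates, [M−H]⁻ plus three diagnostic core fragments — all
at the compound's retention time. RT slots span 0.5–14.5 min (the
chromatographic gradient) with spacing far above the 0.05-min co-elution
window; m/z spans 50–1200. Isomer pairs duplicate a compound at a second RT.
Noise peaks are uniform over the m/z×RT domain. Not emulated: peak shapes,
intensity saturation, mass-accuracy drift, isotope envelopes, and in-source
fragmentation of co-eluting *different* compounds — so a perfect round-trip
here demonstrates the correctness of the annotation logic, not its
robustness to chromatographic pathology in real data.

**Plates.** Sample wells at dilution factors (1, 5, 50, 500) and an ouabain
calibration series (10⁻³..10⁻⁸ M) follow one 4PL on the log10-concentration
scale (defaults A = 1, B = 0.05, scal = 0.5, ouabain IC50 = 10⁻⁷ M), plus an
additive background and optional Gaussian noise.

## Annotation rules and conventions

- Default tolerances: mz_tol = 0.005 Da, rt_tol = 0.05 min (QTOF-scale);
  both configurable everywhere.
- Adduct pairing: candidate pairs must match mass(Na) − mass(H) = 21.9819
  within mz_tol and co-elute within rt_tol; conflicts resolve greedily by
  summed pair intensity with a deterministic tie-break on feature ids, and
  each feature joins at most one pair.
- Proton arithmetic includes the electron mass (0.00055 Da — below tolerance
  but kept exact).
- Genin evidence: [genin+H]⁺ or up to two sequential water losses. The
  water-loss depth is capped at 2; deeper losses exist but add little
  evidence at these tolerances.
- Chain inference enumerates sugar multisets of size ≤ 2 plus an acetyl
  flag. Mass-degenerate residue combinations exist (hexose + dideoxyhexose
  = 2 × deoxyhexose exactly), so combinations supported by an observed
  [parent − outer sugar]⁺ fragment are preferred; remaining ties break
  deterministically (fewest residues, no acetyl, residue names) and
  unresolved di-glycoside orders are flagged `order_resolved=False`.
- Isomers: compounds sharing class, genin, and neutral mass (within
  2·mz_tol) but separated in RT are indexed in ascending RT.
- The default library stores nine genins. Dihydroxy-digitoxigenin is kept by
  formula (C23H34O6) because exact mass cannot separate bipindogenin from
  strophanthidol; nigrescigenin's formula (C23H32O7) is a by-exact-mass
  assignment consistent with hydroxylation of strophanthidin. Negative-mode
  diagnostic fragments default to {96.9601, 95.9528, 74.9915, 259.0129,
  241.0024} m/z (sulfate/thioglucose core ions); the list is configurable.
- Unknown-glucosinolate candidates require ≥ 2 (configurable) diagnostic
  fragments co-eluting with an unmatched parent that is not itself a
  diagnostic fragment.
- `require_pair=False` additionally accepts unpaired [M+H]⁺ features whose
  implied neutral mass matches an enumerated library glycoside; genin
  fragments are still required. The default demands the full pair.

## Combining mixed model

Fitted by REML (statsmodels MixedLM; iteration cap 200, L-BFGS) with fixed
effects experiment + compound (reference experiment's offset defined as 0,
so μ_c is the compound mean at the reference level), a random intercept per
species×compound cell, and a variance component for the
species×compound×experiment term nested within the cell. Three degenerate
regimes bypass REML with a closed-form additive cell-means solution
(experiment offsets from experiment means, cell effects from offset-corrected
cell means): a single experiment (components unidentifiable, flagged),
data the additive structure fits exactly (the noiseless limit, where BLUP
shrinkage is 1 and the closed form *is* the ML solution), and REML
non-convergence (flagged `converged=False`). Species profile entries are
max(0, μ_c + u_sc): negative log-scale values correspond to intensities
below the reliable detection limit. Totals are reported both as sums of the
floored log-scale entries and back-transformed (exp(m) − 0.1 per positive
entry); the natural log is used throughout (base is configurable only by
rescaling, and is documented rather than parameterized).

## Chemodiversity

- Bray–Curtis is computed on row proportions; the proportion conversion is
  part of the operation and all-zero rows are rejected. Inside the
  bootstrap, column resamples can zero a species' row; there d(0,0) = 0 and
  d(0, y) = 1 (the standard extension), rather than failing.
- Ward clustering defaults to the "ward.D" convention (the Ward update
  applied to the dissimilarities as given). It is computed exactly by
  running the squared-update algorithm on sqrt-transformed dissimilarities
  and squaring the merge heights — the merge order is identical because the
  square root is monotone. "ward.D2" is a documented switch.
- Multiscale bootstrap: resampling unit is the compound column (the
  variables that define the profiles), scales default to 0.5–1.4 in steps
  of 0.1. For each cluster, z(r) = Φ⁻¹(1 − BP_r) is fitted as d·√r + c/√r
  by weighted least squares with delta-method binomial weights
  n·φ(z)²/(BP(1−BP)); AU = 1 − Φ(d − c). Clusters with BP ∈ {0, 1} at every
  scale are clamped to that bound and flagged; with fewer than two
  informative scales the BP nearest scale 1 is reported and flagged.
- PCoA: classical scaling of −½D² double-centered; coordinates only for
  eigenvalues above a 1e-10 relative tolerance; percent variance relative
  to the positive-eigenvalue sum; negative eigenvalues are reported, never
  corrected; axis signs fixed by making each axis's largest-magnitude
  coordinate positive.
- Mantel: Pearson correlation of upper triangles under simultaneous
  row/column permutation; two-sided add-one p-value (as everywhere in this
  package, p = (1 + k)/(1 + n) — unbiased and never zero).
- Tanglegram: both trees' node rotations are searched greedily (child-order
  flips, repeated passes until no improvement) to minimize total vertical
  tip displacement on unit-spaced ladders. The significance of a link-length
  difference is assessed by a permutation null that shuffles one tree's tip
  labels and re-optimizes; this scheme is a reasonable stand-in where no
  canonical test exists.

## Phylogenetic statistics

- V[i,j] is the root-to-MRCA path length; tips ordered by sorted label.
- Blomberg's K: â = (1'V⁻¹1)⁻¹1'V⁻¹x; MSE0 = (x−â)'(x−â)/(n−1);
  MSE = (x−â)'V⁻¹(x−â)/(n−1); expected ratio = [tr(V) − n/(1'V⁻¹1)]/(n−1);
  K = (MSE0/MSE)/expected. K ≡ 1 on two-tip trees (algebraic identity,
  asserted in tests). The significance test permutes tip values (the
  conventional implementation; a Brownian-simulation null is the other
  defensible reading and the permutation default is documented as a
  choice), counting permutations with MSE ≤ observed.
- PGLS solves GLS by Cholesky whitening; the F statistic compares the full
  model against the phylogenetic-mean-only model with df (p−1, n−p) — for
  one predictor, the slope test with df (1, n−2). Cross-checked against
  statsmodels GLS in tests.
- Ancestral states: the ML Brownian estimate at a node equals the GLS
  phylogenetic mean of the tree re-rooted at that node; each node is
  matched in a cloned tree by its tip set, rerooted, and evaluated. The
  root estimate equals â.
- Tip rates: ND counts the internal nodes on the root-to-tip path (root
  included — a documented, switch-free convention choice) per unit path
  length; ES = Σ_j l_j (1/2)^(j−1) with l_1 the pendant edge, rate = 1/ES.
- TRC simulation test: observed Pearson r of rates vs trait against r of
  rates vs Brownian traits simulated on the tree (rate fixed at 1 — Pearson
  r is scale-free); two-sided add-one p. The false-positive calibration
  runs ND/ES × PGLS/simulation on generated traits at α = 0.05 and counts
  traits with ≥ 2 significant tests; the simulation null distribution
  depends only on the tree and the rate vector, so it is drawn once per
  rate measure and shared across traits.

## Dose–response

Sample x is the log10 dilution factor (0, 0.699, 1.699, 2.699); calibration
x is log10 molarity. The mixed fit works internally on −x (log10 relative
concentration) so the single logistic orientation
A + (B−A)/(1 + exp((x_mid − x)/scal)) with one positive scal grid covers
both families; midpoints are reported on the input dilution scale. For each
grid scal (21 points log-spaced over [0.05, 5]; the grid contains 0.5
exactly), a joint least-squares fit over (A, B, per-extract midpoints) seeds
a Laplace-approximate maximum-likelihood fit of (A, B, m0, σ_b, σ_e) with a
Gaussian random deviate per extract on the midpoint; the conditional modes
are profiled by a damped, vectorized Gauss-Newton. The fit minimizing AIC
(k = 5) wins. Degenerate regimes (single extract; residual variance below
1e-12, i.e. the noiseless limit where shrinkage vanishes and the LS solution
is the ML solution) use the least-squares solution directly with plugin
variances. The random effect sits on x_mid only — A/B random effects are a
possible extension, not implemented. Non-specific-inhibition controls are
reported alongside, never subtracted.

Ouabain equivalents: at an extract's midpoint the well content equals the
ouabain IC50, so the undiluted well is IC50·10^x_mid molar; the preparation
chain (default 10 mg dry tissue/mL extraction, 100 µL aliquot dried and
reconstituted in 200 µL, 1:5 in-well dilution) scales back to the original
extract, and the ouabain molar mass (584.65 g/mol) converts to µg per mg dry
tissue. Midpoints outside the tested dilution range carry an extrapolation
flag. Every conversion constant is logged in the result.

## Problem sizes and what the tests show

The test suite and the acceptance script run the package at the default
conditions above: 48-tip trees with 500 replicate traits for K behavior;
48 species × 30 compounds × 3 experiments × 2 replicates for mixed-model
recovery; a 30-compound panel (22 cardenolides including two isomer pairs,
8 glucosinolates) for the annotation round-trip; 500 replicates × 199
permutations for the null-calibration KS checks (16-tip trees and 10-object
distance matrices keep each replicate cheap without changing the calibration
property being tested); 1000 traits × 999 simulations for the false-positive
calibration; 6-extract noiseless plates plus 12–20-extract noisy plates for
the 4PL. Passing these shows the algorithms are correct under their own
model assumptions; it does not certify behavior on real chromatograms,
non-Brownian trait evolution, or unbalanced experimental designs (the REML
fit handles imbalance, but the exactness guarantees quoted here are for the
balanced noiseless limit).

## Known limitations

- Stereochemically isomeric sugars of equal mass are indistinguishable by
  construction; isomer indices are positional (RT order), not structural.
- The chemotype classifier is a deterministic dominance rule; real chemotype
  assignment mixes clustering with expert judgment, so label differences on
  borderline species are expected.
- AU support values inherit the multiscale-bootstrap small-sample behavior:
  with few compounds the resample-size grid is coarse and AU for shallow
  clusters is noisy.
- The Laplace approximation is exact only as the random-effect distribution
  is well peaked; for very noisy plates with few dilutions per extract the
  variance components carry approximation error (the midpoints themselves
  are robust).
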