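# Methods

`gdpoet` models and screens short gadolinium-binding peptides. This note
documents the models, the numerical choices, and what the synthetic
generators do and do not emulate.

## Sequence–function model

A peptide's screening score (its r1 ratio — longitudinal relaxivity
relative to peptide-free GdCl3) is modelled as

    score(s) = b + Σ_i w_i · [pattern_i occurs in s]

an intercept `b` plus the weights of every rule whose pattern occurs in the
12-mer `s`. Contribution is presence-based: a rule adds its weight once no
matter how many windows match. An occurrence-count mode
(`EvolutionConfig(scoring_mode="count")`) is available for sensitivity
analysis. The intercept lets the empty model represent the free-Gd level
(r1 ratio 1) and is initialized to the training-label mean.

Two pattern dialects exist. `motif` patterns are literal substrings.
`regex` patterns are fixed-length token strings — literal, character class
`[XYZ]`, negated class `[^XYZ]`, or wildcard `.` — matched against every
window of their own length. Quantifiers and anchors are deliberately
excluded: fixed-length tokens keep matching linear-time and make the
correctness oracle (an exhaustive window scan) trivial, at the cost of not
expressing variable-gap motifs.

## Evolution

Rule sets evolve by generational GP: tournament selection (size 4, ties
broken by fewer rules then earlier creation), uniform rule-exchange
crossover (each parent rule goes to exactly one child, so rule count is
conserved; children over `max_rules` drop their lowest-|weight| rules), and
five structural/numeric mutations each gated independently by
`rule_mutation_rate`: add a random rule, delete a rule, perturb one weight
by Normal(0, `weight_mutation_sigma`), substitute one token, grow/shrink a
pattern by one token. The weight-perturbation operator treats the intercept
as one more tunable coefficient (drawn uniformly from rule weights ∪
{baseline}); without this the intercept could never leave its initial
value, and no rule set could fit a library whose label mean differs from
the generating intercept.

Fitness is training RMSE plus a parsimony penalty of 0.001 per rule —
enough to prune rules that never fire, small enough (an order below the
label noise of interest) not to distort weight estimates. Elitism (1
individual) makes the best penalized fitness non-increasing per
generation. Defaults: population 200, 500 generations, crossover 0.9,
mutation gate 0.3, sigma 0.1, max 20 rules. These are budget choices, not
science; all are config-exposed, and every run is reproducible from
`rng_seed` alone (a single `numpy.random.Generator` drives the run).
Per-pattern match vectors over the training set are cached, so a full
default-budget run on a 74-peptide library takes seconds, not minutes.

## Candidate design

`design_epoch` proposes up to 10 candidates per epoch by multi-restart
hill climbing over single-residue substitutions (50 restarts × 500 steps by
default). Presence-based scoring is piecewise constant — a rule contributes
nothing until its whole pattern is present — so a strict-ascent climber
stalls on plateaus. Two standard remedies: sideways (equal-score) moves are
accepted, and half the restarts start from a random 12-mer with the
realization of one positive-weight rule implanted at a random window.
Diversity is enforced greedily in score order: a candidate is kept only if
it is ≥ 3 Hamming mutations from every kept candidate and every training
sequence (edit distance adds nothing at fixed length 12). Infeasible
constraints yield a smaller panel plus a logged warning, never fabricated
sequences; a warning is also logged if the search saturates below the best
training score.

## Relaxometry

The variable-TR saturation-recovery signal is modelled as
S(TR) = A·(1 − exp(−TR/T1)), fit by bounded Levenberg–Marquardt
(`scipy.optimize.curve_fit`) with A initialized at the signal maximum and
T1 at the TR where the signal crosses (1 − 1/e)·max (linear interpolation —
exact on noiseless data). A constant-offset third parameter is available
(`with_offset=True`) for noisy baselines. Fits whose T1 falls an order of
magnitude below the smallest TR are rejected as degenerate (a flat curve
carries no T1 information on this grid). The default TR grid is the
nine-point preclinical protocol (33–12496 ms).

Relaxivity is the OLS slope of 1/T1 (s⁻¹, T1 converted from ms before
inversion) on concentration (mM): 1/T1 = 1/T1⁰ + r1·[CA]. The blank well
enters the regression as an ordinary point; the intercept estimates 1/T1⁰
rather than being pinned. The r1 ratio is the slope ratio
sample/reference; a single-concentration alternative
(`rate_enhancement_ratio`, ratios of 1/T1 − 1/T1⁰) exists behind its own
function for high-throughput use. Concentration columns must be explicitly
millimolar (`concentration_mM`); a bare `concentration` column is accepted
only with `assume_mM`.

## Physicochemistry

Net charge is the Henderson–Hasselbalch sum over N-terminus, K, R, H
(positive) and C-terminus, D, E, C, Y (negative), assuming free termini
(modification flags are out of scope). The sum is strictly decreasing in
pH, so the isoelectric point is the unique zero in (0, 14), found by
bisection to 1e-6 pH (comfortably inside the 1e-3 charge tolerance at the
root). The default pKa set is Lehninger (N-term 9.69, C-term 2.34, D 3.65,
E 4.25, C 8.33, Y 10.07, H 6.00, K 10.53, R 12.48); EMBOSS and Sillero
tables are bundled, and every result records the table used. Absolute
charges and pI values shift by a few tenths between tables; sign and
threshold conclusions (e.g. "strong binders are negative at buffer pH 5.3")
are table-robust for the bundled screening peptides.

Composition pools residue counts over a peptide set into 20 fractions and
aggregates them into the seven standard side-chain classes (acidic, basic,
aliphatic, aromatic, hydroxylic, sulfur-containing, amidic — a partition of
the alphabet). Enrichment against a reference profile is
log2((f_t + p)/(f_r + p)) with pseudocount p defaulting to 1/n_residues of
the target, keeping ratios finite for absent residues.

## Screening statistics

The ratio-vs-absolute-relaxivity link is a Pearson correlation with the
exact two-sided p-value from t = r·√(n−2)/√(1−r²) on n−2 df
(`scipy.stats.pearsonr`). The peptide-free GdCl3 row is excluded by
default: it anchors the ratio scale at 1 by construction and is not a
peptide observation (including it is supported and roughly halves R² on
the bundled table). "Beneficial" means r1 ratio strictly greater than 1,
the free-Gd level. The bundled screening table's improvement percentages
use the EF1 row's absolute r1 (23 mM⁻¹s⁻¹) as reference — the arithmetic
that reproduces the table's published summary figures; the EF3 row's value
(19) gives larger numbers, a discrepancy the package records rather than
resolves.

## Synthetic data

`simulate_library` emulates the screening library: uniform random 12-mers
(the real training library has near-uniform residue usage), a planted rule
set generating labels, optional Gaussian label noise, and a guaranteed
carrier fraction achieved by implanting a planted rule's realization at a
random window (rejection sampling would be unreliable at n = 74). The
default ground truth — intercept 1.0 plus motif DDD at +0.8, 30% carriers,
library size 74 — puts non-carriers at the free-Gd level and carriers near
the top of the observed 0.9–2.3 screening range. What it does not emulate:
measurement-batch effects, peptide synthesis failures, multi-motif epistasis
or any real sequence–relaxivity physics — passing recovery tests shows the
estimator works when its own model assumptions hold, not that the model is
true of real peptides.

`simulate_dilution` forward-models Eq.-style dilution series: T1 per
concentration from the planted r1 and T1⁰, ideal saturation-recovery
signals on the 9-TR grid, additive Gaussian noise of sd
noise_fraction·amplitude, clipped at zero. At zero noise the full
fit_t1 → fit_r1 pipeline returns the planted r1 to ~1e-7 relative.

## Problem sizes in the test and acceptance runs

Planted-model recovery runs at the study's library size (74) with the
default GP budget; the held-out check uses an 80/20 split, label noise
sd 0.1, median over 5 seeds. Relaxometry Monte-Carlo checks use 100–200
noise replicates at 1% amplitude noise; matcher and pI oracle-equivalence
checks use 10⁴ random pattern/sequence pairs and 500 random peptides
against a 0.001-pH grid. These sizes make the whole suite run in a couple
of minutes on one core while keeping every estimate's Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

- The regex dialect cannot express variable-length gaps or positional
  anchoring; motifs spanning both termini are out of reach.
- The GP fits weights by mutation, not by closed-form regression on the
  match matrix; it converges but spends generations on numeric polishing.
- pI/charge values are pKa-table conventions, not measurements; only
  relative/sign statements should be compared across tools.
- The relaxometry module fits well-averaged signal curves; voxelwise T1
  mapping, B1 correction and image I/O are out of scope.
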