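# Methods

This note documents the models, algorithms and design decisions in
`nmrkrr`: what is computed, under which assumptions, with which defaults,
and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

Given a 3-D molecular structure (element symbols + Cartesian coordinates,
Å), predict per-atom NMR parameters — δ¹H and δ¹³C chemical shifts (ppm)
— and per-bonded-pair one-bond ¹J_CH couplings (Hz). Training labels are
assumed to come from a deterministic electronic-structure method applied
to the same geometries; the machine's job is to reproduce that
geometry→parameter mapping at negligible cost. All predictions are
single-conformer: conformational averaging, solvent effects and the
generation of the 3-D geometries themselves are outside the model.

## Atomic-environment representations

Both families are functions of interatomic distances and angles only, so
they are exactly invariant to rigid motions, and their dimension is fixed
by hyperparameters, never by molecule size.

**Coulomb row.** The atom's row of the molecular Coulomb matrix:
self-term 0.5·Z^2.4 first, then Z_i·Z_j/r_ij (r in Bohr; 1 Å =
1.8897261 Bohr) sorted by descending magnitude — ties broken by neighbour
distance, then atomic number, for determinism — zero-padded to
`max_atoms`. Two-body information only; kept as the baseline family.

**Local many-body representation (`local_mbr`, default).** For centre i:

* one 2-body block per element E in `element_set`: the radial density of
  E-neighbours, Σ_j f(r_ij)·exp(−(g−r_ij)²/2w²), sampled at `n_radial`
  points g over (0, r_cut], with the smooth cutoff
  f(r) = ½(cos(πr/r_cut)+1) for r < r_cut and exactly 0 beyond;
* one 3-body block per unordered element pair: the distribution of angles
  θ_jik, Σ_{j<k} f(r_ij)f(r_ik)·exp(−(a−θ_jik)²/2w_a²), sampled at
  `n_angular` points a over [0, π].

Defaults: r_cut = 5 Å, n_radial = 48, n_angular = 12, radial width
w = 0.1 Å, angular width w_a = 0.2 rad, element_set = (H, C, N, O, F).
The radial resolution matters: chemically meaningful bond-length
variation is of order 0.01–0.05 Å, and a smearing width much larger than
that (e.g. 0.3 Å) measurably erases the C–H bond-length signal that
one-bond couplings depend on — with w = 0.3 Å the coupling model's
held-out error rises by ~15–40% relative. The angular width is a separate
parameter because angles are dimensionless; 0.2 rad resolves
tetrahedral-vs-trigonal differences without fragmenting the distribution.

## Kernel ridge regression

Scalar kernel on environments x, y (vectors under identical
representation parameters):

* laplacian (default): k = exp(−‖x−y‖₁/σ)
* gaussian: k = exp(−‖x−y‖₂²/2σ²)

Both lie in (0, 1] with k(x,x) = 1. The Laplacian default follows the
common pairing of L1 kernels with smeared-density atomic representations;
on the synthetic benchmark it is uniformly more accurate than the
Gaussian (e.g. δ¹³C held-out MAE ~1.0% vs ~1.4% of the label range). σ
defaults to the median pairwise distance among (a ≤400-point subsample
of) the training representations.

Couplings involve a (carbon, hydrogen) environment pair; pair similarity
is the product k(a_C,b_C)·k(a_H,b_H). The ordering is enforced by a typed
pair container, so carbon environments are never compared to hydrogen
environments.

Fitting solves (K + λI)α = y by Cholesky factorisation and verifies the
residual ‖(K+λI)α − y‖∞ < 1e-8·max(1, ‖y‖∞); a non-positive-definite
system raises with advice to increase λ. Targets are centred before the
solve and the mean restored at prediction, keeping α comparably scaled
across ppm (~0–200) and Hz (~100–250) label ranges. Default
λ = 1e-8·n_train (kernels have unit diagonal). Since the published
machines' σ/λ are not available, a structure-level k-fold CV grid search
(`hyperparam_search`) is provided; folds always split by structure so no
molecule straddles train and validation.

## Ensemble variance, filtering, adaptive sampling

A k-fold ensemble (k = 5) shuffles the labelled structures into k seeded
folds and trains one model per fold on the other k−1 folds. For a target,
the prediction is the mean of the k fold predictions and the "spread" is
their population standard deviation — linear units (ppm/Hz), chosen over
squared units because the filter cutoffs are stated in linear units; a
config flag exposes the squared-units reading. When all fold predictions
coincide the spread is exactly 0.

**Filter.** A prediction is kept when spread ≤ cutoff (inclusive
boundary, documented). Default cutoffs: 1 Hz (¹J_CH), 0.1 ppm (δ¹H),
5 ppm (δ¹³C) — the published compromise between accuracy and coverage for
a production-scale machine. At desk scale the appropriate cutoff is
smaller; the examples use a spread quantile instead.

**Adaptive sampling.** Iteration 0 draws `initial` structures uniformly
(seeded). Each iteration trains a k-fold ensemble on the current set
(fold split re-randomised each iteration, seeded), predicts every
remaining superset structure, scores each structure by the **mean** of
its environments' spreads (max available via flag; mean is robust to a
single odd atom), breaks ties by structure id, and moves the top `batch`
into the training set. With several parameters trained jointly, spreads
are z-scored within each parameter before averaging so ppm and Hz are
commensurable. Defaults initial = batch = 100 (production scale);
desk-scale tests use 10/10.

## Calibration

Raw isotropic shieldings σ are referenced to shifts by a line fitted on
calibration pairs, σ = slope·δ + intercept (OLS), inverted exactly at
prediction: δ = (σ − intercept)/slope. Published slope/intercept values
are configuration inputs, not constants, because they depend on the
electronic-structure level. Predicted couplings may carry a systematic
offset relative to experiment; `fit_offset` estimates it as
mean(expt − pred) and `apply_offset` adds it elementwise, which zeroes
the mean residual identically. Calibration is optional and sits upstream
of training — the pipeline accepts ready shifts or raw shieldings plus a
scaling; offsets are applied before filtering when both are active.

## Evaluation and discrimination

Error triples are MAE/RMSE/MaxE (maxe ≥ rmse ≥ mae enforced). Learning
curves train on nested, seeded subsets (within a repeat, larger sets
contain smaller ones) against a fixed held-out set. Candidate geometries
for one molecule are ranked by the geometric mean of their per-parameter
MAEs against the experimental labels (arithmetic mean available);
single-parameter runs reduce to that parameter's MAE. When a variance
filter is active during ranking, any key whose spread exceeds the cutoff
for *any* candidate is dropped for *all* candidates, so every candidate
is scored on identical support — a fairness choice this package makes
explicitly.

## Synthetic benchmark

The generator emulates the *statistical* structure the method assumes; it
is not quantum chemistry.

**Geometries.** A random tree of 4–12 heavy atoms (first always carbon;
others drawn per regime weights over C/N/O/F), bond lengths 1.2–1.6 Å,
branching directions rejected until bond angles at the parent exceed 80°
and all interatomic distances exceed 0.9 Å; hydrogens fill carbon valence
at 1.09 ± 0.02 Å. Everything is deterministic given a seed.

**Labels.** Each atom carries u_i = Σ_j w(elem_j)·Z_j·exp(−r_ij/2.0 Å),
squashed by squash(u) = u/(25 + u). Shifts are base + range·squash(u)
with ranges 0–10 ppm (¹H) and 0–200 ppm (¹³C). Couplings are
100 + 150·g Hz with g = ½·clip((1.19 − r_CH)/0.2, 0, 1) + ½·(ā/π), where
ā is the cosine-cutoff-weighted mean H–C–X angle over the carbon's other
neighbours within 1.8 Å (½ when there are none) — smooth in every
coordinate, like everything the representations encode. Bonded C–H pairs
(r < 1.2 Å) are fixed at generation time and recorded in the labels.
Element weights default to 1 except fluorine = 3: fluorine's outsized
pull on shielding is the real-data analogue, and it places fluorine-rich
molecules in a latent region a C/N/O training set never visits. The
u_scale of 25 keeps squash from saturating there, so those environments
are genuinely mispredicted — not merely different — when absent from
training. The canonical heterogeneous fixture is 90% C/N/O molecules and
10% fluorine-rich ones. Label noise defaults to zero (labels stand in
for a deterministic method); Gaussian noise per parameter is available
for noise-floor studies.

**What passing tests show — and don't.** On this benchmark, KRR with
`local_mbr` recovers the oracle to ~1% (shifts) and ~4.6% (couplings) of
each label range from 200 molecules; learning curves fall monotonically;
ensemble spread correlates positively with error (pooled Spearman ρ ≈
0.28 over >2000 targets); quantile filtering lowers kept-MAE in 10/10
seeds; adaptive sampling beats random selection at equal size in 8/10
seeds; and the unperturbed geometry wins the decoy ranking in ≥9/10
seeds. These demonstrate that the machinery is correct and that its
statistical claims hold when the data-generating process is smooth,
local, and heterogeneous in the assumed way. They do not establish
accuracy on real molecules: real electronic effects are not a smooth
function of a 5 Å neighbourhood alone (conjugation, ring currents,
through-bond effects), real datasets are redundant and biased, and real
label noise is structured. Problem sizes (120–200-molecule supersets,
40–60-molecule held-out sets, 10-seed repetitions) are the package's
desk-scale choices; all are parameters.

## Numerical choices and degenerate inputs

* Cholesky with explicit residual check; failure advises a larger λ.
* Coulomb-row tie-break: distance, then atomic number.
* Cutoffs are smooth and reach exactly 0 at r_cut (true locality).
* Spread uses the population SD (ddof = 0) over k fold predictions and is
  forced to exactly 0 for coincident folds.
* Filter boundary is inclusive (spread = cutoff is kept).
* Isolated atoms yield all-zero `local_mbr` vectors and baseline oracle
  labels; single-point calibration sets and degenerate (all-equal) shift
  calibrations raise.
* Oracle noise draws from a generator seeded by (oracle seed,
  crc32(structure id)), so labels are independent of evaluation order.

## Known limitations

* `local_mbr` is a documented stand-in with the 2-/3-body information
  content of the established many-body families, not a reimplementation
  of any of them; absolute accuracies are not transferable.
* The coupling oracle's angular term makes ¹J_CH the hardest target
  (~4.6% of range at n = 200); shift targets are easier by ~4×.
* Ensemble spread is a coverage signal, not a calibrated posterior; the
  absolute production cutoffs (1 Hz / 0.1 ppm / 5 ppm) are meaningful
  only at production training scale.
* No periodic systems, no conformer ensembles, no neural baselines, no
  sparse kernel approximations.
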