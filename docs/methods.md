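# Methods

## Edge space

All edge-vectorized quantities share one frozen ordering: 0-based,
row-major upper triangle with i < j and the diagonal excluded, so edge
k = i·p − i(i+1)/2 + (j − i − 1) for a p-region parcellation and
m = p(p−1)/2 edges (34,716 at p = 264). The ordering is the one
`numpy.triu_indices(p, 1)` produces; `edge_to_pair` inverts the closed form
with an integer guard so the bijection is exact at any p. Freezing the
ordering matters because every downstream map display, weight import, and
cross-cohort comparison assumes it.

## Connectivity estimation

FC is the sample Pearson correlation between demeaned regional timeseries.
Constant (dead) regions have undefined correlations; their edges are set to
0 with a warning record rather than aborting, so one dead region cannot
kill a batch run.

Partial correlation uses a shrinkage-regularized covariance
Σ_λ = (1−λ)S + λ·diag(S) with the maximum-likelihood denominator T.
Partial correlations are invariant to the T vs T−1 choice, but the
convention is fixed for reproducibility. λ defaults to 0.1, which keeps
Σ_λ positive definite whenever every region has nonzero variance —
including T < p, where the unregularized problem is singular. At λ = 0 a
singular covariance raises an explicit error instructing the caller to
raise λ; no silent jitter is added, because jitter would make results
irreproducible across platforms. Fisher transforms clip |r| at 1 − 1e−6
before atanh so round trips are finite and exact to < 1e−12 for
|r| ≤ 0.999.

## Association maps

Correlations use the Pearson formula throughout; with a 0/1-coded binary
phenotype this is the point-biserial correlation, so one code path serves
edges, SNP dosages, components, and phenotype–phenotype pairs. Two-sided
p-values come from the exact t reference distribution (not a normal
approximation), and the multiple-testing family is the m features of the
current map — edges or SNPs, never pooled across modalities. Complete
cases are taken per feature: SNPs with missing genotypes keep their own
n_used instead of forcing listwise deletion across the whole matrix.
Zero-variance features get r = 0, p = 1; a zero-variance phenotype is an
error, since every feature would be degenerate. Top-k ranking is by |r|
descending with ties broken by ascending feature id for determinism; with
equal n per feature this coincides with ranking by p, and the two can
diverge only when per-feature missingness differs.

The "is map A's signal a subset of map B's" question is operationalized as
the containment fraction |top_kA(A) ∩ top_kB(B)| / kA. The audit defaults
are kA = 20, kB = 50: kA matches the top-k list sizes used elsewhere, and
kB is small enough that containment in it is informative but large enough
to cover a planted effect set with room for sampling noise.

## Prediction against null models

"Bootstrap repetitions" are implemented as repeated random 80/20
train/test splits (Monte-Carlo cross-validation): a held-out test set must
exist for a test metric, and mean ± sd over repetitions is the natural
summary. Classification splits are stratified per class (proportions
preserved within ±1 subject) so no split loses a class. Features are
z-scored with training-split statistics only; top-k feature selection
ranks by |training-split correlation with the target|, also inside the
split, so the test set never leaks into selection.

Models are ridge regression (RMSE) and logistic regression (accuracy).
The fixed defaults are α = 1 and C = 1; `tune=True` replaces them with an
inner 5-fold grid (α over 10^0..10^5, C over 10^−3..10^2). The confound
audit tunes by default: with m ≈ 200 standardized edges and n ≈ 600, an
α = 1 ridge fit overfits noise badly enough to lose to the null even when
a perfectly decodable group signal is present (measured here: test RMSE
19.2 vs null 15.9 on the reference confound cohort, recovering to 15.0 at
CV-selected α ≈ 10³), which would make every audit verdict "inconclusive"
regardless of the data. Tuning is per training split, so it costs 5× grid
size fits but no leakage.

Null baselines are computed on the same test split as the model: the
training-mean predictor for regression (its RMSE is the test-set standard
deviation around the training mean) and the training-majority-class
predictor for classification. Significance against the null is a
one-sided paired Wilcoxon signed-rank across repetitions at α = 0.05 — a
nonparametric default chosen because per-repetition metric differences are
paired, few (≈20), and not plausibly normal; the procedure name is stored
in every result so an alternative can be swapped in and audited.
Both the per-repetition mean ± sd and the best single repetition are
reported, since summaries of either kind appear in practice.

Transfer evaluation refits the classifier per repetition on a bootstrap
draw (with replacement) of the training cohort and scores the full test
cohort and named subgroups; the alternative single-fit reading (one model,
bootstrap-resampled test sets) is available via
`refit_per_repetition=False`. Standardization always comes from the
training side.

The audit verdict is mechanical: *confounded* iff whole-cohort prediction
significantly beats its null and no within-group prediction does;
*not-confounded* if any within-group prediction stays significant;
*inconclusive* if the whole cohort itself is not significant. Groups
below 20 subjects are skipped with a warning rather than producing
unstable fits.

## Synthetic cohorts

The generator emulates the statistical skeleton of a two-ancestry
developmental cohort, not its physiology: edge effects are additive on the
Fisher-z scale and back-transformed (so r stays in range for any effect
size δ), noise is i.i.d. Gaussian per edge, and there is no hemodynamic
autocorrelation, site structure, or linkage disequilibrium. Passing tests
therefore demonstrate that the *inference machinery* behaves correctly
under known ground truth — they do not certify performance on real BOLD
data, where effect sparsity, noise correlation, and site confounds are
harsher.

Reference conditions (the defaults): n = 600 subjects, p = 20 parcels
(m = 190 edges), group-B proportion 0.445 (a roughly 55/45 two-ancestry
split), δ = 0.3 on 40 planted edges over baseline z₀ = 0.3 with edge noise
σ_z = 0.2, score means 102 vs 90 at σ_w = 15 — a −0.8 standardized-score
group gap on a scale where the null RMSE lands near 15, keeping synthetic
outputs on a familiar achievement-test footing. SNPs: 200 loci, ancestral
frequencies uniform on [0.1, 0.9], Balding–Nichols divergence F_ST = 0.1,
10% missing genotypes (so presence filters have work to do). In the
`direct`/`mixed` scenarios the score-effect β defaults to
σ_w / (σ_z √|S_direct|), making the direct-path signal variance equal the
score noise variance (within-group R² = 0.5). Age and sex are drawn
independently of the score by construction.

All randomness flows from one seed through a fixed substream order
(structure, group labels, edges per task, score noise, SNP dosages,
missingness, age, sex, education), so adding a modality never perturbs
earlier draws and identical specs are bit-identical.

`plant_snp_overlap` marks k SNPs as strongly group-diverged and k as
score-affecting with a chosen overlap. Two deliberate design choices keep
the planted structure identifiable: the diverged SNPs get a fixed ±0.25
frequency shift (rather than another Balding–Nichols draw, whose spread
would let planted SNPs land arbitrarily close to background), and the
direct SNP→score effect acts on dosage centered at its *group* expectation,
so the planted effect cannot inflate the between-group score gap and
collapse the score map onto the ancestry map. The default per-dosage
effect (γ = 30 score units) makes the direct-path correlation (≈ 0.22)
exceed the group-induced correlation on diverged-only SNPs (≈ 0.04) by
more than three sampling standard errors at n = 800; recovered top-20
overlaps still scatter ±2 around the planted count at that n, which is the
honest sampling tolerance the tests assert.

## Data model and I/O

Cohorts live in a directory with a YAML manifest naming a phenotype CSV,
per-task connectivity payloads (CSV or HDF5), and an optional SNP dosage
TSV — a deliberately language-neutral layout that any toolchain can read
or write. Subjects present in phenotypes but missing a modality are kept
as all-NaN rows and flagged, never silently dropped, so cohort counts stay
honest. Missing phenotype values are handled complete-case per analysis:
they never satisfy a subgroup predicate, and correlations/regressions drop
them pairwise. SNP dosages keep missingness explicit (NaN) internally;
the ≥-k-subjects presence filter is decided on the missingness mask, and
zero-fill happens only when a model or correlation asks for a dense
matrix — filtering zero-filled values would conflate "missing" with
"homozygous major". The two-level ancestry column is stored both as a
categorical label and a 0/1 code, with the coding recorded where masks are
built.

PCA runs over subjects × edges, centered but not scaled (scaling would
erase FC magnitude structure), with a deterministic sign convention: the
largest-|loading| entry of each component is made positive, so repeated
runs are bit-identical.

## Problem sizes

Tests and the acceptance script run the reference conditions at p = 20
(190 edges) with cohorts of 300–800 subjects, 50-seed null batteries, and
20-seed accuracy comparisons — sizes chosen so the full battery completes
in a few minutes on one core while keeping every statistical margin at
three or more standard errors. The p = 264 edge-space arithmetic is exact
at full scale.

## Known limitations

- The null-comparison test treats the 20 split metrics as exchangeable
  pairs; splits share subjects, so the effective sample size is smaller
  than 20 and the test is mildly anticonservative. Verdicts near
  α = 0.05 deserve a rerun at a different seed.
- Bonferroni control is per map; analyses that scan many phenotypes
  multiply families without further correction.
- Transfer evaluation applies training-cohort standardization only; no
  site harmonization is attempted.
- The generator's Gaussian, LD-free SNPs and independent edges make power
  estimates optimistic relative to real cohorts.
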