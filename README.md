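# connaudit

Headless analysis of functional-connectivity (FC) and imaging-genomics
cohorts, with a focus on **demographic confound auditing**: does a model
that predicts a behavioural score from brain connectivity actually use the
score, or is it quietly predicting ancestry, sex, or socioeconomic status?

It is written for neuroimaging and imaging-genomics researchers who work
with edge-vectorized connectomes (e.g. the 264-region parcellation with
p(p−1)/2 = 34,716 edges), phenotype tables, and SNP dosage matrices, and
who want the exploratory analyses a GUI would offer — association maps,
subgroup comparisons, prediction-vs-null checks — as scriptable, seeded,
reproducible library calls.

## What it computes

**Connectivity.** For a region × time BOLD matrix, FC is the Pearson
correlation matrix; partial-correlation (PC) connectivity comes from a
shrinkage-regularized precision matrix: with Σ_λ = (1−λ)S + λ·diag(S) and
Θ = Σ_λ⁻¹, pc_ij = −Θ_ij / √(Θ_ii Θ_jj). Maps convert between symmetric
matrix and edge-vector form under one frozen ordering (row-major upper
triangle, i < j), and between Pearson-r and Fisher-z (z = atanh r) scales.

**Association mapping.** Every feature (edge, SNP, or PCA component) is
correlated with a phenotype (point-biserial for 0/1 phenotypes); two-sided
p-values come from t = r√((n−2)/(1−r²)) on n−2 df, corrected by Bonferroni
over the m features of the map (p_adj = min(1, m·p)); display maps show
−log10 p_adj clipped at 5. Ranked top-k lists support overlap counts and
containment fractions between maps.

**Prediction vs null.** `bootstrap_predict` runs repeated 80/20 train/test
splits (default 20) of ridge regression (RMSE) or logistic regression
(accuracy), each compared on the same test split to a null predictor
(training mean / training majority class); significance is a one-sided
Wilcoxon signed-rank across repetitions. Variants: top-k feature models
(selected on the training split only), within-group stratified prediction,
and cross-cohort transfer.

**Confound audit.** `confound_audit` combines the pieces: target
distribution per group, feature–target vs feature–confound association maps
with a containment fraction, and whole-cohort vs within-group prediction.
Verdict: *confounded* iff the whole cohort beats the null but no subgroup
does.

**Synthetic cohorts.** A seeded generator plants group effects on chosen
edges (additive on the Fisher-z scale), group-dependent or genuinely
connectivity-driven scores, and ancestry-differentiated SNPs under the
Balding–Nichols model (allele frequencies Beta-distributed around an
ancestral frequency with divergence F_ST). Scenarios `confound`, `direct`,
`mixed`, `null` give ground truth for every pipeline stage.

## Worked example

```python
from connaudit import SplitSpec, SyntheticSpec, confound_audit, generate_cohort

cohort = generate_cohort(SyntheticSpec(n=600, scenario="confound", seed=0))
report = confound_audit(cohort, "wrat", "race", "rest", SplitSpec(seed=0))
print(report.verdict)
```

Running `python examples/03_confound_audit.py` prints:

```
--- scenario: confound ---
group   n  target_mean  target_sd
    A 320   102.373716  15.103860
    B 280    91.110752  14.723733
whole cohort : RMSE 15.05 ± 0.99  (null 15.86)  significant=True
within      A: RMSE 14.42 ± 1.26  (null 14.42)  significant=False
within      B: RMSE 14.73 ± 1.25  (null 14.68)  significant=False
containment of score map in group map: 1.00
verdict: confounded
```

Read: the two groups differ by ~11 score points; predicting the score from
all 190 edges beats the null on the whole cohort (15.05 vs 15.86 RMSE,
significant over 20 splits) but within either group the model does no
better than predicting the group mean — and every score-associated edge
sits inside the group-associated map. The apparent FC→score signal is the
group difference in disguise, so the verdict is *confounded*. In the
`direct` scenario (score truly driven by connectivity) the within-group
predictions stay significant and the verdict flips to *not-confounded*.

The other examples cover FC vs partial correlation on a chain dependence
(`01`), Bonferroni association maps (`02`), SNP filtering and top-20
overlap (`04`), and cross-cohort transfer plus PCA (`05`). A thin CLI
mirrors the library (`connaudit synth|fc|assoc|groups|predict|audit|
transfer|pca|weights|report`); every run writes a `run.json` with the
parameters needed to reproduce it.

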