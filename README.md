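# dxeval

Evaluation of single diagnostic tests against a binary reference standard:
confusion-matrix performance indicators with 95% confidence intervals,
ROC/AUC analysis with DeLong intervals, optimal-cutoff selection and
bootstrap ROC confidence bands — as a scriptable Python library with a
small command-line interface, spreadsheet I/O and a synthetic-data
generator.

## The problem

Before a laboratory or clinical test is adopted, its ability to separate
diseased from non-diseased individuals has to be quantified against a
reference (gold) standard. The core quantities all derive from the 2×2
cross-tabulation of dichotomized test result vs disease status
(TP, FP, FN, TN):

- **Sensitivity** Se = TP/(TP+FN) and **specificity** Sp = TN/(TN+FP),
  with Wilson score intervals (better small-sample behaviour than Wald):

      CI = [ (p̂ + z²/2n) ± z·√(p̂(1−p̂)/n + z²/4n²) ] / (1 + z²/n)

- **Accuracy** (TP+TN)/N, also with a Wilson interval.
- **Predictive values** conditioned on a *user-supplied population
  prevalence* pr via Bayes' theorem — the sample prevalence of a
  case-enriched study cohort is deliberately not used:

      PPV = Se·pr / (Se·pr + (1−Sp)(1−pr)),
      NPV = Sp(1−pr) / (Sp(1−pr) + (1−Se)·pr)

  Their bounds are propagated conservatively by evaluating these
  expressions at all four combinations of the Se and Sp interval limits.
- **Likelihood ratios** LR+ = Se/(1−Sp), LR− = (1−Se)/Sp with Simel-style
  log-scale intervals, e.g.
  `exp( ln LR+ ± z·√(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)) )`.
- **Youden index** J = Se + Sp − 1 with the sum-of-binomial-variances
  normal interval.
- **ROC/AUC** for a quantitative marker: the empirical curve over all
  candidate thresholds, AUC equal to the Mann–Whitney probability
  P(X_case > X_control) with ties counted ½, and a DeLong
  placement-value confidence interval. The **optimal cutoff** minimises
  the Euclidean distance √((1−Se)² + (1−Sp)²) to the top-left corner of
  ROC space; a stratified bootstrap (5000 iterations by default) provides
  a pointwise 95% sensitivity band for the plot.

All intervals use z = 1.96 (fixed 95% level); displayed values are
rounded half-up to 3 decimals; any zero denominator yields a missing
value (`NA` in rendered tables), never an exception.

## Worked example

```python
from dxeval import DiagnosticTest, SyntheticConfig, generate

df = generate(SyntheticConfig(n=113, seed=42))          # Disease, Test1, Test2
res = DiagnosticTest.from_dataframe(df, "Test1", "Disease",
                                    prevalence=0.1).fit(n_boot=5000, seed=7)
print(res.summary())
```

```
Diagnostic test evaluation
==========================
Observations: 113 (diseased: 70, non-diseased: 43; dropped: 0)
Test type: quantitative
Prevalence (population): 0.1
Direction: higher_is_positive
Optimal cutoff: 1.509 (Se = 0.714, Sp = 0.698, distance = 0.416)

Confusion matrix: TP=50  FP=13  FN=20  TN=30

      metric estimate ci_lower ci_upper
 Sensitivity    0.714    0.599    0.807
 Specificity    0.698    0.549    0.814
    Accuracy    0.708    0.618    0.784
         PPV    0.208    0.129    0.325
         NPV    0.956    0.925    0.974
         LR+    2.363    1.465    3.809
         LR-    0.410    0.269    0.623
Youden index    0.412    0.239    0.585
         AUC    0.749    0.655    0.842
```

Reading this: the marker discriminates moderately (AUC 0.749); the
selected cutoff 1.509 favours case detection (Se 0.714 > Sp 0.698). At a
population prevalence of 10%, a positive result only raises the disease
probability to about 21% (PPV), while a negative result is strongly
reassuring (NPV 0.956) — the classic signature of testing in a
low-prevalence population. `res.plot_roc("roc.png")` renders the curve
with its bootstrap band, the cutoff marker and the AUC annotation;
`res.save_metrics("metrics.xlsx")` and
`res.save_confusion_matrix("cm.xlsx")` export the tables.

The same analysis from a shell:

```bash
dxeval simulate --n 113 --seed 42 --out data.xlsx
dxeval run --input data.xlsx --test-col Test1 --ref-col Disease \
           --test-type quantitative --prevalence 0.1 --outdir results/ --seed 7
```

which writes `confusion_matrix.xlsx`, `metrics.xlsx`, `roc_points.csv`
and `roc.png`. Binary (0/1) tests use `--test-type qualitative`; the
cutoff search and band are then skipped and the AUC reduces to
(Se + Sp)/2.

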