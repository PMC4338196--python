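# mirnadx

Serum microRNA diagnostic-index discovery for pancreato-biliary cancer.

Pancreatic and biliary-tract cancers are rarely detected while still
operable. Circulating serum miRNAs measured on single-channel microarrays
offer a minimally invasive marker source, but turning raw array signals
into a validated diagnostic panel takes a long, convention-laden pipeline:
negative-control-based present calls, background subtraction, floor
replacement, quantile normalization, stratified train/test splitting,
Bonferroni-corrected marker selection with independent test-cohort
validation, and an exhaustive Fisher-discriminant search over marker
panels. `mirnadx` implements that pipeline as a tested, reusable library
(with a thin CLI) for anyone building or auditing serum-miRNA classifiers,
together with a synthetic cohort generator that reproduces the study
design it came from: 571 samples in 8 clinical groups, ~2,555 probes, and
ten planted marker miRNAs at published median expression levels.

## The model

For a marker subset with class means μ₁ (cancer) and μ₀ (control) and
pooled within-class covariance S_w, the diagnostic index of a sample with
log2 marker vector x is

    index(x) = wᵀx + b,   w = S_w⁻¹(μ₁ − μ₀),   b = −wᵀ(μ₀ + μ₁)/2

and x is classified pancreato-biliary cancer iff index(x) > 0. Candidate
markers enter the search only if they pass, in the training cohort, a
robustness filter (signal ≥ 2⁶ in > 50% of samples on one side of the
comparison) and a two-sided pooled t-test at Bonferroni-corrected
p < 0.01, and are then re-validated in the held-out test cohort. All
2^k − 1 panels from a k-marker shortlist are fitted and scored
(sensitivity, specificity, accuracy, AUC) on the test cohort.

## Worked example

```python
import mirnadx as mx

# the bundled published 4-miRNA index
model = mx.pb4_model()
cancer = {m: e[0] for m, e in mx.REFERENCE_MARKER_MEDIANS.items()}
control = {m: e[1] for m, e in mx.REFERENCE_MARKER_MEDIANS.items()}
print(mx.apply_index(model, cancer))   # (1.1435, True)
print(mx.apply_index(model, control))  # (-1.2446, False)

# full pipeline on the default synthetic cohort
res = mx.run_pipeline()
print(len(res.annotations))            # 571
print(sum(m.validated for m in res.markers))   # 7  (validated markers)
print(res.best.marker_ids)             # ['miR-4294', 'miR-4476', 'miR-6075', 'miR-4530']
print(res.best.test_metrics.accuracy_reported) # 99.5
```

The first two lines score the published 4-miRNA discriminant function at
the cancer-side and control-side median expression levels of the ten
reference markers: +1.14 (classified cancer) versus −1.24 (classified
non-cancer). The pipeline run generates the 571-sample cohort, preprocesses
it, splits 2/3:1/3, selects and validates markers for the pooled
pancreato-biliary-vs-everything comparison, and searches all panels of the
validated shortlist; on the default seed it validates 7 of the 10 planted
markers (the two weakest planted effects are deliberately marginal — see
`docs/methods.md`) and finds a 4-marker panel with 99.5% test accuracy.

The same stages are available from the shell:

```
mirnadx simulate --seed 17 --out cohort/
mirnadx preprocess --raw cohort/raw.tsv --nc cohort/nc.tsv --out norm.tsv
mirnadx split --annotations cohort/annotations.tsv --seed 17 --out split.json
mirnadx evaluate --model builtin:pb4 --data norm.tsv \
    --annotations cohort/annotations.tsv --out report.csv
mirnadx run-all --seed 17 --out results/
```

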