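"""Marker selection: training-cohort discovery, test-cohort validation.

Candidate marker miRNAs are selected in the training cohort by a pooled
two-sided Student's t-test with Bonferroni correction at alpha = 0.01,
restricted to probes passing a robustness (prevalence) filter — a signal
of at least 2^6 in strictly more than 50% of samples on at least one side
of the comparison.  Selected candidates are then re-tested in the
independent test cohort at the same significance level; a marker counts as
validated only if it passes both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .types import ClinicalGroup, ExpressionMatrix, SampleAnnotation

PB = frozenset({ClinicalGroup.PANCREATIC, ClinicalGroup.BILIARY})


@dataclass(frozen=True)
class ComparisonSpec:
    """One two-sided clinical comparison: cancer side vs control side."""

    name: str
    cancer_side: frozenset
    control_side: frozenset

    def __post_init__(self) -> None:
        if not self.cancer_side or not self.control_side:
            raise ValueError("both comparison sides must be non-empty")
        if self.cancer_side & self.control_side:
            raise ValueError("comparison sides must be disjoint")


def _cmp(name: str, cancer, control) -> ComparisonSpec:
    return ComparisonSpec(name, frozenset(cancer), frozenset(control))


#: The five built-in paired clinical comparisons:
#: i)  pancreatic cancer vs healthy control
#: ii) biliary-tract cancer vs healthy control
#: iii) pancreato-biliary cancer vs non-malignant abnormalities
#: iv) pancreato-biliary cancer vs other cancer types
#: v)  pancreato-biliary cancer vs all other clinical conditions
BUILTIN_COMPARISONS: dict[str, ComparisonSpec] = {
    c.name: c
    for c in [
        _cmp("pc_vs_hc", {ClinicalGroup.PANCREATIC}, {ClinicalGroup.HEALTHY}),
        _cmp("bc_vs_hc", {ClinicalGroup.BILIARY}, {ClinicalGroup.HEALTHY}),
        _cmp("pb_vs_nma", PB, {ClinicalGroup.NONMALIGNANT_PB}),
        _cmp(
            "pb_vs_otc",
            PB,
            {
                ClinicalGroup.COLON,
                ClinicalGroup.STOMACH,
                ClinicalGroup.ESOPHAGEAL,
                ClinicalGroup.LIVER,
            },
        ),
        _cmp("pb_vs_all", PB, frozenset(set(ClinicalGroup) - PB)),
    ]
}


@dataclass
class MarkerTestResult:
    """Selection/validation record for one miRNA in one comparison."""

    mirna_id: str
    mean_log2_cancer: float
    mean_log2_control: float
    direction: str  # "up" or "down" in cancer
    t_statistic: float
    p_train_raw: float
    p_train_bonferroni: float
    p_test_raw: float = float("nan")
    p_test_bonferroni: float = float("nan")
    prevalence_cancer: float = float("nan")
    prevalence_control: float = float("nan")
    passed_training: bool = False
    validated: bool = False
    direction_consistent: bool = True
    degenerate_variance: bool = False


def student_t_test(x, y) -> tuple[float, float]:
    """Two-sided pooled-variance (equal-variance) Student's t-test.

    Returns ``(t, p)`` with the sign of t equal to sign(mean(x) - mean(y))
    and df = n_x + n_y - 2.  Zero pooled variance degenerates to (0, 1)
    for equal means and (inf-signed, 0) for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (
        x.size + y.size - 2
    )
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni family-wise correction: min(1, m * p)."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    return min(1.0, m * p)


def prevalence_filter(
    matrix: ExpressionMatrix,
    cancer_ids: list[str],
    control_ids: list[str],
    signal_log2: float = 6.0,
    fraction: float = 0.5,
) -> pd.Series:
    """Robust-marker filter: keep probes whose log2 signal reaches
    ``signal_log2`` in strictly more than ``fraction`` of samples on at
    least one side of the comparison."""
    if not cancer_ids or not control_ids:
        raise ValueError("both comparison sides must be non-empty")
    cancer = matrix.values[list(cancer_ids)]
    control = matrix.values[list(control_ids)]
    frac_cancer = (cancer >= signal_log2).mean(axis=1)
    frac_control = (control >= signal_log2).mean(axis=1)
    return (frac_cancer > fraction) | (frac_control > fraction)


def _side_ids(
    annotations: list[SampleAnnotation], groups: frozenset, available: set[str]
) -> list[str]:
    return [a.sample_id for a in annotations if a.group in groups and a.sample_id in available]


def select_and_validate(
    train: ExpressionMatrix,
    train_annotations: list[SampleAnnotation],
    test: ExpressionMatrix,
    test_annotations: list[SampleAnnotation],
    comparison: ComparisonSpec,
    config: PipelineConfig | None = None,
) -> list[MarkerTestResult]:
    """Training-cohort selection with independent test-cohort validation.

    Training pass: prevalence filter AND Bonferroni-corrected p < alpha,
    with multiplicity m = probes surviving the prevalence filter (or all
    probes, per ``config.bonferroni_scope``).  Validation re-tests only the
    training-pass candidates in the test cohort; ``config.validation_mode``
    chooses raw or Bonferroni-corrected (over the candidates) significance.
    Results are ranked by ascending training p-value.
    """
    config = config or PipelineConfig()
    if set(train.sample_ids) & set(test.sample_ids):
        raise ValueError("training and test cohorts overlap")

    train_avail = set(train.sample_ids)
    test_avail = set(test.sample_ids)
    tr_cancer = _side_ids(train_annotations, comparison.cancer_side, train_avail)
    tr_control = _side_ids(train_annotations, comparison.control_side, train_avail)
    te_cancer = _side_ids(test_annotations, comparison.cancer_side, test_avail)
    te_control = _side_ids(test_annotations, comparison.control_side, test_avail)
    for name, ids in [
        ("training cancer", tr_cancer),
        ("training control", tr_control),
        ("test cancer", te_cancer),
        ("test control", te_control),
    ]:
        if len(ids) < 2:
            raise ValueError(f"{name} side of {comparison.name} has <2 samples")

    prevalent = prevalence_filter(
        train,
        tr_cancer,
        tr_control,
        signal_log2=config.prevalence_signal_log2,
        fraction=config.prevalence_fraction,
    )
    m_train = int(prevalent.sum()) if config.bonferroni_scope == "prevalence" else train.n_probes
    m_train = max(m_train, 1)

    results: list[MarkerTestResult] = []
    Xc = train.values[tr_cancer].to_numpy()
    Xn = train.values[tr_control].to_numpy()
    for i, probe in enumerate(train.probe_ids):
        if not prevalent.iloc[i]:
            continue
        t, p = student_t_test(Xc[i], Xn[i])
        mc, mn = float(Xc[i].mean()), float(Xn[i].mean())
        results.append(
            MarkerTestResult(
                mirna_id=probe,
                mean_log2_cancer=mc,
                mean_log2_control=mn,
                direction="up" if mc >= mn else "down",
                t_statistic=t,
                p_train_raw=p,
                p_train_bonferroni=bonferroni_adjust(p, m_train),
                prevalence_cancer=float((Xc[i] >= config.prevalence_signal_log2).mean()),
                prevalence_control=float((Xn[i] >= config.prevalence_signal_log2).mean()),
                degenerate_variance=not np.isfinite(t),
            )
        )

    for r in results:
        r.passed_training = r.p_train_bonferroni < config.alpha

    candidates = [r for r in results if r.passed_training]
    m_test = max(len(candidates), 1)
    test_probe_index = {p: i for i, p in enumerate(test.probe_ids)}
    Yc = test.values[te_cancer].to_numpy()
    Yn = test.values[te_control].to_numpy()
    for r in candidates:
        if r.mirna_id not in test_probe_index:
            raise ValueError(f"candidate {r.mirna_id} absent from test matrix")
        i = test_probe_index[r.mirna_id]
        t_te, p_te = student_t_test(Yc[i], Yn[i])
        r.p_test_raw = p_te
        r.p_test_bonferroni = bonferroni_adjust(p_te, m_test)
        p_used = r.p_test_bonferroni if config.validation_mode == "bonferroni" else p_te
        r.validated = p_used < config.alpha
        r.direction_consistent = (np.sign(t_te) == np.sign(r.t_statistic)) or t_te == 0

    results.sort(key=lambda r: (r.p_train_raw, r.mirna_id))
    return results
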