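"""End-to-end orchestration of the marker-discovery pipeline.

simulate -> preprocess -> stratified split -> select & validate markers ->
shortlist the top candidates -> exhaustive panel search -> evaluate.
Everything is a pure function of (generator config, pipeline config,
seed), so one call reproduces a full study run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .discriminant import CombinationResult, combination_search
from .preprocess import preprocess
from .selection import (
    BUILTIN_COMPARISONS,
    ComparisonSpec,
    MarkerTestResult,
    select_and_validate,
)
from .simulate import GeneratorConfig, generate_cohort
from .split import stratified_split
from .types import CohortSplit, ExpressionMatrix, SampleAnnotation


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    matrix: ExpressionMatrix
    annotations: list[SampleAnnotation]
    split: CohortSplit
    markers: list[MarkerTestResult]
    shortlist: list[str]
    combination_results: list[CombinationResult] = field(default_factory=list)
    best_per_size: dict[int, list[CombinationResult]] = field(default_factory=dict)
    best: CombinationResult | None = None


def cancer_labels(
    annotations: list[SampleAnnotation], comparison: ComparisonSpec
) -> pd.Series:
    """Binary labels (1 = cancer side) for the samples on either side of a
    comparison; samples outside both sides are omitted."""
    ids, vals = [], []
    for a in annotations:
        if a.group in comparison.cancer_side:
            ids.append(a.sample_id)
            vals.append(1)
        elif a.group in comparison.control_side:
            ids.append(a.sample_id)
            vals.append(0)
    return pd.Series(vals, index=ids, dtype=int)


def run_pipeline(
    gen_config: GeneratorConfig | None = None,
    config: PipelineConfig | None = None,
    comparison: ComparisonSpec | str = "pb_vs_all",
    shortlist_size: int = 10,
    run_search: bool = True,
) -> PipelineResult:
    """Run the full pipeline on a synthetic cohort.

    The marker shortlist is the ``shortlist_size`` validated markers with
    the smallest training p-values; the panel search fits all non-empty
    subsets of that shortlist.
    """
    gen_config = gen_config or GeneratorConfig()
    config = config or PipelineConfig()
    if isinstance(comparison, str):
        comparison = BUILTIN_COMPARISONS[comparison]

    raw, annotations = generate_cohort(gen_config)
    matrix = preprocess(raw, config)
    split = stratified_split(
        annotations, train_fraction=config.train_fraction, seed=config.rng_seed
    )
    train = matrix.subset_samples(split.train_ids)
    test = matrix.subset_samples(split.test_ids)
    by_id = {a.sample_id: a for a in annotations}
    train_ann = [by_id[s] for s in split.train_ids]
    test_ann = [by_id[s] for s in split.test_ids]

    markers = select_and_validate(train, train_ann, test, test_ann, comparison, config)
    validated = [m for m in markers if m.validated]
    shortlist = [m.mirna_id for m in validated[:shortlist_size]]

    result = PipelineResult(
        matrix=matrix,
        annotations=annotations,
        split=split,
        markers=markers,
        shortlist=shortlist,
    )
    if run_search and shortlist:
        labels = cancer_labels(annotations, comparison)
        tr_ids = [s for s in split.train_ids if s in labels.index]
        te_ids = [s for s in split.test_ids if s in labels.index]
        all_results, best_per_size, best = combination_search(
            train.subset_samples(tr_ids),
            labels.loc[tr_ids],
            test.subset_samples(te_ids),
            labels.loc[te_ids],
            shortlist,
            config,
        )
        result.combination_results = all_results
        result.best_per_size = best_per_size
        result.best = best
    return result
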