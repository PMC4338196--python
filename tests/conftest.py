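import numpy as np
import pandas as pd
import pytest

import mirnadx as mx
from mirnadx.types import ClinicalGroup


def small_group_sizes(scale: int = 1):
    return {
        ClinicalGroup.HEALTHY: 15 * scale,
        ClinicalGroup.PANCREATIC: 10 * scale,
        ClinicalGroup.BILIARY: 10 * scale,
        ClinicalGroup.NONMALIGNANT_PB: 4 * scale,
        ClinicalGroup.COLON: 5 * scale,
        ClinicalGroup.STOMACH: 5 * scale,
        ClinicalGroup.ESOPHAGEAL: 5 * scale,
        ClinicalGroup.LIVER: 6 * scale,
    }


@pytest.fixture
def small_gen_config():
    """A reduced cohort (60 samples, 60 probes) for fast unit tests."""
    return mx.GeneratorConfig(
        group_sizes=small_group_sizes(),
        n_probes=60,
        n_negative_controls=40,
        rng_seed=11,
    )


@pytest.fixture
def small_cohort(small_gen_config):
    return mx.generate_cohort(small_gen_config)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run under the default study conditions.

    Shared session-wide: the 571-sample, 2,555-probe cohort with the ten
    planted markers, preprocessed, split 2/3:1/3, selected/validated on the
    pooled pancreato-biliary comparison, and searched over the shortlist.
    """
    return mx.run_pipeline()


@pytest.fixture
def expr_matrix():
    """A tiny deterministic log2 matrix with group-separated samples."""
    rng = np.random.default_rng(5)
    probes = [f"p{i}" for i in range(8)]
    cancer = [f"C{i}" for i in range(6)]
    control = [f"N{i}" for i in range(6)]
    vals = pd.DataFrame(
        rng.normal(8.0, 0.5, size=(8, 12)), index=probes, columns=cancer + control
    )
    vals.loc["p0", cancer] += 2.0
    return mx.ExpressionMatrix(values=vals, scale="log2"), cancer, control
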