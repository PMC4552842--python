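import numpy as np
import pandas as pd
import pytest

from ckdms import (
    ExpressionMatrix,
    FoldChangeProfile,
    SimulationParams,
    compute_fold_change,
    generate_cohort,
)


def null_params(seed: int, **overrides) -> SimulationParams:
    """A cohort with no planted structure of any kind (the null model)."""
    defaults = dict(
        n_probes=2000,
        n_discovery=31,
        n_validation=0,
        effect_slope_log2=0.0,
        background_de_fraction=0.0,
        bad_spot_fraction=0.0,
        undetectable_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


def clean_params(seed: int, **overrides) -> SimulationParams:
    """Default planted signal but no bad spots / near-background probes."""
    defaults = dict(
        n_probes=2000,
        bad_spot_fraction=0.0,
        undetectable_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


def fc_from_ratios(ratios: pd.DataFrame, detectable=None) -> FoldChangeProfile:
    """Wrap a plain ratio table in a FoldChangeProfile (control of ones)."""
    return FoldChangeProfile(
        ratios=ratios,
        cohort_mean=ratios.mean(axis=1),
        control=pd.Series(1.0, index=ratios.index),
        floor=1.0,
        detectable=detectable,
        cohort_samples=tuple(ratios.columns),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort at reduced probe count, used across modules."""
    return generate_cohort(SimulationParams(n_probes=1000, seed=11))


@pytest.fixture(scope="session")
def small_fold_change(small_cohort):
    c = small_cohort
    return compute_fold_change(c.matrix, c.control, cohort_samples=c.discovery_ids())


@pytest.fixture()
def toy_matrix():
    """5 probes x 3 samples, hand-checkable intensities."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 20.0, 30.0, 40.0, 50.0],
            "s2": [60.0, 80.0, 100.0, 120.0, 140.0],
            "s3": [5.0, 10.0, 200.0, 400.0, 800.0],
        },
        index=[f"p{i}" for i in range(1, 6)],
    )
    return ExpressionMatrix(intensities=values)
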