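import logging

import numpy as np
import pandas as pd
import pytest

from agesig import (
    CohortSpec,
    ExpressionMatrix,
    SampleTable,
    SelectionConfig,
    build_signature,
    nested_loocv_select,
    simulate_training_cohort,
)

# the signature-recovery study design: the discovery cohort layout
# (15 v 15, 2,000 probes, 100 planted, 85 % down, 1 sd effect) with the
# inner selection size scaled to the probe universe (20 = 1 % of probes).
RECOVERY_SPEC = CohortSpec(seed=0)
RECOVERY_CFG = SelectionConfig(n_inner=20, k=5)


def build_matrix(arr, probes=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=probes, columns=samples))


def build_samples(groups: dict[str, str], **extra) -> SampleTable:
    df = pd.DataFrame({"group": pd.Series(groups)})
    for name, values in extra.items():
        df[name] = pd.Series(values)
    df.index.name = "sample_id"
    return SampleTable(df)


@pytest.fixture(scope="session")
def training_run():
    """One full discovery run shared by the slower tests."""
    matrix, samples, annotation, truth = simulate_training_cohort(RECOVERY_SPEC)
    perf = nested_loocv_select(matrix, samples, RECOVERY_CFG)
    logging.disable(logging.WARNING)
    try:
        signature, relaxed = build_signature(perf, matrix, samples, annotation, RECOVERY_CFG)
    finally:
        logging.disable(logging.NOTSET)
    return {
        "matrix": matrix,
        "samples": samples,
        "annotation": annotation,
        "truth": truth,
        "perf": perf,
        "signature": signature,
        "relaxed": relaxed,
        "cfg": RECOVERY_CFG,
        "spec": RECOVERY_SPEC,
    }
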