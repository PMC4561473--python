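"""Shared setup for the analysis drivers: the discovery cohort and the
signature selected on it. Each driver re-derives what it needs from one
seed, so every script is runnable on its own."""

from __future__ import annotations

from pathlib import Path

from agesig import (
    CohortSpec,
    SelectionConfig,
    build_signature,
    nested_loocv_select,
    simulate_training_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

# the discovery design: 15 young v 15 old, 2,000 probes, 100 planted
# signature probes (85 % down-regulated with age) at a 1-sd shift.
# n_inner is scaled to the probe universe (1 %).
DISCOVERY_CFG = SelectionConfig(n_inner=20, k=5)


def discovery_spec(seed: int) -> CohortSpec:
    return CohortSpec(seed=seed)


def run_discovery(seed: int):
    """Simulate the training cohort and select the signature on it."""
    matrix, samples, annotation, truth = simulate_training_cohort(discovery_spec(seed))
    perf = nested_loocv_select(matrix, samples, DISCOVERY_CFG)
    signature, relaxed = build_signature(perf, matrix, samples, annotation, DISCOVERY_CFG)
    return {
        "matrix": matrix,
        "samples": samples,
        "annotation": annotation,
        "truth": truth,
        "perf": perf,
        "signature": signature,
        "relaxed": relaxed,
    }
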