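"""Simulate the discovery cohort and describe what was planted.

Writes results/cohort_summary.tsv (per-group means over signal and null
probes) and results/truth.tsv (the planted signature with directions).
"""

import argparse

import numpy as np
import pandas as pd

from common import RESULTS, discovery_spec
from agesig import simulate_training_cohort


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    spec = discovery_spec(args.seed)
    matrix, samples, annotation, truth = simulate_training_cohort(spec)
    RESULTS.mkdir(exist_ok=True)
    truth.signal.to_csv(RESULTS / "truth.tsv", sep="\t")

    old = (samples.data["group"] == "old").to_numpy()
    signal = matrix.values.loc[truth.signal_probes].to_numpy()
    null_probes = [p for p in matrix.probe_ids if p not in set(truth.signal_probes)]
    null = matrix.values.loc[null_probes].to_numpy()
    down = truth.signal["direction"] == "down"
    rows = {
        "signal_down": matrix.values.loc[truth.signal.index[down]].to_numpy(),
        "signal_up": matrix.values.loc[truth.signal.index[~down]].to_numpy(),
        "null": null,
    }
    summary = pd.DataFrame({
        "n_probes": {k: v.shape[0] for k, v in rows.items()},
        "mean_young": {k: v[:, ~old].mean() for k, v in rows.items()},
        "mean_old": {k: v[:, old].mean() for k, v in rows.items()},
    })
    summary["old_minus_young"] = summary["mean_old"] - summary["mean_young"]
    summary.to_csv(RESULTS / "cohort_summary.tsv", sep="\t")

    print(f"cohort: {spec.n_young} young v {spec.n_old} old, {spec.n_probes} probes")
    print(f"planted: {len(truth.signal)} probes, "
          f"{int((truth.signal['direction'] == 'down').sum())} down-regulated")
    print(f"multi-locus flagged: {int(annotation.data['multi_locus'].sum())}")
    print(summary.round(3).to_string())
    print(f"\nwrote {RESULTS / 'cohort_summary.tsv'} and {RESULTS / 'truth.tsv'}")


if __name__ == "__main__":
    main()
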