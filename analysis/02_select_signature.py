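"""Select the healthy-ageing signature with the nested hold-out loop and
compare it against the planted truth.

Writes results/signature.tsv (>=90 % performance list),
results/extended_signature.tsv (>=70 % list) and
results/selection_summary.tsv.
"""

import argparse

import pandas as pd

from common import RESULTS, run_discovery
from agesig import write_signature


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    run = run_discovery(args.seed)
    perf, signature, relaxed, truth = (
        run["perf"], run["signature"], run["relaxed"], run["truth"],
    )
    RESULTS.mkdir(exist_ok=True)
    write_signature(signature, RESULTS / "signature.tsv")
    write_signature(relaxed, RESULTS / "extended_signature.tsv")

    planted = set(truth.signal_probes)
    selected = set(signature.probe_ids)
    hits = signature.entries.index[signature.entries.index.isin(truth.signal.index)]
    summary = pd.Series({
        "decisions": perf.total_decisions,
        "probe_evaluation_events": perf.total_events,
        "holdout_accuracy": round(perf.overall_accuracy, 4),
        "signature_size": len(signature),
        "extended_size": len(relaxed),
        "recovery_precision": round(len(selected & planted) / len(selected), 4),
        "direction_agreement": round(float(
            (signature.entries.loc[hits, "direction"]
             == truth.signal.loc[hits, "direction"]).mean()
        ), 4),
        "down_fraction": round(float(
            (signature.entries["direction"] == "down").mean()
        ), 4),
    }, name="value")
    summary.to_csv(RESULTS / "selection_summary.tsv", sep="\t")
    print(summary.to_string())
    print(f"\nwrote {RESULTS / 'signature.tsv'} ({len(signature)} probes) "
          f"and {RESULTS / 'extended_signature.tsv'} ({len(relaxed)} probes)")


if __name__ == "__main__":
    main()
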