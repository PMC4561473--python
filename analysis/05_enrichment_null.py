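"""Ask whether the signature's gene-set enrichment profile differs from
chance, using the 10,000-draw random-set null.

The signature genes are tested against a synthetic gene-set collection by
upper-tail hypergeometric tests; the same battery is applied to 10,000
random gene sets of the same size drawn from the platform universe. The
two p-value samples are compared with a two-sample KS test. Writes
results/enrichment_profile.tsv and results/enrichment_null_summary.tsv.
"""

import argparse

import pandas as pd

from common import RESULTS, run_discovery
from agesig import (
    compare_profiles,
    hypergeom_enrich,
    resampling_null,
    simulate_gmt,
)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--draws", type=int, default=10_000)
    args = parser.parse_args()

    run = run_discovery(args.seed)
    annotation, signature = run["annotation"], run["signature"]
    universe = frozenset(annotation.data["gene_symbol"])
    query = frozenset(
        annotation.data.loc[
            [p for p in signature.probe_ids if p in annotation.data.index],
            "gene_symbol",
        ]
    )
    gmt = simulate_gmt(sorted(universe), n_terms=50, size_range=(10, 200),
                       seed=args.seed + 7)
    observed = hypergeom_enrich(query, gmt, universe)
    null = resampling_null(universe, gmt, set_size=len(query),
                           n_draws=args.draws, seed=args.seed + 8)
    comparison = compare_profiles(observed, null)

    RESULTS.mkdir(exist_ok=True)
    observed.table.to_csv(RESULTS / "enrichment_profile.tsv", sep="\t")
    summary = pd.Series({
        "query_genes": len(query),
        "terms_tested": null.n_terms,
        "null_draws": null.n_draws,
        "ks_statistic": round(comparison.ks_statistic, 4),
        "ks_p": round(comparison.p_value, 4),
    }, name="value")
    summary.to_csv(RESULTS / "enrichment_null_summary.tsv", sep="\t")
    print(summary.to_string())
    verdict = ("indistinguishable from" if comparison.p_value > 0.05
               else "different from")
    print(f"\nthe signature's enrichment profile is {verdict} a random "
          f"{len(query)}-gene sample (KS p={comparison.p_value:.3f})")
    print(f"wrote {RESULTS / 'enrichment_profile.tsv'} and "
          f"{RESULTS / 'enrichment_null_summary.tsv'}")


if __name__ == "__main__":
    main()
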