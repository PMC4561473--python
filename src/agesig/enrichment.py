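"""Hypergeometric over-representation with a resampling null.

A signature is tested against a gene-set collection term by term with an
upper-tail hypergeometric test (population = the platform universe). To
ask whether the signature's whole enrichment *profile* is distinguishable
from chance, the same battery is run on many random gene sets of the same
size drawn from the universe, and the observed p-value vector is compared
with the pooled null p-values by a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EnrichmentProfile, GeneSetCollection, NullProfile, ProfileComparison

logger = logging.getLogger("agesig")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    Vectorised over rows when given a 2-D array (one adjustment per row).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    squeeze = p.ndim == 1
    p2 = np.atleast_2d(p)
    m = p2.shape[1]
    order = np.argsort(p2, axis=1, kind="stable")
    ranked = np.take_along_axis(p2, order, axis=1) * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[:, ::-1], axis=1)[:, ::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(p2)
    np.put_along_axis(out, order, adj, axis=1)
    return out[0] if squeeze else out


def _overlap_pvalues(overlaps: np.ndarray, universe_size: int, term_sizes: np.ndarray,
                     query_size: int) -> np.ndarray:
    """Upper-tail hypergeometric P(X >= overlap), broadcast over terms."""
    return stats.hypergeom.sf(overlaps - 1, universe_size, term_sizes, query_size)


def hypergeom_enrich(
    query: set[str] | frozenset[str],
    gmt: GeneSetCollection,
    universe: set[str] | frozenset[str],
) -> EnrichmentProfile:
    """Test one gene set for over-representation in every term.

    ``query`` must be a subset of ``universe``; each term is intersected
    with the universe before testing. A term disjoint from the query gets
    p = 1 exactly (P(X >= 0)).
    """
    query = frozenset(query)
    universe = frozenset(universe)
    if not query:
        raise ValueError("empty query set")
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    restricted = gmt.restricted_to(universe)
    if not restricted.terms:
        raise ValueError("no gene-set terms overlap the universe")
    terms = sorted(restricted.terms)
    term_sizes = np.array([len(restricted.terms[t][1]) for t in terms])
    overlaps = np.array([len(restricted.terms[t][1] & query) for t in terms])
    p = _overlap_pvalues(overlaps, len(universe), term_sizes, len(query))
    table = pd.DataFrame(
        {
            "description": [restricted.terms[t][0] for t in terms],
            "term_size": term_sizes,
            "overlap": overlaps,
            "p_value": p,
            "bh_p": bh_adjust(p),
        },
        index=pd.Index(terms, name="term_id"),
    )
    return EnrichmentProfile(table, query_size=len(query), universe_size=len(universe))


def resampling_null(
    universe: set[str] | frozenset[str],
    gmt: GeneSetCollection,
    set_size: int = 150,
    n_draws: int = 10_000,
    seed: int = 0,
) -> NullProfile:
    """Enrichment null: repeated random query sets of ``set_size`` genes.

    Each draw is sampled uniformly without replacement from the universe
    and run through the same hypergeometric battery (with per-draw BH
    adjustment). Identical seeds give bitwise-identical profiles.
    """
    universe_list = sorted(universe)
    m = len(universe_list)
    if set_size > m:
        raise ValueError(f"set_size={set_size} exceeds the universe ({m} genes)")
    restricted = gmt.restricted_to(frozenset(universe_list))
    if not restricted.terms:
        raise ValueError("no gene-set terms overlap the universe")
    terms = sorted(restricted.terms)
    term_sizes = np.array([len(restricted.terms[t][1]) for t in terms])
    # boolean membership matrix: terms x universe
    index_of = {g: i for i, g in enumerate(universe_list)}
    member = np.zeros((len(terms), m), dtype=bool)
    for row, t in enumerate(terms):
        member[row, [index_of[g] for g in restricted.terms[t][1]]] = True

    rng = np.random.default_rng(seed)
    overlaps = np.empty((n_draws, len(terms)), dtype=np.int64)
    for d in range(n_draws):
        idx = rng.choice(m, size=set_size, replace=False)
        overlaps[d] = member[:, idx].sum(axis=1)
    p = _overlap_pvalues(overlaps, m, term_sizes[None, :], set_size)
    bh = bh_adjust(p)
    return NullProfile(
        n_draws=n_draws,
        set_size=set_size,
        seed=seed,
        n_terms=len(terms),
        p_values=p.ravel(),
        bh_p=bh.ravel(),
    )


def compare_profiles(
    observed: EnrichmentProfile,
    null: NullProfile,
    density_points: int = 101,
) -> ProfileComparison:
    """Two-sample KS between the observed p-values and the pooled null.

    Also returns Gaussian kernel-density summaries of both p-value samples
    on a common [0, 1] grid for plotting (omitted when either sample is
    degenerate).
    """
    obs = observed.p_values
    pooled = null.p_values
    if obs.size == 0 or pooled.size == 0:
        raise ValueError("cannot compare empty profiles")
    ks = stats.ks_2samp(obs, pooled)
    grid = np.linspace(0.0, 1.0, density_points)
    obs_density = null_density = None
    try:
        if np.ptp(obs) > 0 and np.ptp(pooled) > 0:
            obs_density = stats.gaussian_kde(obs)(grid)
            null_density = stats.gaussian_kde(pooled)(grid)
    except np.linalg.LinAlgError:  # pragma: no cover - singular KDE
        pass
    return ProfileComparison(
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        grid=grid,
        observed_density=obs_density,
        null_density=null_density,
    )
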