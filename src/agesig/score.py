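"""The healthy-ageing gene score and its group statistics.

The score is cohort-relative by construction: for every signature gene the
samples are ranked within the cohort, taking the gene's direction from the
original classifier into account, and each sample's score is the median of
its per-gene ranks. For a gene down-regulated with healthy age the sample
with the *highest* expression receives rank 1 and the lowest rank n, so a
large rank means an expression level typical of healthy old tissue; for an
up-regulated gene the opposite orientation is used. Dividing by the number
of samples scales the score to (0, 1]. Higher score = closer to the
healthy-old expression profile. Adding or removing samples changes every
score, because the ranks are recomputed within the cohort.

Ties in expression receive average ranks, and the median across genes
gives every gene equal weight regardless of its dynamic range. A
sum-of-ranks variant is exposed for sensitivity analysis.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    GeneScoreResult,
    GroupComparison,
    SampleTable,
    SignatureModel,
)

logger = logging.getLogger("agesig")


def compute_gene_score(
    matrix: ExpressionMatrix,
    signature: SignatureModel,
    method: str = "median",
) -> GeneScoreResult:
    """Direction-aware rank score per sample.

    ``method="median"`` (default) takes the per-sample median of the
    per-gene ranks; ``method="sum"`` takes the sum (scaled by n_genes * n
    instead of n). Signature genes absent from the matrix are logged and
    skipped; at least one must be present.
    """
    if method not in ("median", "sum"):
        raise ValueError(f"method must be 'median' or 'sum', got {method!r}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to rank")
    present = [p for p in signature.probe_ids if p in matrix.values.index]
    missing = len(signature) - len(present)
    if missing:
        logger.info("gene score: %d signature genes absent from the matrix, skipped", missing)
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    n = matrix.shape[1]
    ranks = np.empty((len(present), n))
    directions = signature.entries.loc[present, "direction"]
    for g, probe in enumerate(present):
        x = matrix.values.loc[probe].to_numpy(dtype=float)
        # down-regulated with age: highest expression -> rank 1 (young-like)
        ranks[g] = stats.rankdata(-x) if directions.iloc[g] == "down" else stats.rankdata(x)
    if method == "median":
        raw = np.median(ranks, axis=0)
        scaled = raw / n
    else:
        raw = ranks.sum(axis=0)
        scaled = raw / (n * len(present))
    frame = pd.DataFrame(
        {"raw_score": raw, "scaled_score": scaled},
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
    return GeneScoreResult(frame, n_genes_used=len(present), genes_used=present)


def _scores_by_group(scores: GeneScoreResult, labels: SampleTable) -> dict[str, np.ndarray]:
    y = labels.groups_for(scores.scores.index)
    return {
        level: scores.scaled[(y == level).to_numpy()].to_numpy()
        for level in sorted(y.unique())
    }


def wilcoxon_compare(
    scores: GeneScoreResult,
    labels: SampleTable,
    group_a: str,
    group_b: str,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test on scaled scores.

    The exact null distribution is used for combined n <= 20 without ties;
    otherwise the normal approximation with tie correction.
    """
    by_group = _scores_by_group(scores, labels)
    for g in (group_a, group_b):
        if g not in by_group or len(by_group[g]) == 0:
            raise ValueError(f"group {g!r} is empty or unknown")
    x, y_ = by_group[group_a], by_group[group_b]
    pooled = np.concatenate([x, y_])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y_, alternative="two-sided", method=method)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_medians={group_a: float(np.median(x)), group_b: float(np.median(y_))},
    )


def kruskal_wallis(scores: GeneScoreResult, labels: SampleTable) -> GroupComparison:
    """Kruskal-Wallis H across all group levels (tie-corrected, chi-square p)."""
    by_group = _scores_by_group(scores, labels)
    if len(by_group) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    groups = list(by_group)
    h, p = stats.kruskal(*by_group.values())
    return GroupComparison(
        group_a="|".join(groups),
        group_b=None,
        statistic=float(h),
        p_value=float(p),
        group_medians={g: float(np.median(v)) for g, v in by_group.items()},
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment, input order preserved.

    Sort the raw p ascending; adjusted_(i) = max over j <= i of
    (m - j + 1) * p_(j), capped at 1. Monotone by construction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty_like(p)
    out[order] = adj
    return out


def posthoc_mw_holm(scores: GeneScoreResult, labels: SampleTable) -> list[GroupComparison]:
    """All pairwise rank-sum tests with Holm step-down adjustment."""
    by_group = _scores_by_group(scores, labels)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    comparisons = [
        wilcoxon_compare(scores, labels, a, b)
        for a, b in itertools.combinations(sorted(by_group), 2)
    ]
    adjusted = holm_adjust([c.p_value for c in comparisons])
    for c, adj in zip(comparisons, adjusted):
        c.adjusted_p = float(adj)
    return comparisons


def regress_score(scores: GeneScoreResult, covariate: pd.Series) -> dict[str, float]:
    """OLS of scaled score on one clinical covariate.

    Returns slope, intercept, r_squared and the slope t-test p-value.
    ``covariate`` is aligned on sample id; pairs with a missing covariate
    are dropped.
    """
    joined = pd.concat([scores.scaled, covariate.rename("covariate")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired observations")
    x = joined["covariate"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    fit = stats.linregress(x, joined["scaled_score"].to_numpy(dtype=float))
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n": int(len(joined)),
    }
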