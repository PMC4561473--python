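"""In-memory containers shared across the pipeline.

Everything downstream (selection, classification, scoring, enrichment)
operates on these thin wrappers around pandas objects. Validation happens
at construction so the numerical code can assume clean inputs: unique
identifiers, finite values, declared group labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("agesig")

DIRECTIONS = ("up", "down")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, probes (rows) x samples (columns).

    ``values`` is a DataFrame indexed by probe id with sample ids as
    columns. ``transform_log`` records the transforms applied so far
    (e.g. ``["log2", "quantile"]``) so a transform is never applied twice.
    """

    values: pd.DataFrame
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0:
            raise ValueError("expression matrix has no probes")
        if self.values.shape[1] == 0:
            raise ValueError("expression matrix has no samples")
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at probe "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, transform: str | None = None) -> "ExpressionMatrix":
        """Return a new matrix carrying this matrix's transform history."""
        log = list(self.transform_log)
        if transform is not None:
            log.append(transform)
        return ExpressionMatrix(values, log)


@dataclass
class SampleTable:
    """Per-sample metadata: group label, optional age and covariates."""

    data: pd.DataFrame  # indexed by sample_id; must have a 'group' column

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise ValueError("sample table lacks mandatory column 'group'")
        _check_unique(self.data.index, "sample ids")
        self.data.index = self.data.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def groups_for(self, sample_ids) -> pd.Series:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples missing from sample table: {missing[:5]}")
        return self.data.loc[list(sample_ids), "group"]

    @property
    def levels(self) -> list[str]:
        return sorted(self.data["group"].unique())


@dataclass
class ProbeAnnotation:
    """Probe id -> gene symbol mapping with a multi-locus flag."""

    data: pd.DataFrame  # indexed by probe_id; gene_symbol, multi_locus, platform

    def __post_init__(self) -> None:
        for col in ("gene_symbol", "multi_locus"):
            if col not in self.data.columns:
                raise ValueError(f"probe annotation lacks mandatory column '{col}'")
        if "platform" not in self.data.columns:
            self.data["platform"] = ""
        _check_unique(self.data.index, "probe ids")
        self.data.index = self.data.index.astype(str)
        self.data["multi_locus"] = self.data["multi_locus"].astype(bool)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    def symbols_for(self, probe_ids) -> pd.Series:
        return self.data.loc[list(probe_ids), "gene_symbol"]


@dataclass
class SignatureModel:
    """Ordered feature list: probe id, direction of change with age, performance.

    ``direction`` is "down" for probes whose expression falls between the
    young and healthy-old groups and "up" for the reverse; the gene score
    and the classifier both consume this fixed orientation.
    """

    entries: pd.DataFrame  # indexed by probe_id; columns direction, performance
    training_note: str = ""

    def __post_init__(self) -> None:
        for col in ("direction", "performance"):
            if col not in self.entries.columns:
                raise ValueError(f"signature lacks column '{col}'")
        _check_unique(self.entries.index, "signature probe ids")
        self.entries.index = self.entries.index.astype(str)
        dirs = self.entries["direction"].str.lower()
        bad = self.entries.index[~dirs.isin(DIRECTIONS)]
        if len(bad):
            raise ValueError(f"unknown direction for probes {list(bad[:5])}")
        self.entries["direction"] = dirs
        perf = self.entries["performance"].astype(float)
        if ((perf < 0) | (perf > 1)).any():
            bad = self.entries.index[(perf < 0) | (perf > 1)]
            raise ValueError(f"performance outside [0,1] for probes {list(bad[:5])}")
        self.entries["performance"] = perf

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.entries.index)


@dataclass
class GeneSetCollection:
    """Named gene sets (term id -> description + member genes)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)

    def restricted_to(self, universe: frozenset[str]) -> "GeneSetCollection":
        """Intersect every term with ``universe``; empty intersections are dropped."""
        kept = {}
        for term, (desc, members) in self.terms.items():
            inter = members & universe
            if inter:
                kept[term] = (desc, inter)
        return GeneSetCollection(kept)


@dataclass
class PerformanceTable:
    """Per-probe tally of hold-out decisions from the nested LOOCV loop."""

    data: pd.DataFrame  # indexed by probe_id; appearances, correct, performance
    total_decisions: int
    n_inner: int

    def __post_init__(self) -> None:
        d = self.data
        if ((d["correct"] < 0) | (d["correct"] > d["appearances"])).any():
            raise ValueError("correct counts outside [0, appearances]")

    @property
    def total_events(self) -> int:
        """Total probe-evaluation events, summed over all decisions."""
        return int(self.data["appearances"].sum())

    @property
    def overall_accuracy(self) -> float:
        """Held-out accuracy over all decisions.

        Every decision credits exactly ``n_inner`` probes, so the
        appearance-weighted correct fraction equals the decision accuracy.
        """
        return float(self.data["correct"].sum() / self.data["appearances"].sum())


@dataclass
class GeneScoreResult:
    """Per-sample healthy-ageing gene score (raw median rank and scaled)."""

    scores: pd.DataFrame  # indexed by sample_id; raw_score, scaled_score
    n_genes_used: int
    genes_used: list[str]

    @property
    def scaled(self) -> pd.Series:
        return self.scores["scaled_score"]


@dataclass
class GroupComparison:
    """Result of a rank-based group test."""

    group_a: str
    group_b: str | None
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    group_medians: dict[str, float] = field(default_factory=dict)


@dataclass
class ClassificationResult:
    """Per-sample kNN decisions; vote_score is the fraction of neighbours
    carrying the positive (old / case) label."""

    predictions: pd.DataFrame  # indexed by sample_id; predicted_label, vote_score[, true_label]
    k: int
    positive_label: str

    @property
    def has_truth(self) -> bool:
        return "true_label" in self.predictions.columns

    def accuracy(self) -> float:
        if not self.has_truth:
            raise ValueError("no true labels attached")
        p = self.predictions
        return float((p["predicted_label"] == p["true_label"]).mean())


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass
class EnrichmentProfile:
    """Per-term over-representation results for one query gene set."""

    table: pd.DataFrame  # indexed by term_id; description, term_size, overlap, p_value, bh_p
    query_size: int
    universe_size: int

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()


@dataclass
class NullProfile:
    """Pooled enrichment p-values from repeated random query draws."""

    n_draws: int
    set_size: int
    seed: int
    n_terms: int
    p_values: np.ndarray  # shape (n_draws * n_terms,), raw
    bh_p: np.ndarray  # same shape, BH-adjusted within each draw


@dataclass
class ProfileComparison:
    ks_statistic: float
    p_value: float
    grid: np.ndarray | None = None
    observed_density: np.ndarray | None = None
    null_density: np.ndarray | None = None
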