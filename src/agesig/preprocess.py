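"""Normalisation and cross-platform harmonisation.

The pipeline's contract starts at a summarised log-intensity matrix (array
summarisation such as RMA/fRMA happens upstream and is not reimplemented
here). This module provides log2 transformation, quantile normalisation,
per-probe scaling/centering, probe->gene collapsing, and symbol-level
mapping of a signature between platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix, ProbeAnnotation, SignatureModel

logger = logging.getLogger("agesig")


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2. Requires strictly positive values; refuses to
    apply twice (the transform log is checked)."""
    if "log2" in matrix.transform_log:
        raise ValueError("matrix is already log2-transformed")
    arr = matrix.values.to_numpy()
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"non-positive value {arr[i, j]} at probe {matrix.probe_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}; cannot log2-transform"
        )
    out = pd.DataFrame(np.log2(arr), index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(out, "log2")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the mean of the per-rank values across samples. Tied
    values within a sample receive the mean of the reference values at the
    ranks the tie occupies, so the output preserves within-sample rank
    order exactly.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        rmin = rankdata(X[:, j], method="min").astype(int)
        rmax = rankdata(X[:, j], method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(frame, "quantile")


def scale_center(matrix: ExpressionMatrix, axis: str = "probes") -> ExpressionMatrix:
    """Center to mean 0 and scale to unit standard deviation (n-1 denominator).

    ``axis="probes"`` (default) standardises each probe across samples;
    ``axis="samples"`` standardises each sample across probes. Probes (or
    samples) with zero variance are dropped with a logged warning.
    """
    if axis not in ("probes", "samples"):
        raise ValueError(f"axis must be 'probes' or 'samples', got {axis!r}")
    values = matrix.values if axis == "probes" else matrix.values.T
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = values.index[~keep]
        logger.warning("dropping %d zero-variance %s during scaling: %s%s",
                       (~keep).sum(), axis, list(dropped[:5]), "..." if len(dropped) > 5 else "")
        arr = arr[keep]
        values = values.loc[keep]
        sd = sd[keep]
    if arr.shape[0] == 0:
        raise ValueError("all rows had zero variance; nothing left to scale")
    out = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    frame = pd.DataFrame(out, index=values.index, columns=values.columns)
    if axis == "samples":
        frame = frame.T
    return matrix.with_values(frame, f"scale_center[{axis}]")


@dataclass
class PlatformMap:
    """Source probe id -> set of destination probe ids, joined on gene symbol."""

    pairs: dict[str, frozenset[str]]
    n_unmapped: int = 0


def build_platform_map(src: ProbeAnnotation, dst: ProbeAnnotation) -> PlatformMap:
    """Join two annotations on gene symbol.

    Only source probes with at least one destination probe appear; the
    number of source probes that failed to map is recorded and logged.
    """
    dst_by_symbol: dict[str, set[str]] = {}
    for probe, symbol in dst.data["gene_symbol"].items():
        dst_by_symbol.setdefault(symbol, set()).add(probe)
    pairs = {}
    unmapped = 0
    for probe, symbol in src.data["gene_symbol"].items():
        targets = dst_by_symbol.get(symbol)
        if targets:
            pairs[probe] = frozenset(targets)
        else:
            unmapped += 1
    if unmapped:
        logger.info("platform map: %d source probes had no destination probe", unmapped)
    return PlatformMap(pairs, unmapped)


def map_signature(
    signature: SignatureModel,
    src: ProbeAnnotation,
    dst: ProbeAnnotation,
) -> SignatureModel:
    """Carry a signature onto another platform via shared gene symbols.

    Direction and performance are copied verbatim; a gene measured by
    several destination probes contributes all of them (each inheriting
    the direction). Entries whose gene symbol is absent from the
    destination platform are counted and logged, mirroring the attrition
    seen when moving a signature between array technologies.
    """
    missing_src = [p for p in signature.probe_ids if p not in src.data.index]
    if missing_src:
        raise KeyError(f"signature probes absent from source annotation: {missing_src[:5]}")
    pmap = build_platform_map(src, dst)
    rows = {}
    dropped = 0
    for probe, entry in signature.entries.iterrows():
        targets = pmap.pairs.get(probe)
        if not targets:
            dropped += 1
            continue
        for t in sorted(targets):
            if t in rows:
                prev = rows[t]
                if prev["direction"] != entry["direction"]:
                    logger.warning("probe %s inherits conflicting directions; keeping %s",
                                   t, prev["direction"])
                prev["performance"] = max(prev["performance"], entry["performance"])
            else:
                rows[t] = {"direction": entry["direction"], "performance": entry["performance"]}
    if dropped:
        logger.info("map_signature: %d of %d entries not mappable to destination platform",
                    dropped, len(signature))
    if not rows:
        raise ValueError("no signature probes mappable to the destination platform")
    entries = pd.DataFrame.from_dict(rows, orient="index")
    entries.index.name = "probe_id"
    note = f"{signature.training_note} [mapped across platforms; {dropped} entries lost]".strip()
    return SignatureModel(entries, training_note=note)


def collapse_to_genes(matrix: ExpressionMatrix, annotation: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse probe rows to one row per gene symbol (arithmetic mean on
    the log scale). Unannotated probes are dropped."""
    annotated = [p for p in matrix.probe_ids if p in annotation.data.index]
    if not annotated:
        raise ValueError("no probes in the matrix are annotated")
    symbols = annotation.symbols_for(annotated)
    sub = matrix.values.loc[annotated]
    collapsed = sub.groupby(symbols.to_numpy()).mean()
    collapsed.index.name = "gene_symbol"
    return matrix.with_values(collapsed, "collapse_to_genes")
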