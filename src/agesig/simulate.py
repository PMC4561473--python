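"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study designs the pipeline is built for:

* a two-group (young vs old) training cohort with a planted directional
  signature — by default 15 vs 15 samples with 85 % of the planted probes
  down-regulated with age, Gaussian log-intensity noise, and a small
  fraction of probes flagged as multi-locus;
* independent validation cohorts sharing the same truth but with fresh
  baselines and noise, optionally attenuated (other tissue, other lab);
* case-control cohorts of older subjects in which the cases carry an
  attenuated version of the old-direction signature and the destination
  platform may lack some signature probes;
* random gene-set collections (a GMT stand-in) with an optional planted
  term for calibrating enrichment.

All randomness flows from the single integer seed in each spec; there is
no global state. Noise is independent across probes — correlated probe
blocks, batch structure and other array artefacts are deliberately out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    SampleTable,
)


@dataclass
class CohortSpec:
    """Design of a two-group cohort with a planted signature.

    Defaults mirror the discovery design: 15 young vs 15 old subjects,
    a 100-probe signature (85 % down-regulated with age) planted in a
    2,000-probe universe at a one-standard-deviation mean shift.
    """

    n_young: int = 15
    n_old: int = 15
    n_probes: int = 2000
    n_signal: int = 100
    frac_down: float = 0.85
    effect_size: float = 1.0
    noise_sd: float = 1.0
    baseline_mean: float = 8.0
    frac_multi_locus: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal > self.n_probes:
            raise ValueError("n_signal cannot exceed n_probes")
        if not 0 <= self.frac_down <= 1:
            raise ValueError("frac_down must lie in [0, 1]")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        if min(self.n_young, self.n_old) < 2:
            raise ValueError("each group needs at least 2 samples")


@dataclass
class CaseControlSpec:
    """Design of an older-age case-control cohort.

    ``attenuation`` is the fraction of the old-direction expression shift
    removed in cases (0 = cases identical to controls, 1 = signature fully
    erased); ``platform_dropout`` is the fraction of signature probes
    absent from the simulated destination platform. ``extra_case_groups``
    adds further diagnosis groups to the same cohort (label, size,
    attenuation), e.g. a milder prodromal group alongside the full cases.
    """

    n_control: int = 70
    n_case: int = 45
    attenuation: float = 0.5
    platform_dropout: float = 0.0
    case_label: str = "case"
    extra_case_groups: tuple[tuple[str, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for att in (self.attenuation, *(g[2] for g in self.extra_case_groups)):
            if not 0 <= att <= 1:
                raise ValueError("attenuation must lie in [0, 1]")
        if not 0 <= self.platform_dropout < 1:
            raise ValueError("platform_dropout must lie in [0, 1)")
        sizes = [self.n_control, self.n_case, *(g[1] for g in self.extra_case_groups)]
        if min(sizes) < 2:
            raise ValueError("each group needs at least 2 samples")
        labels = ["control", self.case_label, *(g[0] for g in self.extra_case_groups)]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


@dataclass
class TruthRecord:
    """Ground truth of a simulated universe: which probes carry signal,
    in which direction, and how strongly (in expression units)."""

    probe_ids: list[str]
    gene_symbols: pd.Series  # indexed by probe_id
    signal: pd.DataFrame  # indexed by probe_id; columns: direction, effect
    noise_sd: float
    spec: CohortSpec = field(repr=False, default=None)

    @property
    def signal_probes(self) -> list[str]:
        return list(self.signal.index)

    @property
    def down_fraction(self) -> float:
        return float((self.signal["direction"] == "down").mean())


def _probe_ids(n: int) -> list[str]:
    return [f"p{i:06d}" for i in range(1, n + 1)]


def _sample_table(rng, groups: list[tuple[str, str, int, tuple[int, int]]]) -> SampleTable:
    """groups: list of (prefix, label, count, age_range)."""
    rows = []
    for prefix, label, count, (lo, hi) in groups:
        ages = rng.integers(lo, hi + 1, size=count)
        rows += [
            {"sample_id": f"{prefix}{i:03d}", "group": label, "age": int(a)}
            for i, a in enumerate(ages, start=1)
        ]
    df = pd.DataFrame(rows).set_index("sample_id")
    return SampleTable(df)


def simulate_training_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, SampleTable, ProbeAnnotation, TruthRecord]:
    """Two-group cohort with a planted directional signature.

    Probe g in sample s is ``baseline_g + 1[s is old] * effect_g + noise``
    with ``noise ~ N(0, noise_sd)`` and ``baseline_g ~ N(baseline_mean, 1)``.
    Down-planted probes get effect ``-effect_size * noise_sd``, up-planted
    probes the positive counterpart; the down count is the rounded
    ``frac_down * n_signal``, allocated deterministically. A fraction of
    probes (possibly overlapping the signal) is flagged multi-locus so the
    selection step's removal rule is exercised.
    """
    rng = np.random.default_rng(spec.seed)
    probes = _probe_ids(spec.n_probes)
    symbols = pd.Series([f"G{i:06d}" for i in range(1, spec.n_probes + 1)],
                        index=probes, name="gene_symbol")

    signal_idx = rng.choice(spec.n_probes, size=spec.n_signal, replace=False)
    n_down = int(round(spec.frac_down * spec.n_signal))
    effects = np.zeros(spec.n_probes)
    directions = np.full(spec.n_probes, "", dtype=object)
    effects[signal_idx[:n_down]] = -spec.effect_size * spec.noise_sd
    directions[signal_idx[:n_down]] = "down"
    effects[signal_idx[n_down:]] = spec.effect_size * spec.noise_sd
    directions[signal_idx[n_down:]] = "up"

    multi = rng.random(spec.n_probes) < spec.frac_multi_locus

    samples = _sample_table(
        rng,
        [("Y", "young", spec.n_young, (19, 28)), ("O", "old", spec.n_old, (59, 77))],
    )
    old_mask = (samples.data["group"] == "old").to_numpy()

    baseline = rng.normal(spec.baseline_mean, 1.0, size=spec.n_probes)
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_probes, spec.n_young + spec.n_old))
    values = baseline[:, None] + effects[:, None] * old_mask[None, :] + noise
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                     columns=samples.data.index)
    )
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {"gene_symbol": symbols, "multi_locus": multi, "platform": "array-sim-A"},
            index=pd.Index(probes, name="probe_id"),
        )
    )
    sig_probes = [probes[i] for i in signal_idx]
    truth = TruthRecord(
        probe_ids=probes,
        gene_symbols=symbols,
        signal=pd.DataFrame(
            {"direction": directions[signal_idx], "effect": effects[signal_idx]},
            index=pd.Index(sig_probes, name="probe_id"),
        ),
        noise_sd=spec.noise_sd,
        spec=spec,
    )
    return matrix, samples, annotation, truth


def simulate_validation_cohort(
    truth: TruthRecord,
    spec: CohortSpec,
    tissue_attenuation: float = 0.0,
) -> tuple[ExpressionMatrix, SampleTable]:
    """Independent cohort on the same probe universe: fresh baselines and
    noise, planted effects scaled by ``1 - tissue_attenuation``."""
    if not 0 <= tissue_attenuation <= 1:
        raise ValueError("tissue_attenuation must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    n_probes = len(truth.probe_ids)
    effects = np.zeros(n_probes)
    pos = {p: i for i, p in enumerate(truth.probe_ids)}
    for probe, row in truth.signal.iterrows():
        effects[pos[probe]] = row["effect"] * (1.0 - tissue_attenuation)

    samples = _sample_table(
        rng,
        [("VY", "young", spec.n_young, (19, 28)), ("VO", "old", spec.n_old, (59, 77))],
    )
    old_mask = (samples.data["group"] == "old").to_numpy()
    baseline = rng.normal(spec.baseline_mean, 1.0, size=n_probes)
    noise = rng.normal(0.0, spec.noise_sd, size=(n_probes, len(samples.data)))
    values = baseline[:, None] + effects[:, None] * old_mask[None, :] + noise
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(truth.probe_ids, name="probe_id"),
                     columns=samples.data.index)
    )
    return matrix, samples


def simulate_case_control(
    truth: TruthRecord,
    spec: CaseControlSpec,
) -> tuple[ExpressionMatrix, SampleTable, ProbeAnnotation]:
    """Older-age case-control cohort on a second platform.

    Controls carry the full old-direction signature; cases carry it scaled
    by ``1 - attenuation``. The emitted platform uses fresh probe ids (one
    per gene) and omits ``platform_dropout`` of the signature genes, so
    mapping a source-platform signature onto it reproduces cross-platform
    attrition.
    """
    rng = np.random.default_rng(spec.seed)
    n_signal = len(truth.signal)
    n_drop = int(round(spec.platform_dropout * n_signal))
    dropped = set(
        rng.choice(truth.signal.index.to_numpy(), size=n_drop, replace=False)
    ) if n_drop else set()
    kept = [p for p in truth.probe_ids if p not in dropped]

    new_ids = [f"b{i:06d}" for i in range(1, len(kept) + 1)]
    symbols = truth.gene_symbols.loc[kept].to_numpy()

    effects = np.zeros(len(kept))
    signal_rows = truth.signal.reindex(kept).dropna()
    pos = {p: i for i, p in enumerate(kept)}
    for probe, row in signal_rows.iterrows():
        effects[pos[probe]] = row["effect"]

    group_designs = [
        ("C", "control", spec.n_control, 0.0),
        ("D", spec.case_label, spec.n_case, spec.attenuation),
    ] + [
        (f"X{i}", label, size, att)
        for i, (label, size, att) in enumerate(spec.extra_case_groups)
    ]
    samples = _sample_table(
        rng, [(prefix, label, size, (65, 75)) for prefix, label, size, _ in group_designs]
    )
    attenuation_of = {label: att for _, label, _, att in group_designs}
    scale = 1.0 - samples.data["group"].map(attenuation_of).to_numpy()
    baseline = rng.normal(truth.spec.baseline_mean if truth.spec else 8.0, 1.0, size=len(kept))
    noise = rng.normal(0.0, truth.noise_sd, size=(len(kept), len(samples.data)))
    values = baseline[:, None] + effects[:, None] * scale[None, :] + noise
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(new_ids, name="probe_id"),
                     columns=samples.data.index)
    )
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {"gene_symbol": symbols, "multi_locus": False, "platform": "beadchip-sim-B"},
            index=pd.Index(new_ids, name="probe_id"),
        )
    )
    return matrix, samples, annotation


def simulate_gmt(
    universe,
    n_terms: int = 50,
    size_range: tuple[int, int] = (10, 200),
    planted_term_from: set[str] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene-set collection over ``universe``.

    Terms are uniform without-replacement draws; ``planted_term_from``
    adds one term equal to the supplied gene set, creating real
    enrichment for calibration tests.
    """
    universe = sorted(universe)
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("term sizes cannot exceed the universe")
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        terms[f"SYN:{i:04d}"] = (f"synthetic term {i}", members)
    if planted_term_from:
        terms["SYN:PLANTED"] = ("planted term", frozenset(planted_term_from))
    return GeneSetCollection(terms)
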