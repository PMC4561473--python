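import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agesig import (
    SelectionConfig,
    SignatureModel,
    build_signature,
    merge_signatures,
    moderated_t,
    nested_loocv_select,
)
from agesig.containers import PerformanceTable
from conftest import build_matrix, build_samples
from test_preprocess import make_annotation, make_signature


def _limma_fixture():
    """Frozen 80x10 matrix whose eBayes moderated t was computed once with
    limma; heterogeneous per-gene variances drawn from the scaled
    inverse-chi-square prior (d0=4, s0^2=1)."""
    rng = np.random.default_rng(2024)
    G, n1, n2 = 80, 5, 5
    v = 1.0 * 4.0 / rng.chisquare(4.0, size=G)
    X = rng.normal(0, np.sqrt(v)[:, None], size=(G, n1 + n2)) + 8.0
    X[:10, n2:] += 1.0
    frame = pd.DataFrame(
        X, index=[f"p{i:03d}" for i in range(G)], columns=[f"s{i}" for i in range(10)]
    ).round(8)
    m = build_matrix(frame.to_numpy(), probes=list(frame.index), samples=list(frame.columns))
    samples = build_samples({f"s{i}": ("young" if i < 5 else "old") for i in range(10)})
    return m, samples


class TestModeratedT:
    # reference values computed with limma::eBayes on the same matrix;
    # signs follow this package's sorted-label convention (young - old),
    # i.e. the negative of limma's old-vs-young coefficient.
    LIMMA_D0 = 4.080746741
    LIMMA_S0SQ = 1.0944847378
    LIMMA_T = {
        "p000": -1.5183606932,
        "p001": -0.2639335593,
        "p002": -0.3831867017,
        "p010": 1.0867072311,
        "p025": 0.7461224979,
        "p050": 0.0894727300,
        "p079": -1.9326714083,
    }

    def test_matches_limma_reference(self):
        m, samples = _limma_fixture()
        res = moderated_t(m, samples)
        assert res["prior_df"].iloc[0] == pytest.approx(self.LIMMA_D0, rel=1e-6)
        assert res["prior_var"].iloc[0] == pytest.approx(self.LIMMA_S0SQ, rel=1e-6)
        for probe, expected in self.LIMMA_T.items():
            assert res.loc[probe, "moderated_t"] == pytest.approx(expected, rel=1e-6)

    def test_prior_df_zero_gives_ordinary_t(self):
        m, samples = _limma_fixture()
        res = moderated_t(m, samples, prior_df=0)
        assert np.allclose(res["moderated_t"], res["ordinary_t"])
        # and the shrunken statistic differs from the ordinary one otherwise
        shrunk = moderated_t(m, samples)
        assert not np.allclose(
            shrunk.sort_index()["moderated_t"], res.sort_index()["ordinary_t"]
        )

    def test_zero_mean_diff_gives_zero_t(self):
        rng = np.random.default_rng(9)
        arr = rng.normal(size=(12, 8))
        arr[0, 4:] = arr[0, :4]  # identical group profiles -> mean_diff 0
        m = build_matrix(arr)
        samples = build_samples({f"s{i + 1}": ("young" if i < 4 else "old") for i in range(8)})
        res = moderated_t(m, samples)
        assert res.loc["g1", "mean_diff"] == pytest.approx(0.0)
        assert res.loc["g1", "moderated_t"] == pytest.approx(0.0)

    def test_shared_variance_prior_recovery(self):
        # all probes share one true variance: the prior variance estimate
        # should recover it and shrinkage should not reorder probes much
        rng = np.random.default_rng(77)
        G = 2000
        arr = rng.normal(0, 1.0, size=(G, 12)) + 8
        m = build_matrix(arr)
        samples = build_samples({f"s{i + 1}": ("young" if i < 6 else "old") for i in range(12)})
        res = moderated_t(m, samples)
        assert res["prior_var"].iloc[0] == pytest.approx(1.0, rel=0.10)
        rho = stats.spearmanr(np.abs(res["moderated_t"]), np.abs(res["ordinary_t"])).statistic
        assert rho > 0.9

    def test_sorted_by_magnitude(self):
        m, samples = _limma_fixture()
        res = moderated_t(m, samples)
        mags = np.abs(res["moderated_t"].to_numpy())
        assert (np.diff(mags) <= 1e-12).all()

    def test_small_groups_rejected(self):
        m = build_matrix(np.random.default_rng(0).normal(size=(12, 3)))
        samples = build_samples({"s1": "young", "s2": "old", "s3": "old"})
        with pytest.raises(ValueError, match="at least 2"):
            moderated_t(m, samples)


@pytest.fixture(scope="module")
def small_cohort():
    rng = np.random.default_rng(15)
    arr = rng.normal(8, 1, size=(30, 8))
    arr[0, 4:] += 5.0  # one strongly separating probe (>=5 sd shift)
    m = build_matrix(arr)
    samples = build_samples({f"s{i + 1}": ("young" if i < 4 else "old") for i in range(8)})
    return m, samples


class TestNestedLoocv:
    def test_counting_conservation(self, small_cohort):
        m, samples = small_cohort
        cfg = SelectionConfig(n_inner=5, k=3)
        perf = nested_loocv_select(m, samples, cfg)
        n = 8
        assert perf.total_decisions == n * (n - 1)
        assert perf.total_events == n * (n - 1) * cfg.n_inner

    def test_perfect_separator_probe(self):
        # a 6-sd separator classified on its own feature axis is never wrong
        rng = np.random.default_rng(15)
        arr = rng.normal(8, 1, size=(30, 16))
        arr[0, 8:] += 6.0
        m = build_matrix(arr)
        samples = build_samples(
            {f"s{i + 1}": ("young" if i < 8 else "old") for i in range(16)}
        )
        perf = nested_loocv_select(m, samples, SelectionConfig(n_inner=1, k=1))
        assert perf.data.loc["g1", "performance"] == 1.0
        assert perf.data.loc["g1", "appearances"] == perf.total_decisions

    def test_sample_order_invariance(self, small_cohort):
        m, samples = small_cohort
        cfg = SelectionConfig(n_inner=5, k=3)
        perf = nested_loocv_select(m, samples, cfg)
        perm = np.random.default_rng(1).permutation(m.shape[1])
        m2 = build_matrix(
            m.values.iloc[:, perm].to_numpy(),
            probes=m.probe_ids,
            samples=[m.sample_ids[i] for i in perm],
        )
        perf2 = nested_loocv_select(m2, samples, cfg)
        pd.testing.assert_frame_equal(
            perf.data.sort_index(), perf2.data.sort_index()
        )

    def test_group_smaller_than_k_plus_1_rejected(self, small_cohort):
        m, samples = small_cohort
        with pytest.raises(ValueError, match="k\\+1"):
            nested_loocv_select(m, samples, SelectionConfig(n_inner=5, k=4))


class TestBuildSignature:
    def _perf(self, rows, total=100, n_inner=10):
        df = pd.DataFrame(rows, columns=["probe_id", "appearances", "correct"]).set_index("probe_id")
        df["performance"] = df["correct"] / df["appearances"]
        return PerformanceTable(df, total_decisions=total, n_inner=n_inner)

    @pytest.fixture()
    def toy_training(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(8, 1, size=(12, 8))
        arr[0, 4:] -= 2.0  # p1 down with age
        arr[1, 4:] += 2.0  # p2 up with age
        probes = [f"p{i + 1}" for i in range(12)]
        m = build_matrix(arr, probes=probes)
        samples = build_samples({f"s{i + 1}": ("young" if i < 4 else "old") for i in range(8)})
        annot = make_annotation({p: f"G{p}" for p in probes})
        return m, samples, annot

    def test_threshold_and_top_n(self, toy_training):
        m, samples, annot = toy_training
        perf = self._perf([("p1", 100, 100), ("p2", 100, 95), ("p3", 100, 60)])
        cfg = SelectionConfig(n_inner=10, top_n=2)
        sig, relaxed = build_signature(perf, m, samples, annot, cfg)
        assert sig.probe_ids == ["p1", "p2"]
        assert len(relaxed) == 2  # p3 at 0.60 misses even the 70 % threshold

    def test_multi_locus_removed_first(self, toy_training):
        m, samples, annot = toy_training
        annot.data.loc["p1", "multi_locus"] = True
        perf = self._perf([("p1", 100, 100), ("p2", 100, 95)])
        sig, _ = build_signature(perf, m, samples, annot, SelectionConfig(n_inner=10, top_n=2))
        assert "p1" not in sig.probe_ids

    def test_rare_probes_filtered(self, toy_training):
        m, samples, annot = toy_training
        # p3 appears in 5 of 100 decisions (below the 10 % floor), all correct
        perf = self._perf([("p1", 100, 95), ("p3", 5, 5)])
        sig, _ = build_signature(perf, m, samples, annot, SelectionConfig(n_inner=10, top_n=2))
        assert "p3" not in sig.probe_ids

    def test_directions_from_full_training_data(self, toy_training):
        m, samples, annot = toy_training
        perf = self._perf([("p1", 100, 95), ("p2", 100, 95)])
        sig, _ = build_signature(perf, m, samples, annot, SelectionConfig(n_inner=10, top_n=2))
        assert sig.entries.loc["p1", "direction"] == "down"
        assert sig.entries.loc["p2", "direction"] == "up"

    def test_never_pads(self, toy_training, caplog):
        m, samples, annot = toy_training
        perf = self._perf([("p1", 100, 95)])
        with caplog.at_level(logging.WARNING, logger="agesig"):
            sig, _ = build_signature(perf, m, samples, annot, SelectionConfig(n_inner=10, top_n=150))
        assert len(sig) == 1
        assert "not padding" in caplog.text


class TestMergeSignatures:
    def test_disjoint_union_150_plus_48(self):
        a = make_signature([(f"a{i}", "down", 0.9) for i in range(150)])
        b = make_signature([(f"b{i}", "up", 0.8) for i in range(48)])
        assert len(merge_signatures(a, b)) == 198

    def test_merge_with_empty_is_identity(self):
        a = make_signature([("p1", "down", 0.9)])
        empty = SignatureModel(
            pd.DataFrame(columns=["direction", "performance"],
                         index=pd.Index([], name="probe_id"))
        )
        assert merge_signatures(a, empty).entries.equals(a.entries)

    def test_idempotent(self):
        a = make_signature([("p1", "down", 0.9), ("p2", "up", 0.8)])
        assert merge_signatures(a, a).entries.equals(a.entries)

    def test_collision_keeps_first_direction_and_max_performance(self):
        a = make_signature([("p1", "down", 0.9)])
        b = make_signature([("p1", "up", 0.95)])
        with pytest.warns(UserWarning, match="conflicting"):
            merged = merge_signatures(a, b)
        assert merged.entries.loc["p1", "direction"] == "down"
        assert merged.entries.loc["p1", "performance"] == 0.95
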