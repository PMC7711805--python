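"""Confusion-matrix metrics, ROC/AUC and the channel comparison table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_u
from udseeg import (
    ConfusionMatrix,
    NUDS,
    UDS,
    FeatureMatrix,
    ChannelProfile,
    channel_comparison,
    compute_metrics,
    generate_feature_table,
    make_report,
    roc_auc,
)


class TestComputeMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionMatrix(tp=90, fn=10, fp=20, tn=80))
        assert m.sen == pytest.approx(90.0)
        assert m.spe == pytest.approx(80.0)
        assert m.pre == pytest.approx(81.82, abs=0.005)
        assert m.acc == pytest.approx(85.0)
        assert m.undefined == ()

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=800, fn=0, fp=0, tn=800))
        assert (m.acc, m.sen, m.spe, m.pre) == (100.0, 100.0, 100.0, 100.0)

    def test_always_positive_predictor(self):
        m = compute_metrics(ConfusionMatrix(tp=800, fn=0, fp=800, tn=0))
        assert m.sen == 100.0 and m.spe == 0.0
        assert m.pre == 50.0 and m.acc == 50.0

    def test_zero_denominator_flagged_not_zero(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fn=0, fp=5, tn=5))
        assert np.isnan(m.sen) and "SEN" in m.undefined
        assert not np.isnan(m.spe)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 1000)] * 4))
def test_metric_identities_property(counts):
    """ACC is the prevalence-weighted combination of SEN and SPE."""
    tp, fn, fp, tn = counts
    cm = ConfusionMatrix(tp, fn, fp, tn)
    if cm.total == 0:
        return
    m = compute_metrics(cm)
    assert m.acc == pytest.approx(100.0 * (tp + tn) / cm.total)
    if tp + fn and tn + fp:
        weighted = (m.sen * (tp + fn) + m.spe * (tn + fp)) / cm.total
        assert m.acc == pytest.approx(weighted)


class TestROC:
    def test_perfect_separation_auc_one(self):
        scores = np.concatenate([np.ones(50) + 1, np.zeros(50)])
        labels = np.array([UDS] * 50 + [NUDS] * 50, dtype=object)
        curve = roc_auc(scores, labels)
        assert curve.auc == pytest.approx(1.0)

    def test_curve_monotone_from_origin_to_one(self, rng):
        scores = rng.normal(size=200)
        labels = np.array([UDS, NUDS] * 100, dtype=object)
        curve = roc_auc(scores, labels)
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()
        assert 0.0 <= curve.auc <= 1.0

    def test_auc_equals_rank_statistic(self, rng):
        # AUC = U / (n1 * n2), including under heavy ties
        scores = rng.integers(0, 10, size=120).astype(float)
        labels = np.array([UDS] * 70 + [NUDS] * 50, dtype=object)
        curve = roc_auc(scores, labels)
        u = brute_force_u(scores[:70], scores[70:])
        assert curve.auc == pytest.approx(u / (70 * 50), abs=1e-12)

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(2024)
        scores = rng.normal(size=2000)
        labels = np.array([UDS] * 1000 + [NUDS] * 1000, dtype=object)
        assert abs(roc_auc(scores, labels).auc - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.array([UDS] * 5, dtype=object))


def _one_channel(a, b, name="C3"):
    values = np.concatenate([a, b])[:, None]
    labels = np.array([UDS] * len(a) + [NUDS] * len(b), dtype=object)
    return FeatureMatrix(values, labels, [name], np.zeros(len(values), dtype=int))


class TestChannelComparison:
    def test_identical_samples_not_significant(self, rng):
        x = rng.normal(size=100)
        df = channel_comparison(_one_channel(x, x.copy()))
        assert df.loc[0, "p_value"] > 0.9
        assert not df.loc[0, "significant"]

    def test_separated_profile_gives_tiny_p(self):
        prof = [ChannelProfile("C3", 0.424, 0.127, 0.534, 0.159)]
        fm = generate_feature_table(prof, 800, seed=31)
        df = channel_comparison(fm)
        assert df.loc[0, "p_value"] < 0.001

    def test_label_swap_symmetry(self, rng):
        a, b = rng.normal(0, 1, 60), rng.normal(0.5, 1, 60)
        fwd = channel_comparison(_one_channel(a, b))
        rev = channel_comparison(_one_channel(b, a))
        assert fwd.loc[0, "p_value"] == pytest.approx(rev.loc[0, "p_value"], rel=1e-9)
        d_fwd = fwd.loc[0, "nuds_mean"] - fwd.loc[0, "uds_mean"]
        d_rev = rev.loc[0, "nuds_mean"] - rev.loc[0, "uds_mean"]
        assert d_fwd == pytest.approx(-d_rev)

    def test_constant_channel_flagged(self):
        fm = _one_channel(np.ones(20), np.ones(20))
        df = channel_comparison(fm)
        assert np.isnan(df.loc[0, "p_value"])
        assert not df.loc[0, "significant"]

    def test_u_statistic_matches_brute_force_small_samples(self, rng):
        for trial in range(30):
            n1, n2 = rng.integers(2, 9, size=2)
            a = rng.integers(0, 6, size=n1).astype(float)  # heavy ties
            b = rng.integers(0, 6, size=n2).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            df = channel_comparison(_one_channel(a, b))
            assert df.loc[0, "u_stat"] == pytest.approx(brute_force_u(a, b))

    def test_adjusted_p_columns_present(self, feature_table_800):
        df = channel_comparison(feature_table_800)
        assert len(df) == 30
        assert (df["p_bonferroni"] >= df["p_value"] - 1e-15).all()
        assert (df["p_fdr"] >= df["p_value"] - 1e-15).all()


class TestMakeReport:
    def test_report_regeneration_is_byte_identical(self, profiles, tmp_path):
        from udseeg import ClassifierSpec, CVConfig, run_cv

        fm = generate_feature_table(profiles, 40, seed=2)
        res = {"sampen": {"lr": run_cv(fm, ClassifierSpec("lr"), CVConfig(n_folds=4, seed=0))}}
        comp = channel_comparison(fm)
        p1 = make_report(res, comp, tmp_path / "a")
        p2 = make_report(res, comp, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_empty_inputs_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            make_report({}, None, tmp_path)
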