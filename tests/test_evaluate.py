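"""Labelling, SMOTE, LOO/cross-cohort trees, DeLong, BH-FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import dcehabitat.evaluate as ev
from dcehabitat.evaluate import (
    delong_test,
    evaluate_cross_cohort,
    evaluate_loo,
    fdr_correct,
    label_biopsies,
    smote_balance,
    tuple_search,
)


class TestLabels:
    def test_gleason_grouping(self):
        df = pd.DataFrame({
            "biopsy_id": ["a", "b", "c", "d"],
            "patient_id": ["p"] * 4,
            "gleason_primary": [3, 3, 4, 5],
            "gleason_secondary": [4, 3, 3, 3],
        })
        records, dropped = label_biopsies(df)
        assert dropped == 0
        assert [r.label for r in records] == [1, 0, 1, 1]

    def test_benign_rows_dropped_and_counted(self):
        df = pd.DataFrame({
            "gleason_primary": [3, None, 0, 4],
            "gleason_secondary": [3, None, 0, 4],
        })
        records, dropped = label_biopsies(df)
        assert len(records) == 2 and dropped == 2

    def test_invalid_component_rejected(self):
        df = pd.DataFrame({"gleason_primary": [6], "gleason_secondary": [3]})
        with pytest.raises(ValueError, match="outside 3..5"):
            label_biopsies(df)


class TestSmote:
    def test_balanced_input_unchanged(self):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array([0, 0, 1, 1])
        Xb, yb = smote_balance(X, y, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_institution_scale_imbalance_equalized(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (84, 3)), rng.normal(3, 1, (15, 3))])
        y = np.array([0] * 84 + [1] * 15)
        Xb, yb = smote_balance(X, y, seed=1)
        counts = np.bincount(yb)
        assert counts[0] == counts[1] == 84
        # majority samples untouched, in order
        assert np.array_equal(Xb[:99], X)

    def test_synthetic_points_lie_on_minority_segments(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(5, 1, (8, 2))])
        y = np.array([0] * 30 + [1] * 8)
        Xb, yb = smote_balance(X, y, k=3, seed=3)
        minority = X[y == 1]
        for s in Xb[38:]:
            on_segment = False
            for i, j in itertools.combinations(range(len(minority)), 2):
                a, b = minority[i], minority[j]
                d = b - a
                t = np.dot(s - a, d) / np.dot(d, d)
                if 0.0 <= t <= 1.0 and np.linalg.norm(s - (a + t * d)) < 1e-9:
                    on_segment = True
                    break
            assert on_segment

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 2))
        y = np.array([0] * 14 + [1] * 6)
        out1 = smote_balance(X, y, seed=5)
        out2 = smote_balance(X, y, seed=5)
        assert np.array_equal(out1[0], out2[0])

    def test_singleton_minority_rejected(self):
        X = np.zeros((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="at least 2"):
            smote_balance(X, y)


class TestLOO:
    def test_perfectly_separable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (10, 2))])
        y = np.array([0] * 20 + [1] * 10)
        res = evaluate_loo(X, y, feature_names=("f1", "f2"), seed=0)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_no_leakage_into_balanced_fold(self, monkeypatch):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (12, 2)), rng.normal(2, 1, (6, 2))])
        y = np.array([0] * 12 + [1] * 6)
        seen = []
        original = ev.smote_balance

        def recording(features, labels, **kw):
            seen.append(np.asarray(features).copy())
            return original(features, labels, **kw)

        monkeypatch.setattr(ev, "smote_balance", recording)
        evaluate_loo(X, y, seed=0)
        assert len(seen) == 18
        for i, fold in enumerate(seen):
            held_out = X[i]
            assert not np.any(np.all(fold == held_out, axis=1))

    def test_global_smote_comparison_mode(self):
        # global balancing runs over the augmented (exactly balanced) set
        # and is flagged as leaky
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (16, 2)), rng.normal(1, 1, (6, 2))])
        y = np.array([0] * 16 + [1] * 6)
        res = evaluate_loo(X, y, seed=0, smote_scope="global")
        assert res.n == 32  # 16 + 16 after balancing
        assert "global_smote_leaky" in res.flags
        with pytest.raises(ValueError, match="smote_scope"):
            evaluate_loo(X, y, smote_scope="everywhere")

    def test_null_labels_near_chance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 2))
        aucs = []
        for s in range(10):
            y = np.random.default_rng(s).permutation([0] * 40 + [1] * 20)
            aucs.append(evaluate_loo(X, y, seed=s).auc)
        assert 0.35 < np.mean(aucs) < 0.65


class TestCrossCohort:
    def test_train_equals_test_is_resubstitution(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(2, 1, (12, 2))])
        y = np.array([0] * 20 + [1] * 12)
        res = evaluate_cross_cohort(X, y, X, y, seed=0)
        assert res.scheme == "cross_cohort"
        assert res.auc > 0.9  # resubstitution on separable-ish data

    def test_covariate_shift_degrades_auc(self):
        rng = np.random.default_rng(1)
        X_tr = np.vstack([rng.normal(0, 1, (40, 1)), rng.normal(3, 1, (40, 1))])
        y = np.array([0] * 40 + [1] * 40)
        aucs = []
        for shift in (0.0, 3.0, 6.0):
            res = evaluate_cross_cohort(X_tr, y, X_tr + shift, y, seed=0)
            aucs.append(res.auc)
        assert aucs[0] > aucs[-1]

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError, match="feature columns"):
            evaluate_cross_cohort(np.zeros((4, 2)), [0, 0, 1, 1],
                                  np.zeros((4, 3)), [0, 0, 1, 1])


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(0)
    y = np.array([0] * 20 + [1] * 10)
    data = {name: rng.normal(y * (0.5 + i * 0.1), 1.0)
            for i, name in enumerate(ev.DCE_FEATURE_NAMES)}
    df = pd.DataFrame(data)
    for name in ("MaxHistGrad", "MinorAxisL"):
        df[name] = rng.normal(y * 0.8, 1.0)
    return df, y


class TestTupleSearch:
    def test_single_and_pair_count(self, toy):
        df, y = toy
        table, results = tuple_search(df, y, scheme="loo", seed=0)
        assert len(table) == 28
        assert sum(len(k) == 1 for k in results) == 7
        assert sum(len(k) == 2 for k in results) == 21

    def test_quadruple_count_and_conservation(self, toy):
        df, y = toy
        adc_pairs = [("MaxHistGrad", "MinorAxisL")]
        table, results = tuple_search(df, y, adc_pairs=adc_pairs,
                                      scheme="loo", seed=0)
        assert len(table) == 28 + 21
        assert sum(len(k) == 4 for k in results) == 21
        # ranking is a permutation: every evaluated tuple appears once
        assert sorted(table["features"]) == sorted(
            "+".join(k) for k in results)

    def test_missing_feature_rejected(self, toy):
        df, y = toy
        with pytest.raises(KeyError):
            tuple_search(df.drop(columns=["wi"]), y, scheme="loo")


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = np.array([0, 1] * 15)
        auc_a, auc_b, p = delong_test(s, s, y)
        assert auc_a == auc_b and p == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(5, 20), rng.integers(5, 20)
        y = np.array([1] * n1 + [0] * n0)
        a = rng.normal(y, 1.0)
        b = rng.normal(y * 0.5, 1.0)
        auc_a, auc_b, _ = delong_test(a, b, y)
        u_a = mannwhitneyu(a[y == 1], a[y == 0]).statistic / (n1 * n0)
        u_b = mannwhitneyu(b[y == 1], b[y == 0]).statistic / (n1 * n0)
        assert auc_a == pytest.approx(u_a)
        assert auc_b == pytest.approx(u_b)

    def test_p_close_to_bootstrap_oracle(self):
        rng = np.random.default_rng(12345)
        n = 20
        y = np.array([1] * n + [0] * n)
        a = rng.normal(y * 1.2, 1.0)
        b = rng.normal(y * 0.4, 1.0)
        _, _, p = delong_test(a, b, y)
        # stratified bootstrap of the AUC difference
        B = 20000
        boot_rng = np.random.default_rng(0)
        pos = boot_rng.integers(0, n, size=(B, n))
        neg = n + boot_rng.integers(0, n, size=(B, n))
        diffs = np.empty(B)
        for i in range(B):
            idx = np.concatenate([pos[i], neg[i]])
            yy = y[idx]
            aucs = []
            for s in (a, b):
                ss = s[idx]
                aucs.append(
                    (ss[yy == 1][:, None] > ss[yy == 0][None, :]).mean()
                    + 0.5 * (ss[yy == 1][:, None] == ss[yy == 0][None, :]).mean())
            diffs[i] = aucs[0] - aucs[1]
        p_boot = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
        assert abs(p - p_boot) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            delong_test(np.arange(4.0), np.arange(4.0), np.ones(4))


class TestFDR:
    def test_hand_worked_example(self):
        thr, flags = fdr_correct(np.array([0.01, 0.02, 0.04]), alpha=0.05)
        assert thr == 0.04 and flags.all()

    def test_all_ones_nothing_significant(self):
        thr, flags = fdr_correct(np.ones(5), alpha=0.05)
        assert thr == 0.0 and not flags.any()

    def test_single_test_reduces_to_alpha(self):
        assert fdr_correct(np.array([0.04]), alpha=0.05)[1].all()
        assert not fdr_correct(np.array([0.06]), alpha=0.05)[1].any()

    def test_matches_statsmodels_on_all_subsets(self):
        from statsmodels.stats.multitest import multipletests
        base = np.array([0.001, 0.008, 0.012, 0.03, 0.049, 0.1, 0.35, 0.9])
        for r in range(1, len(base) + 1):
            for subset in itertools.combinations(base, r):
                p = np.array(subset)
                _, flags = fdr_correct(p, alpha=0.05)
                reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
                assert np.array_equal(flags, reject), subset

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.5, 1.2]))
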