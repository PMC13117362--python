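"""Metrics, Monte-Carlo CV, stress tests, paired statistics and alignment."""

import itertools
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from cognitrace.corpus import CLASSES, Note, PatientRecord
from cognitrace.evaluation import (
    EvaluationError, audit_split_leakage, bootstrap_ci, class_centroid_anchors,
    compute_metrics, delong_test, mcnemar_test, monte_carlo_cv,
    permutation_label_test, procrustes_align, rbf_mmd, temporal_stability,
)

T0 = datetime(2020, 1, 1, tzinfo=timezone.utc)


def proba_for(y_pred, n_classes=3, conf=0.9):
    out = np.full((len(y_pred), n_classes), (1 - conf) / (n_classes - 1))
    out[np.arange(len(y_pred)), y_pred] = conf
    return out


# ---------------------------------------------------------------------------
# metric report


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = compute_metrics(y, proba_for(y))
        assert rep.accuracy == rep.mcc == rep.kappa == 1.0
        assert rep.macro_f1 == 1.0

    def test_chance_level_on_random_predictions(self, rng):
        n = 3000
        y = rng.integers(0, 3, n)
        proba = rng.dirichlet(np.ones(3), size=n)
        rep = compute_metrics(y, proba)
        assert rep.accuracy == pytest.approx(1 / 3, abs=0.04)
        assert rep.kappa == pytest.approx(0.0, abs=0.05)
        assert rep.roc_auc == pytest.approx(0.5, abs=0.04)

    def test_macro_equals_unweighted_mean_of_per_class(self, rng):
        y = rng.integers(0, 3, 200)
        proba = rng.dirichlet(np.ones(3), size=200)
        rep = compute_metrics(y, proba)
        assert rep.macro_f1 == pytest.approx(
            np.mean([rep.per_class[c]["f1"] for c in CLASSES]), abs=1e-12)
        assert rep.sensitivity == pytest.approx(
            np.mean([rep.per_class[c]["recall"] for c in CLASSES]), abs=1e-12)

    def test_hand_confusion_matrix_oracle(self):
        # rows = truth, cols = prediction
        cm = np.array([[5, 1, 0], [2, 4, 1], [0, 2, 3]])
        y_true, y_pred = [], []
        for i in range(3):
            for j in range(3):
                y_true += [i] * cm[i, j]
                y_pred += [j] * cm[i, j]
        rep = compute_metrics(np.array(y_true), proba_for(np.array(y_pred)))
        for i, cls in enumerate(CLASSES):
            tp = cm[i, i]
            fn = cm[i].sum() - tp
            fp = cm[:, i].sum() - tp
            tn = cm.sum() - tp - fn - fp
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            assert rep.per_class[cls]["f1"] == pytest.approx(
                2 * prec * rec / (prec + rec), abs=1e-12)
            assert rep.per_class[cls]["mcc"] == pytest.approx(
                (tp * tn - fp * fn) /
                np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)), abs=1e-12)

    def test_mcc_kappa_exhaustive_small_matrices(self):
        """Brute-force contingency formulas on all 0/1 matrices + random ones."""
        rng = np.random.default_rng(7)
        matrices = [np.array(m).reshape(3, 3)
                    for m in itertools.product((0, 1), repeat=9)]
        matrices += [rng.integers(0, 4, size=(3, 3)) for _ in range(500)]
        for cm in matrices:
            if cm.sum() == 0 or any(cm[i].sum() == 0 for i in range(3)):
                continue
            y_true, y_pred = [], []
            for i in range(3):
                for j in range(3):
                    y_true += [i] * cm[i, j]
                    y_pred += [j] * cm[i, j]
            y_true, y_pred = np.array(y_true), np.array(y_pred)
            rep = compute_metrics(y_true, proba_for(y_pred))
            n = cm.sum()
            po = np.trace(cm) / n
            pe = sum(cm[i].sum() * cm[:, i].sum() for i in range(3)) / n ** 2
            kappa = 0.0 if pe == 1 else (po - pe) / (1 - pe)
            assert rep.kappa == pytest.approx(kappa, abs=1e-9)
            c = np.trace(cm)
            s = n
            t_k = cm.sum(axis=1)
            p_k = cm.sum(axis=0)
            denom = np.sqrt(float(s**2 - (p_k**2).sum()) * float(s**2 - (t_k**2).sum()))
            mcc = 0.0 if denom == 0 else (c * s - (t_k * p_k).sum()) / denom
            assert rep.mcc == pytest.approx(mcc, abs=1e-9)

    def test_absent_class_flagged_undefined(self):
        y = np.array([0, 0, 1, 1])
        rep = compute_metrics(y, proba_for(y))
        assert np.isnan(rep.per_class["AD"]["f1"])
        assert rep.roc_auc is None


# ---------------------------------------------------------------------------
# Monte-Carlo CV


def make_record(pid, label):
    note = Note(note_id=f"{pid}-n0", patient_id=pid, timestamp=T0,
                sections={}, text="stable visit.")
    return PatientRecord(patient_id=pid, notes=[note], label=label)


class FixedModel:
    """Deterministic stub: always predicts the patient's true class."""

    def fit(self, records):
        return self

    def predict_proba(self, records):
        idx = {c: i for i, c in enumerate(CLASSES)}
        return proba_for(np.array([idx[r.label] for r in records]))


class TestMonteCarloCV:
    def corpus(self):
        return [make_record(f"{c}{i}", c) for c in CLASSES for i in range(10)]

    def test_deterministic_classifier_zero_sd(self):
        rep = monte_carlo_cv(self.corpus(), FixedModel, n_folds=5, seed=0)
        assert rep.accuracy == 1.0
        assert rep.sd["accuracy"] == 0.0

    def test_rerun_identical(self):
        a = monte_carlo_cv(self.corpus(), FixedModel, n_folds=5, seed=3)
        b = monte_carlo_cv(self.corpus(), FixedModel, n_folds=5, seed=3)
        assert a.accuracy == b.accuracy and a.sd == b.sd

    def test_needs_two_folds(self):
        with pytest.raises(EvaluationError):
            monte_carlo_cv(self.corpus(), FixedModel, n_folds=1)

    def test_fold_variance_shrinks_with_test_size(self, rng):
        class NoisyModel:
            def __init__(self):
                self.rng = np.random.default_rng(rng.integers(2**31))

            def fit(self, records):
                return self

            def predict_proba(self, records):
                return proba_for(self.rng.integers(0, 3, len(records)))

        big_corpus = [make_record(f"{c}{i}", c) for c in CLASSES for i in range(60)]
        small = monte_carlo_cv(self.corpus(), NoisyModel, n_folds=40,
                               test_frac=0.15, seed=1)
        large = monte_carlo_cv(big_corpus, NoisyModel, n_folds=40,
                               test_frac=0.15, seed=1)
        assert large.sd["accuracy"] < small.sd["accuracy"]


# ---------------------------------------------------------------------------
# temporal stability


class PrefixModel:
    """Stub whose P(class 0) depends on the number of notes seen."""

    def __init__(self, sequence):
        self.sequence = sequence

    def predict_proba(self, records):
        out = []
        for r in records:
            p0 = self.sequence[min(len(r.notes), len(self.sequence)) - 1]
            out.append([p0, (1 - p0) / 2, (1 - p0) / 2])
        return np.array(out)


class TestTemporalStability:
    def record(self, pid, n_notes):
        notes = [Note(note_id=f"{pid}-n{i}", patient_id=pid,
                      timestamp=T0 + timedelta(days=30 * i), sections={}, text="x.")
                 for i in range(n_notes)]
        return PatientRecord(patient_id=pid, notes=notes, label="Normal")

    def test_constant_prefix_probabilities_zero_variance(self):
        rep = temporal_stability(PrefixModel([0.8, 0.8]), [self.record("a", 2)])
        assert rep.per_patient["a"] == pytest.approx(0.0)

    def test_two_prefix_population_variance(self):
        rep = temporal_stability(PrefixModel([0.5, 0.7]), [self.record("a", 2)])
        assert rep.per_patient["a"] == pytest.approx(0.01)

    def test_single_note_patients_excluded_and_counted(self):
        rep = temporal_stability(PrefixModel([0.6, 0.6]),
                                 [self.record("a", 1), self.record("b", 3)])
        assert rep.n_excluded == 1 and set(rep.per_patient) == {"b"}


# ---------------------------------------------------------------------------
# permutation stress test


class TestPermutationTest:
    def test_chance_levels_with_label_blind_model(self):
        records = [make_record(f"{c}{i}", c) for c in CLASSES for i in range(20)]

        class BlindModel:
            def __init__(self):
                self.rng = np.random.default_rng(0)

            def fit(self, records):
                return self

            def predict_proba(self, records):
                return self.rng.dirichlet(np.ones(3), size=len(records))

        out = permutation_label_test(records, BlindModel, n_perms=10, seed=2)
        assert out["mean_accuracy"] == pytest.approx(1 / 3, abs=0.12)
        assert out["mean_auc"] == pytest.approx(0.5, abs=0.12)

    def test_true_score_rank_gives_empirical_p(self):
        records = [make_record(f"{c}{i}", c) for c in CLASSES for i in range(5)]
        out = permutation_label_test(records, FixedModel, n_perms=9, seed=0,
                                     true_score=1.01)
        assert out["p_value"] == pytest.approx(1 / 10)


# ---------------------------------------------------------------------------
# DeLong


def brute_force_delong(scores_a, scores_b, labels):
    """Placement-value oracle via explicit double loops."""
    labels = np.asarray(labels)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]

    def placements(scores):
        v10 = np.array([np.mean([(scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
                                 for j in neg]) for i in pos])
        v01 = np.array([np.mean([(scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
                                 for i in pos]) for j in neg])
        return v10.mean(), v10, v01

    auc_a, v10_a, v01_a = placements(np.asarray(scores_a))
    auc_b, v10_b, v01_b = placements(np.asarray(scores_b))
    var = (np.cov(v10_a, v10_b)[0, 0] + np.cov(v10_a, v10_b)[1, 1]
           - 2 * np.cov(v10_a, v10_b)[0, 1]) / len(pos) \
        + (np.cov(v01_a, v01_b)[0, 0] + np.cov(v01_a, v01_b)[1, 1]
           - 2 * np.cov(v01_a, v01_b)[0, 1]) / len(neg)
    z = (auc_a - auc_b) / np.sqrt(var)
    return z, 2 * stats.norm.sf(abs(z))


class TestDeLong:
    labels = np.array([1, 1, 1, 0, 0, 0])
    a = np.array([0.9, 0.7, 0.4, 0.6, 0.3, 0.1])
    b = np.array([0.8, 0.5, 0.45, 0.7, 0.2, 0.15])

    def test_identical_classifiers(self):
        z, p = delong_test(self.a, self.a, self.labels)
        assert z == 0.0 and p == 1.0

    def test_antisymmetric_swap_negates_z(self):
        z_ab, _ = delong_test(self.a, self.b, self.labels)
        z_ba, _ = delong_test(self.b, self.a, self.labels)
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_matches_placement_value_oracle(self):
        z, p = delong_test(self.a, self.b, self.labels)
        z_o, p_o = brute_force_delong(self.a, self.b, self.labels)
        assert z == pytest.approx(z_o, abs=1e-9)
        assert p == pytest.approx(p_o, abs=1e-9)

    def test_oracle_agreement_on_random_data(self, rng):
        for _ in range(20):
            labels = np.array([1] * 5 + [0] * 7)
            sa, sb = rng.normal(size=12), rng.normal(size=12)
            z, _ = delong_test(sa, sb, labels)
            z_o, _ = brute_force_delong(sa, sb, labels)
            assert z == pytest.approx(z_o, abs=1e-9)

    def test_single_class_fatal(self):
        with pytest.raises(EvaluationError):
            delong_test(self.a, self.b, np.ones(6))


# ---------------------------------------------------------------------------
# McNemar


class TestMcNemar:
    def test_symmetric_discordance_near_zero(self):
        a = np.array([True] * 20 + [False] * 20 + [True] * 60)
        b = np.array([False] * 20 + [True] * 20 + [True] * 60)
        chi2, p = mcnemar_test(a, b)
        assert chi2 == pytest.approx(1 / 40)
        assert p > 0.8

    def test_hand_value_b10_c0(self):
        a = np.array([True] * 10 + [True] * 5)
        b = np.array([False] * 10 + [True] * 5)
        chi2, _ = mcnemar_test(a, b)
        assert chi2 == pytest.approx(8.1)

    def test_no_discordance_degenerate(self):
        a = np.array([True, False, True])
        chi2, p = mcnemar_test(a, a)
        assert chi2 == 0.0 and p == 1.0

    def test_matches_statsmodels_continuity_corrected(self, rng):
        a = rng.random(80) < 0.7
        b = rng.random(80) < 0.6
        chi2, p = mcnemar_test(a, b)
        n01 = int(np.sum(a & ~b))
        n10 = int(np.sum(~a & b))
        sm = sm_mcnemar(np.array([[0, n01], [n10, 0]]), exact=False, correction=True)
        assert chi2 == pytest.approx(float(sm.statistic), abs=1e-12)
        assert p == pytest.approx(float(sm.pvalue), abs=1e-12)


# ---------------------------------------------------------------------------
# bootstrap


def accuracy_metric(y, proba):
    return float(np.mean(proba.argmax(axis=1) == y))


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        y = np.zeros(30, dtype=int)
        lo, hi = bootstrap_ci(accuracy_metric, y, proba_for(y), n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_interval_contains_point_estimate(self, rng):
        y = rng.integers(0, 3, 100)
        pred = y.copy()
        pred[:30] = (pred[:30] + 1) % 3
        proba = proba_for(pred)
        point = accuracy_metric(y, proba)
        lo, hi = bootstrap_ci(accuracy_metric, y, proba, n_boot=500, seed=1)
        assert lo <= point <= hi

    def test_coverage_close_to_nominal(self, rng):
        covered = 0
        n_sims = 200
        for s in range(n_sims):
            y = np.zeros(100, dtype=int)
            pred = np.where(rng.random(100) < 0.7, 0, 1)
            lo, hi = bootstrap_ci(accuracy_metric, y, proba_for(pred),
                                  n_boot=300, seed=s)
            covered += lo - 1e-12 <= 0.7 <= hi + 1e-12
        assert 0.86 <= covered / n_sims <= 0.995


# ---------------------------------------------------------------------------
# Procrustes + MMD


class TestProcrustes:
    def test_rotated_copy_recovered(self, rng):
        X = rng.normal(size=(40, 5))
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        res = procrustes_align(X, X @ Q)
        assert res.disparity == pytest.approx(0.0, abs=1e-18)
        assert res.mmd_after == pytest.approx(0.0, abs=1e-9)

    def test_identity_fixed_point(self, rng):
        X = rng.normal(size=(30, 4))
        res = procrustes_align(X, X)
        np.testing.assert_allclose(res.rotation, np.eye(4), atol=1e-10)
        assert res.scale == pytest.approx(1.0)

    def test_disparity_matches_svd_closed_form(self, rng):
        A = rng.normal(size=(20, 5))
        B = rng.normal(size=(20, 5))
        res = procrustes_align(A, B, allow_scaling=False)
        A0 = A - A.mean(axis=0)
        B0 = B - B.mean(axis=0)
        U, s, Vt = np.linalg.svd(A0.T @ B0)
        R = U @ Vt
        expected = np.sum((A0 @ R - B0) ** 2)
        assert res.disparity == pytest.approx(expected, abs=1e-9)

    def test_alignment_reduces_mmd_on_rotation_shift(self, rng):
        X = rng.normal(size=(60, 4)) + np.array([1.0, 0, 0, 0])
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        Y = X @ Q + 0.01 * rng.normal(size=(60, 4))
        res = procrustes_align(X, Y)
        assert res.mmd_after <= res.mmd_before

    def test_class_centroid_anchors_shape(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array((["Normal"] * 10) + (["MCI"] * 10) + (["AD"] * 10))
        anchors = class_centroid_anchors(X, y)
        assert anchors.shape == (3, 4)

    def test_mmd_zero_for_identical_samples(self, rng):
        X = rng.normal(size=(25, 3))
        assert rbf_mmd(X, X) == pytest.approx(0.0, abs=1e-12)


def test_split_leakage_audit_clean(study_corpus):
    records, _, assignment = study_corpus
    audit = audit_split_leakage(records, assignment)
    assert audit["clean"] and all(not v for v in audit["overlaps"].values())
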