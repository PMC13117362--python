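"""Metrics, patient-level Monte-Carlo cross-validation, stress tests and
cross-cohort alignment.

Everything operates at the patient level: CV folds and bootstrap resamples
never split a patient's notes, and fold disjointness is verified rather than
assumed. Statistical comparisons cover DeLong's paired ROC test (fast
midrank implementation), the continuity-corrected McNemar test, percentile
bootstrap intervals and label-permutation nulls. Cross-cohort embedding
shift is handled by orthogonal Procrustes alignment with an RBF-kernel
maximum mean discrepancy reported before and after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from sklearn import metrics as skm

from .corpus import CLASSES, PatientRecord, SplitAssignment

log = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metric report


@dataclass
class MetricReport:
    accuracy: float
    macro_f1: float
    balanced_accuracy: float
    roc_auc: float | None
    pr_auc: float | None
    sensitivity: float
    specificity: float
    mcc: float
    kappa: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    sd: dict[str, float] | None = None       # across folds, when aggregated

    def as_dict(self):
        out = {k: getattr(self, k) for k in (
            "accuracy", "macro_f1", "balanced_accuracy", "roc_auc", "pr_auc",
            "sensitivity", "specificity", "mcc", "kappa")}
        out["per_class"] = self.per_class
        if self.sd:
            out["sd"] = self.sd
        return out


def macro_f1(y_true, y_pred) -> float:
    return float(skm.f1_score(y_true, y_pred, average="macro", zero_division=0))


def _binary_stats(cm: np.ndarray, i: int) -> dict[str, float]:
    tp = cm[i, i]
    fn = cm[i].sum() - tp
    fp = cm[:, i].sum() - tp
    tn = cm.sum() - tp - fn - fp
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return {"precision": prec, "recall": rec, "f1": f1,
            "specificity": spec, "mcc": mcc}


def compute_metrics(y_true: np.ndarray, proba: np.ndarray) -> MetricReport:
    """Full metric report from true class indices and probability rows."""
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    y_pred = proba.argmax(axis=1)
    labels = list(range(len(CLASSES)))
    present = sorted(set(y_true.tolist()))
    if len(present) < len(labels):
        log.warning("compute_metrics: class(es) %s absent from labels; their "
                    "per-class metrics are undefined",
                    [CLASSES[i] for i in labels if i not in present])
    cm = skm.confusion_matrix(y_true, y_pred, labels=labels)
    per_class = {}
    for i in labels:
        if i in present:
            per_class[CLASSES[i]] = _binary_stats(cm, i)
        else:
            per_class[CLASSES[i]] = {k: float("nan") for k in
                                     ("precision", "recall", "f1", "specificity", "mcc")}
    # macro values over present classes only
    mac = lambda key: float(np.mean([per_class[CLASSES[i]][key] for i in present]))
    try:
        if len(present) == len(labels):
            roc = float(skm.roc_auc_score(y_true, proba, multi_class="ovr",
                                          average="macro"))
        else:
            roc = None
        Y = np.eye(len(labels))[y_true]
        pr = float(np.mean([skm.average_precision_score(Y[:, i], proba[:, i])
                            for i in present]))
    except ValueError:
        roc, pr = None, None
    return MetricReport(
        accuracy=float(skm.accuracy_score(y_true, y_pred)),
        macro_f1=mac("f1"),
        balanced_accuracy=float(skm.balanced_accuracy_score(y_true, y_pred)),
        roc_auc=roc,
        pr_auc=pr,
        sensitivity=mac("recall"),
        specificity=mac("specificity"),
        mcc=float(skm.matthews_corrcoef(y_true, y_pred)),
        kappa=float(skm.cohen_kappa_score(y_true, y_pred)),
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation


def stratified_patient_partition(records, test_frac, rng):
    """One stratified patient-level train/test partition."""
    train_idx, test_idx = [], []
    by_class = {}
    for i, r in enumerate(records):
        by_class.setdefault(r.label, []).append(i)
    for cls in sorted(by_class):
        idx = np.array(by_class[cls])
        rng.shuffle(idx)
        n_test = max(1, int(round(test_frac * len(idx))))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return sorted(train_idx), sorted(test_idx)


def monte_carlo_cv(records: list[PatientRecord], model_factory, n_folds: int = 50,
                   test_frac: float = 0.2, seed: int = 0) -> MetricReport:
    """Repeated stratified patient-level hold-out; reports mean +/- sd.

    ``model_factory()`` must return an object with ``fit(records)`` and
    ``predict_proba(records) -> (n, 3)``. Fold train/test disjointness is
    checked explicitly on every fold.
    """
    if n_folds < 2:
        raise EvaluationError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    label_idx = {c: i for i, c in enumerate(CLASSES)}
    rows = []
    for _ in range(n_folds):
        tr, te = stratified_patient_partition(records, test_frac, rng)
        tr_ids = {records[i].patient_id for i in tr}
        te_ids = {records[i].patient_id for i in te}
        if tr_ids & te_ids:
            raise EvaluationError("patient overlap between CV train and test")
        model = model_factory()
        model.fit([records[i] for i in tr])
        proba = model.predict_proba([records[i] for i in te])
        y = np.array([label_idx[records[i].label] for i in te])
        rows.append(compute_metrics(y, proba))
    keys = ("accuracy", "macro_f1", "balanced_accuracy", "roc_auc", "pr_auc",
            "sensitivity", "specificity", "mcc", "kappa")
    vals = {k: np.array([getattr(r, k) for r in rows], dtype=float) for k in keys}
    mean_report = MetricReport(
        **{k: float(np.nanmean(v)) for k, v in vals.items()},
        per_class={},
        sd={k: float(np.nanstd(v)) for k, v in vals.items()},
    )
    return mean_report


# ---------------------------------------------------------------------------
# temporal stability


@dataclass
class StabilityReport:
    per_patient: dict[str, float]
    mean_variance: float
    n_excluded: int            # single-note patients (variance undefined)


def temporal_stability(model, records: list[PatientRecord]) -> StabilityReport:
    """Variance across visit prefixes of P(final predicted class).

    For each patient, the model is run on every prefix of the note sequence;
    the tracked probability is that of the class predicted from the full
    sequence. Single-note patients are excluded and counted.
    """
    per_patient, excluded = {}, 0
    for r in records:
        if len(r.notes) < 2:
            excluded += 1
            continue
        full = model.predict_proba([r])[0]
        cls = int(full.argmax())
        probs = []
        for t in range(1, len(r.notes) + 1):
            prefix = PatientRecord(
                patient_id=f"{r.patient_id}__prefix{t}", notes=r.notes[:t],
                label=r.label, diagnosis_date=r.diagnosis_date)
            probs.append(model.predict_proba([prefix])[0][cls])
        per_patient[r.patient_id] = float(np.var(probs))
    mean = float(np.mean(list(per_patient.values()))) if per_patient else float("nan")
    return StabilityReport(per_patient=per_patient, mean_variance=mean,
                           n_excluded=excluded)


# ---------------------------------------------------------------------------
# permutation stress test


def permute_labels_class_preserving(records, rng) -> list[PatientRecord]:
    """Shuffle patient labels while preserving class counts."""
    labels = [r.label for r in records]
    perm = list(labels)
    rng.shuffle(perm)
    return [
        PatientRecord(patient_id=r.patient_id, notes=r.notes, label=lab,
                      diagnosis_date=r.diagnosis_date, synthetic_of=r.synthetic_of)
        for r, lab in zip(records, perm)
    ]


def permutation_label_test(records: list[PatientRecord], model_factory,
                           n_perms: int = 20, test_frac: float = 0.2,
                           seed: int = 0, true_score: float | None = None):
    """Retrain under class-preserving label permutations.

    Returns a dict with per-permutation accuracy / macro F1 / macro one-vs-
    rest AUC, their means, and (when ``true_score`` is given, as an accuracy)
    the empirical p-value of the unpermuted model's score in the null.
    """
    rng = np.random.default_rng(seed)
    label_idx = {c: i for i, c in enumerate(CLASSES)}
    accs, f1s, aucs = [], [], []
    for _ in range(n_perms):
        permuted = permute_labels_class_preserving(records, rng)
        tr, te = stratified_patient_partition(permuted, test_frac, rng)
        model = model_factory()
        model.fit([permuted[i] for i in tr])
        proba = model.predict_proba([permuted[i] for i in te])
        y = np.array([label_idx[permuted[i].label] for i in te])
        rep = compute_metrics(y, proba)
        accs.append(rep.accuracy)
        f1s.append(rep.macro_f1)
        aucs.append(rep.roc_auc if rep.roc_auc is not None else 0.5)
    out = {
        "accuracy": accs, "macro_f1": f1s, "auc": aucs,
        "mean_accuracy": float(np.mean(accs)),
        "mean_macro_f1": float(np.mean(f1s)),
        "mean_auc": float(np.mean(aucs)),
    }
    if true_score is not None:
        b = sum(a >= true_score for a in accs)
        out["p_value"] = (b + 1) / (n_perms + 1)
    return out


# ---------------------------------------------------------------------------
# DeLong's paired ROC test


def _midrank(x):
    order = np.argsort(x)
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j < len(x) and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def _delong_placements(scores, labels):
    """Placement values and AUC for one classifier (binary labels)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise EvaluationError("DeLong test needs both classes present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n          # placement of positives
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # placement of negatives
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels):
    """Paired DeLong test for the difference of two AUCs (binary labels).

    Returns (Z, two-sided p). Z > 0 means classifier A has the larger AUC.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("DeLong test needs both classes present")
    auc_a, v10_a, v01_a = _delong_placements(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def delong_test_multiclass(proba_a, proba_b, y_true):
    """One-vs-rest DeLong per class plus a macro-averaged Z."""
    out = {}
    zs = []
    for i, cls in enumerate(CLASSES):
        y_bin = (np.asarray(y_true) == i).astype(int)
        if len(set(y_bin.tolist())) < 2:
            continue
        z, p = delong_test(proba_a[:, i], proba_b[:, i], y_bin)
        out[cls] = {"z": z, "p": p}
        zs.append(z)
    out["macro_z"] = float(np.mean(zs)) if zs else 0.0
    return out


# ---------------------------------------------------------------------------
# McNemar


def mcnemar_test(correct_a, correct_b):
    """Continuity-corrected McNemar chi-square on paired correctness."""
    a = np.asarray(correct_a, dtype=bool)
    c_b = np.asarray(correct_b, dtype=bool)
    b = int(np.sum(a & ~c_b))
    c = int(np.sum(~a & c_b))
    if b + c == 0:
        log.warning("mcnemar_test: no discordant pairs; degenerate (p = 1)")
        return 0.0, 1.0
    chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(metric_fn, y_true, proba, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05):
    """Percentile CI by resampling patients (rows) with replacement."""
    rng = np.random.default_rng(seed)
    y_true = np.asarray(y_true)
    proba = np.asarray(proba)
    n = len(y_true)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(metric_fn(y_true[idx], proba[idx]))
        except ValueError:
            continue
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Procrustes alignment + MMD


def rbf_mmd(X, Y, bandwidth: float | None = None) -> float:
    """Biased RBF-kernel MMD with a median-heuristic bandwidth."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Z = np.vstack([X, Y])
    d2 = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=-1)
    if bandwidth is None:
        med = np.median(d2[d2 > 0]) if np.any(d2 > 0) else 1.0
        bandwidth = np.sqrt(med / 2) or 1.0
    K = np.exp(-d2 / (2 * bandwidth ** 2))
    n, m = len(X), len(Y)
    kxx = K[:n, :n].mean()
    kyy = K[n:, n:].mean()
    kxy = K[:n, n:].mean()
    return float(kxx + kyy - 2 * kxy)


@dataclass
class AlignmentResult:
    aligned_source: np.ndarray
    rotation: np.ndarray
    scale: float
    disparity: float
    mmd_before: float
    mmd_after: float


def procrustes_align(source: np.ndarray, target: np.ndarray,
                     source_anchors: np.ndarray | None = None,
                     target_anchors: np.ndarray | None = None,
                     allow_scaling: bool = True) -> AlignmentResult:
    """Orthogonal Procrustes from source onto target embedding space.

    The transform is fitted on paired anchor sets (by default the full
    matrices, which then must be row-paired; cross-cohort use fits on
    class-conditional centroids via :func:`class_centroid_anchors`) and
    applied globally to ``source``.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    A = np.asarray(source_anchors if source_anchors is not None else src, dtype=float)
    B = np.asarray(target_anchors if target_anchors is not None else tgt, dtype=float)
    if A.shape != B.shape:
        raise EvaluationError("anchor sets must be paired and equal-shaped")
    if min(A.shape) > 0 and np.linalg.matrix_rank(A) < A.shape[1]:
        log.warning("procrustes_align: rank-deficient anchors; solution may be "
                    "non-unique")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - mu_a, B - mu_b
    R, s = orthogonal_procrustes(A0, B0)
    norm_a = np.sum(A0 ** 2)
    scale = (s / norm_a) if (allow_scaling and norm_a > 0) else 1.0
    aligned = (src - mu_a) @ R * scale + mu_b
    aligned_anchors = A0 @ R * scale + mu_b
    disparity = float(np.sum((aligned_anchors - B) ** 2))
    return AlignmentResult(
        aligned_source=aligned, rotation=R, scale=float(scale),
        disparity=disparity,
        mmd_before=rbf_mmd(src, tgt),
        mmd_after=rbf_mmd(aligned, tgt),
    )


def class_centroid_anchors(X, y, classes=CLASSES):
    """Per-class centroids, the default cross-cohort anchor pairing."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    return np.stack([X[y == c].mean(axis=0) for c in classes if np.any(y == c)])


# ---------------------------------------------------------------------------
# leakage audit


def audit_split_leakage(records: list[PatientRecord],
                        assignment: SplitAssignment) -> dict:
    """Hashed-id style audit: overlap across splits must be empty."""
    by_split = {s: set(assignment.patients(s)) for s in ("train", "val", "test")}
    overlaps = {
        f"{a}&{b}": sorted(by_split[a] & by_split[b])
        for a in by_split for b in by_split if a < b
    }
    return {"overlaps": overlaps,
            "clean": all(not v for v in overlaps.values())}
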