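"""Attribution tooling: attention export, permutation feature importance,
and healthy-baseline counterfactual substitution.

All outputs are pure functions of (fitted model, input, seed). Exact Shapley
attribution is deliberately out of scope; permutation importance measures
the macro-F1 drop when one psycholinguistic feature is shuffled across
patients, and counterfactuals replace a patient's biomarker vector with the
Normal-class training mean to quantify how much of the predicted risk rides
on measured language degradation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corpus import CLASSES, PatientRecord
from .evaluation import macro_f1
from .psycholing import FEATURE_NAMES

AD_INDEX = CLASSES.index("AD")


@dataclass
class AttributionReport:
    patient_id: str
    temporal_attention: list[float]
    modality_gates: dict[str, float]
    modality_attention: list | None = None   # (heads, modalities, modalities)
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None):
        obj = {
            "patient_id": self.patient_id,
            "temporal_attention": self.temporal_attention,
            "modality_gates": self.modality_gates,
            "modality_attention": self.modality_attention,
            **self.extras,
        }
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2)


def export_attention(model, record: PatientRecord) -> AttributionReport:
    """Temporal attention per note and modality gate/attention allocation."""
    feats = model._features_for([record])[0]
    _, pred, fused, _, alpha = model.forward(feats, training=False)
    temporal = alpha.tolist() if alpha is not None else [1.0] * 0
    if not temporal:
        temporal = [1.0] if len(record.notes) == 1 else \
            [1.0 / len(record.notes)] * len(record.notes)
    return AttributionReport(
        patient_id=record.patient_id,
        temporal_attention=temporal,
        modality_gates=fused.gates,
        modality_attention=(fused.attention.tolist()
                            if fused.attention is not None else None),
        extras={"probs": pred.probs.tolist()},
    )


def feature_importance(model, records: list[PatientRecord], feature: str,
                       n_shuffles: int = 10, seed: int = 0) -> dict:
    """Permutation importance: macro-F1 drop when ``feature`` is shuffled
    across patients, averaged over ``n_shuffles``."""
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    j = FEATURE_NAMES.index(feature)
    label_idx = {c: i for i, c in enumerate(CLASSES)}
    y = [label_idx[r.label] for r in records]
    feats = model._features_for(records)
    base = macro_f1(y, model.predict_proba(records).argmax(axis=1))
    rng = np.random.default_rng(seed)
    originals = [f.psych_raw.copy() for f in feats]
    drops = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(feats))
        for f, src in zip(feats, perm):
            f.psych_raw[j] = originals[src][j]
        shuffled = macro_f1(y, model.predict_proba(records).argmax(axis=1))
        drops.append(base - shuffled)
    for f, orig in zip(feats, originals):
        f.psych_raw[:] = orig
    return {
        "feature": feature,
        "importance": float(np.mean(drops)),
        "sd": float(np.std(drops)),
        "baseline_macro_f1": base,
        "drops": [float(d) for d in drops],
    }


def healthy_profile(model, train_records: list[PatientRecord]) -> np.ndarray:
    """Normal-class mean biomarker vector from the training split."""
    feats = model._features_for([r for r in train_records if r.label == "Normal"])
    if not feats:
        raise ValueError("no Normal-class records to build a healthy baseline")
    P = np.stack([f.psych_raw for f in feats])
    with np.errstate(all="ignore"):
        return np.nan_to_num(np.nanmean(P, axis=0), nan=0.0)


def counterfactual_substitute(model, record: PatientRecord,
                              healthy: np.ndarray) -> dict:
    """Replace the record's biomarkers with the healthy baseline; report the
    P(AD) shift. Non-psycholinguistic modalities are left untouched."""
    feats = model._features_for([record])[0]
    before = model.predict_proba([record])[0]
    original = feats.psych_raw.copy()
    feats.psych_raw = np.asarray(healthy, dtype=float).copy()
    after = model.predict_proba([record])[0]
    feats.psych_raw = original
    return {
        "patient_id": record.patient_id,
        "p_ad_before": float(before[AD_INDEX]),
        "p_ad_after": float(after[AD_INDEX]),
        "delta": float(after[AD_INDEX] - before[AD_INDEX]),
        "probs_before": before.tolist(),
        "probs_after": after.tolist(),
    }
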