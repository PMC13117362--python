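"""Gated multimodal fusion model and its training objective.

Four modality streams — pooled local text embedding, temporal Bi-LSTM
attention vector, concept-graph encoding, and the projected psycholinguistic
vector — are mapped to a common latent space, mixed by multi-head cross-modal
attention, gated by a sigmoid projection over the concatenated streams, and
classified into {Normal, MCI, AD}. Training minimizes

    L_total = L_cls + lambda * L_contrast

where L_cls is (mean or exact-sum) cross-entropy and L_contrast is a
temperature-scaled cosine contrastive loss over same-patient visit pairs
(gap 6 months to 3 years) against cross-patient negatives.

Ablation variants (transformer_only / bilstm / gnn / full) are pure config:
they share splits, seeds, and preprocessing.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._autograd import Tensor, concat_rows, const, param, stack_rows
from ._nn import AdamW, Linear, Module, MultiHeadAttention, xavier
from .corpus import CLASSES, PatientRecord
from .concept_graph import (
    build_patient_graph, neighbor_average_matrix, node_features,
)
from .neural_encoders import EmbeddingBagEncoder, TemporalEncoder, UNK, get_encoder_factory

log = logging.getLogger(__name__)

VARIANTS = ("transformer_only", "bilstm", "gnn", "no_psych", "full")

GRAPH_NODE_DIM = 11  # [freq, 4 section proportions, degree, 5 domain one-hot]


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture + optimization settings.

    Defaults follow the reference configuration (Bi-LSTM 2x256, GraphSAGE
    3 layers / neighborhood 10, fusion width 512 with multi-head attention,
    psycholinguistic projection 128->64, AdamW lr 2e-5 / weight decay 0.01,
    batch 16, early stopping patience 5, tau 0.05). ``lightweight_config``
    scales the widths and schedule down for CPU-scale corpora.
    """

    variant: str = "full"
    encoder: str = "bag"
    d_embed: int = 64
    d_lstm_hidden: int = 256
    n_lstm_layers: int = 2
    d_graph: int = 64
    n_graph_layers: int = 3
    neighborhood: int = 10
    d_fusion: int = 512
    n_heads: int = 4
    psych_hidden: int = 128
    psych_out: int = 64
    lambda_contrast: float = 0.5
    tau: float = 0.05
    p_drop_path: float = 0.1
    lr: float = 2e-5
    weight_decay: float = 0.01
    batch_size: int = 16
    epochs: int = 50
    patience: int = 5
    loss_reduction: str = "mean"      # "mean" | "sum" (exact closed-form tests)
    min_gap_days: int = 180
    max_gap_days: int = 1095
    n_contrast_candidates: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ModelError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def use_temporal(self):
        return self.variant in ("bilstm", "no_psych", "full")

    @property
    def use_graph(self):
        return self.variant in ("gnn", "no_psych", "full")

    @property
    def use_psych(self):
        return self.variant == "full"

    @property
    def use_contrastive(self):
        return self.variant in ("no_psych", "full") and self.lambda_contrast > 0


def lightweight_config(**overrides) -> ModelConfig:
    """CPU-scale preset used by the test and acceptance harnesses."""
    base = dict(
        d_embed=16, d_lstm_hidden=16, n_lstm_layers=1, d_graph=16,
        d_fusion=32, n_heads=4, psych_hidden=32, psych_out=16,
        lr=5e-3, epochs=25, patience=10, batch_size=8,
    )
    base.update(overrides)
    return ModelConfig(**base)


# ---------------------------------------------------------------------------
# bundled types


@dataclass
class ModalityBundle:
    """Projected per-modality embeddings plus presence flags."""

    local: Tensor | None = None
    temporal: Tensor | None = None
    graph: Tensor | None = None
    psych: Tensor | None = None

    MODALITIES = ("local", "temporal", "graph", "psych")

    def present(self):
        return [m for m in self.MODALITIES if getattr(self, m) is not None]


@dataclass
class FusedEmbedding:
    z: Tensor
    attended: dict[str, Tensor]
    gates: dict[str, float]
    attention: np.ndarray | None = None   # (heads, modalities, modalities)


@dataclass
class Prediction:
    probs: np.ndarray
    logits: np.ndarray

    def __post_init__(self):
        assert abs(self.probs.sum() - 1.0) < 1e-6


@dataclass
class LossValues:
    l_cls: float
    l_contrast: float
    lam: float

    @property
    def l_total(self):
        return self.l_cls + self.lam * self.l_contrast


# ---------------------------------------------------------------------------
# losses (closed-form-testable, used verbatim in training)


def classification_loss(log_probs: list[Tensor], labels: list[int],
                        reduction: str = "mean") -> Tensor:
    """Cross-entropy over patients from log-softmax outputs."""
    terms = [-(lp.slice(y)) for lp, y in zip(log_probs, labels)]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    if reduction == "mean":
        return total * (1.0 / len(terms))
    if reduction == "sum":
        return total
    raise ModelError(f"unknown reduction {reduction!r}")


def _cosine(a: Tensor, b: Tensor) -> Tensor:
    num = (a * b).sum()
    den = ((a * a).sum().sqrt() * (b * b).sum().sqrt()) + 1e-12
    return num / den


def contrastive_loss(anchors: list[Tensor], candidates: list[list[Tensor]],
                     positive_idx: list[int], tau: float = 0.05) -> Tensor:
    """Mean over anchors of -log softmax(sim(anchor, .)/tau) at the positive.

    Each anchor must name exactly one positive among its candidate set.
    """
    if not anchors:
        raise ModelError("contrastive loss needs at least one anchor")
    terms = []
    for a, cands, pos in zip(anchors, candidates, positive_idx):
        if not (0 <= pos < len(cands)):
            raise ModelError("anchor without a designated positive candidate")
        sims = concat_rows([_cosine(a, c) * (1.0 / tau) for c in cands])
        terms.append(-(sims.log_softmax().slice(pos)))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def sample_progression_pairs(
    records: list[PatientRecord],
    rng: np.random.Generator,
    min_gap_days: int = 180,
    max_gap_days: int = 1095,
    max_per_patient: int = 2,
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, str, int]]]:
    """Within-patient positives (gap in [min,max] days) + cross-patient negatives."""
    positives = []
    for r in records:
        eligible = []
        for i in range(len(r.notes)):
            for j in range(i + 1, len(r.notes)):
                gap = (r.notes[j].timestamp - r.notes[i].timestamp).days
                if min_gap_days <= gap <= max_gap_days:
                    eligible.append((r.patient_id, i, j))
        if not eligible:
            if len(r.notes) >= 2:
                log.debug("patient %s: no eligible positive pair", r.patient_id)
            continue
        take = min(max_per_patient, len(eligible))
        idx = rng.choice(len(eligible), size=take, replace=False)
        positives.extend(eligible[k] for k in idx)
    negatives = []
    pids = [r.patient_id for r in records]
    n_notes = {r.patient_id: len(r.notes) for r in records}
    for pid, i, _ in positives:
        others = [q for q in pids if q != pid]
        if not others:
            continue
        q = others[rng.integers(len(others))]
        negatives.append((pid, i, q, int(rng.integers(n_notes[q]))))
    return positives, negatives


# ---------------------------------------------------------------------------
# per-record feature cache (label-independent, reusable across retrains)


@dataclass
class RecordFeatures:
    patient_id: str
    tokens_per_note: list[list[str]]
    psych_raw: np.ndarray            # (9,), may contain NaN sentinels
    graph_M: np.ndarray
    graph_X: np.ndarray              # (n_nodes, GRAPH_NODE_DIM)
    day_offsets: np.ndarray


def precompute_features(records: list[PatientRecord],
                        neighborhood: int = 10,
                        lexicon=None, mask_policy=None) -> dict[str, RecordFeatures]:
    """Tokenize, extract psycholinguistics and build graphs once per record."""
    from .preprocess import tokenize
    from .psycholing import aggregate_patient, note_vector

    cache = {}
    for r in records:
        toks = [n.tokens if n.tokens is not None else tokenize(n.text) for n in r.notes]
        V = np.stack([note_vector(n) for n in r.notes])
        psych = aggregate_patient(V)
        cg = build_patient_graph(r, lexicon=lexicon, mask_policy=mask_policy)
        M = neighbor_average_matrix(cg, neighborhood)
        X = node_features(cg, GRAPH_NODE_DIM)
        t0 = r.notes[0].timestamp
        days = np.array([(n.timestamp - t0).days for n in r.notes], dtype=float)
        cache[r.patient_id] = RecordFeatures(r.patient_id, toks, psych, M, X, days)
    return cache


# ---------------------------------------------------------------------------
# the model


class PsychProjector(Module):
    """Two-ReLU projection of the 9 biomarkers (9 -> hidden -> out)."""

    def __init__(self, rng, d_in, d_hidden, d_out):
        self.l1 = Linear(rng, d_in, d_hidden)
        self.l2 = Linear(rng, d_hidden, d_out)
        self.d_out = d_out

    def __call__(self, f):
        return self.l2(self.l1(f).relu()).relu()


def project_psych(f_p: np.ndarray, projector: PsychProjector) -> Tensor:
    """Project a sentinel-free biomarker vector to its dense embedding."""
    f = np.asarray(f_p, dtype=float)
    if np.any(np.isnan(f)):
        raise ModelError("psycholinguistic vector has unimputed sentinels")
    return projector(const(f))


class FusionHead(Module):
    """Cross-modal attention + sigmoid gating + GELU aggregation + classifier."""

    def __init__(self, rng, d, n_heads, n_classes=3):
        self.d = d
        self.attn = MultiHeadAttention(rng, d, n_heads)
        n_mod = len(ModalityBundle.MODALITIES)
        self.gate = Linear(rng, n_mod * d, n_mod)
        self.agg = Linear(rng, n_mod * d, d)
        self.head = Linear(rng, d, n_classes)

    def fuse(self, bundle: ModalityBundle, training: bool = False,
             rng: np.random.Generator | None = None,
             p_drop: float = 0.0) -> FusedEmbedding:
        present = bundle.present()
        if not present:
            raise ModelError("all modalities absent; nothing to fuse")
        active = list(present)
        if training and p_drop > 0 and rng is not None and len(active) > 1:
            survivors = [m for m in active if rng.random() >= p_drop]
            if not survivors:
                survivors = [active[rng.integers(len(active))]]
            active = survivors
        E = stack_rows([getattr(bundle, m) for m in active])
        attended_rows, attn_w = self.attn(E, E, return_weights=True)
        zero = const(np.zeros(self.d))
        attended = {}
        for m in ModalityBundle.MODALITIES:
            if m in active:
                attended[m] = attended_rows.slice(active.index(m))
            else:
                attended[m] = zero
        cat = concat_rows([attended[m] for m in ModalityBundle.MODALITIES])
        gates = self.gate(cat).sigmoid()
        mask = np.array([1.0 if m in active else 0.0 for m in ModalityBundle.MODALITIES])
        gated = concat_rows([
            attended[m] * (gates.slice(i) * mask[i])
            for i, m in enumerate(ModalityBundle.MODALITIES)
        ])
        z = self.agg(gated).gelu()
        gate_vals = {m: float(gates.data[i]) for i, m in enumerate(ModalityBundle.MODALITIES)}
        return FusedEmbedding(z=z, attended=attended, gates=gate_vals, attention=attn_w)

    def classify(self, z: Tensor) -> tuple[Tensor, Prediction]:
        logits = self.head(z)
        lp = logits.log_softmax()
        probs = np.exp(lp.data)
        return lp, Prediction(probs=probs, logits=logits.data.copy())


def fuse(bundle: ModalityBundle, head: FusionHead, training: bool = False,
         rng: np.random.Generator | None = None, p_drop: float = 0.0) -> FusedEmbedding:
    return head.fuse(bundle, training=training, rng=rng, p_drop=p_drop)


def classify(z: Tensor, head: FusionHead) -> Prediction:
    return head.classify(z)[1]


class CognitraceModel(Module):
    """The patient-level classifier over longitudinal note sequences."""

    def __init__(self, config: ModelConfig, vocab: dict[str, int] | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.vocab = vocab or {UNK: 0}
        enc_cls = get_encoder_factory(config.encoder)
        self.encoder = enc_cls(self.vocab, dim=config.d_embed, seed=config.seed)
        self.temporal = (
            TemporalEncoder(rng, config.d_embed, config.d_lstm_hidden,
                            n_layers=config.n_lstm_layers)
            if config.use_temporal else None
        )
        if config.use_graph:
            dims = [GRAPH_NODE_DIM] + [config.d_graph] * config.n_graph_layers
            self.graph_weights = [param(xavier(rng, a, b)) for a, b in zip(dims, dims[1:])]
        else:
            self.graph_weights = []
        self.psych_proj = (
            PsychProjector(rng, 9, config.psych_hidden, config.psych_out)
            if config.use_psych else None
        )
        d = config.d_fusion
        self.proj_local = Linear(rng, config.d_embed, d)
        self.proj_temporal = Linear(rng, 2 * config.d_lstm_hidden, d) if config.use_temporal else None
        self.proj_graph = Linear(rng, config.d_graph, d) if config.use_graph else None
        self.proj_psych = Linear(rng, config.psych_out, d) if config.use_psych else None
        self.fusion = FusionHead(rng, d, config.n_heads)
        self.psych_impute_: np.ndarray | None = None
        self.psych_scale_: tuple[np.ndarray, np.ndarray] | None = None
        self.history_: list[dict] = []

    # -- forward ------------------------------------------------------------

    def _note_embeddings(self, feats: RecordFeatures) -> list[Tensor]:
        return [self.encoder.encode(toks) for toks in feats.tokens_per_note]

    def forward(self, feats: RecordFeatures, training: bool = False,
                rng: np.random.Generator | None = None):
        cfg = self.config
        embs = self._note_embeddings(feats)
        local = stack_rows(embs).mean(axis=0)
        bundle = ModalityBundle(local=self.proj_local(local))
        u_states, alpha = None, None
        if cfg.use_temporal:
            enc = self.temporal(embs)
            u_states, alpha = enc.u, enc.alpha
            bundle.temporal = self.proj_temporal(enc.v)
        if cfg.use_graph:
            if len(feats.graph_X):
                h = const(feats.graph_X)
                M = const(feats.graph_M)
                for W in self.graph_weights:
                    h = ((M @ h) @ W).relu()
                g = h.mean(axis=0)
            else:
                g = const(np.zeros(cfg.d_graph))
            bundle.graph = self.proj_graph(g)
        if cfg.use_psych:
            f = feats.psych_raw.copy()
            if np.any(np.isnan(f)):
                if self.psych_impute_ is None:
                    raise ModelError("sentinel psych features but no imputation means fitted")
                f[np.isnan(f)] = self.psych_impute_[np.isnan(f)]
            if self.psych_scale_ is not None:
                mu, sd = self.psych_scale_
                f = (f - mu) / sd
            bundle.psych = self.proj_psych(self.psych_proj(const(f)))
        fused = self.fusion.fuse(bundle, training=training, rng=rng,
                                 p_drop=cfg.p_drop_path if training else 0.0)
        log_probs, pred = self.fusion.classify(fused.z)
        return log_probs, pred, fused, u_states, alpha

    # -- fitting ------------------------------------------------------------

    def fit(self, records: list[PatientRecord],
            val_records: list[PatientRecord] | None = None,
            cache: dict[str, RecordFeatures] | None = None,
            verbose: bool = False) -> "CognitraceModel":
        cfg = self.config
        if cache is None:
            cache = precompute_features(records + (val_records or []),
                                        neighborhood=cfg.neighborhood)
        self._cache = cache
        # vocabulary from training text only
        if len(self.vocab) <= 1:
            counts: dict[str, int] = {}
            for r in records:
                for toks in cache[r.patient_id].tokens_per_note:
                    for t in toks:
                        counts[t] = counts.get(t, 0) + 1
            self.vocab.update({t: i + 1 for i, t in enumerate(sorted(counts))})
            rng0 = np.random.default_rng(cfg.seed)
            self.encoder.vocab = self.vocab
            self.encoder.table = param(xavier(rng0, len(self.vocab), cfg.d_embed))
        # imputation means from the training split
        P = np.stack([cache[r.patient_id].psych_raw for r in records])
        with np.errstate(all="ignore"):
            self.psych_impute_ = np.nan_to_num(np.nanmean(P, axis=0), nan=0.0)
            sd = np.nan_to_num(np.nanstd(P, axis=0), nan=1.0)
        sd[sd == 0] = 1.0
        self.psych_scale_ = (self.psych_impute_.copy(), sd)

        rng = np.random.default_rng(cfg.seed + 1)
        opt = AdamW(self.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        label_idx = {c: i for i, c in enumerate(CLASSES)}
        y = {r.patient_id: label_idx[r.label] for r in records}
        best_f1, best_state, patience_left = -1.0, None, cfg.patience
        self.history_ = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(records))
            ep_cls = ep_con = 0.0
            n_batches = 0
            for start in range(0, len(records), cfg.batch_size):
                batch = [records[i] for i in order[start:start + cfg.batch_size]]
                opt.zero_grad()
                log_probs, labels, u_map = [], [], {}
                for r in batch:
                    lp, _, _, u, _ = self.forward(cache[r.patient_id], training=True, rng=rng)
                    log_probs.append(lp)
                    labels.append(y[r.patient_id])
                    if u is not None:
                        u_map[r.patient_id] = u
                l_cls = classification_loss(log_probs, labels, cfg.loss_reduction)
                loss = l_cls
                l_con_val = 0.0
                if cfg.use_contrastive and len(u_map) > 1:
                    pos, neg = sample_progression_pairs(
                        [r for r in batch if r.patient_id in u_map], rng,
                        cfg.min_gap_days, cfg.max_gap_days, max_per_patient=1)
                    anchors, cands, pidx = [], [], []
                    other_pids = list(u_map)
                    for pid, i, j in pos:
                        negs = []
                        while len(negs) < cfg.n_contrast_candidates - 1:
                            q = other_pids[rng.integers(len(other_pids))]
                            if q == pid:
                                continue
                            negs.append(u_map[q][rng.integers(len(u_map[q]))])
                        anchors.append(u_map[pid][i])
                        cands.append([u_map[pid][j]] + negs)
                        pidx.append(0)
                    if anchors:
                        l_con = contrastive_loss(anchors, cands, pidx, cfg.tau)
                        l_con_val = float(l_con.data)
                        loss = l_cls + cfg.lambda_contrast * l_con
                loss.backward()
                opt.step()
                ep_cls += float(l_cls.data)
                ep_con += l_con_val
                n_batches += 1
            entry = {
                "epoch": epoch,
                "l_cls": ep_cls / n_batches,
                "l_contrast": ep_con / n_batches,
                "l_total": (ep_cls + cfg.lambda_contrast * ep_con) / n_batches,
            }
            if val_records:
                from .evaluation import macro_f1
                probs = self.predict_proba(val_records)
                yv = [label_idx[r.label] for r in val_records]
                entry["val_macro_f1"] = macro_f1(yv, probs.argmax(axis=1))
                if entry["val_macro_f1"] > best_f1 + 1e-12:
                    best_f1 = entry["val_macro_f1"]
                    best_state = [p.data.copy() for p in self.parameters()]
                    patience_left = cfg.patience
                else:
                    patience_left -= 1
            self.history_.append(entry)
            if verbose:
                log.info("epoch %d: %s", epoch, entry)
            if val_records and patience_left <= 0:
                break
        if best_state is not None:
            for p, s in zip(self.parameters(), best_state):
                p.data = s
        return self

    # -- inference ----------------------------------------------------------

    def _features_for(self, records: list[PatientRecord]) -> list[RecordFeatures]:
        cache = getattr(self, "_cache", {})
        missing = [r for r in records if r.patient_id not in cache]
        if missing:
            cache = {**cache, **precompute_features(missing, self.config.neighborhood)}
            self._cache = cache
        return [cache[r.patient_id] for r in records]

    def predict_proba(self, records: list[PatientRecord]) -> np.ndarray:
        out = []
        for feats in self._features_for(records):
            _, pred, _, _, _ = self.forward(feats, training=False)
            out.append(pred.probs)
        return np.stack(out)

    def predict(self, records: list[PatientRecord]) -> list[str]:
        probs = self.predict_proba(records)
        return [CLASSES[i] for i in probs.argmax(axis=1)]

    def losses(self, l_cls: float, l_contrast: float) -> LossValues:
        return LossValues(l_cls=l_cls, l_contrast=l_contrast,
                          lam=self.config.lambda_contrast)


def train(records: list[PatientRecord], config: ModelConfig,
          val_records: list[PatientRecord] | None = None,
          cache: dict[str, RecordFeatures] | None = None) -> CognitraceModel:
    """Fit a model from scratch on the training split (leakage-checked)."""
    if val_records is None and config.patience < config.epochs:
        log.debug("no validation split: early stopping disabled")
    train_ids = {r.patient_id for r in records}
    if val_records and train_ids & {r.patient_id for r in val_records}:
        raise ModelError("patient overlap between train and validation splits")
    model = CognitraceModel(config)
    return model.fit(records, val_records=val_records, cache=cache)


def ablate(records, assignment, variants=VARIANTS, config: ModelConfig | None = None,
           cache=None) -> dict[str, dict]:
    """Train every ablation variant on identical splits/seeds; report metrics."""
    from .evaluation import compute_metrics
    base = config or lightweight_config()
    train_r = assignment.subset(records, "train")
    val_r = assignment.subset(records, "val")
    test_r = assignment.subset(records, "test")
    if cache is None:
        cache = precompute_features(records, neighborhood=base.neighborhood)
    out = {}
    for variant in variants:
        cfg = replace(base, variant=variant)
        model = CognitraceModel(cfg)
        model.fit(train_r, val_records=val_r, cache=cache)
        probs = model.predict_proba(test_r)
        y = [CLASSES.index(r.label) for r in test_r]
        out[variant] = {
            "metrics": compute_metrics(np.array(y), probs),
            "history": copy.deepcopy(model.history_),
            "model": model,
        }
    return out
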