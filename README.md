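# cognitrace

Patient-level screening of cognitive state — **Normal**, **MCI** (mild
cognitive impairment), **AD** (Alzheimer's disease) — from *longitudinal*
clinical notes. The package is aimed at clinical-NLP researchers who want a
fully inspectable, CPU-scale implementation of multimodal language-decline
modeling: every stage from raw note JSONL to attribution reports runs
deterministically from a seed, with a calibrated synthetic-corpus generator
standing in for restricted EHR data.

## The model

For a patient *p* with time-ordered notes d(p,1), …, d(p,T), four modality
streams are built and fused:

1. **Local text** — each note is encoded by a pluggable text encoder
   (default: a trainable embedding bag, s(p,t) = MeanPool over token
   embeddings; a long-context transformer can be registered through the same
   adapter interface) and mean-pooled over notes.
2. **Temporal progression** — a Bi-LSTM over the note embeddings,
   u(p,t) = BiLSTM(s(p,t)), with additive temporal attention
   v(p) = Σ α(t)·u(p,t), Σ α(t) = 1.
3. **Concept graph** — a patient-specific graph whose nodes are clinical
   concept ids (dictionary-matched; diagnostic concepts masked) and whose
   edge weights count same-note co-occurrence plus consecutive-note
   adjacency; encoded by a 3-layer GraphSAGE-mean network, h(v)^(k+1) =
   σ(W^(k) · mean({h(v)} ∪ {h(u): u ∈ N(v)})), neighborhood sample ≤ 10,
   ≤ 200 nodes, then mean-pooled to g(p).
4. **Psycholinguistic biomarkers** — nine note-level features (TTR, MATTR,
   content–function ratio, mean length of utterance, parse-depth proxy,
   subordination index, entity overlap, lexical cohesion, referential
   clarity), aggregated to the patient level and projected 9 → 128 → 64
   with ReLU layers to f′(p).

The streams are projected to a common width, mixed by multi-head cross-modal
attention, gated by a sigmoid projection over the concatenated streams, and
aggregated with a GELU layer into z(p); a dense softmax head yields
ŷ(p). Training minimizes

    L = L_cls + λ · L_contrast,      λ = 0.5 by default

where L_cls is cross-entropy and L_contrast is a temperature-scaled
(τ = 0.05) cosine contrastive loss whose positives are same-patient visit
pairs 6 months – 3 years apart and whose negatives are cross-patient pairs.
All neural components run on a small NumPy reverse-mode autodiff core that
is gradient-checked against finite differences in the test suite; no deep
learning framework is required.

Everything is patient-atomic: splits (stratified 70/15/15), Monte-Carlo CV
folds, bootstrap resamples and ADASYN oversampling never separate a
patient's notes, and diagnostic terms/concepts are masked before any
feature sees the text.

## Worked example

```python
import numpy as np
from cognitrace import generate_corpus, split_patients, CLASSES
from cognitrace.fusion_model import CognitraceModel, lightweight_config
from cognitrace.evaluation import compute_metrics
from cognitrace.explain import export_attention

records = generate_corpus({"Normal": 30, "MCI": 30, "AD": 30}, seed=7)
splits = split_patients(records, seed=0)
model = CognitraceModel(lightweight_config(seed=0))
model.fit(splits.subset(records, "train"),
          val_records=splits.subset(records, "val"))

test = splits.subset(records, "test")
y = np.array([CLASSES.index(r.label) for r in test])
report = compute_metrics(y, model.predict_proba(test))
print(f"test accuracy      {report.accuracy:.3f}")
print(f"test macro F1      {report.macro_f1:.3f}")
print(f"test ROC AUC (ovr) {report.roc_auc:.3f}")

attn = export_attention(model, test[0])
print(f"modality gates     { {k: round(v, 2) for k, v in attn.modality_gates.items()} }")
```

Output (about two minutes on one CPU):

```
test accuracy      0.833
test macro F1      0.822
test ROC AUC (ovr) 0.958
modality gates     {'local': 0.86, 'temporal': 0.13, 'graph': 0.07, 'psych': 0.69}
```

The 90-patient demo corpus is deliberately small; at the study scale used
by the test suite (100 patients per class) the full model reaches macro
F1 ≥ 0.9 held-out and strictly outperforms its psycholinguistics-ablated
counterpart on the same seed. The gate values are the per-modality sigmoid
coefficients for this patient: text and biomarker streams dominate here.

The same pipeline is available from the shell:

```bash
cognitrace simulate --classes 100,100,100 --seed 7 --out sim/
cognitrace split    --notes sim/notes.jsonl --labels sim/labels.tsv --seed 0 --out splits.tsv
cognitrace features --in sim/notes.jsonl --labels sim/labels.tsv --out features.csv
cognitrace train    --notes sim/notes.jsonl --labels sim/labels.tsv --out run/
cognitrace ablate   --notes sim/notes.jsonl --labels sim/labels.tsv
cognitrace explain  --notes sim/notes.jsonl --labels sim/labels.tsv \
                    --patient p00003 --mode counterfactual
```

## Synthetic corpora

Real longitudinal EHR note sets with cognitive-state labels are access-
restricted, so `cognitrace.synthetic_data` generates corpora whose
note-level biomarker statistics are *constructed* to match published
class-conditional profiles: per-note targets for TTR, MLU, subordination
and referential clarity are drawn from the class profile, moment-matched
within the class, and realized as clause-structured text over a closed
lexicon (so the heuristic segmenter parses it unambiguously). MCI/AD
patients decline linearly within their span; concept vocabulary drifts
from independence- toward care-related domains. `inject_label_noise` and
`shifted_cohort` support the label-noise and cross-cohort stress tests.

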