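# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `cognitrace`, and what the synthetic-data experiments do
and do not establish.

## Problem setting

The unit of analysis is the patient: a label in {Normal, MCI, AD} attached
to a time-ordered sequence of clinical notes spanning one to several years.
The working hypothesis is that cognitive decline leaves measurable traces
in documentation language — shrinking lexical diversity, simpler syntax,
less coherent discourse, and a drift of the clinical vocabulary from
independence- toward care-related concepts — and that these traces are more
reliable longitudinally than in any single note. Labels are assumed to be
weak (administrative-code provenance), which motivates the label-noise and
label-permutation stress tests.

## Psycholinguistic features

Nine note-level features, all deterministic:

| feature | definition | default |
|---|---|---|
| TTR | distinct word types / tokens, case-folded | — |
| MATTR | mean TTR over sliding windows of exactly `window` tokens, stride 1 | window = 50 |
| content–function ratio | content tokens / all tokens (closed function-word stop list) | `content_over_total` |
| MLU | tokens per clause, averaged over clauses | — |
| parse depth | per-sentence proxy: 2 + #subordinate clauses + 1 if multi-clause, averaged | — |
| subordination index | subordinate clauses / clauses | — |
| entity overlap | \|entities shared with previous sentence\| / \|entities in later sentence\|, entities = closed noun lexicon | — |
| lexical cohesion | mean cosine of adjacent sentence embeddings; default embedding = L2-normalized bag-of-words counts | — |
| referential clarity | 1 − ambiguous pronouns / pronouns; a pronoun is ambiguous if no lexicon noun occurs in the previous k sentences or earlier in its own sentence; 1.0 when no pronouns | k = 2 |

Conventions worth making explicit:

- **Parser adapter.** The default segmenter is heuristic — sentences split
  on `.!?`, clauses on `,;:`, a clause is subordinate iff it *opens* with a
  subordinating conjunction, and parse depth is a proxy on a different
  scale from true constituency depth. A real parser can be swapped in via
  the adapter interface; the feature definitions are unchanged. The
  heuristic's noun inventory is a closed lexicon, so entity overlap and
  referential clarity measure exactly what the generator controls, not
  open-vocabulary coreference.
- **Content–function ratio** is content/(all tokens), bounded in [0, 1];
  the alternative content/function reading is exposed via `mode=` because
  published summaries are ambiguous between the two.
- **Referential clarity** reads "inverse frequency" as 1 − rate (bounded),
  not 1/count; the antecedent window k = 2 sentences is a configurable
  convention, and the pronoun's own sentence counts only up to the pronoun.
- **Sentinels.** Undefined features (empty note, one sentence, zero
  clauses) are NaN and are excluded from patient aggregation with weight
  renormalization — never imputed at the feature level. Imputation to the
  training-split mean happens only at the model boundary, where a dense
  vector is required.
- Patient aggregation is attention-weighted averaging; uniform weights are
  the non-model default.

## Synthetic corpus generator

The generator is the package's test substrate and defines its study
conditions. Each class carries: per-feature (mean, sd) targets; a concept
domain mixture over {cognition, function, care, mood, general} with an
optional end-of-span mixture for vocabulary drift; notes/patient ~
N(15.1, 7.4) truncated at 3; spans uniform on 1–6 years; note length ~
N(250, 60) tokens clipped to [120, 450].

Four features are constructed to target, the rest emerge:

- **TTR** — a new-type quota: the note introduces exactly
  round(TTR·N) distinct types, new types drawn from a closed filler pool
  (function words first, then pseudo-clinical content words, disjoint from
  the noun/pronoun/conjunction lexicons), reuse drawn Zipf-style by
  introduction rank.
- **MLU** — N = round(C·MLU) tokens distributed over C clauses.
- **Subordination** — round(s·C) clauses open with a conjunction.
- **Referential clarity** — each note plants 5–7 pronouns; an ambiguous
  pronoun sits behind two noun-free sentences (its whole antecedent window
  is inside the block), a clear one directly after a sentence with a
  planted noun. The ambiguous count is quantized to the pronoun grid, so an
  error-diffusion carry propagates the residual fraction across notes,
  keeping the corpus mean unbiased.

Per-note targets are baseline (patient offset, 0.25 class-sd) + linear
within-patient drift for MCI/AD (+0.65 → −0.65 class-sd across the span;
none for Normal) + visit noise (0.55 class-sd), then **moment-standardized
per class** — an affine map, so trajectory shapes survive — and clamped to
feature ranges. Standardization makes the realized note-level mean/sd match
the configured profile at any seed; residual bias from clamping is ~10⁻³
for the most boundary-adjacent feature (Normal-class referential clarity),
well inside the 2·SE acceptance band at n = 500.

The variance decomposition and the domain mixtures are the package's
definition of the *well-separated default regime*: class-conditional
marginals are fixed by the profiles, while between-patient spread is kept
small enough that an ideal patient-level classifier separates the classes
almost perfectly. MATTR, cohesion, parse depth, content–function ratio and
entity overlap are emergent — their class ordering is correct but their
absolute levels are properties of the construction, not calibrated targets.
The molecular covariate table (hippocampal volume etc.) can be emitted but
feeds nothing.

What passing generator-based tests shows: the extractor and the pipeline
are internally consistent, leakage-free, and able to learn exactly the
signals the generator encodes. What it does not show: performance on real
clinical text, whose vocabulary is open, whose parses are harder, and whose
label noise is not under experimental control.

## Model and training

Streams and widths (reference configuration / CPU preset in parentheses):
embedding bag d = 64 (16); Bi-LSTM 2 layers, hidden 256 (1 layer, 16),
bidirectional states concatenated; GraphSAGE 3 layers, width 64 (16),
neighborhood sample 10, node cap 200, AGG = mean, pool = mean; psych
projection 9 → 128 → 64 (32 → 16) with ReLU, inputs z-scored with
training-split moments; fusion width 512 (32) with 4-head cross-modal
attention; sigmoid gates from the concatenated attended streams; GELU
aggregation; softmax head.

- Initial graph node state = [normalized frequency, section distribution,
  weighted degree, concept-domain one-hot]. The one-hot is the minimal
  concept-identity signal: with anonymous features a shared-weight GNN
  cannot represent *which* concepts a patient mentions, only how connected
  they are.
- Neighbor sampling is seeded by a CRC32 hash of (patient id, node id), so
  encodings are reproducible and insertion-order invariant.
- Missing modalities (e.g. a patient with no matched concepts) pass a zero
  vector whose gate path is masked; drop-path removes whole modalities with
  p = 0.1 during training, always keeping at least one.
- Objective L = L_cls + λ·L_contrast with λ = 0.5 (the mixing weight has no
  published value; 0.5 gives the two terms the same order of magnitude at
  τ = 0.05). L_cls is a batch mean by default; an exact-sum switch exists
  for closed-form tests. Contrastive anchors/positives are Bi-LSTM note
  states of the same patient 180–1095 days apart; negatives are states of
  other patients in the batch.
- Optimizer AdamW; the reference lr 2e-5 / batch 16 / 50 epochs targets
  transformer-scale fine-tuning, while the CPU preset trains from scratch
  and uses lr 5e-3, batch 8, ≤ 25 epochs, early stopping on validation
  macro F1 with patience 10. All randomness flows from one integer seed;
  two runs with the same seed are bitwise identical.
- Ablation variants are pure configuration: `transformer_only`, `bilstm`
  (+temporal), `gnn` (+graph), `no_psych` (all but biomarkers), `full`.
  They share splits, preprocessing and seeds by construction.

## Evaluation conventions

- Metrics: accuracy, macro F1 (unweighted mean of per-class F1), balanced
  accuracy, macro one-vs-rest ROC AUC, macro PR-AUC, macro sensitivity/
  specificity, MCC, Cohen's κ, plus the per-class table. A class absent
  from the truth yields NaN per-class entries and a macro over present
  classes, with a warning.
- Monte-Carlo CV: repeated stratified patient-level hold-out; fold
  disjointness is asserted, not assumed. Desk defaults 50 folds, 1000
  bootstrap resamples, 20–200 permutations; the published protocol's
  10,000s are reachable via arguments.
- Temporal stability is defined here (no published formula) as the
  variance across visit prefixes of P(final predicted class), averaged over
  patients; single-note patients are excluded and counted.
- DeLong's paired AUC test uses the fast midrank placement formulation;
  multi-class is handled one-vs-rest with a macro Z.
- McNemar uses the continuity-corrected statistic (|b−c|−1)²/(b+c); zero
  discordance returns p = 1 flagged.
- Procrustes alignment fits the orthogonal transform (optional scaling) on
  paired anchors — cross-cohort pairing uses class-conditional centroids,
  an interpretation, since no correspondence rule is published — and
  reports RBF-kernel MMD (median-heuristic bandwidth) before and after.

## Explainability

Attention export returns the temporal α per note, the per-modality gates
and cross-modal attention mass. Feature importance is permutation-based:
the macro-F1 drop when one biomarker column is shuffled across patients
(exact Shapley attribution is out of scope). Counterfactual substitution
replaces a patient's biomarker vector with the Normal-class training mean
and reports the P(AD) shift; it leaves the text and graph streams
untouched, so it isolates the biomarker contribution only.

## Problem sizes

Test and acceptance runs use: 500 notes/class for calibration; a balanced
300-patient corpus (≈ 4,500 notes) for training-based checks; 20 label
permutations with 3-epoch retrainings; CPU-preset model widths. These are
the package's desk-scale study conditions; the reference configuration
remains available through `ModelConfig` defaults.

## Known limitations

- The heuristic parser's depth proxy is not on the constituency-depth
  scale; swap in a parser adapter before comparing depth values to
  published parse statistics.
- The embedding-bag encoder ignores word order inside a note; the adapter
  interface (`name`, `dim`, `max_length`, `encode`) is the path to a
  long-context transformer.
- Back-translation and masked-LM augmentation are adapter stubs (they
  require external translation/LM models); only synonym substitution runs
  locally.
- The concept matcher is a longest-match dictionary over a ~60-phrase toy
  lexicon; a licensed UMLS pipeline plugs in through the same interface.
- Generator text is template-structured; models trained on it should not
  be expected to transfer to natural clinical prose.
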