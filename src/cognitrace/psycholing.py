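"""The nine psycholinguistic biomarkers and their patient-level aggregation.

Features span lexical diversity (type-token ratio, moving-average TTR,
content-function ratio), syntactic complexity (mean length of utterance,
parse-depth proxy, subordination index) and discourse coherence (entity
overlap, lexical cohesion, referential clarity). All are computed per note
with a deterministic heuristic segmenter by default; a real constituency
parser can be swapped in through the parser-adapter interface.

Undefined features (e.g. cohesion of a one-sentence note) are NaN sentinels
and are excluded — never imputed — from patient-level aggregation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Note, PatientRecord
from .preprocess import tokenize

FEATURE_NAMES = (
    "ttr", "mattr", "content_function_ratio", "mlu", "parse_depth",
    "subordination_index", "entity_overlap", "lexical_cohesion",
    "referential_clarity",
)
N_FEATURES = len(FEATURE_NAMES)

SENTINEL = float("nan")

PRONOUNS = frozenset(
    "he she it they him her them his hers its theirs himself herself itself themselves".split()
)

SUBORDINATORS = frozenset(
    "because although while since unless whereas if when though until once".split()
)

FUNCTION_WORDS = frozenset(
    """a an the and or but nor so yet of in on at by for with to from into onto
    over under about as is are was were be been being am do does did has have
    had will would shall should can could may might must not no this that
    these those there here then than very too also just only more most much
    some any all both each either neither which who whom whose what""".split()
) | PRONOUNS | SUBORDINATORS

# Closed noun lexicon used by the heuristic adapter for antecedent and entity
# detection; a swapped-in parser adapter can use true POS tags instead.
NOUN_LEXICON = frozenset(
    """patient daughter son wife husband nurse doctor family caregiver aide
    neighbor friend memory appetite mood gait sleep balance pain speech
    attention orientation recall language home hospital clinic ward unit bed
    room kitchen garden medication dose tablet pill insulin walker cane chair
    glasses keys wallet phone letter newspaper book meal breakfast lunch
    dinner morning evening night week month year visit exam test scan score
    result plan review referral follow-up followup fall bruise wound rash
    fever cough breath chest heart lung kidney blood pressure sugar weight
    diet fluid bowel bladder skin leg arm hand foot head neck back hip""".split()
)


@dataclass
class ClauseSegmentation:
    """Sentence and clause token spans from the (pluggable) parser adapter."""

    sentences: list[list[str]]                 # tokens per sentence
    clauses: list[list[list[str]]]             # tokens per clause per sentence
    subordinate: list[list[bool]]              # subordinate flag per clause
    depths: list[float] = field(default_factory=list)  # per-sentence depth proxy

    @property
    def all_clauses(self):
        return [c for s in self.clauses for c in s]

    @property
    def n_clauses(self):
        return sum(len(s) for s in self.clauses)

    @property
    def n_subordinate(self):
        return sum(int(f) for s in self.subordinate for f in s)


class HeuristicParser:
    """Deterministic punctuation-and-lexicon segmenter.

    Sentences split on ``.!?``, clauses on ``,;:``; a clause is subordinate
    when it opens with a subordinating conjunction. Per-sentence depth is a
    proxy: 2 for a bare clause, +1 per subordinate clause, +1 if the sentence
    is multi-clause at all.
    """

    name = "heuristic"

    def segment(self, text: str) -> ClauseSegmentation:
        sentences, clauses, subflags, depths = [], [], [], []
        for sent_txt in re.split(r"[.!?]+", text):
            sent_txt = sent_txt.strip()
            if not sent_txt:
                continue
            cls_tokens, cls_flags = [], []
            for clause_txt in re.split(r"[,;:]+", sent_txt):
                toks = tokenize(clause_txt)
                if not toks:
                    continue
                cls_tokens.append(toks)
                cls_flags.append(toks[0] in SUBORDINATORS)
            if not cls_tokens:
                continue
            sent_toks = [t for c in cls_tokens for t in c]
            sentences.append(sent_toks)
            clauses.append(cls_tokens)
            subflags.append(cls_flags)
            depths.append(2.0 + sum(cls_flags) + (1.0 if len(cls_tokens) > 1 else 0.0))
        return ClauseSegmentation(sentences, clauses, subflags, depths)

    def sentence_embedding(self, sent_tokens: list[str]) -> np.ndarray:
        """L2-normalized bag-of-words count vector (vocabulary = the note)."""
        raise NotImplementedError  # embeddings are built note-locally below


DEFAULT_PARSER = HeuristicParser()


# ---------------------------------------------------------------------------
# individual features


def type_token_ratio(tokens: list[str]) -> float:
    if not tokens:
        return SENTINEL
    toks = [t.lower() for t in tokens]
    return len(set(toks)) / len(toks)


def mattr(tokens: list[str], window: int = 50) -> float:
    """Mean TTR over all contiguous windows of exactly ``window`` tokens."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if not tokens:
        return SENTINEL
    toks = [t.lower() for t in tokens]
    n = len(toks)
    if n <= window:
        return type_token_ratio(toks)
    # sliding-window distinct count with an occurrence multiset
    counts: dict[str, int] = {}
    distinct = 0
    total = 0.0
    for i, t in enumerate(toks):
        counts[t] = counts.get(t, 0) + 1
        if counts[t] == 1:
            distinct += 1
        if i >= window:
            old = toks[i - window]
            counts[old] -= 1
            if counts[old] == 0:
                distinct -= 1
        if i >= window - 1:
            total += distinct / window
    return total / (n - window + 1)


def content_function_ratio(tokens: list[str], mode: str = "content_over_total") -> float:
    """Share of content words; two readings of the ratio are exposed."""
    if not tokens:
        return SENTINEL
    toks = [t.lower() for t in tokens]
    n_function = sum(t in FUNCTION_WORDS for t in toks)
    n_content = len(toks) - n_function
    if mode == "content_over_total":
        return n_content / len(toks)
    if mode == "content_over_function":
        return SENTINEL if n_function == 0 else n_content / n_function
    raise ValueError(f"unknown mode {mode!r}")


def mean_length_of_utterance(seg: ClauseSegmentation) -> float:
    n = seg.n_clauses
    if n == 0:
        return SENTINEL
    return sum(len(c) for c in seg.all_clauses) / n


def parse_depth(seg: ClauseSegmentation) -> float:
    if not seg.depths:
        return SENTINEL
    return float(np.mean(seg.depths))


def subordination_index(seg: ClauseSegmentation) -> float:
    n = seg.n_clauses
    if n == 0:
        return SENTINEL
    return seg.n_subordinate / n


def _sentence_vectors(sentences: list[list[str]]) -> np.ndarray:
    vocab = sorted({t for s in sentences for t in s})
    index = {t: i for i, t in enumerate(vocab)}
    M = np.zeros((len(sentences), len(vocab)))
    for i, s in enumerate(sentences):
        for t in s:
            M[i, index[t]] += 1
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def lexical_cohesion(sentence_embeddings: np.ndarray) -> float:
    """Mean cosine similarity between adjacent (already normalized) rows."""
    E = np.asarray(sentence_embeddings, dtype=float)
    if len(E) < 2:
        return SENTINEL
    norms = np.linalg.norm(E, axis=1)
    norms[norms == 0] = 1.0
    En = E / norms[:, None]
    sims = np.sum(En[:-1] * En[1:], axis=1)
    return float(np.mean(sims))


def entity_overlap(seg: ClauseSegmentation, noun_lexicon=NOUN_LEXICON) -> float:
    """Shared entities between consecutive sentences over the later one's."""
    ents = [set(t for t in s if t in noun_lexicon) for s in seg.sentences]
    ratios = [
        len(a & b) / len(b)
        for a, b in zip(ents[:-1], ents[1:])
        if b
    ]
    return float(np.mean(ratios)) if ratios else SENTINEL


def referential_clarity(
    tokens: list[str],
    seg: ClauseSegmentation,
    k: int = 2,
    pronoun_lexicon=PRONOUNS,
    noun_lexicon=NOUN_LEXICON,
) -> float:
    """1 - (ambiguous pronouns / pronouns); no pronouns -> 1.0 by convention.

    A pronoun is ambiguous when no candidate antecedent noun occurs in the
    preceding ``k`` sentences or earlier in its own sentence.
    """
    n_pron = n_ambig = 0
    for i, sent in enumerate(seg.sentences):
        prior: set[str] = set()
        for s in seg.sentences[max(0, i - k):i]:
            prior.update(t for t in s if t in noun_lexicon)
        seen_in_sentence: set[str] = set()
        for tok in sent:
            if tok in pronoun_lexicon:
                n_pron += 1
                if not prior and not seen_in_sentence:
                    n_ambig += 1
            elif tok in noun_lexicon:
                seen_in_sentence.add(tok)
    if n_pron == 0:
        return 1.0
    return 1.0 - n_ambig / n_pron


# ---------------------------------------------------------------------------
# note- and patient-level vectors


def note_vector(note: Note, parser=DEFAULT_PARSER) -> np.ndarray:
    """All nine features for one (normalized) note, NaN where undefined."""
    tokens = note.tokens if note.tokens is not None else tokenize(note.text)
    seg = parser.segment(note.text)
    emb = _sentence_vectors(seg.sentences) if seg.sentences else np.zeros((0, 0))
    return np.array([
        type_token_ratio(tokens),
        mattr(tokens),
        content_function_ratio(tokens),
        mean_length_of_utterance(seg),
        parse_depth(seg),
        subordination_index(seg),
        entity_overlap(seg),
        lexical_cohesion(emb),
        referential_clarity(tokens, seg),
    ])


def aggregate_patient(vectors: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Attention-weighted per-feature mean, excluding NaN sentinels.

    Weights must be nonnegative and sum to 1 over the notes; for each
    feature, weights of sentinel notes are dropped and the rest renormalized.
    A feature that is sentinel in every note stays sentinel.
    """
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2 or V.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n_notes, {N_FEATURES}) matrix")
    n = len(V)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be nonnegative and sum to 1 over notes")
    out = np.empty(N_FEATURES)
    for j in range(N_FEATURES):
        valid = ~np.isnan(V[:, j])
        wj = w[valid]
        if wj.sum() <= 0:
            out[j] = SENTINEL
        else:
            out[j] = float(np.dot(wj / wj.sum(), V[valid, j]))
    return out


def patient_mean_features(records: list[PatientRecord], parser=DEFAULT_PARSER) -> np.ndarray:
    """Uniform-weight patient aggregates, one row per record."""
    rows = []
    for record in records:
        V = np.stack([note_vector(n, parser) for n in record.notes]) if record.notes \
            else np.full((1, N_FEATURES), np.nan)
        rows.append(aggregate_patient(V))
    return np.stack(rows)


def features_dataframe(records: list[PatientRecord], parser=DEFAULT_PARSER) -> pd.DataFrame:
    """Note-level feature matrix with sentinel flags, ready for CSV export."""
    rows = []
    for record in records:
        for note in record.notes:
            v = note_vector(note, parser)
            row = {"patient_id": record.patient_id, "note_id": note.note_id}
            row.update({name: v[i] for i, name in enumerate(FEATURE_NAMES)})
            row.update({f"{name}_sentinel": bool(np.isnan(v[i]))
                        for i, name in enumerate(FEATURE_NAMES)})
            rows.append(row)
    return pd.DataFrame(rows)
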