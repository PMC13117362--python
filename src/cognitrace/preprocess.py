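"""Text normalization, diagnosis masking, and patient-atomic class balancing.

Normalization expands clinical abbreviations, optionally applies a pluggable
speller, lowercases word tokens, and preserves PHI placeholders such as
``[**NAME**]`` as single distinct tokens. Masking removes diagnostic language
(longest match first) before any feature ever sees the text, and ADASYN
resampling duplicates whole minority-patient sequences — never individual
notes — using density weights on patient-level feature vectors.
"""

from __future__ import annotations

import copy
import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .corpus import CLASSES, Note, PatientRecord

log = logging.getLogger(__name__)

MASK_TOKEN = "[**MASK**]"

PLACEHOLDER_RE = re.compile(r"\[\*\*[^\]]*\*\*\]")
_WORD_RE = re.compile(r"\[\*\*[^\]]*\*\*\]|[a-z0-9']+", re.IGNORECASE)


class PreprocessError(ValueError):
    """Fatal preprocessing contract violation (e.g. leakage guard)."""


class AdapterNotConfigured(RuntimeError):
    """A pluggable augmentation/speller adapter was requested but not set up."""


def tokenize(text: str) -> list[str]:
    """Word tokens, case-folded; PHI placeholders survive as single tokens."""
    out = []
    for m in _WORD_RE.finditer(text):
        tok = m.group(0)
        out.append(tok if PLACEHOLDER_RE.fullmatch(tok) else tok.lower())
    return out


# ---------------------------------------------------------------------------
# normalization


def read_abbreviations(path) -> dict[str, str]:
    """TSV ``short<TAB>expansion`` with no header."""
    table = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            short, _, expansion = line.partition("\t")
            table[short.strip().lower()] = expansion.strip()
    return table


def normalize_text(text: str, abbrev_table: dict[str, str], speller=None) -> tuple[str, int]:
    """Expand abbreviations chunk-wise; returns (text, n_expansions)."""
    out_chunks, n_exp = [], 0
    for chunk in text.split():
        if PLACEHOLDER_RE.fullmatch(chunk):
            out_chunks.append(chunk)
            continue
        core = chunk.strip(".,;:!?")
        prefix_len = chunk.index(core) if core else 0
        prefix = chunk[:prefix_len]
        suffix = chunk[prefix_len + len(core):] if core else chunk
        key = core.lower()
        if key and key in abbrev_table:
            core = abbrev_table[key]
            n_exp += 1
        elif speller is not None and key:
            core = speller(core)
        out_chunks.append(prefix + core.lower() + suffix)
    return " ".join(out_chunks), n_exp


def normalize_note(note: Note, abbrev_table: dict[str, str], speller=None) -> Note:
    """Normalized copy with tokens populated; idempotent on reapplication."""
    if speller is None:
        log.debug("normalize_note: no speller adapter; spelling step skipped")
    text, n_exp = normalize_text(note.text, abbrev_table, speller)
    sections = {
        name: normalize_text(sec, abbrev_table, speller)[0]
        for name, sec in note.sections.items()
    }
    out = Note(
        note_id=note.note_id,
        patient_id=note.patient_id,
        timestamp=note.timestamp,
        sections=sections,
        text=text,
        tokens=tokenize(text),
        meta=dict(note.meta),
    )
    out.meta["abbreviations_expanded"] = n_exp
    return out


@dataclass
class NormalizationReport:
    tokens_before_mean: float
    tokens_before_sd: float
    tokens_after_mean: float
    tokens_after_sd: float
    abbreviations_expanded: int
    masked_terms: int


def normalize_corpus(
    records: list[PatientRecord],
    abbrev_table: dict[str, str],
    speller=None,
    mask_policy: "MaskPolicy | None" = None,
) -> tuple[list[PatientRecord], NormalizationReport]:
    """Normalize (and optionally mask) every note; report corpus statistics."""
    before, after = [], []
    n_exp = n_masked = 0
    out_records = []
    for record in records:
        new_notes = []
        for note in record.notes:
            before.append(len(tokenize(note.text)))
            norm = normalize_note(note, abbrev_table, speller)
            n_exp += norm.meta["abbreviations_expanded"]
            if mask_policy is not None:
                norm = mask_diagnostic_language(norm, mask_policy)
                n_masked += norm.meta["masked_terms"]
            after.append(len(norm.tokens))
            new_notes.append(norm)
        out_records.append(PatientRecord(
            patient_id=record.patient_id, notes=new_notes, label=record.label,
            diagnosis_date=record.diagnosis_date, synthetic_of=record.synthetic_of,
            meta=dict(record.meta),
        ))
    report = NormalizationReport(
        tokens_before_mean=float(np.mean(before)) if before else 0.0,
        tokens_before_sd=float(np.std(before)) if before else 0.0,
        tokens_after_mean=float(np.mean(after)) if after else 0.0,
        tokens_after_sd=float(np.std(after)) if after else 0.0,
        abbreviations_expanded=n_exp,
        masked_terms=n_masked,
    )
    return out_records, report


# ---------------------------------------------------------------------------
# diagnosis masking


@dataclass
class MaskPolicy:
    """Diagnostic-language mask: surface terms plus concept ids to drop."""

    terms: list[str]
    concept_ids: set[str] = field(default_factory=set)
    replacement: str = MASK_TOKEN

    def __post_init__(self):
        lex = {t.lower() for t in self.terms}
        if self.replacement.lower() in lex:
            raise PreprocessError("mask replacement token must not be in the lexicon")
        # longest match first so 'alzheimer's disease' wins over 'disease'
        ordered = sorted(self.terms, key=len, reverse=True)
        self._pattern = re.compile(
            r"\b(?:" + "|".join(re.escape(t) for t in ordered) + r")(?:\b|(?=\s|$|[.,;:!?]))",
            re.IGNORECASE,
        ) if ordered else None

    @classmethod
    def from_file(cls, path, **kw):
        with open(path, encoding="utf-8") as fh:
            terms = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
        return cls(terms=terms, **kw)


DEFAULT_MASK_TERMS = [
    "alzheimer's disease", "alzheimers disease", "alzheimer disease", "alzheimer's",
    "dementia", "mild cognitive impairment", "mci", "cognitive decline",
    "cognitive impairment", "neurodegeneration", "senile",
]


def mask_text(text: str, policy: MaskPolicy) -> tuple[str, int]:
    if policy._pattern is None:
        raise PreprocessError("mask lexicon is empty")
    count = 0

    def _sub(m):
        nonlocal count
        count += 1
        return policy.replacement

    return policy._pattern.sub(_sub, text), count


def mask_diagnostic_language(note: Note, policy: MaskPolicy) -> Note:
    """Replace every lexicon match by the reserved token (longest match wins)."""
    text, count = mask_text(note.text, policy)
    sections = {}
    for name, sec in note.sections.items():
        masked, c = mask_text(sec, policy)
        sections[name] = masked
        count += c
    out = Note(
        note_id=note.note_id, patient_id=note.patient_id, timestamp=note.timestamp,
        sections=sections, text=text,
        tokens=tokenize(text) if note.tokens is not None else None,
        meta=dict(note.meta),
    )
    out.meta["masked_terms"] = count
    return out


# ---------------------------------------------------------------------------
# patient-atomic ADASYN


def adasyn_patient_oversample(
    records: list[PatientRecord],
    features: np.ndarray | None = None,
    target_class: str | None = None,
    seed: int = 0,
    k_neighbors: int = 5,
    split: str = "train",
) -> list[PatientRecord]:
    """Balance classes by duplicating whole minority-patient sequences.

    Density weights follow ADASYN: a minority patient whose feature-space
    neighborhood contains more out-of-class patients receives more copies.
    Copies are verbatim note sequences with new ids (``<orig>_syn<k>``) and a
    provenance flag; no synthetic intermediate visits are ever created.

    ``features`` is an (n_patients, d) matrix aligned with ``records``; by
    default the patient-mean psycholinguistic vector is used.
    """
    if split != "train":
        raise PreprocessError("ADASYN oversampling is restricted to the training split")
    if features is None:
        from .psycholing import patient_mean_features
        features = patient_mean_features(records)
    features = np.asarray(features, dtype=float)
    features = np.nan_to_num(features, nan=0.0)
    mu, sd = features.mean(axis=0), features.std(axis=0)
    sd[sd == 0] = 1.0
    X = (features - mu) / sd

    counts = Counter(r.label for r in records)
    majority = max(counts.values())
    rng = np.random.default_rng(seed)
    out = list(records)
    classes = [target_class] if target_class else [c for c in CLASSES if c in counts]
    for cls in classes:
        n_cls = counts.get(cls, 0)
        if n_cls == 0 or n_cls == majority:
            continue
        if n_cls < 2:
            raise PreprocessError(
                f"class {cls!r} has a single patient; ADASYN density weights undefined"
            )
        idx_cls = [i for i, r in enumerate(records) if r.label == cls]
        k = min(k_neighbors, len(records) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, neigh = nn.kneighbors(X[idx_cls])
        ratios = np.array([
            np.mean([records[j].label != cls for j in row if j != i][:k])
            for i, row in zip(idx_cls, neigh)
        ])
        weights = ratios / ratios.sum() if ratios.sum() > 0 else np.full(len(idx_cls), 1 / len(idx_cls))
        n_new = majority - n_cls
        chosen = rng.choice(len(idx_cls), size=n_new, replace=True, p=weights)
        syn_counter: Counter = Counter()
        for c in chosen:
            src = records[idx_cls[c]]
            syn_counter[src.patient_id] += 1
            j = syn_counter[src.patient_id]
            clone = copy.deepcopy(src)
            clone.patient_id = f"{src.patient_id}_syn{j}"
            clone.synthetic_of = src.patient_id
            for note in clone.notes:
                note.patient_id = clone.patient_id
                note.note_id = f"{note.note_id}_syn{j}"
            out.append(clone)
    return out


# ---------------------------------------------------------------------------
# training-set augmentation


def read_synonyms(path) -> dict[str, str]:
    table = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            a, _, b = line.partition("\t")
            table[a.strip().lower()] = b.strip().lower()
    return table


TOY_SYNONYMS = {
    "loss": "deficit", "decline": "deterioration", "confusion": "disorientation",
    "trouble": "difficulty", "forgetful": "absentminded", "unsteady": "unstable",
}


def _synonym_variant(note: Note, lexicon: dict[str, str]) -> Note | None:
    toks = note.tokens if note.tokens is not None else tokenize(note.text)
    if not any(t in lexicon for t in toks):
        return None
    pattern = re.compile(r"\b(" + "|".join(re.escape(t) for t in lexicon) + r")\b", re.IGNORECASE)
    text = pattern.sub(lambda m: lexicon[m.group(0).lower()], note.text)
    return Note(
        note_id=f"{note.note_id}_aug0", patient_id=note.patient_id,
        timestamp=note.timestamp, sections=dict(note.sections), text=text,
        tokens=tokenize(text), meta={"augmented_from": note.note_id},
    )


def augment_training_notes(
    records: list[PatientRecord],
    methods: list[str] = ("synonym",),
    synonym_lexicon: dict[str, str] | None = None,
    split: str = "train",
) -> list[PatientRecord]:
    """Append augmentation variants inside each training record.

    Only synonym substitution runs locally; ``back_translation`` and
    ``mlm`` are adapter stubs that raise until an external model is wired in.
    Calling this on a non-training split is a hard error (leakage guard).
    """
    if split != "train":
        raise PreprocessError("augmentation is restricted to the training split")
    lexicon = synonym_lexicon or TOY_SYNONYMS
    for method in methods:
        if method == "synonym":
            continue
        if method in ("back_translation", "mlm"):
            raise AdapterNotConfigured(f"adapter not configured: {method}")
        raise PreprocessError(f"unknown augmentation method {method!r}")
    out = []
    for record in records:
        variants = []
        for note in record.notes:
            if "synonym" in methods:
                v = _synonym_variant(note, lexicon)
                if v is not None:
                    variants.append(v)
        out.append(PatientRecord(
            patient_id=record.patient_id, notes=list(record.notes) + variants,
            label=record.label, diagnosis_date=record.diagnosis_date,
            synthetic_of=record.synthetic_of, meta=dict(record.meta),
        ))
    return out
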