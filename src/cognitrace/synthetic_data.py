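"""Seeded generator of longitudinal synthetic note corpora.

Each class (Normal / MCI / AD) carries a psycholinguistic profile (means and
SDs for the note-level biomarkers), a concept-domain mixture (independence
vs. care-dependence vocabulary), a notes-per-patient distribution and a span
range. Four features are *constructed* to target: type-token ratio (via a
new-type quota over a closed filler pool), mean length of utterance (clause
length plan), subordination index (clause-initial conjunctions) and
referential clarity (pronouns with controlled antecedent presence). The
remaining features (MATTR, content-function ratio, parse depth, entity
overlap, cohesion) emerge from the same construction.

Per-note targets are drawn from the class profile and then moment-
standardized within the class (an affine map), so the realized note sample
matches the configured mean/SD rather than drifting with the seed; within-
patient trajectories (linear decline for MCI/AD plus visit noise) survive
the affine map unchanged in shape.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .corpus import CLASSES, Note, PatientRecord
from .concept_graph import TOY_LEXICON
from .psycholing import NOUN_LEXICON, PRONOUNS, SUBORDINATORS


class ProfileError(ValueError):
    pass


# ---------------------------------------------------------------------------
# profiles


@dataclass
class FeatureTarget:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ProfileError("feature sd must be positive")


@dataclass
class TrajectorySpec:
    """Within-patient drift model (generator-defined; only the sign of the
    decline is ever asserted downstream)."""

    mode: str = "stable"            # "stable" | "decline"
    baseline_sd: float = 0.25       # patient offset, in class-sd units
    drift_amplitude: float = 0.65   # +amp at first visit -> -amp at last
    visit_noise_sd: float = 0.55    # i.i.d. per-visit noise, class-sd units


@dataclass
class ClassProfile:
    label: str
    features: dict[str, FeatureTarget]
    mixture: dict[str, float]                 # concept-domain weights
    mixture_end: dict[str, float] | None = None   # vocabulary drift target
    notes_mean: float = 15.1
    notes_sd: float = 7.4
    min_notes: int = 3
    span_years: tuple[float, float] = (1.0, 6.0)
    note_len_mean: float = 250.0
    note_len_sd: float = 60.0
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)

    def validate(self):
        for name in ("ttr", "mlu", "subordination_index", "referential_clarity"):
            if name not in self.features:
                raise ProfileError(f"profile {self.label}: missing target {name!r}")
        f = self.features
        if not (0 < f["ttr"].mean <= 1):
            raise ProfileError(f"profile {self.label}: TTR mean out of (0,1]")
        if f["mlu"].mean < 3:
            raise ProfileError(f"profile {self.label}: MLU mean below 3 tokens/clause")
        for name in ("subordination_index", "referential_clarity"):
            if not (0 <= f[name].mean <= 1):
                raise ProfileError(f"profile {self.label}: {name} mean out of [0,1]")
        s = sum(self.mixture.values())
        if abs(s - 1.0) > 1e-6 or any(v < 0 for v in self.mixture.values()):
            raise ProfileError(f"profile {self.label}: mixture must be a simplex")
        return self


def _targets(rows: dict[str, tuple[float, float]]) -> dict[str, FeatureTarget]:
    return {k: FeatureTarget(*v) for k, v in rows.items()}


# Class-conditional biomarker statistics (text-derived features only).
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "Normal": ClassProfile(
        label="Normal",
        features=_targets({
            "ttr": (0.71, 0.08), "mattr": (0.69, 0.07),
            "content_function_ratio": (0.48, 0.05), "mlu": (14.2, 3.5),
            "parse_depth": (6.5, 1.2), "subordination_index": (0.31, 0.07),
            "lexical_cohesion": (0.73, 0.08), "referential_clarity": (0.92, 0.05),
        }),
        mixture={"function": 0.58, "general": 0.25, "cognition": 0.05,
                 "mood": 0.07, "care": 0.05},
        trajectory=TrajectorySpec(mode="stable", drift_amplitude=0.0),
    ),
    "MCI": ClassProfile(
        label="MCI",
        features=_targets({
            "ttr": (0.64, 0.10), "mattr": (0.62, 0.09),
            "content_function_ratio": (0.43, 0.06), "mlu": (12.1, 3.2),
            "parse_depth": (5.8, 1.1), "subordination_index": (0.27, 0.06),
            "lexical_cohesion": (0.67, 0.09), "referential_clarity": (0.88, 0.06),
        }),
        mixture={"function": 0.32, "general": 0.24, "cognition": 0.25,
                 "mood": 0.12, "care": 0.07},
        mixture_end={"function": 0.22, "general": 0.22, "cognition": 0.30,
                     "mood": 0.13, "care": 0.13},
        trajectory=TrajectorySpec(mode="decline"),
    ),
    "AD": ClassProfile(
        label="AD",
        features=_targets({
            "ttr": (0.56, 0.12), "mattr": (0.54, 0.11),
            "content_function_ratio": (0.37, 0.07), "mlu": (9.8, 2.9),
            "parse_depth": (4.9, 1.0), "subordination_index": (0.21, 0.05),
            "lexical_cohesion": (0.58, 0.10), "referential_clarity": (0.81, 0.08),
        }),
        mixture={"function": 0.06, "general": 0.18, "cognition": 0.36,
                 "mood": 0.13, "care": 0.27},
        mixture_end={"function": 0.03, "general": 0.15, "cognition": 0.35,
                     "mood": 0.12, "care": 0.35},
        trajectory=TrajectorySpec(mode="decline"),
    ),
}

# Optional biomarker covariate rows (emitted on request, consumed by nothing).
MOLECULAR_COVARIATES = {
    "hippocampal_volume": {"Normal": (3.8, 0.4), "MCI": (3.1, 0.5), "AD": (2.4, 0.6)},
    "amyloid_beta": {"Normal": (42.5, 5.1), "MCI": (65.2, 6.3), "AD": (88.7, 7.4)},
    "tau_protein": {"Normal": (18.3, 3.2), "MCI": (29.7, 4.1), "AD": (41.5, 5.0)},
    "cortical_thickness": {"Normal": (2.6, 0.3), "MCI": (2.2, 0.3), "AD": (1.8, 0.2)},
    "fdg_pet": {"Normal": (1.35, 0.12), "MCI": (1.10, 0.15), "AD": (0.85, 0.14)},
    "white_matter_fa": {"Normal": (0.52, 0.05), "MCI": (0.46, 0.06), "AD": (0.39, 0.07)},
}


# ---------------------------------------------------------------------------
# closed vocabularies for text realization

_SUB_LIST = sorted(SUBORDINATORS - {"once"})
_PRONOUN_LIST = ["she", "he", "they", "it"]
# person/object nouns that never begin a concept phrase
RC_NOUNS = ["daughter", "son", "wife", "husband", "nurse", "neighbor",
            "walker", "kitchen", "garden", "letter", "newspaper", "wallet"]

_FUNCTION_FILLER = ["the", "a", "of", "in", "on", "with", "and", "was", "is",
                    "for", "to", "at", "as", "but", "not", "very", "more"]

def _plain(phrase: str) -> bool:
    # only phrases whose realization as space-joined tokens round-trips
    from .preprocess import tokenize
    return phrase == " ".join(tokenize(phrase))


_CONCEPTS_BY_DOMAIN: dict[str, list[str]] = {}
for _phrase, _cid, _dom, _diag in TOY_LEXICON:
    if not _diag and _plain(_phrase):
        _CONCEPTS_BY_DOMAIN.setdefault(_dom, []).append(_phrase)


def _build_content_pool() -> list[str]:
    stems = [
        "observ", "report", "describ", "present", "remain", "appear", "improv",
        "review", "continu", "assess", "monitor", "discuss", "not", "eval",
        "respond", "toler", "requir", "deni", "express", "perform", "complet",
        "attend", "engag", "orient", "focus", "settl", "adjust", "maintain",
        "general", "moder", "mild", "sever", "gradu", "steadi", "calm",
        "alert", "coher", "fluent", "clear", "slow", "brisk", "routin",
    ]
    suffixes = ["ed", "es", "ing", "ely", "ant", "ive", "ous", "al",
                "er", "est", "ish", "ence", "ured"]
    banned = set(NOUN_LEXICON) | set(PRONOUNS) | set(SUBORDINATORS) \
        | set(_FUNCTION_FILLER) | {"dementia", "mci"}
    for phrase, _cid, _dom, _diag in TOY_LEXICON:
        banned |= set(phrase.lower().split())
    pool = []
    for s in stems:
        for suf in suffixes:
            w = s + suf
            if w not in banned and w not in pool:
                pool.append(w)
    return pool


CONTENT_POOL = _build_content_pool()


# ---------------------------------------------------------------------------
# note realization


def _realize_note(ttr_t, mlu_t, sub_t, rc_t, mixture, rng, profile,
                  vocab_prefix: str = "", rc_state: dict | None = None):
    """Build one note's text hitting the four constructed targets.

    Returns (text, sections) where sections concatenate to the text.
    ``rc_state`` carries an error-diffusion residual so the *corpus-level*
    mean ambiguous-pronoun fraction matches the targets exactly even though
    each note quantizes the fraction to a multiple of 1/n_pronouns.
    """
    n_target = float(np.clip(rng.normal(profile.note_len_mean, profile.note_len_sd),
                             120, 450))
    n_clauses = max(4, int(round(n_target / mlu_t)))
    n_pron = int(min(5 + rng.integers(0, 3), max(1, (n_clauses - 2) // 3)))
    frac = 1.0 - rc_t
    carry = rc_state.get("carry", 0.0) if rc_state is not None else 0.0
    n_ambig = int(np.clip(round((frac + carry) * n_pron), 0, n_pron))
    if rc_state is not None:
        rc_state["carry"] = carry + frac - n_ambig / n_pron
    n_tokens = int(round(n_clauses * mlu_t))

    # clause skeletons: (fixed_tokens, noun_free)
    sentences: list[list[dict]] = []
    for _ in range(n_ambig):          # 2 noun-free sentences then a pronoun
        sentences.append([{"fixed": [], "noun_free": True}])
        sentences.append([{"fixed": [], "noun_free": True}])
        sentences.append([{"fixed": [_PRONOUN_LIST[rng.integers(len(_PRONOUN_LIST))]],
                           "noun_free": True}])
    for _ in range(n_pron - n_ambig):  # antecedent noun then a pronoun
        noun = RC_NOUNS[rng.integers(len(RC_NOUNS))]
        sentences.append([{"fixed": [noun], "noun_free": False}])
        sentences.append([{"fixed": [_PRONOUN_LIST[rng.integers(len(_PRONOUN_LIST))]],
                           "noun_free": True}])
    n_content = n_clauses - sum(len(s) for s in sentences)
    content_clauses = []
    while n_content > 0:
        size = int(min(n_content, 1 + rng.integers(0, 3)))
        sent = [{"fixed": [], "noun_free": False} for _ in range(size)]
        sentences.append(sent)
        content_clauses.extend(sent)
        n_content -= size
    # shuffle at segment-block level: each pronoun's antecedent window must
    # stay inside its own block, so blocks move as units
    blocks = []
    n_seg_sents = n_ambig * 3 + (n_pron - n_ambig) * 2
    b = 0
    while b < len(sentences):
        if b < n_ambig * 3:
            blocks.append(sentences[b:b + 3]); b += 3
        elif b < n_seg_sents:
            blocks.append(sentences[b:b + 2]); b += 2
        else:
            blocks.append(sentences[b:b + 1]); b += 1
    rng.shuffle(blocks)
    sentences = [s for blk in blocks for s in blk]
    clauses = [c for s in sentences for c in s]

    # subordinating conjunctions open a quota of clauses
    n_sub = int(np.clip(round(sub_t * len(clauses)), 0, len(clauses)))
    for idx in rng.choice(len(clauses), size=n_sub, replace=False):
        c = clauses[idx]
        c["fixed"] = [_SUB_LIST[rng.integers(len(_SUB_LIST))]] + c["fixed"]

    # concept phrases from the class mixture go into non-noun-free clauses
    hosts = [c for c in clauses if not c["noun_free"]]
    if hosts:
        domains = sorted(mixture)
        w = np.array([mixture[d] for d in domains], dtype=float)
        w = w / w.sum()
        for _ in range(2 + rng.integers(0, 3)):
            dom = domains[rng.choice(len(domains), p=w)]
            phrase = _CONCEPTS_BY_DOMAIN[dom][rng.integers(len(_CONCEPTS_BY_DOMAIN[dom]))]
            hosts[rng.integers(len(hosts))]["fixed"].extend(phrase.split())

    skel_tokens = [t for c in clauses for t in c["fixed"]]
    n_skel = len(skel_tokens)
    if n_skel > n_tokens:
        n_tokens = n_skel
    n_filler = n_tokens - n_skel
    alloc = rng.multinomial(n_filler, np.full(len(clauses), 1.0 / len(clauses)))

    # new-type quota so the realized distinct count hits round(ttr * n_tokens)
    u0 = len(set(skel_tokens))
    u_target = int(np.clip(round(ttr_t * n_tokens), u0, u0 + n_filler))
    needed = u_target - u0
    pool = [vocab_prefix + w for w in _FUNCTION_FILLER] + \
           [vocab_prefix + w for w in CONTENT_POOL]
    head = pool[:len(_FUNCTION_FILLER)]
    tail = pool[len(_FUNCTION_FILLER):]
    rng.shuffle(head)
    rng.shuffle(tail)
    pool = head + tail
    introduced: list[str] = []
    remaining = n_filler
    zipf_cache = np.array([])
    for c, extra in zip(clauses, alloc):
        fillers = []
        for _ in range(int(extra)):
            new = (needed >= remaining) or (not introduced) or \
                  (needed > 0 and rng.random() < needed / remaining)
            if new and needed > 0 and len(introduced) < len(pool):
                w = pool[len(introduced)]
                introduced.append(w)
                needed -= 1
                zipf_cache = 1.0 / np.arange(1, len(introduced) + 1)
            elif introduced:
                p = zipf_cache / zipf_cache.sum()
                w = introduced[rng.choice(len(introduced), p=p)]
            else:       # degenerate: no types yet but quota exhausted
                w = pool[0]
                introduced.append(w)
                zipf_cache = np.array([1.0])
            fillers.append(w)
            remaining -= 1
        # fillers go after the fixed opening tokens (conjunction/pronoun/noun)
        c["tokens"] = c["fixed"] + fillers

    sent_texts = [", ".join(" ".join(c["tokens"]) for c in s if c["tokens"])
                  for s in sentences]
    sent_texts = [t for t in sent_texts if t]
    n_sent = len(sent_texts)
    cut1 = max(1, int(0.4 * n_sent))
    cut2 = max(cut1 + 1, int(0.5 * n_sent)) if n_sent > 2 else cut1
    sections = {
        "history": ". ".join(sent_texts[:cut1]) + ".",
        "medications": (". ".join(sent_texts[cut1:cut2]) + ".") if cut2 > cut1 else "",
        "assessment": (". ".join(sent_texts[cut2:]) + ".") if cut2 < n_sent else "",
    }
    sections = {k: v for k, v in sections.items() if v}
    text = " ".join(sections.values())
    return text, sections


# ---------------------------------------------------------------------------
# corpus generation


_CAL_FEATURES = ("ttr", "mlu", "subordination_index", "referential_clarity")
_CLAMPS = {"ttr": (0.10, 0.98), "mlu": (4.0, 40.0),
           "subordination_index": (0.0, 0.95), "referential_clarity": (0.0, 1.0)}


def _standardize(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if len(x) < 2 or np.std(x) == 0:
        return np.full_like(x, mean)
    return mean + sd * (x - x.mean()) / x.std()


def _plan_class(profile: ClassProfile, n_patients: int, rng,
                n_notes_cap: int | None = None):
    """Visit plan + per-note feature targets for one class."""
    plans = []
    total = 0
    i = 0
    while (n_notes_cap is None and i < n_patients) or \
          (n_notes_cap is not None and total < n_notes_cap):
        T = max(profile.min_notes, int(round(rng.normal(profile.notes_mean,
                                                        profile.notes_sd))))
        if n_notes_cap is not None:
            T = min(T, n_notes_cap - total)
        span = rng.uniform(*profile.span_years) * 365.0
        days = np.sort(rng.choice(np.arange(1, int(span)), size=T - 1,
                                  replace=False)) if T > 1 else np.array([], dtype=int)
        days = np.concatenate(([0], days))
        plans.append(days)
        total += T
        i += 1

    traj = profile.trajectory
    targets = {}
    for name in _CAL_FEATURES:
        ft = profile.features[name]
        vals = []
        for days in plans:
            T = len(days)
            base = rng.normal(0.0, traj.baseline_sd)
            if traj.mode == "decline" and T > 1:
                drift = np.linspace(traj.drift_amplitude, -traj.drift_amplitude, T)
            else:
                drift = np.zeros(T)
            noise = rng.normal(0.0, traj.visit_noise_sd, size=T)
            vals.append((base + drift + noise) * ft.sd)
        flat = np.concatenate(vals)
        flat = _standardize(flat, ft.mean, ft.sd)
        lo, hi = _CLAMPS[name]
        targets[name] = np.clip(flat, lo, hi)
    return plans, targets


def _mixture_at(profile: ClassProfile, frac: float) -> dict[str, float]:
    if profile.mixture_end is None:
        return profile.mixture
    mix = {d: (1 - frac) * profile.mixture[d] + frac * profile.mixture_end.get(d, 0.0)
           for d in profile.mixture}
    s = sum(mix.values())
    return {d: v / s for d, v in mix.items()}


def generate_class_notes(profile: ClassProfile, n_notes: int, seed: int,
                         start: datetime | None = None,
                         pid_offset: int = 0,
                         vocab_prefix: str = "") -> list[PatientRecord]:
    """Generate whole patients until exactly ``n_notes`` notes exist."""
    profile.validate()
    rng = np.random.default_rng(seed)
    start = start or datetime(2018, 1, 1, tzinfo=timezone.utc)
    plans, targets = _plan_class(profile, 0, rng, n_notes_cap=n_notes)
    rc_state = {"carry": 0.0}
    records = []
    k = 0
    for p, days in enumerate(plans):
        pid = f"p{pid_offset + p:05d}"
        t0 = start + timedelta(days=int(rng.integers(0, 1461)))
        notes = []
        T = len(days)
        for t, day in enumerate(days):
            frac = t / (T - 1) if T > 1 else 0.0
            text, sections = _realize_note(
                targets["ttr"][k], targets["mlu"][k],
                targets["subordination_index"][k],
                targets["referential_clarity"][k],
                _mixture_at(profile, frac), rng, profile, vocab_prefix,
                rc_state=rc_state)
            notes.append(Note(
                note_id=f"{pid}-n{t:03d}", patient_id=pid,
                timestamp=t0 + timedelta(days=int(day)),
                sections=sections, text=text,
            ))
            k += 1
        records.append(PatientRecord(patient_id=pid, notes=notes, label=profile.label))
    return records


def generate_corpus(n_per_class: dict[str, int] | int,
                    profiles: dict[str, ClassProfile] | None = None,
                    seed: int = 7,
                    vocab_prefix: str = "") -> list[PatientRecord]:
    """Patient-count-driven corpus over all classes; deterministic per seed."""
    profiles = profiles or DEFAULT_PROFILES
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in profiles}
    records = []
    pid_offset = 0
    for ci, (cls, n) in enumerate(sorted(n_per_class.items())):
        profile = profiles[cls].validate()
        rng = np.random.default_rng(seed + 1000 * ci)
        start = datetime(2018, 1, 1, tzinfo=timezone.utc)
        plans, targets = _plan_class(profile, n, rng)
        rc_state = {"carry": 0.0}
        k = 0
        for p, days in enumerate(plans):
            pid = f"p{pid_offset + p:05d}"
            t0 = start + timedelta(days=int(rng.integers(0, 1461)))
            notes = []
            T = len(days)
            for t, day in enumerate(days):
                frac = t / (T - 1) if T > 1 else 0.0
                text, sections = _realize_note(
                    targets["ttr"][k], targets["mlu"][k],
                    targets["subordination_index"][k],
                    targets["referential_clarity"][k],
                    _mixture_at(profile, frac), rng, profile, vocab_prefix,
                    rc_state=rc_state)
                notes.append(Note(
                    note_id=f"{pid}-n{t:03d}", patient_id=pid,
                    timestamp=t0 + timedelta(days=int(day)),
                    sections=sections, text=text,
                ))
                k += 1
            records.append(PatientRecord(patient_id=pid, notes=notes,
                                         label=profile.label))
        pid_offset += len(plans)
    records.sort(key=lambda r: r.patient_id)
    return records


def emit_covariates(records: list[PatientRecord], seed: int = 0) -> pd.DataFrame:
    """Optional molecular/imaging covariate table (not used by any model)."""
    rng = np.random.default_rng(seed)
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id}
        for name, by_class in MOLECULAR_COVARIATES.items():
            mean, sd = by_class[r.label]
            row[name] = rng.normal(mean, sd)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# label noise and distribution shift


def inject_label_noise(records: list[PatientRecord], rate: float,
                       seed: int = 0) -> list[PatientRecord]:
    """Reassign exactly round(rate*n) patients to a uniformly different class."""
    if not 0 <= rate <= 1:
        raise ValueError("noise rate must be in [0, 1]")
    n_flip = int(round(rate * len(records)))
    rng = np.random.default_rng(seed)
    idx = set(rng.choice(len(records), size=n_flip, replace=False)) if n_flip else set()
    out = []
    for i, r in enumerate(records):
        r2 = copy.copy(r)
        if i in idx:
            others = [c for c in CLASSES if c != r.label]
            r2 = PatientRecord(patient_id=r.patient_id, notes=r.notes,
                               label=others[rng.integers(len(others))],
                               diagnosis_date=r.diagnosis_date,
                               synthetic_of=r.synthetic_of,
                               meta={**r.meta, "label_flipped": True})
        out.append(r2)
    return out


@dataclass
class ShiftSpec:
    """Distribution shift for a surrogate external cohort."""

    feature_mean_delta: dict[str, float] = field(default_factory=dict)
    note_len_scale: float = 1.0
    mixture_shift: dict[str, float] = field(default_factory=dict)
    vocab_prefix: str = ""


def shifted_cohort(profiles: dict[str, ClassProfile] | None,
                   shift: ShiftSpec, n_per_class: dict[str, int] | int,
                   seed: int) -> list[PatientRecord]:
    """Generate a cohort under the shifted profiles for zero-shot testing."""
    profiles = profiles or DEFAULT_PROFILES
    shifted = {}
    for cls, prof in profiles.items():
        feats = {k: FeatureTarget(v.mean + shift.feature_mean_delta.get(k, 0.0), v.sd)
                 for k, v in prof.features.items()}
        mix = {d: max(1e-9, w + shift.mixture_shift.get(d, 0.0))
               for d, w in prof.mixture.items()}
        s = sum(mix.values())
        mix = {d: w / s for d, w in mix.items()}
        shifted[cls] = replace(
            prof, features=feats, mixture=mix,
            note_len_mean=prof.note_len_mean * shift.note_len_scale,
        )
    return generate_corpus(n_per_class, shifted, seed=seed,
                           vocab_prefix=shift.vocab_prefix)
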