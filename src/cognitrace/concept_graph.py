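"""Patient-specific concept co-occurrence graphs and a GraphSAGE-mean encoder.

Concepts are matched by a longest-match dictionary matcher over a bundled toy
lexicon (cognition / daily function / care-dependence / mood / general
domains); a licensed UMLS pipeline can be plugged in through the same
``(phrase, concept_id, is_diagnostic)`` interface. Each patient's graph has a
node per distinct concept and an undirected edge weighted by same-note
co-occurrence plus consecutive-note temporal adjacency. Graphs are capped at
200 nodes, and masked diagnostic concepts never enter a graph.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import Note, PatientRecord, SECTION_NAMES
from .preprocess import MaskPolicy

MAX_NODES = 200


class ConceptError(ValueError):
    pass


@dataclass(frozen=True)
class LexiconEntry:
    phrase: str
    concept_id: str
    domain: str = "general"
    is_diagnostic: bool = False


# Toy clinical concept lexicon: phrase -> concept id, spanning independence
# vs. care-dependence vocabulary so class mixtures are expressible.
TOY_LEXICON = [
    # cognition domain
    ("memory loss", "C0002622", "cognition", False),
    ("memory complaint", "C1739170", "cognition", False),
    ("disorientation", "C0233407", "cognition", False),
    ("word finding difficulty", "C0473568", "cognition", False),
    ("forgetfulness", "C0542476", "cognition", False),
    ("confusion", "C0009676", "cognition", False),
    ("poor recall", "C0474407", "cognition", False),
    ("repeats questions", "C4230537", "cognition", False),
    ("misplaces objects", "C4230538", "cognition", False),
    ("gets lost", "C4230539", "cognition", False),
    ("impaired judgment", "C0233535", "cognition", False),
    ("reduced attention", "C0233414", "cognition", False),
    ("slow processing", "C4230540", "cognition", False),
    ("language difficulty", "C0023520", "cognition", False),
    # daily-function / independence domain
    ("independent living", "C0682343", "function", False),
    ("manages medications", "C3266656", "function", False),
    ("manages finances", "C3266657", "function", False),
    ("drives independently", "C4230541", "function", False),
    ("prepares meals", "C4230542", "function", False),
    ("shops independently", "C4230543", "function", False),
    ("good orientation", "C4230544", "function", False),
    ("normal gait", "C0231691", "function", False),
    ("stable mood", "C4230545", "function", False),
    ("exercises regularly", "C4230546", "function", False),
    ("social engagement", "C0679201", "function", False),
    ("hobbies maintained", "C4230547", "function", False),
    # care-dependence domain
    ("self-care difficulty", "C1299586", "care", False),
    ("needs supervision", "C4230548", "care", False),
    ("caregiver support", "C0086279", "care", False),
    ("assistance with dressing", "C4230549", "care", False),
    ("assistance with bathing", "C4230550", "care", False),
    ("feeding assistance", "C4230551", "care", False),
    ("wandering behavior", "C0424092", "care", False),
    ("nursing placement", "C0687639", "care", False),
    ("fall risk", "C1268740", "care", False),
    ("incontinence", "C0021167", "care", False),
    ("day program", "C4230552", "care", False),
    ("home health aide", "C0019855", "care", False),
    # mood / behavior
    ("agitation", "C0085631", "mood", False),
    ("apathy", "C0085632", "mood", False),
    ("anxiety", "C0003467", "mood", False),
    ("depressed mood", "C0344315", "mood", False),
    ("sleep disturbance", "C0037317", "mood", False),
    ("irritability", "C0022107", "mood", False),
    # general clinical
    ("hypertension", "C0020538", "general", False),
    ("diabetes", "C0011849", "general", False),
    ("hyperlipidemia", "C0020473", "general", False),
    ("osteoarthritis", "C0029408", "general", False),
    ("chronic pain", "C0150055", "general", False),
    ("hearing loss", "C0011053", "general", False),
    ("visual impairment", "C3665347", "general", False),
    ("weight loss", "C1262477", "general", False),
    ("fatigue", "C0015672", "general", False),
    ("dizziness", "C0012833", "general", False),
    # diagnostic concepts: masked out of graphs by policy
    ("alzheimer's disease", "C0002395", "diagnostic", True),
    ("dementia", "C0497327", "diagnostic", True),
    ("mild cognitive impairment", "C1270972", "diagnostic", True),
    ("cognitive decline", "C0234985", "diagnostic", True),
]


def default_lexicon() -> list[LexiconEntry]:
    return [LexiconEntry(*row) for row in TOY_LEXICON]


def read_lexicon(path) -> list[LexiconEntry]:
    """TSV ``phrase<TAB>concept_id<TAB>is_diagnostic`` (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    out = []
    for _, row in df.iterrows():
        out.append(LexiconEntry(
            phrase=row[cols["phrase"]],
            concept_id=row[cols["concept_id"]],
            domain=row[cols["domain"]] if "domain" in cols else "general",
            is_diagnostic=str(row.get(cols.get("is_diagnostic", ""), "0")).lower()
            in ("1", "true", "yes"),
        ))
    return out


def extract_concepts(
    note: Note,
    lexicon: list[LexiconEntry] | None = None,
    mask_policy: MaskPolicy | None = None,
) -> list[tuple[str, tuple[int, int]]]:
    """Longest-match, case-insensitive, non-overlapping concept matches.

    Diagnostic lexicon entries — and any concept id listed in the mask
    policy — are excluded; the count of filtered matches is recorded in
    ``note.meta['masked_concepts']``.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    if not lexicon:
        raise ConceptError("concept lexicon is empty")
    by_phrase = {e.phrase.lower(): e for e in lexicon}
    ordered = sorted(by_phrase, key=len, reverse=True)
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(p) for p in ordered) + r")\b",
        re.IGNORECASE,
    )
    blocked = set(mask_policy.concept_ids) if mask_policy else set()
    out, n_masked = [], 0
    for m in pattern.finditer(note.text):
        entry = by_phrase[m.group(0).lower()]
        if entry.is_diagnostic or entry.concept_id in blocked:
            n_masked += 1
            continue
        out.append((entry.concept_id, m.span()))
    note.meta["masked_concepts"] = note.meta.get("masked_concepts", 0) + n_masked
    return out


@dataclass
class ConceptGraph:
    """Undirected patient concept graph with per-node frequency features."""

    patient_id: str
    graph: nx.Graph
    meta: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self):
        return self.graph.number_of_nodes()


def build_patient_graph(
    record: PatientRecord,
    concept_lists: list[list[str]] | None = None,
    lexicon: list[LexiconEntry] | None = None,
    mask_policy: MaskPolicy | None = None,
    max_nodes: int = MAX_NODES,
) -> ConceptGraph:
    """Graph over the patient's concepts.

    Edge weight = (# notes where both concepts appear) + (# consecutive-note
    pairs where one appears in each). When more than ``max_nodes`` distinct
    concepts occur, the most frequent are kept (ties broken lexicographically).
    """
    if concept_lists is None:
        concept_lists = [
            [cid for cid, _ in extract_concepts(n, lexicon, mask_policy)]
            for n in record.notes
        ]
    # frequency and per-section counts
    counts: dict[str, int] = {}
    section_counts: dict[str, np.ndarray] = {}
    sec_index = {s: i for i, s in enumerate(SECTION_NAMES)}
    for note, concepts in zip(record.notes, concept_lists):
        sec_of_span = None
        for cid in concepts:
            counts[cid] = counts.get(cid, 0) + 1
            vec = section_counts.setdefault(cid, np.zeros(len(SECTION_NAMES) + 1))
            # attribute to a section when the phrase occurs in exactly one
            hit = [i for s, i in sec_index.items()
                   if s in note.sections and cid in note.sections[s]]
            vec[hit[0] if len(hit) == 1 else -1] += 1
        del sec_of_span
    keep = sorted(counts, key=lambda c: (-counts[c], c))[:max_nodes]
    keepset = set(keep)

    domain_of = {e.concept_id: e.domain for e in (lexicon or default_lexicon())}
    G = nx.Graph()
    total = sum(counts[c] for c in keep) or 1
    for cid in keep:
        sec = section_counts[cid]
        sec_norm = sec / sec.sum() if sec.sum() else sec
        G.add_node(cid, count=counts[cid], freq=counts[cid] / total,
                   section_dist=sec_norm,
                   domain=domain_of.get(cid, "general"))
    note_sets = [set(c) & keepset for c in concept_lists]
    # same-note co-occurrence
    for s in note_sets:
        for a in s:
            for b in s:
                if a < b:
                    w = G.get_edge_data(a, b, {"weight": 0})["weight"]
                    G.add_edge(a, b, weight=w + 1)
    # consecutive-note temporal adjacency
    for s1, s2 in zip(note_sets[:-1], note_sets[1:]):
        for a in s1:
            for b in s2:
                if a == b:
                    continue
                x, y = min(a, b), max(a, b)
                w = G.get_edge_data(x, y, {"weight": 0})["weight"]
                G.add_edge(x, y, weight=w + 1)
    return ConceptGraph(patient_id=record.patient_id, graph=G,
                        meta={"n_distinct": len(counts)})


# ---------------------------------------------------------------------------
# GraphSAGE-mean encoding


@dataclass
class GraphEncoderParams:
    """Weights of a K-layer GraphSAGE-mean encoder (AGG = mean, pool = mean)."""

    weights: list[np.ndarray]          # W^(k), shape (d_in_k, d_out_k)
    sample_size: int = 10
    activation: str = "relu"

    @property
    def n_layers(self):
        return len(self.weights)

    @property
    def d_in(self):
        return self.weights[0].shape[0]


def _stable_seed(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


DOMAINS = ("cognition", "function", "care", "mood", "general")


def node_features(cgraph: ConceptGraph, dim: int) -> np.ndarray:
    """Initial node states: [freq, section distribution, degree, domain
    one-hot], zero-padded to ``dim``."""
    nodes = cgraph.nodes
    n = len(nodes)
    if n == 0:
        return np.zeros((0, dim))
    deg = dict(cgraph.graph.degree(weight="weight"))
    max_deg = max(deg.values()) or 1 if deg else 1
    X = np.zeros((n, dim))
    for i, v in enumerate(nodes):
        data = cgraph.graph.nodes[v]
        onehot = np.zeros(len(DOMAINS))
        dom = data.get("domain", "general")
        if dom in DOMAINS:
            onehot[DOMAINS.index(dom)] = 1.0
        row = np.concatenate(([data["freq"]], data["section_dist"],
                              [deg.get(v, 0) / max_deg], onehot))
        X[i, :min(dim, len(row))] = row[:dim]
    return X


def neighbor_average_matrix(cgraph: ConceptGraph, sample_size: int = 10) -> np.ndarray:
    """Row-stochastic matrix M with M @ H = mean over {v} ∪ sampled N(v).

    Neighbor sampling (at most ``sample_size`` per node) is seeded by a
    stable hash of (patient_id, node id), so the matrix — and everything
    downstream — is reproducible and independent of insertion order.
    """
    nodes = cgraph.nodes
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for v in nodes:
        nbrs = sorted(cgraph.graph.neighbors(v))
        if len(nbrs) > sample_size:
            rng = np.random.default_rng(_stable_seed(cgraph.patient_id, v))
            nbrs = list(rng.choice(nbrs, size=sample_size, replace=False))
        members = [index[v]] + [index[u] for u in nbrs]
        for j in members:
            M[index[v], j] = 1.0 / len(members)
    return M


def graphsage_layer(
    h: np.ndarray,
    cgraph: ConceptGraph,
    params: GraphEncoderParams,
    k: int,
    M: np.ndarray | None = None,
) -> np.ndarray:
    """One message-passing step: h' = act(W_k · mean({h_v} ∪ {h_u: u∈N(v)}))."""
    W = params.weights[k]
    if h.shape[1] != W.shape[0]:
        raise ConceptError(
            f"layer {k}: state dim {h.shape[1]} != weight fan-in {W.shape[0]}"
        )
    if M is None:
        M = neighbor_average_matrix(cgraph, params.sample_size)
    z = (M @ h) @ W
    if params.activation == "relu":
        return np.maximum(z, 0.0)
    if params.activation == "identity":
        return z
    raise ConceptError(f"unknown activation {params.activation!r}")


def graph_pool(h: np.ndarray, dim: int | None = None) -> tuple[np.ndarray, bool]:
    """Mean pooling over node states; empty graph -> zero vector + flag."""
    if len(h) == 0:
        if dim is None:
            raise ConceptError("empty graph needs an explicit output dim")
        return np.zeros(dim), True
    return h.mean(axis=0), False


def graphsage_encode(
    cgraph: ConceptGraph, params: GraphEncoderParams
) -> tuple[np.ndarray, bool]:
    """Full K-layer encoding followed by mean pooling."""
    d_out = params.weights[-1].shape[1]
    if cgraph.n_nodes == 0:
        return np.zeros(d_out), True
    h = node_features(cgraph, params.d_in)
    M = neighbor_average_matrix(cgraph, params.sample_size)
    for k in range(params.n_layers):
        h = graphsage_layer(h, cgraph, params, k, M=M)
    return graph_pool(h)


def export_graph(cgraph: ConceptGraph, edges_path, nodes_path) -> None:
    """Edge list + node table as TSV."""
    rows = [{"concept_a": a, "concept_b": b, "weight": d["weight"]}
            for a, b, d in cgraph.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["concept_a", "concept_b", "weight"]).to_csv(
        edges_path, sep="\t", index=False)
    nrows = [{"concept_id": v, "count": d["count"], "freq": d["freq"]}
             for v, d in cgraph.graph.nodes(data=True)]
    pd.DataFrame(nrows, columns=["concept_id", "count", "freq"]).to_csv(
        nodes_path, sep="\t", index=False)
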