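"""Synthetic clinical corpora and knowledge graphs with planted structure.

Real coded discharge summaries and the medical knowledge graph behind
them are access-restricted, so every component here is exercised on
synthetic data that reproduces their *statistical* shape:

* long noisy notes — pseudo-word noise tokens with code-specific
  multi-token keyword phrases spliced in at random positions;
* one to several codes per record with Zipf-skewed code frequencies
  (most codes are rare, a few dominate);
* a five-class ontology in which each code attaches to a disease or
  surgery node, codes are grouped into related families that share
  symptom/medicine/examination neighbours (so second-order graph
  proximity carries signal), and related codes also share a keyword
  phrase in text.

Everything is reproducible: the same spec and seed give byte-identical
output.  A :class:`GroundTruth` sidecar records which phrases were
planted where, which is what localization tests score attention against.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .corpus import DEFAULT_STOPWORDS, RawRecord
from .graph import KnowledgeGraph

_SYLLABLES = (
    "ba be bi bo bu ca ce ci co cu da de di do du fa fe fi fo fu ga ge gi go gu "
    "ha he hi ho hu ja je ji jo ju ka ke ki ko ku la le li lo lu ma me mi mo mu "
    "na ne ni no nu pa pe pi po pu ra re ri ro ru sa se si so su ta te ti to tu "
    "va ve vi vo vu za ze zi zo zu"
).split()

#: Codes are grouped into families of this size; family members share one
#: keyword phrase and the same symptom/medicine/examination hub nodes.
GROUP_SIZE = 4


def _make_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Unique lowercase pseudo-words (3-4 syllables, never stop words)."""
    words: list[str] = []
    while len(words) < n:
        w = "".join(rng.choice(_SYLLABLES, size=rng.integers(3, 5)))
        if w not in taken and w not in DEFAULT_STOPWORDS:
            taken.add(w)
            words.append(w)
    return words


def _code_name(i: int) -> str:
    """Synthetic ICD-9-style code string for code index ``i``."""
    return f"{100 + i}.{i % 10}"


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic corpus.

    Defaults give a 500-record, 20-code corpus with notes of 100–300
    tokens, 1–8 codes per record and Zipf-1.0 code skew — a scaled-down
    analogue of a coded discharge-summary benchmark that still trains in
    minutes on one CPU.
    """

    n_records: int = 500
    n_codes: int = 20
    codes_per_record: tuple[int, int] = (1, 8)
    note_length: tuple[int, int] = (100, 300)
    keywords_per_code: int = 2
    noise_vocab_size: int = 500
    code_frequency_skew: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.n_codes < 1 or self.keywords_per_code < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.codes_per_record
        if not (1 <= lo <= hi <= self.n_codes):
            raise ValueError("codes_per_record range must satisfy 1 <= lo <= hi <= n_codes")
        nlo, nhi = self.note_length
        if not (1 <= nlo <= nhi):
            raise ValueError("note_length range must satisfy 1 <= lo <= hi")
        if self.noise_vocab_size < 0 or self.code_frequency_skew < 0:
            raise ValueError("noise_vocab_size and skew must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: keyword phrases per code and their positions.

    ``placements[record_id]`` lists ``(code, start, end)`` token spans
    (end exclusive) of every planted phrase in the final token sequence.
    """

    keywords: dict[str, list[list[str]]]
    placements: dict[str, list[tuple[str, int, int]]]
    code_frequencies: dict[str, int]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        placements = {
            rid: [(c, int(a), int(b)) for c, a, b in spans]
            for rid, spans in raw["placements"].items()
        }
        return cls(raw["keywords"], placements, {k: int(v) for k, v in raw["code_frequencies"].items()})

    def spans_for(self, record_id: str, code: str) -> list[tuple[int, int]]:
        return [(a, b) for c, a, b in self.placements.get(record_id, []) if c == code]


def generate_ontology(n_codes: int, aux_per_class: int = 10, seed: int = 0) -> KnowledgeGraph:
    """Build a connected five-class knowledge graph over ``n_codes`` codes.

    Codes attach to disease nodes (every fourth code to a surgery node).
    Code families of :data:`GROUP_SIZE` consecutive codes share a
    symptom, a medicine and an examination hub, and each code gets 1–2
    extra private auxiliary neighbours — so family members have similar
    neighbour sets while unrelated codes do not.
    """
    if n_codes < 2:
        raise ValueError("need at least 2 codes")
    if aux_per_class < 1:
        raise ValueError("aux_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    kg = KnowledgeGraph()

    aux_ids: dict[str, list[str]] = {}
    for cls_name, prefix in (("symptom", "S"), ("medicine", "M"), ("examination", "E")):
        ids = [f"{prefix}{j:03d}" for j in range(aux_per_class)]
        for nid in ids:
            kg.add_node(nid, cls_name, f"{cls_name}-{nid}")
        aux_ids[cls_name] = ids

    code_nodes: list[str] = []
    for i in range(n_codes):
        code = _code_name(i)
        ncls = "surgery" if i % 4 == 3 else "disease"
        nid = f"D{i:03d}" if ncls == "disease" else f"G{i:03d}"
        kg.add_node(nid, ncls, f"{ncls}-{code}", code=code)
        code_nodes.append(nid)

    def relation(code_cls: str, aux_cls: str) -> str:
        if aux_cls == "symptom":
            return "manifests_as" if code_cls == "disease" else "related"
        if aux_cls == "medicine":
            return "treats_med" if code_cls == "disease" else "related"
        return "examined_by"

    n_groups = (n_codes + GROUP_SIZE - 1) // GROUP_SIZE
    for i, nid in enumerate(code_nodes):
        grp = i // GROUP_SIZE
        ncls = kg.node_class(nid)
        # shared family hubs -> second-order proximity within the family
        for aux_cls in ("symptom", "medicine", "examination"):
            hub = aux_ids[aux_cls][grp % aux_per_class]
            kg.add_edge(nid, hub, relation(ncls, aux_cls))
        # private neighbours keep families from collapsing to one point
        for aux_cls in ("symptom", "medicine", "examination"):
            pool = aux_ids[aux_cls]
            extra = rng.choice(len(pool), size=min(2, len(pool)), replace=False)
            for j in extra:
                kg.add_edge(nid, pool[j], relation(ncls, aux_cls))
        # surgery treats a disease of the same family when one exists
        if ncls == "surgery":
            family = [code_nodes[j] for j in range(grp * GROUP_SIZE, min((grp + 1) * GROUP_SIZE, n_codes))]
            diseases = [m for m in family if kg.node_class(m) == "disease"]
            if diseases:
                kg.add_edge(nid, diseases[0], "treats_surg")

    # stitch components together deterministically if sparse aux pools split them
    import networkx as nx

    comps = sorted(nx.connected_components(kg.g), key=lambda c: sorted(c)[0])
    for comp in comps[1:]:
        kg.add_edge(sorted(comps[0])[0], sorted(comp)[0], "related")
    _ = n_groups
    return kg


def generate_corpus(
    spec: GeneratorSpec, ontology: KnowledgeGraph
) -> tuple[list[RawRecord], GroundTruth]:
    """Generate records with planted keyword evidence for their codes.

    Per record: draw the code count uniformly from ``codes_per_record``,
    draw that many distinct codes with Zipf-skewed probabilities, lay
    down uniform noise tokens, then splice in every keyword phrase of
    every assigned code (its private phrases plus its family's shared
    phrase) at random boundaries between noise tokens.  Phrase token
    spans in the final sequence are recorded in the ground truth.
    """
    codes = sorted(ontology.codes)[: spec.n_codes]
    if len(codes) < spec.n_codes:
        raise ValueError("ontology carries fewer codes than the spec requests")
    rng = np.random.default_rng(spec.seed)

    taken: set[str] = set()
    n_groups = (spec.n_codes + GROUP_SIZE - 1) // GROUP_SIZE
    keywords: dict[str, list[list[str]]] = {}
    for gi in range(n_groups):
        shared_len = int(rng.integers(2, 4))
        shared = _make_words(rng, shared_len, taken)
        for code in codes[gi * GROUP_SIZE : (gi + 1) * GROUP_SIZE]:
            phrases = [
                _make_words(rng, int(rng.integers(2, 4)), taken)
                for _ in range(spec.keywords_per_code)
            ]
            phrases.append(list(shared))
            keywords[code] = phrases
    noise_vocab = _make_words(rng, spec.noise_vocab_size, taken)

    ranks = np.arange(1, spec.n_codes + 1, dtype=np.float64)
    weights = ranks ** (-spec.code_frequency_skew)
    weights /= weights.sum()

    records: list[RawRecord] = []
    placements: dict[str, list[tuple[str, int, int]]] = {}
    freq: Counter[str] = Counter()
    lo, hi = spec.codes_per_record
    nlo, nhi = spec.note_length

    for ridx in range(spec.n_records):
        rid = f"R{ridx:05d}"
        n_assigned = int(rng.integers(lo, hi + 1))
        assigned = [codes[i] for i in rng.choice(spec.n_codes, size=n_assigned, replace=False, p=weights)]
        freq.update(assigned)

        n_noise = int(rng.integers(nlo, nhi + 1))
        noise = (
            [noise_vocab[i] for i in rng.integers(0, len(noise_vocab), size=n_noise)]
            if noise_vocab
            else []
        )

        phrases = [(code, phrase) for code in assigned for phrase in keywords[code]]
        # insertion points are boundaries between noise tokens, so phrases
        # never split each other; sort so spans can be computed in one pass
        cuts = sorted(rng.integers(0, len(noise) + 1, size=len(phrases)))
        order = rng.permutation(len(phrases))
        tokens: list[str] = []
        spans: list[tuple[str, int, int]] = []
        prev = 0
        for cut, oi in zip(cuts, order):
            tokens.extend(noise[prev:cut])
            code, phrase = phrases[oi]
            spans.append((code, len(tokens), len(tokens) + len(phrase)))
            tokens.extend(phrase)
            prev = cut
        tokens.extend(noise[prev:])

        records.append(RawRecord(rid, " ".join(tokens), frozenset(assigned)))
        placements[rid] = spans

    gt = GroundTruth(keywords, placements, {c: freq.get(c, 0) for c in codes})
    return records, gt
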