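"""Medical knowledge graph and SDNE structural node embeddings.

The graph has five node classes — disease, symptom, medicine, surgery,
examination — and typed edges (a disease *manifests as* symptoms, a
medicine or surgery *treats* it, an examination detects it).  Diagnosis
and procedure codes attach to disease/surgery nodes.

Node vectors come from SDNE (Structural Deep Network Embedding): an
autoencoder over adjacency rows whose objective combines

* first-order proximity  — connected nodes get nearby embeddings,
  ``L1 = sum_ij s_ij ||r_i - r_j||^2``;
* second-order proximity — nodes with similar neighbour sets get nearby
  embeddings, enforced by reconstructing each adjacency row,
  ``L2 = sum_ij w_ij (s_hat_ij - s_ij)^2`` with observed entries
  up-weighted by a penalty factor so the sparse reconstruction does not
  collapse to zero;
* an L2 penalty on the autoencoder weights.

Total objective: ``L = L1 + alpha * L2 + beta * Lreg``.

The embedding is structural only: relation labels and node classes do
not enter the objective, and the graph is embedded as undirected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .corpus import CodeSet

NODE_CLASSES = ("disease", "symptom", "medicine", "surgery", "examination")
RELATIONS = ("manifests_as", "treats_med", "treats_surg", "examined_by", "related")

#: Node classes that may carry a code string.
CODE_BEARING_CLASSES = ("disease", "surgery")


class KnowledgeGraph:
    """Typed undirected graph over the five-class medical ontology.

    Thin wrapper around :class:`networkx.Graph` that enforces the schema:
    every node has a class from :data:`NODE_CLASSES` and a display name;
    codes attach to disease/surgery nodes, at most one node per code.
    """

    def __init__(self) -> None:
        self.g = nx.Graph()
        self._code_to_node: dict[str, str] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, node_class: str, name: str, code: str | None = None) -> None:
        if node_class not in NODE_CLASSES:
            raise ValueError(f"unknown node class {node_class!r}")
        if code is not None:
            if node_class not in CODE_BEARING_CLASSES:
                raise ValueError(f"class {node_class!r} cannot carry a code")
            if code in self._code_to_node:
                raise ValueError(f"code {code!r} already attached to node {self._code_to_node[code]!r}")
            self._code_to_node[code] = node_id
        self.g.add_node(node_id, node_class=node_class, name=name, code=code)

    def add_edge(self, u: str, v: str, relation: str = "related") -> None:
        if relation not in RELATIONS:
            raise ValueError(f"unknown relation {relation!r}")
        if u not in self.g or v not in self.g:
            raise ValueError("edges must reference existing nodes")
        self.g.add_edge(u, v, relation=relation)

    # -- views ------------------------------------------------------------
    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self.g.nodes)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def code_to_node(self) -> dict[str, str]:
        return dict(self._code_to_node)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._code_to_node)

    def node_class(self, node_id: str) -> str:
        return self.g.nodes[node_id]["node_class"]

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.g)

    def adjacency(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Dense symmetric 0/1 adjacency with zero diagonal, in node order."""
        ids = self.node_ids
        s = nx.to_numpy_array(self.g, nodelist=ids, weight=None, dtype=np.float64)
        np.fill_diagonal(s, 0.0)
        return ids, s

    # -- plain-text serialization ----------------------------------------
    # node table: id <TAB> class <TAB> name <TAB> code-or-dash
    # edge list : src <TAB> dst <TAB> relation
    def save(self, node_path: str | Path, edge_path: str | Path) -> None:
        with open(node_path, "w") as fh:
            for nid in self.g.nodes:
                a = self.g.nodes[nid]
                fh.write(f"{nid}\t{a['node_class']}\t{a['name']}\t{a['code'] or '-'}\n")
        with open(edge_path, "w") as fh:
            for u, v, a in self.g.edges(data=True):
                fh.write(f"{u}\t{v}\t{a['relation']}\n")

    @classmethod
    def load(cls, node_path: str | Path, edge_path: str | Path) -> "KnowledgeGraph":
        kg = cls()
        with open(node_path) as fh:
            for line in fh:
                nid, ncls, name, code = line.rstrip("\n").split("\t")
                kg.add_node(nid, ncls, name, None if code == "-" else code)
        with open(edge_path) as fh:
            for line in fh:
                u, v, rel = line.rstrip("\n").split("\t")
                kg.add_edge(u, v, rel)
        return kg


# ---------------------------------------------------------------------------
# SDNE losses (exposed separately so they can be checked against brute force)
# ---------------------------------------------------------------------------

def first_order_loss(r: np.ndarray, s: np.ndarray, degree_weighted: bool = False) -> float:
    """First-order proximity loss ``sum_ij w_ij ||r_i - r_j||^2``.

    ``w = s`` by default, so each undirected edge is counted in both
    directions.  With ``degree_weighted=True`` each term is additionally
    scaled by the degree of node ``i``.
    """
    r = np.asarray(r, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if r.shape[0] != s.shape[0] or s.shape[0] != s.shape[1]:
        raise ValueError("embedding rows must match adjacency dimension")
    w = s * s.sum(axis=1, keepdims=True) if degree_weighted else s
    sq = np.sum(r * r, axis=1)
    # sum_ij w_ij (|r_i|^2 + |r_j|^2 - 2 r_i.r_j)
    return float(np.sum(w * (sq[:, None] + sq[None, :])) - 2.0 * np.sum(w * (r @ r.T)))


def _first_order_grad(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    # d/dr_k sum_ij w_ij||r_i-r_j||^2 = 2[(row_k+col_k) r_k - sum_j (w_kj+w_jk) r_j]
    rowsum = w.sum(axis=1)
    colsum = w.sum(axis=0)
    return 2.0 * ((rowsum + colsum)[:, None] * r - (w + w.T) @ r)


def second_order_loss(s_hat: np.ndarray, s: np.ndarray, penalty: float = 5.0) -> float:
    """Penalty-weighted adjacency reconstruction error.

    ``sum_ij w_ij (s_hat_ij - s_ij)^2`` with ``w_ij = penalty`` where an
    edge is observed and 1 elsewhere.  ``penalty=1`` is the plain squared
    Frobenius error.
    """
    s_hat = np.asarray(s_hat, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if s_hat.shape != s.shape:
        raise ValueError("reconstruction must match adjacency shape")
    if penalty < 1:
        raise ValueError("penalty must be >= 1")
    w = np.where(s != 0, penalty, 1.0)
    return float(np.sum(w * (s_hat - s) ** 2))


# ---------------------------------------------------------------------------
# SDNE training
# ---------------------------------------------------------------------------

@dataclass
class SdneConfig:
    """Hyperparameters for the SDNE autoencoder.

    ``alpha`` balances the two proximity terms.  The first-order term on
    a connected graph is purely contractive — left dominant it collapses
    all embeddings onto one direction — so the default weights the
    reconstruction (second-order) term heavily, matching the usual SDNE
    practice of treating first-order proximity as a mild regulariser.
    """

    dim: int = 128          # embedding dimension d_g
    alpha: float = 20.0     # weight of the second-order (reconstruction) term
    beta: float = 1e-4      # weight of the L2 penalty on autoencoder weights
    penalty: float = 5.0    # up-weight on observed adjacency entries
    epochs: int = 300
    lr: float = 0.001
    seed: int = 0
    degree_weighted_first_order: bool = False


@dataclass
class NodeEmbeddings:
    """Per-node SDNE vectors, row order matching ``node_ids``."""

    node_ids: tuple[str, ...]
    vectors: np.ndarray  # (n, d_g)
    config: SdneConfig
    loss_history: list[float] = field(default_factory=list)

    def row(self, node_id: str) -> np.ndarray:
        return self.vectors[self.node_ids.index(node_id)]

    def save(self, path: str | Path) -> None:
        n, d = self.vectors.shape
        with open(path, "w") as fh:
            fh.write(f"{n} {d}\n")
            for nid, vec in zip(self.node_ids, self.vectors):
                fh.write(nid + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path, config: SdneConfig | None = None) -> "NodeEmbeddings":
        with open(path) as fh:
            n, d = map(int, fh.readline().split())
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        vec = np.asarray(rows, dtype=np.float64)
        if vec.shape != (n, d):
            raise ValueError("embedding file shape does not match its header")
        return cls(tuple(ids), vec, config or SdneConfig(dim=d))


def train_sdne(kg: KnowledgeGraph, config: SdneConfig | None = None) -> NodeEmbeddings:
    """Fit the SDNE autoencoder and return per-node embeddings.

    Encoder: one dense tanh layer from the adjacency row to ``dim``;
    decoder: dense sigmoid layer back to the row.  Trained with Adam on
    ``L1 + alpha*L2 + beta*Lreg``.  Deterministic under ``config.seed``.
    """
    from .training import Adam  # local import: training builds on model/graph

    cfg = config or SdneConfig()
    if kg.n_nodes < 2:
        raise ValueError("SDNE needs a graph with at least 2 nodes")
    if not kg.is_connected():
        warnings.warn("graph is disconnected; embeddings computed per component", stacklevel=2)

    ids, s = kg.adjacency()
    n = s.shape[0]
    w_rec = np.where(s != 0, cfg.penalty, 1.0)
    w_first = s * s.sum(axis=1, keepdims=True) if cfg.degree_weighted_first_order else s

    rng = np.random.default_rng(cfg.seed)
    lim1 = np.sqrt(6.0 / (n + cfg.dim))
    params = {
        "W1": rng.uniform(-lim1, lim1, size=(n, cfg.dim)),
        "b1": np.zeros(cfg.dim),
        "W2": rng.uniform(-lim1, lim1, size=(cfg.dim, n)),
        "b2": np.zeros(n),
    }
    adam = Adam(lr=cfg.lr)
    history: list[float] = []

    for _ in range(cfg.epochs):
        # forward
        z = s @ params["W1"] + params["b1"]
        r = np.tanh(z)
        u = r @ params["W2"] + params["b2"]
        s_hat = 1.0 / (1.0 + np.exp(-u))

        diff = s_hat - s
        l2nd = float(np.sum(w_rec * diff * diff))
        l1st = first_order_loss(r, s, degree_weighted=cfg.degree_weighted_first_order)
        lreg = float(np.sum(params["W1"] ** 2) + np.sum(params["W2"] ** 2))
        history.append(l1st + cfg.alpha * l2nd + cfg.beta * lreg)

        # backward
        du = cfg.alpha * 2.0 * w_rec * diff * s_hat * (1.0 - s_hat)
        grads = {
            "W2": r.T @ du + 2.0 * cfg.beta * params["W2"],
            "b2": du.sum(axis=0),
        }
        dr = du @ params["W2"].T + _first_order_grad(r, w_first)
        dz = dr * (1.0 - r * r)
        grads["W1"] = s.T @ dz + 2.0 * cfg.beta * params["W1"]
        grads["b1"] = dz.sum(axis=0)
        adam.step(params, grads)

    r = np.tanh(s @ params["W1"] + params["b1"])
    return NodeEmbeddings(ids, r, cfg, loss_history=history)


# ---------------------------------------------------------------------------
# Code-aligned embedding matrix y_g
# ---------------------------------------------------------------------------

def extract_code_embeddings(
    emb: NodeEmbeddings,
    kg: KnowledgeGraph,
    codes: CodeSet | Sequence[str],
    missing: str = "error",
    seed: int | None = None,
) -> np.ndarray:
    """Return the ``l_g x d_g`` matrix of code-node embeddings in code order.

    A code without a graph node raises a KeyError naming it; with
    ``missing="random"`` (and a seed) the row falls back to a random
    vector instead, mirroring the no-knowledge-graph ablation.
    """
    code_list = list(codes.codes if isinstance(codes, CodeSet) else codes)
    d = emb.vectors.shape[1]
    out = np.empty((len(code_list), d), dtype=np.float64)
    index = {nid: i for i, nid in enumerate(emb.node_ids)}
    c2n = kg.code_to_node
    rng = np.random.default_rng(seed) if seed is not None else None
    for i, code in enumerate(code_list):
        node = c2n.get(code)
        if node is None or node not in index:
            if missing == "random":
                if rng is None:
                    raise ValueError("missing='random' requires a seed")
                out[i] = rng.standard_normal(d)
                continue
            raise KeyError(f"code {code!r} has no node in the knowledge graph")
        out[i] = emb.vectors[index[node]]
    return out


def random_code_embeddings(n_codes: int, dim: int, seed: int) -> np.ndarray:
    """Seeded random label vectors for the no-knowledge-graph ablation."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_codes, dim))
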