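"""Multi-label metrics and attention-based explanation extraction.

Metrics follow the micro convention: true/false positives and negatives
are pooled over every (record, code) cell before precision, recall, F1
and ROC-AUC are computed, and P@k is the mean fraction of each record's
k highest-scoring codes that are true.  A code counts as predicted when
its probability strictly exceeds the threshold (ties at the threshold
are negative); 0/0 ratios are defined as 0.

Explanations come from the attention maps: each pooled feature position
maps back to a source-token span, candidate fixed-width token windows
are scored by the maximum attention weight of any overlapping position,
and the top non-overlapping windows are returned per code.  Human
judgments of such segments (correct / incorrect) can be tabulated into
a weight-stratified accuracy table; on synthetic corpora the planted
keyword spans serve as an automatic judge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .corpus import EncodedRecord, Vocabulary
from .model import ModelConfig


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(scores: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> ConfusionCounts:
    """Pool confusion counts over all (record, code) cells; strict ``>``."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y))
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0,1)")
    pred = scores > threshold
    pos = y.astype(bool)
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    return ConfusionCounts(tp, fp, fn, tn)


def micro_prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Micro precision, recall and F1 from pooled counts (0/0 -> 0)."""
    prec = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def micro_auc(scores: np.ndarray, y: np.ndarray) -> float | None:
    """ROC AUC over all cells pooled into one ranking problem; ties count 1/2.

    Returns ``None`` when the pooled cells are all-positive or
    all-negative (the AUC is undefined there, not a number).
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    t = np.asarray(y).ravel().astype(int)
    if t.min() == t.max():
        return None
    return float(roc_auc_score(t, s))


def precision_at_k(scores: np.ndarray, y: np.ndarray, k: int = 5) -> float:
    """Mean fraction of each record's top-k scored codes that are true.

    Score ties are broken by code order (lower label index wins), so the
    result is deterministic.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y))
    if k < 1 or k > scores.shape[1]:
        raise ValueError("k must be in [1, number of codes]")
    top = np.argsort(-scores, axis=1, kind="stable")[:, :k]
    hits = np.take_along_axis(y, top, axis=1).sum(axis=1)
    return float(np.mean(hits / k))


# ---------------------------------------------------------------------------
# attention explanations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExplanationSegment:
    """A fixed-width token window supporting one predicted code."""

    record_id: str
    code: str
    start: int  # token span [start, end) in the encoded note
    end: int
    text: str
    weight: float

    @property
    def segment_id(self) -> str:
        return f"{self.record_id}:{self.code}:{self.start}"


@dataclass(frozen=True)
class JudgedSegment:
    segment: ExplanationSegment
    judgment: str  # "correct" | "incorrect"

    def __post_init__(self) -> None:
        if self.judgment not in ("correct", "incorrect"):
            raise ValueError("judgment must be 'correct' or 'incorrect'")


def extract_segments(
    A: np.ndarray,
    record: EncodedRecord,
    model_cfg: ModelConfig,
    codes: Sequence[str],
    vocab: Vocabulary | None = None,
    width: int = 5,
    top_n: int = 1,
) -> list[ExplanationSegment]:
    """Top attention windows per code for one record.

    ``A`` is the ``(l_g, n')`` attention map from a forward pass on this
    record and ``codes`` names the code of every row to explain (usually
    the predicted ones).  A window's weight is the maximum attention
    weight of any pooled position overlapping it (that is also the
    weight reported on the segment); because every window touching the
    peak position shares that maximum, ties are resolved toward the
    window whose tokens carry the most attention overall (sum of
    per-token weights), then by start position.  ``top_n``
    non-overlapping windows are chosen greedily by descending weight.
    A note shorter than ``width`` yields its single full-note window.
    """
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    n_tok = max(1, record.n_tokens)
    if vocab is not None:
        inv = {i: t for t, i in vocab.token_to_index.items()}
        toks = [inv.get(int(i), "?") for i in record.token_indices[:n_tok]]
    else:
        toks = [str(int(i)) for i in record.token_indices[:n_tok]]

    win = min(width, n_tok)
    starts = range(0, n_tok - win + 1)
    spans = [model_cfg.position_span(t) for t in range(A.shape[1])]

    out: list[ExplanationSegment] = []
    for row, code in enumerate(codes):
        weights = A[row]
        # per-token weight: max over pooled positions covering the token
        tok_w = np.zeros(n_tok)
        for t, (ps, pe) in enumerate(spans):
            if ps >= n_tok:
                break
            seg = tok_w[ps : min(pe, n_tok)]
            np.maximum(seg, weights[t], out=seg)
        scored = []
        for s in starts:
            e = s + win
            scored.append((tok_w[s:e].max(), float(tok_w[s:e].sum()), s))
        scored.sort(key=lambda ws: (-ws[0], -ws[1], ws[2]))
        chosen: list[tuple[float, int]] = []
        for w, _, s in scored:
            if len(chosen) >= top_n:
                break
            if all(s + win <= cs or s >= cs + win for _, cs in chosen):
                chosen.append((w, s))
        for w, s in chosen:
            out.append(
                ExplanationSegment(record.record_id, code, s, s + win, " ".join(toks[s : s + win]), float(w))
            )
    return out


def interpretability_table(
    judged: Iterable[JudgedSegment], weight_cut: float = 0.8
) -> dict[str, dict]:
    """Weight-stratified judgment accuracy.

    Segments split into a high stratum (weight >= ``weight_cut``) and a
    low stratum; each reports total, correct and accuracy rounded to 3
    decimals (``None`` for an empty stratum).
    """
    strata = {"high": [0, 0], "low": [0, 0]}  # [total, correct]
    for js in judged:
        key = "high" if js.segment.weight >= weight_cut else "low"
        strata[key][0] += 1
        strata[key][1] += js.judgment == "correct"
    return {
        key: {
            "total": tot,
            "correct": cor,
            "accuracy": round(cor / tot, 3) if tot else None,
        }
        for key, (tot, cor) in strata.items()
    }


def auto_judge(
    segments: Iterable[ExplanationSegment], ground_truth, record_ids_to_codes=None
) -> list[JudgedSegment]:
    """Judge segments against planted keyword spans (synthetic corpora only).

    A segment is correct when its window overlaps any planted span of
    its code in its record.
    """
    out = []
    for seg in segments:
        spans = ground_truth.spans_for(seg.record_id, seg.code)
        hit = any(a < seg.end and b > seg.start for a, b in spans)
        out.append(JudgedSegment(seg, "correct" if hit else "incorrect"))
    return out


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_metrics_report(metrics: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in metrics.items():
            fh.write(f"{key}: {val}\n")


def write_segments(segments: Iterable[ExplanationSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.segment_id}\t{seg.code}\t{seg.text}\t{seg.weight:.4f}\n")


def read_judgments(
    segments: Sequence[ExplanationSegment], path: str | Path
) -> list[JudgedSegment]:
    """Attach human judgments (``segment_id<TAB>correct|incorrect``) to segments."""
    by_id = {seg.segment_id: seg for seg in segments}
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            seg_id, verdict = line.split("\t")
            if seg_id not in by_id:
                raise KeyError(f"judgment references unknown segment {seg_id!r}")
            out.append(JudgedSegment(by_id[seg_id], verdict))
    return out
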