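"""Micro metrics against counting oracles; explanation extraction contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import medcoder as mc
from medcoder.corpus import EncodedRecord
from medcoder.evaluation import (
    ConfusionCounts,
    ExplanationSegment,
    JudgedSegment,
    confusion,
    extract_segments,
    interpretability_table,
    micro_auc,
    micro_prf,
    precision_at_k,
    read_judgments,
    write_segments,
)
from medcoder.model import ModelConfig


class TestConfusion:
    def test_exact_predictions_no_errors(self):
        y = np.array([[1, 0], [0, 1]], dtype=float)
        c = confusion(y, y)
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (2, 2)

    def test_threshold_ties_are_negative(self):
        scores = np.full((2, 3), 0.5)
        y = np.ones((2, 3))
        c = confusion(scores, y, threshold=0.5)
        assert c.tp == 0 and c.fn == 6

    def test_matches_cell_by_cell_loop(self):
        rng = np.random.default_rng(0)
        scores = rng.random((4, 3))
        y = (rng.random((4, 3)) < 0.5).astype(int)
        c = confusion(scores, y, 0.5)
        tp = fp = fn = tn = 0
        for i in range(4):
            for j in range(3):
                pred = scores[i, j] > 0.5
                if pred and y[i, j]:
                    tp += 1
                elif pred:
                    fp += 1
                elif y[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        assert c.total == 12


class TestMicroPrf:
    def test_hand_arithmetic_example(self):
        p, r, f1 = micro_prf(ConfusionCounts(tp=10, fp=6, fn=4, tn=0))
        assert p == pytest.approx(0.625)
        assert r == pytest.approx(10 / 14)
        assert f1 == pytest.approx(2 * p * r / (p + r))
        assert f1 == pytest.approx(2 / 3, abs=1e-3)

    def test_perfect_counts(self):
        assert micro_prf(ConfusionCounts(5, 0, 0, 3)) == (1.0, 1.0, 1.0)

    def test_all_zero_convention(self):
        assert micro_prf(ConfusionCounts(0, 0, 0, 10)) == (0.0, 0.0, 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_pooled_reference_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, l = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        scores = rng.random((n, l))
        y = (rng.random((n, l)) < 0.5).astype(int)
        p, r, f1 = micro_prf(confusion(scores, y))
        from sklearn.metrics import precision_score, recall_score

        pred = (scores > 0.5).astype(int)
        assert p == pytest.approx(precision_score(y.ravel(), pred.ravel(), zero_division=0))
        assert r == pytest.approx(recall_score(y.ravel(), pred.ravel(), zero_division=0))
        assert 0.0 <= f1 <= 1.0


class TestMicroAuc:
    def test_perfect_separation_is_one(self):
        scores = np.array([[0.9, 0.8], [0.7, 0.1]])
        y = np.array([[1, 1], [1, 0]])
        assert micro_auc(scores, y) == 1.0

    def test_constant_scores_give_half(self):
        scores = np.full((2, 3), 0.4)
        y = np.array([[1, 0, 1], [0, 0, 1]])
        assert micro_auc(scores, y) == pytest.approx(0.5)

    def test_degenerate_pool_is_undefined(self):
        assert micro_auc(np.array([[0.2, 0.9]]), np.array([[1, 1]])) is None
        assert micro_auc(np.array([[0.2, 0.9]]), np.array([[0, 0]])) is None

    def test_matches_mann_whitney_pair_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            scores = rng.random((2, 3))
            y = (rng.random((2, 3)) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            s, t = scores.ravel(), y.ravel()
            pos, neg = s[t == 1], s[t == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert micro_auc(scores, y) == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random((5, 4))
        y = (rng.random((5, 4)) < 0.4).astype(int)
        if y.min() == y.max():
            y[0, 0] = 1 - y[0, 0]
        a = micro_auc(scores, y)
        b = micro_auc(1 / (1 + np.exp(-7 * scores)), y)
        assert a == pytest.approx(b, abs=1e-12)


class TestPrecisionAtK:
    def test_all_true_in_top_k(self):
        scores = np.array([[0.9, 0.8, 0.7, 0.1]])
        y = np.array([[1, 1, 1, 0]])
        assert precision_at_k(scores, y, 3) == 1.0

    def test_no_true_codes_is_zero(self):
        scores = np.array([[0.9, 0.8]])
        assert precision_at_k(scores, np.zeros((1, 2)), 2) == 0.0

    def test_tie_break_by_code_order(self):
        scores = np.array([[0.5, 0.5, 0.5]])
        y = np.array([[1, 0, 0]])
        assert precision_at_k(scores, y, 1) == 1.0  # first code wins the tie

    def test_k_p_at_k_equals_mean_hits_and_is_nondecreasing(self):
        rng = np.random.default_rng(3)
        scores = rng.random((6, 8))
        y = (rng.random((6, 8)) < 0.4).astype(int)
        expected = []
        for k in range(1, 9):
            pk = precision_at_k(scores, y, k)
            top = np.argsort(-scores, axis=1, kind="stable")[:, :k]
            hits = np.take_along_axis(y, top, axis=1).sum(axis=1).mean()
            assert k * pk == pytest.approx(hits, abs=1e-9)
            expected.append(k * pk)
        assert all(a <= b + 1e-9 for a, b in zip(expected, expected[1:]))


def _record(n_tok, max_len=40):
    idx = np.zeros(max_len, dtype=np.int32)
    idx[:n_tok] = np.arange(2, 2 + n_tok)
    return EncodedRecord("r0", idx, np.array([1], dtype=np.int8), n_tokens=n_tok)


_CFG = ModelConfig(vocab_size=64, n_labels=1, d=4, d_g=2, d_f=2,
                   kernel_sizes=(4, 5, 6), pool=2, max_len=40)


class TestExtractSegments:
    def test_concentrated_attention_returns_covering_window(self):
        n_pos = _CFG.n_positions(40)
        A = np.full((1, n_pos), 1e-6)
        A[0, 10] = 0.9  # covers tokens [20, 27)
        segs = extract_segments(A, _record(40), _CFG, ["584.9"], width=5, top_n=1)
        (seg,) = segs
        ps, pe = _CFG.position_span(10)
        assert seg.start < pe and seg.end > ps
        assert seg.weight == pytest.approx(0.9)

    def test_uniform_attention_first_window_by_tie_break(self):
        n_pos = _CFG.n_positions(40)
        A = np.full((1, n_pos), 1.0 / n_pos)
        (seg,) = extract_segments(A, _record(40), _CFG, ["584.9"], width=5, top_n=1)
        assert seg.start == 0

    def test_short_note_yields_single_full_window(self):
        A = np.ones((1, _CFG.n_positions(40)))
        (seg,) = extract_segments(A, _record(3), _CFG, ["584.9"], width=5, top_n=2)
        assert (seg.start, seg.end) == (0, 3)

    def test_windows_non_overlapping_weights_non_increasing(self):
        rng = np.random.default_rng(4)
        A = rng.random((1, _CFG.n_positions(40)))
        A /= A.sum()
        segs = extract_segments(A, _record(40), _CFG, ["584.9"], width=5, top_n=3)
        assert len(segs) == 3
        for a, b in zip(segs, segs[1:]):
            assert a.weight >= b.weight
        spans = sorted((s.start, s.end) for s in segs)
        assert all(x[1] <= y[0] for x, y in zip(spans, spans[1:]))


class TestInterpretabilityTable:
    def test_stratified_accuracies_from_counts(self):
        segs = []
        for i in range(16):
            segs.append(JudgedSegment(
                ExplanationSegment("r", "c", 0, 5, "t", 0.9), "correct" if i < 10 else "incorrect"))
        for i in range(84):
            segs.append(JudgedSegment(
                ExplanationSegment("r", "c", 0, 5, "t", 0.3), "correct" if i < 60 else "incorrect"))
        table = interpretability_table(segs, weight_cut=0.8)
        assert table["high"] == {"total": 16, "correct": 10, "accuracy": 0.625}
        assert table["low"] == {"total": 84, "correct": 60, "accuracy": 0.714}

    def test_all_correct_both_strata(self):
        segs = [JudgedSegment(ExplanationSegment("r", "c", 0, 5, "t", w), "correct")
                for w in (0.9, 0.1)]
        table = interpretability_table(segs)
        assert table["high"]["accuracy"] == 1.0
        assert table["low"]["accuracy"] == 1.0

    def test_empty_stratum_undefined(self):
        segs = [JudgedSegment(ExplanationSegment("r", "c", 0, 5, "t", 0.2), "correct")]
        assert interpretability_table(segs)["high"]["accuracy"] is None

    def test_invalid_judgment_rejected(self):
        with pytest.raises(ValueError):
            JudgedSegment(ExplanationSegment("r", "c", 0, 5, "t", 0.2), "maybe")


def test_segments_and_judgments_roundtrip(tmp_path):
    segs = [
        ExplanationSegment("r1", "584.9", 3, 8, "a b c d e", 0.91),
        ExplanationSegment("r2", "428.0", 0, 5, "f g h i j", 0.42),
    ]
    write_segments(segs, tmp_path / "segs.tsv")
    assert len((tmp_path / "segs.tsv").read_text().splitlines()) == 2
    (tmp_path / "judge.tsv").write_text(
        f"{segs[0].segment_id}\tcorrect\n{segs[1].segment_id}\tincorrect\n"
    )
    judged = read_judgments(segs, tmp_path / "judge.tsv")
    assert [j.judgment for j in judged] == ["correct", "incorrect"]


def test_auto_judge_scores_overlap_against_ground_truth(small_world):
    gt = small_world["gt"]
    rec = small_world["records"][0]
    code, a, b = gt.placements[rec.record_id][0]
    good = ExplanationSegment(rec.record_id, code, max(0, a - 1), a + 2, "x", 0.5)
    bad = ExplanationSegment(rec.record_id, code, b + 5, b + 10, "x", 0.5)
    judged = mc.auto_judge([good, bad], gt)
    assert [j.judgment for j in judged] == ["correct", "incorrect"]
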