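# Methods

This note documents the models implemented in `medcoder`, the design
decisions behind them, the synthetic study conditions, and what the
package's tests do and do not establish.

## Text preprocessing

Notes are cleaned by removing de-identification placeholders
(`[** ... **]` spans are dropped wholesale), lowercasing, keeping
alphanumeric token runs, and removing stop words (a small bundled
English list by default; injectable). The vocabulary keeps tokens with
training-corpus frequency ≥ `min_count` (default 3); rarer tokens
encode as UNK. We read the frequency interpretation of "rare words"
as the natural partner of UNK replacement; an optional flag
additionally drops tokens shorter than a character threshold. Notes
are truncated to the *first* `max_len` tokens (clinical notes
front-load diagnoses and history) and right-padded with PAD = 0.
PAD embeddings are pinned to zero and participate in convolution; no
masking is applied by default.

The label space is the `k` most frequent codes (descending frequency,
lexicographic tie-break, order frozen thereafter); records retaining no
selected code are discarded, and that rejection is a distinct signal
(`NoRetainedCodesError`) from malformed input.

## Classifier

See the README for the architecture. Non-obvious choices:

* **Pooling preserves positions.** Global max-pooling would destroy
  the position axis that label-wise attention and explanation
  extraction need, so max-pooling uses window = stride = `p` (default
  2) along positions, with the last partial window kept. Pooled maps
  from kernels 4/5/6 have slightly different lengths; shorter maps are
  right-zero-padded before channel concatenation so position `t` means
  the same token span in every channel block: tokens
  `[t·p, t·p + k_max + p − 1)`.
* **Label representation.** `D = W_g·y_gᵀ + b` with a learnable bias;
  a `use_label_bias=False` flag drops the bias. `y_g` is a fixed input
  produced by the graph embedder, not fine-tuned.
* **Output layer** is a per-label inner product
  `⟨v_i, W_o[i]⟩ + b_i` — one weight vector per code — so the model
  emits exactly `l_g` independent probabilities.
* **Activation** is ReLU by default (`tanh` and `linear` exist, the
  latter mainly for identity-style tests).
* **Dropout** (default 0.4) acts on `H'` during training only,
  inverted scaling.
* Decision threshold is strictly greater than 0.5; a probability of
  exactly 0.5 is a negative.

All parameters, gradients and the optimizer are NumPy. The backward
pass returns, besides parameter gradients, `∇_X L` for the embedded
input, which FGM consumes. Gradient correctness is enforced by a test
comparing analytic and central-difference gradients for every
parameter of a toy model (relative error < 1e-4).

## Training

Summed-over-labels binary cross-entropy, averaged over the batch, plus
`λ·Σ‖W‖²` over weight matrices (embedding, convolution, `W_g`, `W_o`;
biases excluded). Probabilities are clamped to `[1e-7, 1−1e-7]` inside
the loss. Optimizer is Adam. A NaN/∞ loss aborts with a diagnostic.

FGM (per batch): (1) clean forward/backward; (2)
`r_adv = ε·g/‖g‖₂` with `g = ∇_X L` and the Frobenius norm over the
whole batch gradient (a per-example-norm variant sits behind
`per_example_norm`); (3) forward/backward at `X + r_adv`; (4) the
embedding table itself is never written, so restoration is structural;
(5) one Adam update with the *sum* of clean and adversarial gradients.
`ε` has no canonical value; the default is 1.0 and the CLI logs it
prominently. With `ε = 0` the step degenerates to a double-weighted
clean step, which is tested exactly.

Early stopping monitors validation micro-F1 with patience 5 by
default; the best-validation checkpoint is returned. Training is
deterministic under the config seed.

Default hyperparameters are the reference settings: `d = 100`,
`d_g = 128`, `d_f = 50`, kernels `{4,5,6}`, `lr = 0.001`,
`dropout = 0.4`, `λ = 1e-5`, `max_len = 1800`, batch 16.

## Graph embedding (SDNE)

Encoder: one dense tanh layer from the (dense, symmetric, 0/1)
adjacency row to `d_g`; decoder: dense sigmoid layer back to the row.
Objective `L = L_1st + α·L_2nd + β·L_reg` with

* `L_1st = Σ_ij s_ij‖r_i − r_j‖²` (each undirected edge counted both
  directions; a degree-weighted variant sits behind a flag),
* `L_2nd = Σ_ij w_ij(ŝ_ij − s_ij)²`, `w_ij = penalty` (default 5) on
  observed entries and 1 elsewhere — without the penalty the sparse
  reconstruction collapses to zero; penalty = 1 recovers the plain
  Frobenius error,
* `L_reg` = squared weights of encoder and decoder.

**Choice of α.** On a connected graph the first-order term is purely
contractive: left dominant it drives all embeddings onto a single
direction (we measured all-pairs cosine ≈ 0.94 with α = 1, destroying
the family structure the downstream attention needs). The default
α = 20 makes reconstruction dominant, the usual SDNE balance in which
first-order proximity acts as a mild regulariser; with it, code
families separate (two-clique separation holds in 10/10 seeded runs)
while connected nodes still embed nearby. β defaults to 1e-4,
epochs to 300, Adam lr 0.001. Longer training slowly re-contracts the
space, so the epoch budget is part of the recipe, not a convergence
target. Relation labels and node classes do not enter the objective;
the graph is embedded undirected.

`extract_code_embeddings` returns the `l_g×d_g` matrix in code order
and fails loudly on a code without a node; `missing="random"` (seeded)
substitutes random rows, and `random_code_embeddings` generates the
fully random matrix used by the no-knowledge-graph ablation.

## Synthetic study conditions

The generator emulates the statistical shape of coded discharge
summaries: long noisy notes, 1–8 codes per record, Zipf-skewed code
frequencies (exponent 1.0), and code-specific textual evidence. Each
code carries two private keyword phrases of 2–3 pseudo-word tokens
plus one phrase shared with its code family (families of 4 consecutive
codes); families also share symptom/medicine/examination hub nodes in
the generated ontology, so keyword sharing and graph proximity are
aligned. Multi-token phrases give the kernel-4..6 convolutions
super-token signal. Noise tokens are drawn uniformly from a disjoint
pseudo-word vocabulary; there is no semantic noise model. Everything
is byte-reproducible under the spec seed, and a ground-truth sidecar
records every planted span, which the localization checks score
against.

Default corpus: 500 records, 20 codes, notes of 100–300 tokens. The
recovery runs use a reduced model (`d = 50`, `d_f = 25`, `d_g = 32`,
`max_len = 300`, dropout 0.2) and Adam lr 5e-3 for 15 epochs — at 25
minibatches per epoch the reference lr of 1e-3 converges much more
slowly, and the reduced dimensions keep a full pipeline run at a few
minutes on one CPU. The 10-seed ablation sweep uses 160 records / 10
codes / notes of 60–150 tokens with a correspondingly smaller model.

**What passing on this fixture shows — and does not.** Passing shows
the implementation can recover planted multi-label structure end to
end, that attention localizes real evidence, and that every equation
matches its brute-force oracle. It does not show clinical-grade
performance: real notes have correlated vocabulary, section structure,
synonymy and label noise that the generator deliberately omits.

A documented negative result: replacing the SDNE code embeddings with
seeded random vectors ("no-knowledge-graph" ablation) is *not*
consistently worse on this fixture. Because `W_g` is trainable, any
set of distinct fixed label vectors spans the same representable label
space; the graph's contribution is an inductive bias whose value
appears only when codes are data-poor. In our sweeps the direction
turns favourable in data-starved regimes but stays within seed noise
(winning 4–6 of 10 seeds), consistent with the small effect sizes
reported for knowledge-graph ablations on real corpora. The
acceptance suite therefore contains a directional ablation test that
currently fails, kept as an honest record rather than weakened.

## Explanations

Pooled position `t` maps to tokens `[t·p, t·p + k_max + p − 1)`. For
each code, candidate `width`-token windows (default 5) are scored by
the maximum attention weight of any overlapping position — the weight
reported on the segment. Every window touching the peak position
shares that maximum, so ties resolve toward the window whose tokens
carry the most attention in total (sum of per-token weights), then by
start position; `top_n` non-overlapping windows are chosen greedily.
Notes shorter than the width yield one full-note window. Human
judgments (`correct`/`incorrect` per segment) are read from a file and
never fabricated; on synthetic corpora, overlap with planted spans
(`auto_judge`) substitutes as an automatic judge. The
weight-stratified table splits segments at weight ≥ 0.8 (configurable)
and reports total/correct/accuracy (3 decimals) per stratum, with an
empty stratum's accuracy undefined (`None`).

## Metrics

Micro conventions throughout: confusion counts pooled over all
(record, code) cells; precision/recall/F1 from the pooled counts with
0/0 defined as 0; ROC-AUC on the pooled cells (ties count ½,
undefined — `None` — when the pool is single-class); P@k is the mean
fraction of the k top-scored codes that are true, with score ties
broken by code order. `k·P@k` is the expected number of correct codes
among the top k and is non-decreasing in k, which the tests assert.

## Known limitations

* The NumPy implementation is single-threaded BLAS-bound; it is sized
  for the synthetic corpora, not 40k-document corpora.
* No pretrained word vectors, by design; no section extraction beyond
  an optional header whitelist; no macro-averaged metrics.
* SDNE depth is fixed at one hidden layer; alternative graph embedders
  are out of scope except the random-vector ablation.
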