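# Methods

`tcmspred` predicts whether a Traditional Chinese Medicine herb is
indicated for a clinical symptom, by fusing three views of a (herb,
symptom) pair: semantic co-occurrence of the two tokens in a text corpus,
network proximity between the herb's protein targets and the symptom's
associated genes on a protein-protein interaction (PPI) graph, and the
identity of the gene sets themselves.  This note records the model, its
assumptions, the defaults, the synthetic benchmark, and the numerical
choices that were genuinely open.

## Semantic embeddings (skip-gram with negative sampling)

Herb and symptom identifiers are treated as tokens of a corpus (one
sentence per line).  For each (center w, context c) pair within a window
of width `w = 5`, the trainer ascends

    L = log σ(u_c · v_w) + Σ_{j=1..k} log σ(−u_{n_j} · v_w),

with `k = 5` negatives drawn from the unigram distribution raised to
0.75.  Sampled negatives that coincide with the context or center token
are skipped for that update, as in the reference word2vec implementation;
with vocabularies of ~100 tokens this is not an optimization but a
correctness issue, since a token would otherwise frequently be its own
negative.  Defaults: dimension 128, 5 epochs, learning rate 0.025
decaying linearly to 1e-4, `min_count = 1`.

Two deliberate simplifications, both documented behaviors rather than
knobs: the context window is fixed (word2vec's random window shrinking is
omitted) and training is strictly sequential single-worker.  Together
they make training bit-reproducible under a seed, which the pipeline's
determinism contract requires.  Downstream, association geometry is read
off the *input* vectors (`v_w`); out-of-vocabulary tokens receive the
zero vector with a logged warning rather than failing.

## Network proximity

For a herb target set T and symptom gene set G on the PPI graph, the
proximity is the asymmetric closest distance of network medicine:

    d(T, G) = (1/|T|) Σ_{t∈T} min_{g∈G} sp(t, g),

with `sp` the unit-weight shortest-path hop count.  Targets that cannot
reach any member of G contribute a sentinel of (diameter of the largest
connected component) + 1 — finite, and scaled to the graph rather than an
arbitrary constant.  Genes referenced by herbs or symptoms but absent
from the PPI edge list are retained as isolated nodes so set sizes (and
hence the overlap statistics) are preserved.

The raw distance is standardized into `z = (d_obs − μ_null) / σ_null`
against a degree-preserving null: `n_perm = 100` random set pairs matched
to |T|, |G| and each set's log2-degree-bin profile (bins with fewer than
5 nodes are merged upward so small graphs still sample stably).  When the
null is degenerate (σ = 0) the z-score is reported as 0 with a flag
rather than an infinity.  Null moments are cached per degree-profile
signature; with ~10-gene target sets the 60 × 40 pair grid reuses a few
dozen signatures, which is what makes full-grid featurization take
seconds rather than minutes.

Scalar overlap features complete the proximity block: Jaccard
|T∩G|/|T∪G| and overlap coefficient |T∩G|/min(|T|,|G|).

## Fusion network

Four blocks, mirroring the predictor's architecture:

1. **Main feature processor** — an MLP (default one hidden layer of 128,
   ReLU, dropout 0.1) over the concatenation of the two semantic vectors
   and the four proximity scalars (d_obs, z, Jaccard, overlap), the
   scalars standardized to zero mean / unit variance on the training
   pairs (the moments are stored with the model).
2. **Bidirectional LSTM target encoders** — each entity's gene set is
   rendered as a token sequence (lexicographic order, since sets carry no
   order but recurrent encoders need one; padded/truncated to L,
   default 64), embedded by a learned gene-embedding table (d_g = 32,
   trained end-to-end) and encoded by a standard-gate BiLSTM (64 units
   per direction; forget-gate bias initialized to 1).
3. **Cross-modal attention** — scaled dot-product attention
   `A = softmax(Q K^T / √d_a)` with Q from one entity's encoder states
   and K = V from the other's, applied in both directions (herb targets
   attending over symptom genes, and vice versa).  Masked key positions
   receive exactly zero weight; each direction's context is mean-pooled
   over valid query positions.
4. **Classifier** — an MLP (default hidden 64) over the processor output
   concatenated with both pooled attention contexts, ending in a sigmoid;
   the output is the association probability.

Training minimizes mean binary cross-entropy with Adam (lr 1e-3, batch
32), early-stopping on the AUC of an internal stratified 10% validation
split with patience 5 and restoring the best epoch's parameters.  All
randomness (initialization, shuffling, dropout, splits) flows from the
single config seed; prediction runs with dropout off and is
deterministic.  The whole network is float64 and differentiated by the
package's own reverse-mode autodiff core (`tcmspred.autograd`), which
keeps the analytic gradients directly checkable against central finite
differences.

Ablations are first-class: `ModelConfig.modalities` selects any subset of
{semantic, proximity, sequence}; the proximity-only configuration is the
standing baseline.

## Evaluation

Stratified k-fold cross-validation (default k = 10) assigns each class
round-robin to folds after a seeded shuffle, carrying the round-robin
position across class strata; per-stratum fold sizes differ by at most
one, and classes smaller than k are spread rather than rejected (only
k > n fails).  AUC is the Mann-Whitney rank statistic — the probability
a random positive outscores a random negative, ties counted half.
Confusion matrices threshold at τ = 0.5 (configurable; no threshold is
canonical for this task) and report per-class accuracy, optionally
decomposed by a category label.

Feature computation is **transductive**: embeddings and proximity are
computed once on the full knowledge base and only association labels are
held out.  This matches the link-prediction framing (the graph and
corpus are fixed background knowledge), but it does mean CV does not
measure generalization to unseen herbs, symptoms, or graphs.

## Prioritization

A disease is a symptom set (e.g., 30 curated renal-fibrosis symptoms).
An herb's total score is the **sum** of predicted probabilities over the
set — bounded by [0, |S|], so a score near 14 over 30 symptoms
corresponds to mean pair probability ≈ 0.46.  Per symptom, herbs are
ranked by descending probability with lexicographic tie-breaks; rank 1 is
the "preferred" and rank 2 the "secondary" candidate for that symptom.
Both the summation convention and the rank-1/rank-2 reading are recorded
interpretations, chosen because they are the only ones consistent with
sub-unit pair probabilities aggregating to double-digit disease scores.

## Synthetic benchmark

The generator emulates a SymMap-style knowledge base with planted,
mutually consistent structure.  Genes are partitioned evenly into
modules; the PPI graph is a stochastic block model (within-module edge
probability p_in, between p_out, p_in > p_out).  Each herb and symptom
has a home module and draws its gene set from it with probability 0.9
(else uniformly), with Poisson-dispersed set sizes.  A pair is truly
associated iff the cosine of the two module-occupancy profiles is at
least θ; observed labels flip independently with probability ε.  The
corpus seeds each sentence with a truly associated pair and fills
remaining slots half with same-module tokens, half uniformly; a coverage
pass guarantees every token occurs.

Default profile: 60 herbs, 40 symptoms, 300 genes, 6 modules,
p_in = 0.15, p_out = 0.01, ~10 targets/herb, ~15 genes/symptom, θ = 0.8,
ε = 0.05, 5000 sentences of length 8, seed 7.  Under this profile about
a fifth of pairs are positive, and the 5% label noise caps the observed
AUC of even a perfect scorer near 0.90 — recovery results should be read
against that ceiling, not against 1.0.

What the generator does *not* emulate: real interactome topology beyond
modularity (no hubs/scale-free tails), herb polypharmacology across many
modules, curation biases, or natural-language corpora.  Passing the
recovery study therefore demonstrates that the pipeline extracts a
planted multimodal signal end-to-end; it says nothing about accuracy on
real SymMap-derived data, whose curated inputs are not distributed.

## Problem sizes for the recovery study

The recovery study (tests and `scripts/acceptance.py`) runs 5-fold CV on
the default profile with a reduced network — gene embedding 16, LSTM
hidden 24 per direction, processor (64,), classifier (32,), sequence
length 16, batch 64, at most 15 epochs with patience 3.  The synthetic
KB has ~100 tokens and ~10–15-gene sets, so the reduced capacity loses
nothing measurable while keeping a full CV sweep in the low minutes on
one CPU; the library defaults above remain sized for larger, real
knowledge bases.  Determinism is exercised by running the full CLI chain
twice on a miniature profile (12 herbs, 8 symptoms, 90 genes) and
comparing output bytes.

## Known limitations

- Transductive CV (above) — no inductive generalization claim.
- The gene-token encoders see lexicographic order; the encoders could in
  principle exploit that arbitrary order, which is why the proximity-only
  ablation is kept as a reference point.
- The permutation null conditions on degree-bin profiles only; higher-
  order structure (module identity) is deliberately not matched, since
  that is the very signal being measured.
- Single-worker SGNS and a pure-numpy network trade speed for exact
  reproducibility; vocabularies far beyond ~10^4 tokens or sequence
  lengths far beyond ~10^2 would need a compiled backend.
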