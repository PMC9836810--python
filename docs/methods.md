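# Methods

`tcmgen` generates traditional Chinese medicine (TCM) prescriptions — an
unordered, duplicate-free set of herbs — from a symptom token sequence.
The model is a sequence-to-sequence generator with three knowledge hooks
around a recurrent encoder and an autoregressive decoder: an auxiliary
prescription→efficacy branch that supervises the symptom encoder, a
retrieval step that pools herbs from similar known cases into a
candidate set, and a dual-source copy/coverage output layer. This note
records the model as implemented, its assumptions, the numerical and
design choices that were genuinely open, and what the synthetic
benchmarks do and do not show.

## Model

**Hybrid symptom encoder.** Symptom tokens `s_1..s_n` are embedded and
read by a bidirectional GRU. A *hybrid module* mixes the two directional
states per position with a learned scalar gate:

    h_i = w_i h_i^f + (1 - w_i) h_i^b
    w_i = sigmoid( w_z . [h_i^f, h_{i-1}, e(s_{i-1}), u_i] + b_z )

with `u_i = (sum_{j<i} w_j) e(s_i)` the current embedding scaled by the
accumulated gate mass of the strict prefix. The accumulation term is
written self-referentially in some formulations (the sum running to
`j = i`); only the strict-prefix reading is causal, so that is what is
computed, left to right, with zero vectors for all boundary terms.
Content representation at decoder step `t` is additive attention over
the mixed states queried by the previous decoder state:
`Cs_t = sum_i a_ti h_i`, `a_t = softmax_i V.tanh(W_s s_{t-1} + W_h h_i)`.

**Guidance branch (efficacy supervision).** The gold prescription is
encoded by a second hybrid encoder (same structure, its own parameters,
herb embeddings shared with the decoder) into `Ch`; a small
autoregressive decoder then generates the prescription's efficacy
phrase, conditioned on `Ch` as a prepended context embedding. The branch
exists to force the symptom representation toward what the prescription
implies: a cosine gate compares `Cs` (zero-query form) with `Ch` and
scales an auxiliary penalty by `max(0, delta - SC) * (1 - SC)` with
`delta = 0.6`. When the two representations already agree
(`SC >= delta`) guidance is off; below the threshold it grows smoothly.
How "reduced supervision" maps onto training is not fixed by the source
formulation; realising it as a hinge-scaled auxiliary loss term is this
package's choice (switchable off for ablation).

**Retrieval (knowledge base and candidate pool).** Every training pair
contributes a record (symptoms, prescription, content representation).
A query is scored against all records by the blended dissimilarity

    Sim = lambda1 (1 - cos) + lambda2 ED / max ED,   lambda1 = 0.4,

with the Euclidean term normalised per query over the scanned records
(max-normalisation; min–max is a config option — the normalisation is
not pinned down by the source, and per-query max needs no corpus
statistics). The `k = 20` lowest-Sim records (stable ties by record
index) donate their herbs, deduplicated in first-occurrence order, to
the herbal candidate pool (HCP). During training a pair's own record is
excluded from its retrieval so the label cannot leak (switchable). KB
representations are refreshed with the current encoder every
`kb_refresh_epochs` epochs (default 1).

**Dual-source attention and copy/coverage decoder.** At step `t` the
decoder attends separately over the conventional herb library (CHL —
herbs with corpus frequency above a cutoff; published cutoff 480, scaled
for small corpora) and over the HCP; a gate
`g_hyb = sigmoid(w . [s_{t-1}, HCP context, e(h_{t-1})])` splits mass
between the two sets (HCP slots carry `g_hyb a^2`, CHL slots
`(1 - g_hyb) a^1`). A herb in both sets keeps two slots whose masses
merge by token when the copy distribution is scattered into the
vocabulary. The candidate context `O_t` is the blended-attention-weighted
sum of candidate *herb embeddings*: the printed form that sums candidate
attention against encoder states indexed by symptom position is
dimensionally inconsistent, and the embedding reading is the consistent
one. Coverage attention over encoder states is conditioned on a pooled
(summed; mean optional) embedding of the herbs generated so far, which
lets the model steer away from symptoms already served; its bias is a
parameter distinct from the HCP attention bias (the printed reuse is
treated as a typographical collision). The autoregressive core is a
small pre-norm causal transformer (default 2 layers; a GRU core is a
config option); step contexts (`O_t`, `Cs_t`, coverage context) are
linearly projected and added to the token-embedding stream. The output
mixes a vocabulary softmax over `[s_{t-1}, Cs_t]` with the scattered
candidate copy mass, weighted by `p_gen = sigmoid(w_s s_t + w_p
e(h_{t-1}) + w_c Cs_t + b)`. Greedy decoding stops at EOS or 23 herbs;
mask mode zeroes already-emitted herbs (and specials) before the argmax
and renormalises, making duplicates impossible by construction.

## Objective

Prescriptions are weak-order sequences, so the prescription branch uses
a *soft* cross-entropy whose step-t target is the average of the one-hot
label and the label bag scaled by 1/M (M = number of label steps,
including the EOS step — a uniform-scaling choice documented here). The
guidance branch adds an ordered per-step cross-entropy (efficacy phrases
are ordered) to the same soft loss, giving the multilevel guidance loss
with weights `phi1, phi2`; the joint objective blends the two branches
with `psi1, psi2`. All four weights are learned as `exp(-rho)` with a
`+rho` regulariser (homoscedastic-uncertainty weighting) — the source
states the weights are learned but gives no mechanism, and this
parameterisation guarantees positivity; fixed weights are a config
option. Optimisation is Adam (lr 1e-3, betas 0.9/0.999, eps 1e-6),
teacher-forced, with gradients averaged over minibatches of 8 pairs
(the published batch of 64 targets corpora three orders of magnitude
larger). The state with the lowest epoch-mean total loss is kept — model
selection by training loss, as the source prescribes, with no dev split.
A non-finite loss aborts training with the last good state retained.
Log-probabilities are clamped at 1e-12 (with a warning) so the loss is
total. The guidance branch may also be pretrained on
prescription–efficacy pairs (`ckgm_pretrain_epochs`, default 0 = joint
only; the source does not order the two phases).

All of this runs on a package-internal reverse-mode autodiff engine over
NumPy (`tcmgen.autodiff`): float64 tapes over small dense tensors, with
analytic backward rules validated against central finite differences at
1e-4 relative tolerance (with an absolute floor at the
central-difference noise level, machine-eps x |loss| / step).

## Synthetic data

Real corpora for this task pair free-text symptom presentations with
multi-herb formulas and cluster into *syndromes*: each syndrome calls
for a fixed core herb set plus looser assistants, and its formulas share
an efficacy phrase. The generator reproduces exactly that structure with
abstract tokens: a seeded world of syndromes (weighted symptom pools,
disjoint core sets, assistant pools, efficacy phrases), SP pairs drawn
by sampling a syndrome, its symptoms (Zipf-skewed within the pool;
off-syndrome noise tokens at a configurable rate, default 0.1) and a
prescription (cores plus 1–3 assistants), and PE pairs pairing a formula
with the phrase. Defaults: 4 syndromes, 60-token symptom and herb
vocabularies, 4 core + 6 assistant-pool herbs per syndrome, 4–10
symptoms per pair. Every generated pair satisfies the corpus length caps
(21 symptoms, 23 herbs) by construction.

What the generator does *not* emulate: linguistic structure in symptoms,
herb dosages, herb–herb incompatibility rules, label noise, and the
heavy multi-syndrome mixing of real presentations. Passing tests on
this corpus therefore demonstrate that the machinery (retrieval,
attention routing, copy/coverage, multi-task weighting) works and that
the model can exploit syndrome structure — not that it reaches any
particular accuracy on real clinical text.

## Benchmarks and problem sizes

* **Memorisation**: 50 SP pairs, hidden/embedding size 32, up to 300
  epochs with early stop once training-set F1 clears 0.95 (checked every
  10 epochs); macro F1 >= 0.9 on the training set is the pass mark.
* **Retrieval oracle**: 200-record KBs, 50 queries, exact top-20
  agreement against an independent full sort.
* **Candidate-pool enrichment**: 4 syndromes, 200 pairs (>= 30 records
  per syndrome), noise 0.1, k = 20; the pool should contain >= 90% of
  the query syndrome's core herbs, averaged over 50 queries. This holds
  already for an untrained encoder: same-syndrome symptom bags share
  most tokens, which a random recurrent encoder maps to nearby states.
* **Ablation direction**: the candidate-set ablations (full vs only-CHL
  vs no-candidates) are compared by mean test F1 over 3 seeds. The
  benchmark is deliberately *sparse*: 8 syndromes, 120-herb vocabulary,
  100 pairs (75 train / 25 test), 35 epochs, hidden size 20, single-layer
  core, k = 15. Sparsity matters: with a dense 60-herb vocabulary the
  plain vocabulary softmax solves the task outright and candidate
  copying is pure overhead, inverting the expected ordering. The
  mechanism being tested — copying from retrieved similar formulas —
  pays off exactly when the output space is large relative to the data,
  which is the regime of the real corpora (thousands of herbs, ~10 per
  formula); the benchmark reproduces that regime at desk scale.

Problem sizes throughout (dimensions 4–32 in tests, 12–32 in the
acceptance script) are the package's own desk-scale choices; the
published configuration (512-dimensional embeddings and hidden states,
500 epochs, batch 64, pretrained GPT-2 decoder) targets GPU-scale
training on ~100k pairs and is reachable through the same config
surface.

## Known limitations

* Single-sequence processing (no batched tensor ops): throughput is
  Python-overhead-bound; fine at desk scale, unsuitable for 100k-pair
  corpora.
* The efficacy decoder and the prescription decoder default to the same
  small transformer core; loading pretrained GPT-2 weights is out of
  scope (the adapter contract exists, the weights do not ship).
* Greedy decoding only; no beam search or sampling.
* `Cs`/`Ch` for the similarity gate use the zero-query (first-step)
  content representations — a fixed, documented choice where the source
  leaves the step unspecified.
* The evaluation fixtures encode published reference numbers for
  score-aggregation arithmetic; they are inputs, not results of this
  package's training.
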