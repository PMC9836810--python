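# tcmgen

Knowledge-guided sequence-to-sequence generation of traditional Chinese
medicine (TCM) prescriptions from symptom text.

A TCM prescription is an unordered, duplicate-free set of herbs matched
to a patient's symptom presentation. `tcmgen` is for researchers in
computational TCM / biomedical NLP who want a trainable, fully
inspectable reference implementation of a knowledge-guided prescription
generator — and a seeded synthetic-corpus generator to exercise it
without access to clinical data.

The model couples a sequence-to-sequence backbone with three knowledge
hooks:

* **Hybrid bidirectional encoder** — a BiGRU over symptom tokens whose
  forward/backward states are mixed per position by a learned gate
  `h_i = w_i h_i^f + (1-w_i) h_i^b`, then summarised per decoding step by
  additive attention into a content representation `Cs_t`.
* **Efficacy guidance branch** — the gold prescription is encoded by the
  same hybrid structure and decoded into its efficacy phrase; a cosine
  gate `max(0, δ − cos(Cs, Ch))` (δ = 0.6) strengthens this auxiliary
  supervision exactly when the symptom and prescription representations
  disagree.
* **Retrieval + dual-source copy/coverage decoder** — the k = 20 most
  similar known cases under the blended score
  `Sim = λ₁(1 − cos) + λ₂·ED/max ED` (λ₁ = 0.4) pool their herbs into a
  candidate set; the decoder splits attention between that pool and a
  high-frequency herb library with an adaptive gate, mixes copied
  candidate mass with a vocabulary softmax via `p_gen`, and a coverage
  term conditioned on already-generated herbs suppresses repetition.
  Masked greedy decoding guarantees duplicate-free prescriptions.

Training minimises a weak-order *soft* cross-entropy over herbs plus the
multilevel guidance loss, with task weights learned through
homoscedastic-uncertainty parameterisation. Everything runs on a compact
reverse-mode autodiff engine over NumPy (float64, finite-difference
validated) — no deep-learning framework required.

## Worked example

```python
from tcmgen import (ModelConfig, PrescriptionModel, SynthConfig,
                    generate_corpus, make_world)

synth = SynthConfig(seed=7, n_pairs_sp=50, n_pairs_pe=20)
sp, pe = generate_corpus(make_world(synth), synth)

cfg = ModelConfig(d_embed=32, d_hidden=32, d_att=32, epochs=60, k=10, seed=7)
model = PrescriptionModel(sp, pe, cfg, chl_min_count=0)
results = model.fit()
print(results.summary())
print("prescription:", results.generate(sp[0].symptoms))
print("train metrics:", results.evaluate(sp))
```

Output from this exact script (60 epochs, ~1 minute on one CPU):

```
Prescription Generation Model Results
======================================================
SP pairs (train):        50
PE pairs:                20
herb vocabulary:         42
symptom vocabulary:      63
conventional library:    38 herbs
knowledge base:          50 records
hidden / embed size:     32 / 32
decoder core:            transformer (2 layers)
retrieval k / lambda1:   10 / 0.4
cosine gate delta:       0.6
epochs run:              60
best epoch (total loss): 58  (14.1971)
final herb soft loss:    13.4418
final guidance loss:     4.4597
task weights:            psi1=0.733 psi2=0.800 phi1=0.761 phi2=1.000
======================================================
prescription: ['H041', 'H047', 'H032', 'H039', 'H015']
train metrics: {'precision': 0.9214761904761904, 'recall': 0.798095238095238, 'f1': 0.8504505494505494, 'n': 50}
```

Reading the output: the summary reports corpus and architecture sizes,
the best (lowest) epoch-mean total loss, its herb-branch and
guidance-branch components, and the learned task weights (all positive
by construction). `generate` returns a duplicate-free herb list;
`evaluate` scores generated prescriptions against the labels as sets
(macro precision / recall / F1). Longer training memorises this corpus
to F1 ≥ 0.95.

The same round trip is available from the shell:

```bash
tcmgen synth --out-dir corpus --seed 1
tcmgen train corpus/sp.jsonl --pe corpus/pe.jsonl --out model --epochs 40
tcmgen generate model --symptoms "S001 S002 S007" --kb corpus/sp.jsonl
tcmgen evaluate predictions.jsonl gold.jsonl
```

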