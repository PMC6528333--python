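# Methods

## Pipeline model

The package extracts chemical-induced disease (CID) relations from
annotated abstracts in four stages.

**Candidate construction.** Mentions are typed (Chemical/Disease) and
normalized to MeSH IDs; mentions with ID `-1` and overlapping
chemical/disease spans are never paired. Intra-sentence candidates are the
full cross product of co-occurring mention pairs, without restriction.
Inter-sentence candidates are pruned in order: (1) an entity-ID pair that
co-occurs in any sentence of the document is excluded from the
inter-sentence level entirely; (2) mention pairs more than 3 sentences
apart are dropped; (3) of the remaining realizations of one entity-ID
pair, only the nearest is kept — nearest by sentence distance, then by the
number of whitespace tokens between the mention starts, then by earliest
chemical and disease offset. A hypernym filter removes any instance whose
chemical (disease) ID is a MeSH tree-number ancestor of a chemical
(disease) ID occurring in another candidate of the same document; removal
is computed once against the pre-filter set, so ancestor chains are pruned
to their most specific member in a single pass. The comparison is
same-type only: cross-type tree-prefix tests are meaningless because
chemical and disease IDs live in different MeSH subtrees.

**Shortest dependency paths.** The classifier input is the shortest path
between the two mention head tokens in the sentence's dependency tree,
serialized as lowercased words interleaved with (direction, tag,
direction) segments — `↑` for a child-to-parent step, `↓` for the
reverse, the tag being the dependency label of the traversed edge. For a
path over `w` words the sequence has `4w − 3` tokens. Inter-sentence
paths join the two sentence roots through a synthetic root that
contributes no word: the crossing emits `(↑, root, ↑)` then
`(↓, tag-of-root, ↓)`, one extra segment, total `4w`. The mention head
token is the last parse token overlapping the mention span (head-final
heuristic; relevant only for multi-word mentions). Parses are inputs, read
from CoNLL-style blocks; token alignment with the text assumes whitespace
tokenization, lowercasing, and removal of edge punctuation — a mismatch
raises rather than guessing.

**Knowledge representations.** Corpus entity pairs are annotated with
their KB relation (`marker/mechanism`, `therapeutic`,
`inferred-association`); pairs absent from the KB receive the synthetic
`null` relation, which participates in training like any other. When a
pair is curated with several relations, `marker/mechanism` takes
precedence, then `therapeutic` — the most CID-specific label wins, since
downstream only `marker/mechanism` denotes a true CID. The merged triple
set is embedded by the translation model `e_c + r ≈ e_d` with the
margin-ranking hinge against corrupted triples (one corruption per triple
per epoch, head or tail replaced with probability ½, resampled out of the
true set). Entity vectors are initialized as the mean of their mention
word vectors — placing entities in the word-vector space from the start —
and relation vectors uniform in [−0.25, 0.25].

**Classifier.** Two convolutional branches read the same embedded SDP.
Each branch gates its convolutional features with one focused entity:
feature path `tanh(X∗W_s + b_s)`, gate path
`relu(X∗W_a + V_a·e + b_a)` (GTRU; GTU uses a sigmoid gate, GLU a linear
feature path with a sigmoid gate), output their product. Feature maps for
window widths 1–5 are zero-padded to the input length and stacked; padding
keeps the declared `l × n` map shape and makes multi-width stacking
well-defined. Pooling is attention of each feature column against the
pair's relation embedding (`g_i = tanh(W_g M[:,i] + b_g) · r`, softmax,
weighted sum); by default the two branches share attention parameters
(DGate-SAtt) so the entities communicate through a common relevance model,
with the other three sharing modes available. Shared storage is literal:
the branches alias the same arrays, and gradients accumulate into them
from both. The concatenated pooled features pass through a relu layer and
a binary softmax; training minimizes mean cross-entropy with Adam
(batch 20, learning rate 1e-4 intra / 2e-4 inter), early-stopped on
validation F1 over a document-granular 80/20 split (document granularity
prevents near-duplicate instances of one document from leaking across the
split). Prediction ties (p = 0.5) resolve negative — conservative for
precision. Document-level results are the OR over instance predictions
per (document, chemical-ID, disease-ID), scored as P/R/F1 against gold
pairs; each level's predictions are also scored alone against the full
gold set, which is why the inter-sentence level has intrinsically low
recall.

Entity and relation embeddings are *inputs* to the classifier — frozen
during its training — while token embeddings (words, dependency tags, the
two direction symbols) are trainable. Variant configurations: SA replaces
relation attention by scalar self-attention; AE replaces trained entity
embeddings by mention-word averages; AE-SA does both and therefore reads
no trained knowledge at all (the embedding space counts its lookups so
this is testable).

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| embedding dims d = k | 100 | word, entity and relation vectors share one space |
| filters per window | 100 | over windows 1–5, so l = 500 channels |
| hidden width h0 | 100 | pre-softmax relu layer |
| gate / attention | GTRU / relation | GTU, GLU, self-attention available |
| sharing | DGate-SAtt | gates per-branch, attention shared |
| margin γ | 1.0 | hinge margin of the translation model |
| translation epochs / lr | 500 / 0.01 | SGD, L2 norm, unit-normalized entities per epoch |
| classifier lr | 1e-4 intra, 2e-4 inter | Adam, batch 20 |
| max epochs / patience | 50 / 5 | early stop on validation F1 |

Choices the sources leave open, fixed here: the filter count is
interpreted as 100 *per window size*; h0 = 100; the hinge norm is L2 and
its optimizer plain SGD (the Adam settings belong to the classifier);
γ = 1; no dropout or weight decay. Gate biases initialize to 1 so gates
start open — a zero-centered relu pre-activation would zero half the
feature map at initialization and starve early gradients (the same reason
LSTM forget gates are initialized positive); other weights use
Glorot-uniform, embeddings and `V_a` uniform [−0.25, 0.25].

## Numerical notes

All network arithmetic is float64 numpy with hand-derived gradients; the
test suite checks them against central finite differences (tolerance 1e-4
relative with a 1e-9 absolute floor below the differencing noise) and the
whole forward pass against an independent scalar re-implementation
(1e-8). Softmaxes subtract the maximum before exponentiation; the sigmoid
is evaluated branch-wise for stability; cross-entropy clips probabilities
at 1e-300 before the log. Degenerate inputs fail loudly: empty SDPs,
empty batches, mixed-level training sets, cyclic or multi-root parses,
offsets outside the text. An entity unseen in embedding training falls
back to its mention-word average (the AE representation), logged once.

## The synthetic generator

Real CDR corpora cannot be redistributed, so every stage is exercised on
generated data emitting the exact same file formats (PubTator, CoNLL-style
parses, KB TSV, MeSH TSV, word2vec text). Documents realize one
chemical–disease pair in a templated sentence frame whose dependency tree
is built alongside — parses are valid by construction and every SDP is
known. The planted label rule is: positive iff the frame verb is a trigger
("induced", "caused" vs "reversed", "prevented") *and* the KB curates the
pair as marker/mechanism; a configurable noise rate flips labels, so the
Bayes-optimal score is computable. Pairs are KB-covered with probability
`informative_fraction` (covered pairs split evenly between
marker/mechanism and distractor relations), document realizations include
intra, inter (distance 1–3), beyond-cutoff (distance 4, never gold, since
the distance rule makes them unrecoverable), repeated-mention and
planted-ancestor variants, exercising every construction rule and the
hypernym filter in situ.

What passing on this data shows — and does not. It shows the pipeline's
rules, gradients and training loop are correct, that the classifier can
exploit KB guidance (the label depends on a relation only visible through
the knowledge embeddings, so knowledge-ablated variants are structurally
handicapped), and that attention localizes on trigger tokens. It does not
show robustness to parse errors, tokenization mismatches, multi-word
entity surface forms, coreference, or the heavy class imbalance of real
abstracts — the templated language has none of these.

## Study conditions for the shipped experiments

The acceptance tests and `scripts/acceptance.py` run at reduced sizes
chosen once as the package's characterization conditions: corpora of 760
documents (giving a 400-train / 100-test split of intra-sentence
instances, or a 100-document held-out set for document-level scoring),
embedding dimension 16, 10 filters per window (50 channels), hidden width
32, 30 training epochs without early stopping (validation F1 starts flat
at zero while the decision boundary forms, so patience-based stopping
inside a 30-epoch budget would measure the stopping rule, not the model),
translation-embedding training for 50 epochs on the corpus KB and 500 on
the planted link-prediction KB (130 training triples, 30 held-out queries
ranked against 9 distractors). Under these conditions the full model
reaches held-out F1 ≈ 100, its knowledge ablations plateau near the
trigger-only ceiling, the link-prediction top-1 rate is 100%, and the
Only-KB baseline shows perfect recall with distractor-limited precision —
the qualitative pattern expected when prior knowledge carries half the
label signal.

## Known limitations

Sentence splitting is a deterministic rule (terminator + uppercase, with
an abbreviation guard) chosen for reproducibility, not linguistic
fidelity; mentions crossing a detected boundary merge the sentences.
Evaluation is at entity-ID level only; unnormalized mentions are excluded
from pairing and scoring. The trainer is single-threaded per-instance
numpy — adequate at the shipped scales, not for a 1.8M-triple KB or a
500-filter model, where minibatch-vectorized or GPU code would be needed.
The relation-merging OR is deliberately simple and inherits every false
positive of its inputs.
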