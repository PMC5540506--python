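# Methods

`ncstruct` classifies non-coding RNA (ncRNA) sequences from their secondary
structure. The pipeline has four stages: structure graphs, closed frequent
sub-graph mining, boolean featurization, and a small 1-D convolutional
network, evaluated by stratified cross-validation with a frozen feature
space. This note records the model, its assumptions, the parameters that
matter, and the design decisions taken where the design was genuinely open.

## Structure graphs

A predicted secondary structure in extended dot-bracket notation is read as
an undirected labelled graph: one vertex per nucleotide (labelled `A`, `C`,
`G`, `U`, or `N` for anything else), *backbone* edges between consecutive
positions, and a *pair* edge per base pair. Bracket families `()`, `[]`,
`{}`, `<>` and `A–Z`/`a–z` are matched independently, so crossing families
encode pseudoknots. Both edge types are kept, with distinct bond labels:
mined fragments may then span stem + loop context, which is what makes them
informative local motifs. Pairs between adjacent bases are rejected as
geometrically impossible, and each base may pair with at most one partner.

Coordinates are 0-based internally; any positions in output files follow the
1-based bioinformatics convention and say so in their headers. `T` is mapped
to `U` on input and IUPAC degenerate codes collapse to `N`; `N` matches only
`N` during mining, so support counting stays well defined (no wildcard
semantics).

## Closed frequent sub-graph mining

A *fragment* is a connected, labelled sub-graph; its *support* is the number
of graphs containing at least one label- and bond-preserving embedding
(embedding multiplicity within a graph is irrelevant). Matching is sub-graph
— not induced-sub-graph — isomorphism: a fragment may omit edges that exist
between its nodes in a host. Given a support threshold (percent of graphs,
converted with `ceil`) and a size window `[m, n]` in **nodes**, the miner
returns every fragment that is frequent, within the window, and *closed*:
no one-edge extension occurring in the data (and still within the window —
the search is truncated at `n` nodes) has equal support. Closedness removes
the redundancy of reporting every sub-fragment of a frequent motif at the
same support.

The search grows fragments depth-first from single-node seeds, molecular-
miner style: each fragment carries its full embedding list, extensions are
enumerated from those embeddings (so only extensions that actually occur are
considered), and the support of an extension is obtained by filtering
embeddings rather than by fresh isomorphism searches. Duplicates reached
along different search paths are pruned with a canonical code: the
lexicographically minimal "column" serialization over all connectivity-
respecting node orders, found by branch-and-bound. Equal codes iff
isomorphic; the code doubles as the stable fragment identifier in all file
formats, and output is sorted by (size, code), making fragment files
byte-reproducible.

`oracle_mine` recomputes the same contract by brute force — every connected
edge-subset of every graph is enumerated, canonicalized and counted — and is
the independent reference the miner is tested against on randomized small
instances. It is restricted to graphs of at most 10 nodes.

## Feature space

Mining a training collection yields an ordered fragment list; the boolean
matrix A(g, s) has a row per graph and a column per fragment, 1 where the
fragment embeds in the graph. At training time the matrix is read directly
off the miner's per-fragment supporting ids (and equals the explicitly
matched matrix — a tested invariant). Unseen sequences are *projected* into
the frozen feature space: each frozen fragment is matched against the new
graph with an exact backtracking matcher; nothing is re-mined, and absent
fragments simply contribute 0. Column order is always the frozen fragment
file order.

## The network

The classifier is a 1-D CNN over the boolean feature vector x ∈ {0,1}^L:

    conv(k1, n1) → logistic → max-pool(2) → conv(k2, n2, multi-channel)
    → logistic → max-pool(2) → flatten → dense(hidden, tanh)
    → dense(n_classes) → softmax

Convolutions are valid (no padding), stride 1, implemented as
cross-correlation; layer ℓ output length is Lℓ − k + 1. Pooling is
non-overlapping with width fixed at 2; an odd trailing element is dropped
(floor semantics). Defaults: k1 = k2 = 5, n1 = 10, n2 = 20, hidden = 500.
With binary inputs a width-5 kernel can encounter at most 2⁵ − 1 = 31
distinct nonzero patterns, which bounds the useful first-layer kernel count;
n1 = 10 stays well below it. For L = 6443 input features the dimension chain
is 6439 → 3219 → 3215 → 1607, so the flattened feature vector has
20 × 1607 = 32140 components.

Training minimizes categorical cross-entropy by mini-batch stochastic
gradient descent. Weights start from uniform fan-in-scaled initialisation;
biases start at zero; every random choice (init, epoch shuffling) comes from
one integer seed, so identical (data, config) pairs give bit-identical
models. Forward, backward and the update rule are explicit numpy; the
analytic gradients are verified against central finite differences
(relative error < 1e-6 on a small network). Ties in max-pooling route the
gradient to the left element; prediction ties go to the lowest class index.

### Optimisation on mined-fragment inputs

Two logistic convolution layers attenuate the between-sample variance of a
binary input roughly by the factor σ′ ≈ 0.25 each, so on mined fragment
matrices the flattened features vary across samples by only ~10⁻² even
though they are linearly separable. Under small mini-batches the
class-composition noise of each batch then dominates the useful gradient
and the output layer performs a random walk; momentum amplifies the walk.
Full-batch gradient descent removes that noise entirely and converges
reliably at a learning rate of 0.05 (training accuracy 1.0 within ~350
steps on the synthetic study data). The package therefore keeps classic
mini-batch defaults (`batch_size=20`, `learning_rate=0.1`, `epochs=200`),
which behave well on strongly separable inputs, but the cross-validation
study configuration uses full-batch descent: `batch_size` larger than the
training set, `learning_rate=0.05`, `epochs=350`, float32 arithmetic, and a
runtime-scaled network (n1 = 8, n2 = 14, hidden = 32 — same architecture
family, smaller maps). All of these are ordinary config fields.

The hidden activation is tanh (the logistic function is reserved for the
convolution layers, applied before pooling); the loss, rates and
initialisation are package choices since only "stochastic gradient descent"
is inherent to the method. `k2` defaults to 5 (the evaluated configuration)
but is exposed in the config.

## Evaluation

Six statistics are computed per class from the one-vs-rest reduction of the
confusion matrix: accuracy (TP+TN)/(TP+TN+FP+FN), sensitivity TP/(TP+FN),
specificity TN/(TN+FP), precision TP/(TP+FP), F-score 2TP/(2TP+FP+FN), and
Matthews correlation. Arithmetic is exact-rational before conversion to
float; a zero denominator yields 0 with a warning (degenerate folds only).
Multi-class summaries are macro averages (unweighted over classes — the
benchmark is nearly balanced); the overall trace accuracy
(correct/total) is reported alongside because macro one-vs-rest accuracy
and micro accuracy answer different questions. Multi-class MCC is the macro
average of the per-class binary MCCs, matching the reduction used for the
other statistics.

Cross-validation is stratified (per-class round-robin after a seeded
shuffle) so every class appears in every training fold. Per fold, fragments
are mined on the **training portion only**, the CNN is trained on the
training matrix, and the held-out records are projected into that fold's
frozen feature space — no information flows from test to train, which a
test asserts by checking fragment supporting ids. The reported confusion
matrix is the elementwise sum of the per-fold matrices; statistics are
computed from the summed matrix. Fold f trains with seed `base_seed + f`.

## Synthetic data

The generator emulates a multi-class ncRNA family benchmark without
downloads. Class c's signature is a fixed hairpin: a stem of 3 + c base
pairs (sequence drawn from a fixed template) closed by a class-specific
loop trinucleotide. The motif is embedded at a seeded random offset in
random unpaired flanking sequence; record lengths are uniform on 40–60 nt
(typical of small ncRNA, and long enough for distinctive context).
Structures are emitted as ground truth alongside the sequences, so the
feature signal is controlled; the toy base-pair-maximisation folder
(Nussinov-style dynamic programming, Watson–Crick + GU pairs, minimum
hairpin loop of 3, deterministic leftmost-pairing traceback) exists to
exercise the FASTA-only path, not to generate the training structures.
Mutation noise substitutes nucleotides at a per-position rate *after* motif
embedding, leaving the structure string untouched — a simple model of
predictor/sequence mismatch. Mutation randomness comes from its own seeded
stream, so the same seed yields identical records and structures at every
mutation rate.

What the generator does *not* emulate: realistic family size distributions,
sequence conservation gradients, pseudoknotted signatures, or structure-
predictor error models. Passing the recovery study therefore demonstrates
that the pipeline's stages compose correctly and can recover clean
structural signal — not that real-family accuracy would match.

## Study problem sizes

The end-to-end recovery study uses 5 classes × 40 records, mined per fold
at 10% support with 2–6-node fragments (~900 fragments per fold), ten
folds. These sizes keep a full run in the minutes range on a single CPU
while leaving every stage non-trivial; the acceptance script reruns the
whole study from scratch.

## Known limitations

* The miner's canonical code search is exponential in the worst case
  (highly symmetric unlabelled graphs); on RNA graphs — sparse, 4–5 labels
  — it is effectively linear. Fragment size is bounded by `max_size` anyway.
* `oracle_mine` is exhaustive and limited to ≤10-node graphs by design.
* The CNN is CPU-only, dense numpy; no regularisation, early stopping or
  architecture search is provided.
* Projection matches fragments one at a time; for very large frozen spaces
  an index over fragment labels would be the next optimisation.
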