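# Methods

## Model

A label taxonomy is a rooted tree; every class label is a node. Two
labelling policies occur in practice and both are supported: *type-1*
(only leaves are labels, as in tieredImageNet-style datasets) and *type-2*
(internal nodes may be labels, the norm in medical taxonomies — a scan can
be "Lung Opacity" without a finer finding). The package's severity unit is
the **height of the lowest common ancestor** of predicted and true labels:
`h(v)` is the maximum edge count from `v` to a leaf of its subtree, so
leaves have height 0, a correct prediction costs 0, and the tree height
`H` bounds every single-label mistake. This height convention (rather than
depth-from-root or path length) is the one under which the packaged
14-label chest taxonomy has bound 2 and within-branch confusions score
strictly below cross-branch ones.

All severity, CRM and HXE computations consume the `K × K` cost matrix
`C[i,j] = h(LCA(label_i, label_j))`. The diagonal is forced to 0 even for
internal-node labels (a correct prediction must be free); off-diagonal
entries lie in `[1, H]` and satisfy the ultrametric inequality
`C[i,k] ≤ max(C[i,j], C[j,k])`, both verified by property tests against a
brute-force ancestor-enumeration oracle.

### Multiclass severity

Per-sample severity is `C[ŷ, y]`; classifier severity is its mean ±
**population** standard deviation over *all* samples, correct predictions
contributing 0. Averaging over all samples (rather than errors only) makes
the distribution zero-inflated, which is why reported stds commonly exceed
means for accurate models. Per-label severity, by contrast, averages over
the *misclassified* samples of each true label by default — otherwise
labels could never approach the bound `H` — with `include_correct=True`
switching to all-samples averaging; labels with no errors report 0 plus an
explicit flag.

### Multilabel severity

With false positives `I = {i : ŷ(i)=1, y(i)=0}` and false negatives
`J = {j : y(j)=1, ŷ(j)=0}`,

    S = (1/|J|) Σ_{i∈I} Σ_{j∈J} C[i, j].

When `J = ∅` the double sum is empty and `S = 0` — including when `I ≠ ∅`.
That limit is not obviously the intended one (false-positive-only errors
cost nothing), so it is documented loudly here and in the docstring rather
than silently absorbed; the statistic is bounded by `|I|·H`. One-hot
vectors with a single disagreement recover the multiclass statistic
exactly. Scores are binarized at a configurable threshold, default 0.5.

### Companion metrics

Accuracy is `(TP+TN)/(TP+TN+FP+FN)`. AUROC is the standard rank statistic
(probability a random positive outranks a random negative, ties ½) —
implemented via scikit-learn and cross-checked against an exhaustive
pair-counting oracle — macro-averaged over labels, with single-class
labels flagged undefined and excluded from the macro mean rather than
imputed. F1 is per-label binary F1, macro-averaged. No bootstrap: the
reported spread is the per-sample population std only.

## CRM

`risk = C @ p` exactly (double precision, no epsilon); the decision is the
arg-min with ties broken to the lowest label index, a deterministic choice
the formulation itself leaves open. With a zero-one cost matrix the rule
collapses to arg-max, a closed form the tests assert. The top-k variant
sorts by ascending risk with a stable sort.

The multilabel soft-label route rescales `C @ p` into `[0,1]` and flips it
so low risk means high score. Because raw `C @ p` is unbounded when
independent sigmoidal scores do not sum to 1, two normalizations are
exposed: `sum` (renormalize `p`, divide risks by `H`) and `minmax`
(per-sample min-max rescale), default `minmax`. A constant risk vector
maps to a uniform 0.5. This rescaling is the largest interpretive step in
the package and is deliberately configurable; as the simulation example
shows, the soft-label route can *raise* measured severity, so it should be
treated as a diagnostic transform, not a guaranteed reducer.

## HXE

Leaf distributions factorize along root paths via subtree-mass ratios;
`path_probability` telescopes back to the leaf probability (checked to
1e-9). The loss is the weighted negative log of each conditional on the
target's path, with conditionals clamped at `ε = 1e-12` before the log
(configurable constant `LOG_CLAMP`); a zero-mass parent is clamped the
same way in the denominator, keeping the loss finite on degenerate inputs.
Edge weights use exponential decay `exp(−α · (H − depth))`, so `α = 0`
gives uniform weights (the default, chosen because no canonical value
exists) and `α > 0` recovers the usual discount of near-root edges; the
weight of an edge into a deepest leaf is always 1.

Type-2 taxonomies break the leaf-only assumption of the factorization, so
`augment_type2_tree` grafts a virtual leaf (name suffixed `*`) under every
labelled internal node to carry the "exactly this node" outcome; label
count and tree height are preserved and `leaf_for_label` maps labels to
their representative leaves. The alternative route — collapsing multilabel
data to multiclass by keeping one positive label — is also provided
(`collapse_multilabel_to_multiclass`, policies `deepest`/`first`/
`seeded-random`), since both appear in practice; the collapse is lossy by
construction and drops label-free samples with a logged count.

## Synthetic data

The generators produce exactly what the metrics consume — taxonomy,
scores, truth — because every claim the package makes lives in score
space. Defaults model a modest medical-style taxonomy and classifier:
depth 2, branching 3–5, n = 5000, Dirichlet concentration 1.0 for
conditionals, calibrated scores (temperature off), per-label prevalence
0.15, and equal within/cross-branch flip rates of 0.15.

* `simulate_multiclass` draws a true conditional per sample from a
  symmetric Dirichlet, samples the label from it, and reports the
  conditional itself (calibrated) or a temperature-flattened distortion.
  Calibration is what makes CRM provably no worse than arg-max in
  expectation, and the Monte-Carlo tests check exactly that with 3-SE
  slack at n = 10,000.
* `simulate_multilabel` draws positives at the prevalence, propagates them
  up to labelled ancestors (every truth vector is hierarchy-consistent by
  construction), then corrupts each sample's deepest positive: swapped
  within its level-1 branch at `within_flip`, across branches at
  `cross_flip`. Defining flips relative to the level-1 ancestor of the
  deepest positive manipulates the LCA height of the induced error
  directly, so the two rates separate severity from error count — the
  package's central demonstration, asserted at n = 5,000.

Seeding: one integer seed per call, split into independent sub-streams via
`numpy.random.SeedSequence([seed, stream])`, so outputs are byte-identical
on repeat and insensitive to internal draw order.

What the simulations do **not** emulate: image feature extraction, learned
score correlations between related labels, label noise in the ground
truth, and real-world class imbalance (imbalance is a knob, not a default).
Passing tests therefore certify the metric algebra and the decision
theory, not any claim about how trained networks behave on real
radiographs.

## Packaged taxonomy

The bundled 14-label chest-radiograph tree (data file
`src/soe/data/chexpert.json`, height 2) places No Finding, Support
Devices, Fracture, Enlarged Cardiomediastinum and Lung Opacity at level 1,
Cardiomegaly under Enlarged Cardiomediastinum, and the eight specific lung
findings under Lung Opacity. Published edge lists for this dataset vary —
some nest Pneumonia under Consolidation, which would give height 3 — and
the bundled tree is the flattened variant consistent with a severity bound
of 2 and with Pneumonia/Consolidation as a within-branch pair. Being a
data file, it is trivially replaced by users with a different taxonomy.

## Numerical and interface choices

* Label order is document order of the input spec and is canonical: every
  matrix, CSV column block and vector follows it, and a mismatched order
  is an error, never a silent reorder.
* CSV schemas: multiclass `sample_id,true_label,<labels...>`; multilabel
  two files sharing `sample_id,<labels...>` (scores and binary truth).
* Severity moments use population (ddof = 0) standard deviation.
* Reports serialize to JSON and to aligned text with `mean ± std` at two
  decimals.

## Known limitations

* Trees only — no DAG taxonomies, no multiple inheritance.
* No learned or user-weighted cost matrices; the cost is always LCA
  height.
* The multilabel severity assigns 0 to false-positive-only samples (see
  above); pair it with F1 when that failure mode matters.
* HXE is exposed as a pure numeric function for evaluation; no training
  loop or autodiff integration is included.
* Problem sizes in the test suite (trees up to depth 5 capped at ~60
  labels for the quadratic oracle comparisons; simulations at n =
  5,000–10,000) were chosen to make the Monte-Carlo checks sharp while
  keeping the suite fast to run routinely.
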