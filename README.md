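# soe — Severity of Error for hierarchical label sets

Accuracy and AUROC count a classifier's mistakes; they say nothing about how
*bad* each mistake is. In medical image classification the labels usually
live in a taxonomy (CheXpert's thoracic findings, ICD-10 code blocks), and
confusing two sibling findings is a far milder event than calling a
pneumonia "No Finding". `soe` quantifies that difference and implements the
two standard severity-reduction routes so they can be evaluated side by
side, entirely in score space — no images or model training required.

## The statistic

Given a rooted label taxonomy, the severity of a single prediction is the
height of the lowest common ancestor of the predicted and true labels,

```
S_i = h( LCA(ŷ_i, y_i) )
```

where `h(v)` is the maximum edge count from node `v` down to a leaf of its
subtree (leaves have height 0, so a correct prediction costs 0 and the tree
height `H` bounds every single-label mistake). A classifier's severity is
the expectation `E[S]` over samples, reported as mean ± population std.

For multilabel outputs, with false-positive label set
`I = {i : ŷ(i)=1, y(i)=0}` and false-negative set
`J = {j : y(j)=1, ŷ(j)=0}`, the per-sample severity is

```
S = (1/|J|) Σ_{i∈I} Σ_{j∈J} h( LCA(i, j) )
```

which is 0 when the prediction matches the truth and reduces exactly to the
single-pair statistic for one-hot vectors with a single disagreement.

Two severity-reduction frameworks are included:

* **CRM** (conditional risk minimization): post-inference relabelling by
  `argmin_k Σ_j C[k,j] p(j)` with `C` the LCA-height cost matrix — the
  Bayes rule for the cost when the scores are calibrated — plus top-k
  re-ranking and a multilabel variant that rescales the risk vector
  `C·p` into per-label soft labels.
* **HXE** (hierarchical cross-entropy): the leaf probability factorized
  into conditionals along the root path,
  `L = −Σ_l λ_l log p(C^(l) | C^(l+1))`, with exponential-decay edge
  weights; on a flat tree with unit weights it equals ordinary
  cross-entropy. Taxonomies whose internal nodes are themselves labels are
  handled by virtual-leaf augmentation.

Hierarchies are read from nested JSON, newick strings with named internal
nodes, or plain lists of hierarchical code strings (prefix nesting à la
ICD-10). A 14-label chest-radiograph taxonomy of height 2 ships with the
package (`soe.chexpert_tree()`).

## Worked example

```python
from soe import chexpert_tree, cost_matrix, sample_severity

tree = chexpert_tree()
cm = cost_matrix(tree)
print(len(tree.labels), tree.height(), cm.max_cost)
print(sample_severity(cm, "Consolidation", "Pneumonia"))
print(sample_severity(cm, "No Finding", "Pneumonia"))
```

prints

```
14 2 2.0
1.0
2.0
```

— fourteen labels, tree height 2, so 2 is the worst any single-label error
can score; a Consolidation/Pneumonia confusion stays inside the Lung
Opacity branch (severity 1) while No Finding vs Pneumonia share only the
root (severity 2, the bound).

Running `python examples/multilabel_severity.py` simulates two multilabel
classifiers with identical 30% error budgets, one confined to
within-branch confusions and one crossing branches:

```
within-branch errors: SoE 0.22 ± 0.41
cross-branch errors : SoE 0.44 ± 0.83
```

Same error count, twice the severity — the distinction the metric exists
to expose. The other scripts in `examples/` demonstrate CRM relabelling on
a calibrated simulation, HXE evaluation, and code-list tree construction;
each prints its numbers with a line on what they mean.

A thin CLI mirrors the library: `soe cost-matrix`, `soe eval`,
`soe compare`, `soe crm`, `soe hxe`, `soe simulate` (see `soe --help`).

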