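"""Severity facts of the packaged 14-label chest-radiograph taxonomy.

Builds the LCA-height cost matrix and prices a few representative
confusions: same-branch mistakes cost 1 edge, cross-branch mistakes cost 2
(the tree height, the worst any single-label error can be).
"""

from soe import chexpert_tree, cost_matrix, sample_severity

tree = chexpert_tree()
cm = cost_matrix(tree)

print(f"labels: {len(tree.labels)}, tree height: {tree.height()}")
print(f"maximum possible single-label severity: {cm.max_cost:.0f}\n")

pairs = [
    ("Consolidation", "Pneumonia"),     # siblings under Lung Opacity
    ("Lung Opacity", "Atelectasis"),    # parent predicted for its child
    ("No Finding", "Pneumonia"),        # only the root in common
    ("Cardiomegaly", "Pleural Effusion"),
]
for pred, truth in pairs:
    s = sample_severity(cm, pred, truth)
    print(f"predict {pred!r:<20} when truth is {truth!r:<18} -> severity {s:.0f}")

print(
    "\nSeverity counts tree edges to the lowest common ancestor: 0 is a"
    "\ncorrect call, 1 a within-branch confusion, 2 a cross-branch one."
)
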