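"""Building a label taxonomy straight from hierarchical code strings.

Medical codes such as ICD-10 encode their own hierarchy in their prefixes:
J18.9 sits under J18, which sits under the J block of respiratory disease.
Given a list of codes and the prefix lengths that define the levels, the
tree — and with it the whole severity machinery — comes for free.
"""

from soe import build_from_codes, cost_matrix, sample_severity

codes = ["J12", "J12.0", "J12.1", "J18", "J18.9", "K50", "K50.1"]
tree = build_from_codes(codes, level_cutpoints=[1, 3, 5])

print("nodes:", ", ".join(sorted(tree.nodes)))
print("labels (the input codes):", ", ".join(tree.labels))
print(f"tree height: {tree.height()}\n")

cm = cost_matrix(tree)
for pred, truth in [("J12.0", "J12.1"), ("J12.0", "J18.9"), ("J12.0", "K50.1")]:
    print(f"predict {pred} for {truth}: severity {sample_severity(cm, pred, truth):.0f}")

print(
    "\nSibling codes under J12 cost 1; J12-vs-J18 confusions meet at the J"
    "\nblock; respiratory-vs-digestive confusions meet only at the root."
)
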