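"""Charge-position similarity clustering restricted to a functional face.

Builds a two-lineage synthetic alignment (one group with a fully conserved
charge pattern at 12 face positions, one with its own partially scrambled
pattern), counts like-charge positions (both K/R or both D/E) per pair over
those columns, clusters with complete linkage, and prints the top split.
"""

from esimap import hcluster, make_conservation_groups, pairwise_charge_similarity

face_columns = list(range(1, 13))
aln, groups = make_conservation_groups(
    n_group1=6, n_group2=6, face_columns=face_columns, seed=3, n_residues=24)

matrix = pairwise_charge_similarity(aln, columns=[c - 1 for c in face_columns])
print("like-charge position counts (first 4 sequences):")
print(matrix.to_frame().iloc[:4, :4].to_string())

dend = hcluster(matrix)
cut = dend.cut(2)
for cluster_id in sorted(set(cut.values())):
    labels = sorted(l for l, c in cut.items() if c == cluster_id)
    true_groups = sorted({groups[l] for l in labels})
    print(f"top-split cluster {cluster_id}: {labels} (lineage {true_groups})")
print("Newick:", dend.newick())
print("The top split separates the conserved-pattern lineage from the")
print("scrambled one: charge POSITION, not net charge, drives the grouping.")
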