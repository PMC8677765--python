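"""Relate representational clustering to selective-unit counts.

Embeds conv5 responses to the selection images by PCA, computes the
centroid-based silhouette index per class, counts units selective to each
class, and reports the Pearson correlation between class-level silhouette
and selective-unit count.
"""

import numpy as np

import convsel
from convsel.clustering import pca_embed, selectivity_vs_clustering, silhouette_index

CLASSES = ("face", "scrambled_face", "hand", "horn", "flower", "chair")

net = convsel.build_network(convsel.desk_architecture(), convsel.InitConfig(seed=1001))
stim = convsel.generate_stimulus_set(
    convsel.StimulusSpec(n_per_class=130, image_size=127, seed=1)
)
sel = stim.partition("selection")
t5 = convsel.extract_responses(net, sel, layers=["conv5"])[0]

emb = pca_embed(t5.values)
_, per_class_si = silhouette_index(emb.embedding, sel.class_labels, mode="paper")
counts = {
    c: int(convsel.selectivity_frame(t5, sel.class_labels, c)["is_selective"].sum())
    for c in CLASSES
}
print(f"{'class':<16}{'silhouette':>12}{'selective units':>17}")
for c in CLASSES:
    print(f"{c:<16}{per_class_si[c]:>12.3f}{counts[c]:>17}")
r, p = selectivity_vs_clustering(per_class_si, counts)
print(f"\nPearson r(silhouette, count) = {r:.2f} (p = {p:.2f}, n = {len(CLASSES)} classes)")

print(
    "\nClasses that form tighter, better-separated response clusters tend to"
    "\nhave more units selective to them; one network gives a noisy estimate,"
    "\nthe pipeline's multi-network study pools this over seeds."
)
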