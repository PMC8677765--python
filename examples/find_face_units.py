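"""Find face-selective units in one untrained network, layer by layer.

Builds a desk-scale untrained network (quarter-width AlexNet, 127 px input),
generates the six-class synthetic stimulus set, and reports how many units
in each conv layer respond significantly more to faces than to every other
class (two-sided rank-sum, p < 0.001, uncorrected), together with their mean
face-selectivity index (FSI).
"""

import numpy as np

import convsel

net = convsel.build_network(convsel.desk_architecture(), convsel.InitConfig(seed=1001))
stim = convsel.generate_stimulus_set(
    convsel.StimulusSpec(n_per_class=130, image_size=127, seed=1)
)
sel = stim.partition("selection")

tables = convsel.extract_responses(
    net, sel, layers=["conv1", "conv2", "conv3", "conv4", "conv5"]
)
print(f"{'layer':<7}{'units':>8}{'face-selective':>16}{'%':>7}{'mean FSI':>10}")
for t in tables:
    df = convsel.selectivity_frame(t, sel.class_labels, "face")
    hits = df["is_selective"]
    fsi = df.loc[hits, "fsi"].mean() if hits.any() else float("nan")
    print(
        f"{t.layer:<7}{t.n_units:>8}{int(hits.sum()):>16}"
        f"{100 * hits.mean():>7.2f}{fsi:>10.2f}"
    )

print(
    "\nEach row: units whose mean response to faces exceeds every non-face"
    "\nclass significantly. A nonzero count in conv5 of an untrained network"
    "\nis the headline phenomenon: face-selective units without any training."
)
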