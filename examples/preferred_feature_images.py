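"""Estimate what a face-selective unit wants to see (reverse correlation).

Iteratively presents Gaussian-bump probes to one face-selective and one
non-selective conv5 unit of an untrained network, accumulates response-
weighted probes into a preferred feature image (PFI), and scores each PFI by
its face-configuration index (FCI): the mean pixel-wise correlation with the
face images used for unit selection.
"""

import numpy as np

import convsel
from convsel.pfi import ProbeConfig, face_configuration_index, reverse_correlation_pfi

net = convsel.build_network(convsel.desk_architecture(), convsel.InitConfig(seed=1001))
stim = convsel.generate_stimulus_set(
    convsel.StimulusSpec(n_per_class=130, image_size=127, seed=1)
)
sel_mask = np.asarray([t == "selection" for t in stim.partition_tags])
sel_labels = np.asarray(stim.class_labels)[sel_mask]
refs = stim.images[sel_mask][sel_labels == "face"]

t5 = convsel.extract_responses(net, stim.partition("selection"), layers=["conv5"])[0]
per_class = {
    c: convsel.selectivity_frame(t5, list(sel_labels), c)["is_selective"].to_numpy()
    for c in ("face", "scrambled_face", "hand", "horn", "flower", "chair")
}
face_pool = np.flatnonzero(per_class["face"])
none_pool = np.flatnonzero(~np.any(np.stack(list(per_class.values())), axis=0))

def central_units(pool, k=3):
    # prefer units whose spatial position is nearest the map center
    order = t5.unit_order[pool]
    center = order[:, 1:].astype(float) - order[:, 1:].mean(axis=0)
    return pool[np.argsort((center ** 2).sum(axis=1))[:k]]


cfg = ProbeConfig(n_probes=150, n_iterations=15, seed=7)
for name, pool in (("face-selective", face_pool), ("non-selective", none_pool)):
    fcis = []
    for j in central_units(pool):
        unit = t5.unit_index(int(j))
        res = reverse_correlation_pfi(net, unit, cfg)
        fci = face_configuration_index(res.image, refs)
        fcis.append(fci)
        print(
            f"{name:<15} unit (ch {unit.channel:3d}, {unit.row},{unit.col}): "
            f"FCI = {fci:+.3f}, mean response {res.response_trace[0]:.3f} -> "
            f"{res.response_trace[-1]:.3f}"
        )
    print(f"{name:<15} group mean FCI = {np.nanmean(fcis):+.3f}\n")

print(
    "A positive FCI means the estimated preferred image shares the spatial"
    "\nconfiguration of the face stimuli. Single-unit estimates at this"
    "\nprobe budget are noisy; the pipeline's multi-network study pools"
    "\ndozens of units per group to test the face-selective > non-selective"
    "\ncontrast."
)
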