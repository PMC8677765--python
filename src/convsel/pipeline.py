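"""End-to-end experiment orchestration.

A run is described by a YAML/dict config with four sections (network,
stimulus, analysis, seed).  The master seed deterministically derives every
module seed (seed + fixed per-purpose offsets, plus the network index), so
re-running an identical config reproduces all numeric outputs bit-for-bit.
Each run writes a manifest (config hash + package version), per-stage CSV
tables and a JSON summary into its output directory.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import clustering as _clustering
from . import detection as _detection
from . import invariance as _invariance
from . import pfi as _pfi
from .net import (
    ArchitectureSpec,
    InitConfig,
    build_network,
    default_architecture,
    desk_architecture,
    extract_responses,
)
from .selectivity import SelectionConfig, fsi_table, selectivity_frame
from .stimuli import StimulusSpec, generate_stimulus_set, generate_viewpoint_set

__all__ = ["RunConfig", "run_experiment", "summarize_runs", "PRESETS"]

# seed derivation offsets (master seed + offset [+ network index])
_SEED_STIMULI = 1
_SEED_DETECTION = 2
_SEED_VIEWPOINT = 3
_SEED_NETWORK = 1000  # + network index
_SEED_PFI = 5000  # + network index

PRESETS: dict[str, dict] = {
    # full protocol: AlexNet geometry, 6 classes x 260 images, 100 networks
    "paper": {
        "network": {"arch": "alexnet", "n_networks": 100},
        "stimulus": {"n_per_class": 260, "image_size": 227},
        "analysis": {
            "layers": ["conv1", "conv2", "conv3", "conv4", "conv5"],
            "selection": {"alpha": 0.001},
            "detection": {"enabled": True, "unit_counts": [50], "n_trials": 100},
            "clustering": {"enabled": True, "mode": "paper"},
            "pfi": {"enabled": False},
            "invariance": {"enabled": False},
        },
    },
    # one-CPU scale: quarter-width network, smaller canvas and set
    "desk": {
        "network": {"arch": "desk", "n_networks": 10},
        "stimulus": {"n_per_class": 130, "image_size": 127},
        "analysis": {
            "layers": ["conv1", "conv2", "conv3", "conv4", "conv5"],
            "selection": {"alpha": 0.001},
            "detection": {"enabled": True, "unit_counts": [20], "n_trials": 30},
            "clustering": {"enabled": True, "mode": "paper"},
            "pfi": {"enabled": False},
            "invariance": {"enabled": False},
        },
    },
}

_KNOWN = {
    "network": {"arch", "n_networks", "init", "input_size", "channel_scale", "lrn"},
    "network.init": {"distribution", "scale_percent", "zero_bias"},
    "stimulus": {
        "classes", "n_per_class", "image_size", "background", "luminance_target",
        "contrast_target", "object_fraction",
    },
    "analysis": {"layers", "selection", "detection", "clustering", "pfi", "invariance"},
    "analysis.selection": {"alpha", "nonface_pool"},
    "analysis.detection": {"enabled", "unit_counts", "n_trials", "populations"},
    "analysis.clustering": {"enabled", "mode", "n_components"},
    "analysis.pfi": {"enabled", "n_probes", "n_iterations", "units_per_group", "networks"},
    "analysis.invariance": {"enabled", "n_identities", "alpha", "max_units"},
}


class ConfigError(ValueError):
    pass


def _check_keys(d: Mapping, scope: str) -> None:
    known = _KNOWN.get(scope)
    if known is None:
        return
    for k in d:
        if k not in known:
            raise ConfigError(f"unknown key {k!r} in config section {scope!r}")
        if isinstance(d[k], Mapping):
            _check_keys(d[k], f"{scope}.{k}")


@dataclass
class RunConfig:
    """Validated experiment configuration."""

    network: dict
    stimulus: dict
    analysis: dict
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], preset: str | None = None) -> "RunConfig":
        base: dict = copy.deepcopy(PRESETS[preset]) if preset else {
            "network": {}, "stimulus": {}, "analysis": {},
        }
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        for section in raw:
            if section not in ("network", "stimulus", "analysis"):
                raise ConfigError(f"unknown config section {section!r}")
            _merge(base[section], raw[section])
        for section in ("network", "stimulus", "analysis"):
            _check_keys(base[section], section)
        return cls(
            network=base["network"], stimulus=base["stimulus"],
            analysis=base["analysis"], seed=seed,
        )

    @classmethod
    def from_yaml(cls, path, preset: str | None = None) -> "RunConfig":
        import yaml

        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw, preset=preset)

    def to_dict(self) -> dict:
        return {
            "network": self.network, "stimulus": self.stimulus,
            "analysis": self.analysis, "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- resolved pieces -------------------------------------------------

    def architecture(self) -> ArchitectureSpec:
        arch = self.network.get("arch", "desk")
        size = self.network.get("input_size")
        if arch == "alexnet":
            return default_architecture(
                lrn=self.network.get("lrn", False), input_size=size or 227,
                channel_scale=self.network.get("channel_scale", 1.0),
            )
        if arch == "desk":
            return desk_architecture(input_size=size or 127)
        raise ConfigError(f"unknown architecture {arch!r}")

    def init_config(self, net_index: int) -> InitConfig:
        init = self.network.get("init", {})
        return InitConfig(
            distribution=init.get("distribution", "gaussian"),
            scale_percent=init.get("scale_percent", 100.0),
            seed=self.seed + _SEED_NETWORK + net_index,
            zero_bias=init.get("zero_bias", False),
        )

    def stimulus_spec(self) -> StimulusSpec:
        s = dict(self.stimulus)
        s.setdefault("image_size", self.architecture().input_shape[0])
        return StimulusSpec(seed=self.seed + _SEED_STIMULI, **s)


def _merge(base: dict, extra: Mapping) -> None:
    for k, v in extra.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = copy.deepcopy(v)


# ---------------------------------------------------------------------------


def run_experiment(config: RunConfig | Mapping, outdir) -> str:
    """Execute the configured pipeline; returns the run directory path.

    Stage order: stimuli -> responses -> selectivity -> (optional)
    detection / clustering / pfi / invariance.  A stage failure is recorded
    in the manifest and later stages that do not depend on it still run.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    os.makedirs(outdir, exist_ok=True)
    from . import __version__

    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "stages": {},
    }
    arch = config.architecture()
    n_networks = int(config.network.get("n_networks", 1))
    analysis = config.analysis
    sel_cfg = SelectionConfig(
        alpha=analysis.get("selection", {}).get("alpha", 0.001),
        seed=config.seed,
    )
    layers = analysis.get("layers", ["conv5"])
    spec = config.stimulus_spec()
    stim = generate_stimulus_set(spec)
    classes = list(spec.classes)
    manifest["stages"]["stimuli"] = {"status": "ok", "n_images": len(stim)}

    sel_stim = stim.partition("selection")
    sel_labels = sel_stim.class_labels

    layer_rows, unit_frames, det_frames, clust_rows, pfi_rows, inv_rows = (
        [], [], [], [], [], []
    )
    fci_refs = sel_stim.images[np.asarray(sel_stim.class_labels) == "face"]

    for i in range(n_networks):
        net = build_network(arch, config.init_config(i))
        tables = extract_responses(net, stim, layers=layers)
        by_layer = {t.layer: t for t in tables}
        sel_idx = np.asarray(
            [t == "selection" for t in stim.partition_tags]
        )
        # selectivity in every requested layer (selection partition only)
        per_class_sel_conv5: dict[str, np.ndarray] = {}
        final = layers[-1]
        for lname in layers:
            t = by_layer[lname]
            tsel = type(t)(
                layer=t.layer, values=t.values[sel_idx], unit_order=t.unit_order,
                stimulus_ids=[s for s, m in zip(t.stimulus_ids, sel_idx) if m],
            )
            for cls in classes:
                df = selectivity_frame(tsel, sel_labels, cls, sel_cfg)
                hits = df["is_selective"].to_numpy()
                if lname == final:
                    per_class_sel_conv5[cls] = hits
                layer_rows.append(
                    {
                        "network": i, "layer": lname, "target_class": cls,
                        "n_units": t.n_units, "n_selective": int(hits.sum()),
                        "pct_selective": 100.0 * hits.sum() / t.n_units,
                        "fsi_mean": float(df.loc[hits, "fsi"].mean()) if hits.any() else np.nan,
                    }
                )
                if cls == "face" and lname == final:
                    sub = df[df["is_selective"]].copy()
                    sub.insert(0, "network", i)
                    sub.insert(1, "layer", lname)
                    unit_frames.append(sub)
        det_cfg_raw = analysis.get("detection", {})
        if det_cfg_raw.get("enabled", False):
            try:
                for pop in det_cfg_raw.get(
                    "populations", ["face_selective", "shuffled_control"]
                ):
                    pool_sizes = _detection.unit_populations(
                        per_class_sel_conv5, by_layer[final].n_units
                    )
                    counts = [
                        n for n in det_cfg_raw.get("unit_counts", [20])
                        if n <= pool_sizes[pop].size
                    ]
                    if not counts:
                        continue
                    dcfg = _detection.DetectionConfig(
                        unit_counts=tuple(counts),
                        n_trials=det_cfg_raw.get("n_trials", 30),
                        population=pop,
                        seed=config.seed + _SEED_DETECTION + i,
                    )
                    res = _detection.detection_experiment(
                        by_layer[final], stim, per_class_sel_conv5, dcfg
                    )
                    acc = res.accuracy.copy()
                    acc.insert(0, "network", i)
                    det_frames.append(acc)
                manifest["stages"]["detection"] = {"status": "ok"}
            except Exception as e:  # recorded, pipeline continues
                manifest["stages"]["detection"] = {"status": "error", "error": str(e)}
        clust_raw = analysis.get("clustering", {})
        if clust_raw.get("enabled", False):
            try:
                t = by_layer[final]
                emb = _clustering.pca_embed(
                    t.values[sel_idx], clust_raw.get("n_components")
                )
                si, per_class = _clustering.silhouette_index(
                    emb.embedding, sel_labels, mode=clust_raw.get("mode", "paper")
                )
                counts = {c: int(per_class_sel_conv5[c].sum()) for c in classes}
                r, p = _clustering.selectivity_vs_clustering(per_class, counts)
                for c in classes:
                    clust_rows.append(
                        {
                            "network": i, "class": c, "si": per_class[c],
                            "n_selective": counts[c], "pearson_r": r, "pearson_p": p,
                        }
                    )
                manifest["stages"]["clustering"] = {"status": "ok"}
            except Exception as e:
                manifest["stages"]["clustering"] = {"status": "error", "error": str(e)}
        pfi_raw = analysis.get("pfi", {})
        if pfi_raw.get("enabled", False) and i < pfi_raw.get("networks", 3):
            try:
                pcfg = _pfi.ProbeConfig(
                    n_probes=pfi_raw.get("n_probes", 150),
                    n_iterations=pfi_raw.get("n_iterations", 10),
                    seed=config.seed + _SEED_PFI + i,
                )
                k = pfi_raw.get("units_per_group", 3)
                rng = np.random.default_rng(config.seed + _SEED_PFI + i)
                t = by_layer[final]
                face_pool = np.flatnonzero(per_class_sel_conv5["face"])
                any_sel = np.zeros(t.n_units, dtype=bool)
                for m in per_class_sel_conv5.values():
                    any_sel |= m
                none_pool = np.flatnonzero(~any_sel)
                for group, pool in (("face_selective", face_pool), ("non_selective", none_pool)):
                    if pool.size == 0:
                        continue
                    chosen = rng.choice(pool, size=min(k, pool.size), replace=False)
                    for j in chosen:
                        res = _pfi.reverse_correlation_pfi(net, t.unit_index(int(j)), pcfg)
                        fci = _pfi.face_configuration_index(res.image, fci_refs)
                        pfi_rows.append(
                            {
                                "network": i, "group": group, "unit": int(j),
                                "fci": fci, "degenerate": res.degenerate,
                                "final_response": float(res.response_trace[-1]),
                            }
                        )
                manifest["stages"]["pfi"] = {"status": "ok"}
            except Exception as e:
                manifest["stages"]["pfi"] = {"status": "error", "error": str(e)}
        inv_raw = analysis.get("invariance", {})
        if inv_raw.get("enabled", False):
            try:
                vp = generate_viewpoint_set(
                    n_identities=inv_raw.get("n_identities", 10),
                    seed=config.seed + _SEED_VIEWPOINT,
                    image_size=arch.input_shape[0],
                )
                vt = extract_responses(net, vp, layers=[final])[0]
                face_cols = np.flatnonzero(per_class_sel_conv5["face"])
                max_units = inv_raw.get("max_units", 200)
                if face_cols.size > max_units:
                    face_cols = face_cols[:max_units]
                sub = type(vt)(
                    layer=vt.layer, values=vt.values[:, face_cols],
                    unit_order=vt.unit_order[face_cols], stimulus_ids=vt.stimulus_ids,
                )
                tunings = _invariance.classify_viewpoint_units(
                    sub, vp.class_labels, alpha=inv_raw.get("alpha", 0.05)
                )
                for tu in tunings:
                    inv_rows.append(
                        {
                            "network": i, "channel": tu.unit.channel,
                            "row": tu.unit.row, "col": tu.unit.col,
                            "category": tu.category, "anova_p": tu.anova_p,
                            "invariance_index": tu.invariance_index,
                        }
                    )
                manifest["stages"]["invariance"] = {"status": "ok"}
            except Exception as e:
                manifest["stages"]["invariance"] = {"status": "error", "error": str(e)}

    pd.DataFrame(layer_rows).to_csv(os.path.join(outdir, "selectivity_layerwise.csv"), index=False)
    if unit_frames:
        pd.concat(unit_frames, ignore_index=True).to_csv(
            os.path.join(outdir, "face_units.csv"), index=False
        )
    if det_frames:
        pd.concat(det_frames, ignore_index=True).to_csv(
            os.path.join(outdir, "detection.csv"), index=False
        )
    if clust_rows:
        pd.DataFrame(clust_rows).to_csv(os.path.join(outdir, "clustering.csv"), index=False)
    if pfi_rows:
        pd.DataFrame(pfi_rows).to_csv(os.path.join(outdir, "pfi_fci.csv"), index=False)
    if inv_rows:
        pd.DataFrame(inv_rows).to_csv(os.path.join(outdir, "viewpoint_tuning.csv"), index=False)
    manifest["stages"].setdefault("selectivity", {"status": "ok"})
    with open(os.path.join(outdir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return str(outdir)


def desk_study(
    seed: int = 0,
    n_networks: int = 10,
    n_per_class: int = 130,
    image_size: int = 127,
    unit_count: int = 20,
    n_trials: int = 30,
    pfi_networks: int = 5,
    pfi_units_per_group: int = 7,
    pfi_probes: int = 150,
    pfi_iterations: int = 10,
) -> dict:
    """The desk-scale replication study: several untrained quarter-width
    networks analysed end to end on one synthetic stimulus set.

    Returns pooled quantities: per-layer face-selective fractions, decoding
    accuracy of face-selective units vs. the shuffled control, the
    face-configuration index of face-unit vs. non-selective-unit PFIs, and
    the class-level silhouette/selectivity correlation.
    """
    from .pfi import ProbeConfig, face_configuration_index, reverse_correlation_pfi
    from .selectivity import rank_sum_test

    arch = desk_architecture(input_size=image_size)
    spec = StimulusSpec(n_per_class=n_per_class, image_size=image_size, seed=seed + _SEED_STIMULI)
    stim = generate_stimulus_set(spec)
    classes = list(spec.classes)
    sel_idx = np.asarray([t == "selection" for t in stim.partition_tags])
    sel_labels = [l for l, m in zip(stim.class_labels, sel_idx) if m]
    fci_refs = stim.images[sel_idx][np.asarray(sel_labels) == "face"]
    layers = ["conv1", "conv2", "conv3", "conv4", "conv5"]
    sel_cfg = SelectionConfig()

    layer_counts = {l: [0, 0] for l in layers}  # [selective, total]
    det_rows, fci_face, fci_none = [], [], []
    si_per_class = {c: [] for c in classes}
    counts_per_class = {c: [] for c in classes}
    from . import clustering as _cl

    for i in range(n_networks):
        net = build_network(arch, InitConfig(seed=seed + _SEED_NETWORK + i))
        tables = extract_responses(net, stim, layers=layers)
        by_layer = {t.layer: t for t in tables}
        per_class_sel: dict[str, np.ndarray] = {}
        for lname in layers:
            t = by_layer[lname]
            tsel = type(t)(
                layer=lname, values=t.values[sel_idx], unit_order=t.unit_order,
                stimulus_ids=[s for s, m in zip(t.stimulus_ids, sel_idx) if m],
            )
            df = selectivity_frame(tsel, sel_labels, "face", sel_cfg)
            hits = df["is_selective"].to_numpy()
            layer_counts[lname][0] += int(hits.sum())
            layer_counts[lname][1] += t.n_units
            if lname == "conv5":
                per_class_sel["face"] = hits
                tsel5 = tsel
        for c in classes:
            if c == "face":
                continue
            per_class_sel[c] = selectivity_frame(tsel5, sel_labels, c, sel_cfg)[
                "is_selective"
            ].to_numpy()
        t5 = by_layer["conv5"]
        for pop in ("face_selective", "shuffled_control"):
            pools = _detection.unit_populations(per_class_sel, t5.n_units)
            if pools[pop].size < unit_count:
                continue
            dcfg = _detection.DetectionConfig(
                unit_counts=(unit_count,), n_trials=n_trials, population=pop,
                seed=seed + _SEED_DETECTION + i,
            )
            acc = _detection.detection_experiment(t5, stim, per_class_sel, dcfg).accuracy
            acc.insert(0, "network", i)
            det_rows.append(acc)
        emb = _cl.pca_embed(t5.values[sel_idx])
        _, per_class_si = _cl.silhouette_index(emb.embedding, sel_labels, mode="paper")
        for c in classes:
            si_per_class[c].append(per_class_si[c])
            counts_per_class[c].append(int(per_class_sel[c].sum()))
        if i < pfi_networks:
            pcfg = ProbeConfig(
                n_probes=pfi_probes, n_iterations=pfi_iterations,
                seed=seed + _SEED_PFI + i,
            )
            rng = np.random.default_rng(seed + _SEED_PFI + i)
            any_sel = np.zeros(t5.n_units, dtype=bool)
            for m in per_class_sel.values():
                any_sel |= m
            for sink, pool in (
                (fci_face, np.flatnonzero(per_class_sel["face"])),
                (fci_none, np.flatnonzero(~any_sel)),
            ):
                if pool.size == 0:
                    continue
                chosen = rng.choice(pool, size=min(pfi_units_per_group, pool.size), replace=False)
                for j in chosen:
                    res = reverse_correlation_pfi(net, t5.unit_index(int(j)), pcfg)
                    if res.degenerate:
                        continue
                    fci = face_configuration_index(res.image, fci_refs)
                    if np.isfinite(fci):
                        sink.append(fci)

    det = pd.concat(det_rows, ignore_index=True)
    face_acc = det[det["population"] == "face_selective"]["accuracy"]
    shuf_acc = det[det["population"] == "shuffled_control"]["accuracy"]
    frac = {l: layer_counts[l][0] / layer_counts[l][1] for l in layers}
    deep = sum(layer_counts[l][0] for l in ("conv3", "conv4", "conv5")) / sum(
        layer_counts[l][1] for l in ("conv3", "conv4", "conv5")
    )
    early = sum(layer_counts[l][0] for l in ("conv1", "conv2")) / sum(
        layer_counts[l][1] for l in ("conv1", "conv2")
    )
    mean_si = {c: float(np.mean(v)) for c, v in si_per_class.items()}
    mean_counts = {c: int(round(np.mean(v))) for c, v in counts_per_class.items()}
    r, p = _clustering.selectivity_vs_clustering(mean_si, mean_counts)
    fci_p = (
        rank_sum_test(fci_face, fci_none, sidedness="greater")
        if fci_face and fci_none
        else float("nan")
    )
    return {
        "layer_fraction": frac,
        "deep_fraction": float(deep),
        "early_fraction": float(early),
        "face_acc_mean": float(face_acc.mean()),
        "face_acc_sd": float(face_acc.std(ddof=1)),
        "shuffled_acc_mean": float(shuf_acc.mean()),
        "shuffled_acc_sd": float(shuf_acc.std(ddof=1)),
        "fci_face": [float(v) for v in fci_face],
        "fci_nonselective": [float(v) for v in fci_none],
        "fci_face_mean": float(np.mean(fci_face)) if fci_face else float("nan"),
        "fci_nonselective_mean": float(np.mean(fci_none)) if fci_none else float("nan"),
        "fci_rank_sum_p": float(fci_p),
        "si_per_class": mean_si,
        "counts_per_class": mean_counts,
        "si_count_pearson_r": float(r),
        "si_count_pearson_p": float(p),
        "n_networks": n_networks,
    }


def summarize_runs(run_dirs: Sequence) -> dict:
    """Across-run aggregate: mean +- sd of face-unit counts, FSI and accuracy."""
    if len(run_dirs) == 0:
        raise ValueError("need at least one completed run")
    hashes, counts, fsis, accs = set(), [], [], []
    for d in run_dirs:
        with open(os.path.join(d, "manifest.json")) as f:
            m = json.load(f)
        hashes.add(m["config_hash"])
        lw = pd.read_csv(os.path.join(d, "selectivity_layerwise.csv"))
        face_final = lw[(lw["target_class"] == "face")]
        final_layer = face_final["layer"].iloc[-1]
        per_net = face_final[face_final["layer"] == final_layer].groupby("network")
        counts.extend(per_net["n_selective"].sum().tolist())
        fsis.extend(face_final[face_final["layer"] == final_layer]["fsi_mean"].dropna().tolist())
        det_path = os.path.join(d, "detection.csv")
        if os.path.exists(det_path):
            det = pd.read_csv(det_path)
            sel = det[det["population"] == "face_selective"]
            if len(sel):
                accs.extend(sel.groupby("network")["accuracy"].mean().tolist())
    if len(hashes) > 1:
        raise ValueError(f"incompatible configs across runs: {sorted(hashes)}")

    def ms(v):
        a = np.asarray(v, dtype=float)
        return {
            "mean": float(a.mean()) if a.size else float("nan"),
            "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0,
            "n": int(a.size),
        }

    return {
        "face_unit_count": ms(counts),
        "face_unit_fsi": ms(fsis),
        "detection_accuracy": ms(accs),
        "n_runs": len(run_dirs),
    }
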