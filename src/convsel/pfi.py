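"""Preferred feature images by iterative reverse correlation.

The classical reverse-correlation estimate of a unit's preferred input is the
response-weighted average of random probe stimuli.  Here the probes are
bright or dark 2D Gaussian blobs at uniformly random positions on a neutral
gray canvas; each iteration superimposes fresh probes on the current
preferred-feature image (PFI), accumulates response-weighted probe deviations
(responses are mean-centered within the batch to remove the DC bias of the
always-positive ReLU outputs), and renormalizes the PFI to zero mean and
fixed RMS.  For a linear(ized) unit this recovers the unit's filter up to
scale; iterating sharpens the estimate for deeper nonlinear units.

The face-configuration index (FCI) of a PFI is its mean pixel-wise Pearson
correlation with a reference set of face images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .net import NetworkModel, UnitIndex, unit_responses

__all__ = [
    "ProbeConfig",
    "PFIResult",
    "make_probe_stimuli",
    "reverse_correlation_pfi",
    "face_configuration_index",
]


@dataclass(frozen=True)
class ProbeConfig:
    n_probes: int = 2500
    sigma_px: tuple[float, float] = (4.0, 16.0)
    amplitude: float = 0.25  # of the dynamic range; sign equiprobable
    n_iterations: int = 100
    mix_gain: float = 1.0  # weight of accumulated PFI when building probes
    pfi_rms: float = 0.12  # fixed RMS of the renormalized PFI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 100:
            raise ValueError("n_probes must be >= 100")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PFIResult:
    image: np.ndarray  # (H, W) float, zero-mean
    response_trace: np.ndarray  # mean response per iteration
    unit: UnitIndex | None
    degenerate: bool  # unit never rose above zero in any iteration


def _gaussian_bumps(
    size: int, n: int, cfg: ProbeConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n, size, size) signed Gaussian bumps on a zero canvas."""
    ys = rng.uniform(0, size, n)
    xs = rng.uniform(0, size, n)
    sig = rng.uniform(cfg.sigma_px[0], cfg.sigma_px[1], n)
    sign = rng.choice([-1.0, 1.0], n)
    grid = np.arange(size, dtype=np.float32)
    out = np.empty((n, size, size), dtype=np.float32)
    for i in range(n):
        gy = np.exp(-0.5 * ((grid - ys[i]) / sig[i]) ** 2)
        gx = np.exp(-0.5 * ((grid - xs[i]) / sig[i]) ** 2)
        out[i] = (sign[i] * cfg.amplitude) * gy[:, None] * gx[None, :]
    return out


def make_probe_stimuli(
    cfg: ProbeConfig,
    size: int,
    base: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probe batch and the bare bumps.

    Each probe is (base if given else neutral gray 0.5) + one signed Gaussian
    bump at a uniform random position, clipped to [0, 1].  Returns
    (probes (n, size, size), bumps (n, size, size)).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    bumps = _gaussian_bumps(size, cfg.n_probes, cfg, rng)
    canvas = np.full((size, size), 0.5, dtype=np.float32) if base is None else base.astype(np.float32)
    probes = np.clip(canvas[None] + bumps, 0.0, 1.0)
    return probes, bumps


def reverse_correlation_pfi(
    net: NetworkModel,
    unit: UnitIndex,
    cfg: ProbeConfig = ProbeConfig(),
) -> PFIResult:
    """Iterative reverse-correlation PFI of one unit.

    Iteration k presents probes built on the current PFI, accumulates
    (response - batch mean) * bump into the PFI and renormalizes it to zero
    mean and cfg.pfi_rms.  A unit that never responds above zero in any
    iteration is returned flagged degenerate with a flat PFI.
    """
    size = net.spec.input_shape[0]
    rng = np.random.default_rng(cfg.seed)
    pfi = np.zeros((size, size), dtype=np.float32)
    trace = np.zeros(cfg.n_iterations)
    ever_responded = False
    for it in range(cfg.n_iterations):
        base = np.clip(0.5 + cfg.mix_gain * pfi, 0.0, 1.0)
        probes, bumps = make_probe_stimuli(cfg, size, base=base, rng=rng)
        resp = unit_responses(net, probes, unit)
        trace[it] = resp.mean()
        if np.all(resp <= 0):
            continue  # nothing to accumulate this round
        ever_responded = True
        w = resp - resp.mean()
        delta = np.tensordot(w.astype(np.float32), bumps, axes=(0, 0)) / len(resp)
        pfi = pfi + delta
        pfi -= pfi.mean()
        rms = np.sqrt((pfi**2).mean())
        if rms > 0:
            pfi *= cfg.pfi_rms / rms
    return PFIResult(
        image=pfi, response_trace=trace, unit=unit, degenerate=not ever_responded
    )


def face_configuration_index(
    pfi: np.ndarray, reference_images: Sequence[np.ndarray]
) -> float:
    """Mean pixel-wise Pearson correlation between a PFI and reference faces.

    The PFI is bilinearly resampled to the reference resolution when needed.
    Returns NaN for a constant PFI (correlation undefined).
    """
    refs = [np.asarray(r, dtype=np.float64) for r in reference_images]
    if len(refs) == 0:
        raise ValueError("need at least one reference image")
    p = np.asarray(pfi, dtype=np.float64)
    if p.shape != refs[0].shape:
        from skimage.transform import resize

        p = resize(p, refs[0].shape, order=1, preserve_range=True)
    pv = p.ravel() - p.mean()
    pn = np.sqrt((pv**2).sum())
    if pn == 0:
        return float("nan")
    cors = []
    for r in refs:
        rv = r.ravel() - r.mean()
        rn = np.sqrt((rv**2).sum())
        if rn == 0:
            cors.append(np.nan)
            continue
        cors.append(float(pv @ rv / (pn * rn)))
    return float(np.nanmean(cors))
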