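"""Similarity-controlled synthetic stimulus sets.

Generates grayscale square images, each containing one schematic foreground
object (face, scrambled face, hand, horn, flower, chair by default) overlaid
on a phase-scrambled background, with luminance, RMS contrast, object size
and position matched across classes.  Faces are parametric schematics (head
ellipse, eyes, nose, mouth with seeded geometry), not photographs; the other
classes are distinct parametric silhouettes.  Scrambled faces are produced by
patch-scrambling face exemplars, and a windowed phase scramble provides a
local-texture control that preserves local statistics while destroying the
global configuration.

A viewpoint renderer produces five head-yaw classes (-90, -45, 0, 45, 90
degrees) for several identities; by construction the -theta image is the
exact horizontal mirror of the +theta image of the same identity.

Sets are plain in-memory arrays plus pandas metadata, and round-trip to a
directory of PNGs with a CSV manifest (the same layout accepts user-supplied
real images).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.fft import fft2, ifft2
from skimage import draw as skdraw
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "StimulusSpec",
    "StimulusSet",
    "DEFAULT_CLASSES",
    "generate_exemplar",
    "phase_scramble",
    "patch_scramble",
    "local_texture_scramble",
    "transform_object",
    "generate_viewpoint_set",
    "generate_stimulus_set",
    "generate_transform_sweep",
    "registered_classes",
]

DEFAULT_CLASSES = ("face", "scrambled_face", "hand", "horn", "flower", "chair")

# partition ratio follows the 200/40/20 protocol (selection / train / test)
_PARTITION_RATIO = (200, 40, 20)

# graded within-class geometric variability (jitter multiplier per class).
# Grades run inversely to each schematic class's intrinsic feature
# distinctiveness, so that class separability in response space spans a wide
# range: highly distinctive classes (flower's radial configuration, the face
# configuration) are also geometrically consistent, weakly distinctive ones
# (horn, scrambled face) are not -- emulating photograph sets whose classes
# differ in intra-class image similarity.
_DEFAULT_VARIABILITY = {
    "face": 0.7,
    "scrambled_face": 1.1,
    "hand": 1.2,
    "chair": 0.8,
    "horn": 1.3,
    "flower": 0.5,
}

_CANVAS = 160  # internal drawing resolution before size normalization


@dataclass(frozen=True)
class StimulusSpec:
    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_per_class: int = 260
    image_size: int = 227
    background: str = "phase_scrambled"  # or "uniform"
    luminance_target: float = 0.5
    contrast_target: float = 0.18
    seed: int = 0
    object_fraction: float = 0.48  # sqrt(bbox area) / image size
    jitter_scale: float = 0.08
    jitter_offset_frac: float = 0.05  # of image size
    jitter_rotation_deg: float = 8.0
    class_variability: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        if self.n_per_class < 10:
            raise ValueError("n_per_class must be >= 10")
        if self.background not in ("phase_scrambled", "uniform"):
            raise ValueError(f"unknown background {self.background!r}")

    def variability(self, class_name: str) -> float:
        """Within-class geometric-variability multiplier.

        Classes are graded by construction (faces are the most consistent
        class, flowers the least), emulating stimulus sets whose classes
        differ in intra-class image similarity; the multiplier scales the
        per-image scale/position/rotation jitter.
        """
        if self.class_variability is not None:
            return float(self.class_variability.get(class_name, 1.0))
        return _DEFAULT_VARIABILITY.get(class_name, 1.0)

    def partition_sizes(self) -> tuple[int, int, int]:
        """Proportional 200:40:20 split of n_per_class (selection, train, test)."""
        total = sum(_PARTITION_RATIO)
        n_sel = round(self.n_per_class * _PARTITION_RATIO[0] / total)
        n_train = round(self.n_per_class * _PARTITION_RATIO[1] / total)
        n_test = self.n_per_class - n_sel - n_train
        if min(n_sel, n_train, n_test) < 1:
            raise ValueError("n_per_class too small for a proportional split")
        return n_sel, n_train, n_test


@dataclass
class StimulusSet:
    """Images + labels + partition tags + per-image transform metadata."""

    images: np.ndarray  # (N, H, W) float32 in [0, 1]
    class_labels: list[str]
    partition_tags: list[str]  # selection | train | test
    transform_meta: pd.DataFrame  # scale, dx, dy, rotation, yaw, identity
    stimulus_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.class_labels) == len(self.partition_tags) == n == len(self.stimulus_ids)):
            raise ValueError("inconsistent set lengths")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, mask: np.ndarray) -> "StimulusSet":
        idx = np.flatnonzero(mask)
        return StimulusSet(
            images=self.images[idx],
            class_labels=[self.class_labels[i] for i in idx],
            partition_tags=[self.partition_tags[i] for i in idx],
            transform_meta=self.transform_meta.iloc[idx].reset_index(drop=True),
            stimulus_ids=[self.stimulus_ids[i] for i in idx],
        )

    def partition(self, tag: str) -> "StimulusSet":
        return self.subset(np.asarray([t == tag for t in self.partition_tags]))

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.class_labels)

    def save_dir(self, path) -> None:
        from PIL import Image

        os.makedirs(path, exist_ok=True)
        rows = []
        for i, sid in enumerate(self.stimulus_ids):
            fname = f"{sid}.png"
            arr = np.clip(self.images[i] * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(os.path.join(path, fname))
            meta = self.transform_meta.iloc[i]
            rows.append(
                {
                    "filename": fname,
                    "class": self.class_labels[i],
                    "partition": self.partition_tags[i],
                    "scale": meta.get("scale", 1.0),
                    "dx": meta.get("dx", 0.0),
                    "dy": meta.get("dy", 0.0),
                    "rotation": meta.get("rotation", 0.0),
                    "yaw": meta.get("yaw", np.nan),
                    "identity": meta.get("identity", -1),
                }
            )
        pd.DataFrame(rows).to_csv(os.path.join(path, "manifest.csv"), index=False)

    @classmethod
    def load_dir(cls, path) -> "StimulusSet":
        from PIL import Image

        manifest = pd.read_csv(os.path.join(path, "manifest.csv"))
        images, ids = [], []
        for fname in manifest["filename"]:
            arr = np.asarray(Image.open(os.path.join(path, fname)).convert("L"), dtype=np.float32)
            images.append(arr / 255.0)
            ids.append(os.path.splitext(fname)[0])
        meta = manifest[["scale", "dx", "dy", "rotation", "yaw", "identity"]].reset_index(drop=True)
        return cls(
            images=np.stack(images),
            class_labels=list(manifest["class"]),
            partition_tags=list(manifest["partition"]),
            transform_meta=meta,
            stimulus_ids=ids,
        )


# ---------------------------------------------------------------------------
# parametric object drawing (value 0 = empty; object pixels in (0, 1])


def _ellipse(canvas, r, c, rr, cc, value, rotation=0.0):
    ys, xs = skdraw.ellipse(r, c, rr, cc, shape=canvas.shape, rotation=rotation)
    canvas[ys, xs] = value


def _rect(canvas, r0, c0, r1, c1, value):
    ys, xs = skdraw.rectangle((int(r0), int(c0)), end=(int(r1), int(c1)), shape=canvas.shape)
    canvas[ys.astype(int), xs.astype(int)] = value


def _draw_face(rng_id: np.random.Generator, rng_var: np.random.Generator, s: int) -> np.ndarray:
    cv = np.zeros((s, s), dtype=np.float32)
    aspect = 1.25 + 0.22 * rng_id.uniform(-1, 1)
    hw = s * (0.30 + 0.03 * rng_id.uniform(-1, 1) + 0.012 * rng_var.uniform(-1, 1))
    hh = hw * aspect
    cy, cx = s * 0.5, s * 0.5
    head_val = 0.74 + 0.14 * rng_id.uniform(-1, 1)
    _ellipse(cv, cy, cx, hh, hw, head_val)
    eye_dy = hh * (0.28 + 0.08 * rng_id.uniform(-1, 1) + 0.02 * rng_var.uniform(-1, 1))
    eye_dx = hw * (0.42 + 0.10 * rng_id.uniform(-1, 1))
    eye_r = s * (0.035 + 0.011 * rng_id.uniform(-1, 1))
    eye_val = 0.18 + 0.08 * rng_id.uniform(-1, 1)
    for sgn in (-1, 1):
        jx = s * 0.008 * rng_var.uniform(-1, 1)
        _ellipse(cv, cy - eye_dy, cx + sgn * eye_dx + jx, eye_r, eye_r * 1.4, eye_val)
    nose_len = hh * (0.30 + 0.05 * rng_id.uniform(-1, 1))
    nose_w = s * (0.016 + 0.005 * rng_id.uniform(-1, 1))
    _ellipse(cv, cy + nose_len * 0.15, cx, nose_len * 0.5, nose_w, 0.5 + 0.1 * rng_id.uniform(-1, 1))
    mouth_dy = hh * (0.55 + 0.06 * rng_id.uniform(-1, 1))
    mouth_w = hw * (0.45 + 0.10 * rng_id.uniform(-1, 1))
    _ellipse(cv, cy + mouth_dy, cx, s * 0.018, mouth_w, 0.25 + 0.08 * rng_id.uniform(-1, 1))
    return cv


def _draw_hand(rng_id, rng_var, s: int) -> np.ndarray:
    cv = np.zeros((s, s), dtype=np.float32)
    palm_val = 0.62 + 0.08 * rng_id.uniform(-1, 1)
    pw = s * (0.17 + 0.02 * rng_id.uniform(-1, 1))
    ph = pw * (1.15 + 0.1 * rng_id.uniform(-1, 1))
    cy, cx = s * 0.62, s * 0.5
    _ellipse(cv, cy, cx, ph, pw, palm_val)
    n_fingers = 5
    base_angles = np.linspace(-0.55, 0.55, n_fingers) + 0.05 * rng_id.uniform(-1, 1)
    for i, a in enumerate(base_angles):
        ln = s * (0.22 + 0.05 * rng_id.uniform(-1, 1) + 0.01 * rng_var.uniform(-1, 1))
        if i in (0, n_fingers - 1):
            ln *= 0.75  # thumb / pinky shorter
        fy = cy - ph * 0.75
        tipy = fy - ln * np.cos(a)
        tipx = cx + (ln + ph * 0.6) * np.sin(a)
        midy, midx = (fy + tipy) / 2, (cx * 0.3 + tipx * 0.7)
        _ellipse(cv, midy, midx, ln * 0.55, s * 0.026, palm_val + 0.05, rotation=-a)
    return cv


def _draw_horn(rng_id, rng_var, s: int) -> np.ndarray:
    cv = np.zeros((s, s), dtype=np.float32)
    val = 0.70 + 0.08 * rng_id.uniform(-1, 1)
    curve = 0.9 + 0.25 * rng_id.uniform(-1, 1)
    base_r = s * (0.045 + 0.008 * rng_id.uniform(-1, 1))
    length = s * (0.52 + 0.05 * rng_id.uniform(-1, 1))
    for sgn in (-1, 1):
        ts = np.linspace(0.0, 1.0, 60)
        jit = 0.02 * rng_var.uniform(-1, 1)
        ys = s * 0.80 - length * ts
        xs = s * 0.5 + sgn * (s * 0.06 + (curve + jit) * s * 0.22 * ts**1.7)
        rs = base_r * (1.0 - 0.85 * ts)
        for y, x, r in zip(ys, xs, rs):
            yy, xx = skdraw.disk((y, x), max(r, 1.2), shape=cv.shape)
            cv[yy, xx] = val
    return cv


def _draw_flower(rng_id, rng_var, s: int) -> np.ndarray:
    cv = np.zeros((s, s), dtype=np.float32)
    n_petals = int(rng_id.integers(6, 10))
    cy, cx = s * 0.5, s * 0.5
    pr = s * (0.17 + 0.02 * rng_id.uniform(-1, 1))
    pw = s * (0.065 + 0.012 * rng_id.uniform(-1, 1))
    petal_val = 0.75 + 0.08 * rng_id.uniform(-1, 1)
    phase = rng_var.uniform(0, 2 * np.pi / n_petals)
    for i in range(n_petals):
        a = 2 * np.pi * i / n_petals + phase
        py = cy + (pr + pw) * np.sin(a)
        px = cx + (pr + pw) * np.cos(a)
        _ellipse(cv, py, px, pw * 1.6, pw, petal_val, rotation=a + np.pi / 2)
    _ellipse(cv, cy, cx, pr * 0.75, pr * 0.75, 0.35 + 0.06 * rng_id.uniform(-1, 1))
    return cv


def _draw_chair(rng_id, rng_var, s: int) -> np.ndarray:
    cv = np.zeros((s, s), dtype=np.float32)
    val = 0.58 + 0.1 * rng_id.uniform(-1, 1)
    seat_y = s * (0.55 + 0.03 * rng_id.uniform(-1, 1))
    seat_h = s * (0.05 + 0.01 * rng_id.uniform(-1, 1))
    left, right = s * 0.28, s * (0.70 + 0.02 * rng_id.uniform(-1, 1))
    back_w = s * (0.045 + 0.01 * rng_id.uniform(-1, 1))
    _rect(cv, s * 0.16, left, seat_y, left + back_w, val + 0.1)  # backrest
    _rect(cv, seat_y, left, seat_y + seat_h, right, val)  # seat
    leg_w = s * (0.032 + 0.006 * rng_id.uniform(-1, 1))
    leg_len = s * (0.26 + 0.02 * rng_var.uniform(-1, 1))
    for x in (left, right - leg_w):
        _rect(cv, seat_y + seat_h, x, seat_y + seat_h + leg_len, x + leg_w, val - 0.08)
    # cross bar between legs
    _rect(cv, seat_y + seat_h + leg_len * 0.6, left, seat_y + seat_h + leg_len * 0.6 + leg_w * 0.8, right, val - 0.05)
    return cv


_GENERATORS: dict[str, Callable] = {
    "face": _draw_face,
    "hand": _draw_hand,
    "horn": _draw_horn,
    "flower": _draw_flower,
    "chair": _draw_chair,
}


def registered_classes() -> list[str]:
    return sorted(_GENERATORS) + ["scrambled_face"]


def _normalize_object_size(layer: np.ndarray, image_size: int, fraction: float) -> np.ndarray:
    """Center the object and scale so sqrt(bbox area) = fraction * image_size."""
    ys, xs = np.nonzero(layer > 0)
    if ys.size == 0:
        raise ValueError("empty object layer")
    crop = layer[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    h, w = crop.shape
    target = fraction * image_size
    f = target / np.sqrt(h * w)
    nh, nw = max(2, int(round(h * f))), max(2, int(round(w * f)))
    crop = resize(crop, (nh, nw), order=1, anti_aliasing=True, preserve_range=True).astype(
        np.float32
    )
    crop[crop < 0.04] = 0.0
    out = np.zeros((image_size, image_size), dtype=np.float32)
    r0 = (image_size - nh) // 2
    c0 = (image_size - nw) // 2
    out[r0 : r0 + nh, c0 : c0 + nw] = crop
    return out


def _texture_field(size: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-std 1/f noise field (natural-image-like spectrum)."""
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    amp = 1.0 / np.sqrt(fx**2 + fy**2 + (1.0 / size) ** 2)
    spec = amp * np.exp(2j * np.pi * rng.random((size, size)))
    field = ifft2(spec).real
    field -= field.mean()
    sd = field.std()
    return (field / sd if sd > 0 else field).astype(np.float32)


def _texturize(layer: np.ndarray, rng: np.random.Generator, amp: float) -> np.ndarray:
    """Add surface texture to the object so its local statistics resemble
    the textured (phase-scrambled) background rather than flat shading."""
    if amp <= 0:
        return layer
    mask = layer > 0
    out = layer.copy()
    field = _texture_field(layer.shape[0], rng)
    out[mask] = np.clip(layer[mask] + amp * field[mask], 0.05, 1.0)
    return out


def generate_exemplar(
    class_name: str,
    identity_seed,
    variation_seed,
    image_size: int = 227,
    object_fraction: float = 0.48,
    scramble_grid: int = 6,
    texture_amp: float = 0.15,
) -> np.ndarray:
    """One foreground object layer (0 = empty), centered, size-normalized.

    identity_seed fixes the shape parameters (the "individual"); variation_seed
    fixes the residual jitter, so novel exemplars of a known identity can be
    produced by changing only variation_seed.  Objects carry a seeded 1/f
    surface texture (texture_amp = its pixel std) so that local patch
    statistics are comparable to the phase-scrambled background.
    """
    if class_name == "scrambled_face":
        face = generate_exemplar(
            "face", identity_seed, variation_seed, image_size, object_fraction,
            texture_amp=texture_amp,
        )
        return _scramble_object(face, scramble_grid, _seed_to_int(identity_seed, variation_seed))
    if class_name not in _GENERATORS:
        raise ValueError(
            f"unknown class {class_name!r}; registered: {registered_classes()}"
        )
    rng_id = np.random.default_rng(identity_seed)
    rng_var = np.random.default_rng(variation_seed)
    layer = _GENERATORS[class_name](rng_id, rng_var, _CANVAS)
    layer = _normalize_object_size(layer, image_size, object_fraction)
    tex_rng = np.random.default_rng(_seed_to_int(identity_seed, variation_seed, 17))
    return _texturize(layer, tex_rng, texture_amp)


def _seed_to_int(*seeds) -> int:
    ss = np.random.SeedSequence([_as_entropy(s) for s in seeds])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _as_entropy(s) -> int:
    if isinstance(s, (tuple, list)):
        return _seed_to_int(*s)
    return int(s) & 0xFFFFFFFF


def _scramble_object(layer: np.ndarray, grid_n: int, seed: int) -> np.ndarray:
    """Patch-scramble the object's bounding box in place of the intact object."""
    ys, xs = np.nonzero(layer > 0)
    r0, r1, c0, c1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    crop = patch_scramble(layer[r0:r1, c0:c1], grid_n, seed)
    out = np.zeros_like(layer)
    out[r0:r1, c0:c1] = crop
    return out


# ---------------------------------------------------------------------------
# image-statistic controls


def phase_scramble(image: np.ndarray, seed, clip: bool = True) -> np.ndarray:
    """Randomize Fourier phases, preserving the 2D amplitude spectrum.

    Phases are taken from the spectrum of a white-noise image so Hermitian
    symmetry (hence a real output) holds by construction; the DC component is
    kept, so the mean is preserved exactly before clipping.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("phase_scramble expects a square 2D image")
    rng = np.random.default_rng(seed)
    f = fft2(img)
    amp = np.abs(f)
    noise_phase = np.angle(fft2(rng.standard_normal(img.shape)))
    g = amp * np.exp(1j * noise_phase)
    g[0, 0] = f[0, 0]
    out = ifft2(g).real
    if clip:
        out = np.clip(out, 0.0, 1.0)
    return out.astype(np.float32)


def patch_scramble(image: np.ndarray, grid_n: int, seed) -> np.ndarray:
    """Split into grid_n x grid_n patches and permute them uniformly.

    The multiset of patches (hence the pixel histogram) is preserved exactly
    when grid_n divides the image size; otherwise the image is zero-padded
    before scrambling and cropped back.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape
    ph = -(-h // grid_n) * grid_n
    pw = -(-w // grid_n) * grid_n
    padded = np.zeros((ph, pw), dtype=np.float32)
    padded[:h, :w] = img
    bh, bw = ph // grid_n, pw // grid_n
    blocks = padded.reshape(grid_n, bh, grid_n, bw).transpose(0, 2, 1, 3).reshape(-1, bh, bw)
    perm = np.random.default_rng(seed).permutation(len(blocks))
    blocks = blocks[perm]
    out = (
        blocks.reshape(grid_n, grid_n, bh, bw).transpose(0, 2, 1, 3).reshape(ph, pw)
    )
    return out[:h, :w]


def local_texture_scramble(image: np.ndarray, window_px: int, seed) -> np.ndarray:
    """Phase-scramble overlapping windows independently and blend.

    Destroys the global configuration while approximately preserving windowed
    amplitude spectra (and hence local texture statistics); the limiting case
    window >= image size is exactly a global phase scramble.  This is a
    texture-preserving control in the spirit of texform stimuli, not the
    original texform synthesis.
    """
    if window_px < 8:
        raise ValueError("window_px must be >= 8")
    img = np.asarray(image, dtype=np.float64)
    n = img.shape[0]
    if window_px >= n:
        return phase_scramble(img, seed)
    step = max(1, window_px // 2)
    wnd = np.hanning(window_px)[:, None] * np.hanning(window_px)[None, :] + 0.01
    acc = np.zeros_like(img)
    wsum = np.zeros_like(img)
    rng = np.random.default_rng(seed)
    starts = sorted(set(list(range(0, n - window_px + 1, step)) + [n - window_px]))
    for r in starts:
        for c in starts:
            patch = img[r : r + window_px, c : c + window_px]
            scr = phase_scramble(patch, int(rng.integers(0, 2**31 - 1)), clip=False)
            acc[r : r + window_px, c : c + window_px] += scr * wnd
            wsum[r : r + window_px, c : c + window_px] += wnd
    out = acc / wsum
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def transform_object(
    image_fg: np.ndarray,
    scale: float = 1.0,
    offset_px: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
) -> np.ndarray:
    """Scale/shift/rotate a foreground layer about its centroid.

    offset_px is (dx, dy): dx shifts rightward (columns), dy downward (rows).
    Rotation is counterclockwise; 180 degrees implements the inversion
    condition.  Raises if the transformed object would be clipped by the
    frame.
    """
    fg = np.asarray(image_fg, dtype=np.float32)
    dx, dy = offset_px
    if scale == 1.0 and dx == 0.0 and dy == 0.0 and rotation_deg == 0.0:
        return fg.copy()
    ys, xs = np.nonzero(fg > 0)
    if ys.size == 0:
        return fg.copy()
    cy, cx = ys.mean(), xs.mean()
    theta = np.deg2rad(rotation_deg)
    # build forward map in (x, y) convention, then invert for warp
    t = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(rotation=-theta)  # CCW in display coords (y down)
        + AffineTransform(scale=scale)
        + AffineTransform(translation=(cx + dx, cy + dy))
    )
    out = warp(fg, t.inverse, order=1, cval=0.0, preserve_range=True).astype(np.float32)
    border = np.concatenate([out[0], out[-1], out[:, 0], out[:, -1]])
    if np.any(border > 0.05):
        raise ValueError("transformed object is clipped by the frame")
    return out


# ---------------------------------------------------------------------------
# full set assembly


def _normalize_stats(img: np.ndarray, lum: float, con: float) -> np.ndarray:
    """Set mean and pixel RMS (std) to the targets.

    Clipping to [0, 1] shrinks the achieved std, so the gain is adjusted
    iteratively until the post-clip statistics converge to the targets
    (well under 1% in practice).
    """
    x = np.asarray(img, dtype=np.float64)
    sd = x.std()
    if sd < 1e-9:
        raise ValueError("flat image: contrast normalization infeasible")
    z = (x - x.mean()) / sd
    gain, shift = con, lum
    out = np.clip(shift + gain * z, 0.0, 1.0)
    for _ in range(8):
        m, s = out.mean(), out.std()
        if abs(s - con) < 1e-4 * con and abs(m - lum) < 1e-4:
            break
        gain *= con / s
        shift += lum - m
        out = np.clip(shift + gain * z, 0.0, 1.0)
    return out.astype(np.float32)


def _background(size: int, kind: str, rng: np.random.Generator) -> np.ndarray:
    if kind == "uniform":
        return np.full((size, size), 0.5, dtype=np.float32)
    # phase-scrambled version of a schematic object composed on gray, giving
    # a background with natural-image-like second-order statistics
    cls = ["face", "hand", "horn", "flower", "chair"][int(rng.integers(0, 5))]
    layer = generate_exemplar(cls, int(rng.integers(0, 2**31 - 1)), 0, image_size=size)
    base = np.where(layer > 0, layer, 0.5).astype(np.float64)
    return phase_scramble(base, int(rng.integers(0, 2**31 - 1)), clip=False).astype(np.float32)


def _compose(
    layer: np.ndarray, bg: np.ndarray, lum: float, con: float
) -> np.ndarray:
    img = np.where(layer > 0, layer, bg)
    return _normalize_stats(img, lum, con)


def generate_stimulus_set(spec: StimulusSpec) -> StimulusSet:
    """The full similarity-controlled set: n_per_class images per class,
    luminance/contrast-normalized, partitioned into selection/train/test."""
    rng = np.random.default_rng(spec.seed)
    n_sel, n_train, n_test = spec.partition_sizes()
    images, labels, tags, ids, meta = [], [], [], [], []
    for ci, cls in enumerate(spec.classes):
        tag_pool = (
            ["selection"] * n_sel + ["train"] * n_train + ["test"] * n_test
        )
        tag_pool = [tag_pool[k] for k in rng.permutation(spec.n_per_class)]
        for i in range(spec.n_per_class):
            identity = (spec.seed, ci, i)
            layer = generate_exemplar(
                cls, identity, (spec.seed, ci, i, 1),
                image_size=spec.image_size, object_fraction=spec.object_fraction,
            )
            v = spec.variability(cls)
            scale = 1.0 + spec.jitter_scale * v * rng.uniform(-1, 1)
            lim = spec.jitter_offset_frac * v * spec.image_size
            dx = rng.uniform(-lim, lim)
            dy = rng.uniform(-lim, lim)
            rot = spec.jitter_rotation_deg * v * rng.uniform(-1, 1)
            try:
                layer = transform_object(layer, scale, (dx, dy), rot)
            except ValueError:
                scale, dx, dy, rot = 1.0, 0.0, 0.0, 0.0
            bg = _background(spec.image_size, spec.background, rng)
            images.append(
                _compose(layer, bg, spec.luminance_target, spec.contrast_target)
            )
            labels.append(cls)
            tags.append(tag_pool[i])
            ids.append(f"{cls}_{i:04d}")
            meta.append(
                {"scale": scale, "dx": dx, "dy": dy, "rotation": rot, "yaw": np.nan, "identity": i}
            )
    return StimulusSet(
        images=np.stack(images).astype(np.float32),
        class_labels=labels,
        partition_tags=tags,
        transform_meta=pd.DataFrame(meta),
        stimulus_ids=ids,
    )


# ---------------------------------------------------------------------------
# viewpoint set


def _draw_face_yaw(rng_id: np.random.Generator, yaw_deg: float, s: int) -> np.ndarray:
    """Schematic head at a non-negative yaw; feature x-positions foreshorten
    with cos(yaw) and shift with sin(yaw)."""
    assert yaw_deg >= 0
    cv = np.zeros((s, s), dtype=np.float32)
    y = np.deg2rad(yaw_deg)
    cosy, siny = np.cos(y), np.sin(y)
    aspect = 1.25 + 0.15 * rng_id.uniform(-1, 1)
    hw0 = s * (0.30 + 0.02 * rng_id.uniform(-1, 1))
    hh = hw0 * aspect
    hw = hw0 * (0.72 + 0.28 * cosy)  # head narrows toward profile
    cy, cx = s * 0.5, s * 0.5
    head_val = 0.78 + 0.08 * rng_id.uniform(-1, 1)
    _ellipse(cv, cy, cx, hh, hw, head_val)
    if yaw_deg >= 85:  # profile: nose silhouette bump
        _ellipse(cv, cy, cx + hw * 0.95, hh * 0.16, s * 0.035, head_val)
    eye_dy = hh * (0.28 + 0.06 * rng_id.uniform(-1, 1))
    eye_dx0 = hw0 * (0.42 + 0.08 * rng_id.uniform(-1, 1))
    eye_r = s * (0.035 + 0.008 * rng_id.uniform(-1, 1))
    eye_val = 0.18 + 0.06 * rng_id.uniform(-1, 1)
    for sgn in (-1, 1):
        ex = cx + (sgn * eye_dx0 * cosy + hw0 * 0.25 * siny)
        if abs(ex - cx) < hw * 0.92:  # far eye hides behind the head edge
            _ellipse(cv, cy - eye_dy, ex, eye_r, eye_r * 1.4 * max(cosy, 0.35), eye_val)
    nose_len = hh * (0.30 + 0.05 * rng_id.uniform(-1, 1))
    nx = cx + hw0 * 0.55 * siny
    if abs(nx - cx) < hw * 0.9:
        _ellipse(cv, cy + nose_len * 0.15, nx, nose_len * 0.5, s * 0.016, 0.5)
    mouth_dy = hh * (0.55 + 0.06 * rng_id.uniform(-1, 1))
    mx = cx + hw0 * 0.40 * siny
    mouth_w = hw0 * 0.45 * (0.5 + 0.5 * cosy)
    if abs(mx - cx) - mouth_w < hw * 0.9:
        _ellipse(cv, cy + mouth_dy, mx, s * 0.018, mouth_w, 0.25)
    return cv


def generate_viewpoint_set(
    n_identities: int = 10,
    yaws: Sequence[float] = (-90, -45, 0, 45, 90),
    seed: int = 0,
    image_size: int = 227,
    luminance_target: float = 0.5,
    contrast_target: float = 0.18,
    object_fraction: float = 0.48,
) -> StimulusSet:
    """Head-yaw classes x identities; yaw -theta is exactly the horizontal
    mirror of yaw +theta for the same identity, and the frontal view equals
    its own mirror."""
    yaws = list(yaws)
    if sorted(yaws) != sorted(-y for y in yaws):
        raise ValueError("yaw list must be symmetric about 0")
    rng = np.random.default_rng(seed)
    rendered: dict[tuple[int, float], np.ndarray] = {}
    for ident in range(n_identities):
        id_entropy = _seed_to_int(seed, 777, ident)
        bg = _background(image_size, "phase_scrambled", rng).astype(np.float64)
        bg_sym = 0.5 * (bg + bg[:, ::-1])
        for yaw in sorted({abs(y) for y in yaws}):
            layer = _draw_face_yaw(np.random.default_rng(id_entropy), yaw, _CANVAS)
            layer = _normalize_object_size(layer, image_size, object_fraction)
            layer = _texturize(layer, np.random.default_rng(id_entropy + 1), 0.15)
            img = np.where(layer > 0, layer, bg_sym)
            if yaw == 0:
                img = 0.5 * (img + img[:, ::-1])
            img = _normalize_stats(img, luminance_target, contrast_target)
            rendered[(ident, yaw)] = img
    images, labels, ids, meta = [], [], [], []
    for ident in range(n_identities):
        for yaw in yaws:
            base = rendered[(ident, abs(yaw))]
            img = base[:, ::-1].copy() if yaw < 0 else base
            images.append(img)
            labels.append(f"yaw{int(yaw):+d}")
            ids.append(f"vp_id{ident}_yaw{int(yaw):+d}")
            meta.append(
                {"scale": 1.0, "dx": 0.0, "dy": 0.0, "rotation": 0.0, "yaw": float(yaw), "identity": ident}
            )
    n = len(images)
    return StimulusSet(
        images=np.stack(images).astype(np.float32),
        class_labels=labels,
        partition_tags=["test"] * n,
        transform_meta=pd.DataFrame(meta),
        stimulus_ids=ids,
    )


# ---------------------------------------------------------------------------
# transform sweeps (size / position / rotation incl. inversion)


def generate_transform_sweep(
    kind: str,
    levels: Sequence[float],
    classes: Sequence[str] = DEFAULT_CLASSES,
    n_per_class: int = 20,
    seed: int = 0,
    image_size: int = 227,
    luminance_target: float = 0.5,
    contrast_target: float = 0.18,
    object_fraction: float = 0.40,
) -> dict[float, StimulusSet]:
    """Paired stimulus sets across transform levels.

    kind: 'scale' (levels are size multipliers), 'position' (pixel offsets
    along x) or 'rotation' (degrees; 180 is the inversion condition).  The
    same exemplars and backgrounds are reused at every level, so sets are
    paired by identity across levels.
    """
    if kind not in ("scale", "position", "rotation"):
        raise ValueError(f"unknown transform kind {kind!r}")
    if len(levels) == 0:
        raise ValueError("empty transform level list")
    rng = np.random.default_rng(seed)
    base_layers, base_bgs, base_meta = [], [], []
    for ci, cls in enumerate(classes):
        for i in range(n_per_class):
            layer = generate_exemplar(
                cls, (seed, 99, ci, i), (seed, 99, ci, i, 1),
                image_size=image_size, object_fraction=object_fraction,
            )
            base_layers.append(layer)
            base_bgs.append(_background(image_size, "phase_scrambled", rng))
            base_meta.append((cls, i))
    out: dict[float, StimulusSet] = {}
    for lv in levels:
        scale, (dx, dy), rot = 1.0, (0.0, 0.0), 0.0
        if kind == "scale":
            scale = float(lv)
        elif kind == "position":
            dx = float(lv)
        else:
            rot = float(lv)
        images, labels, ids, meta = [], [], [], []
        for (cls, i), layer, bg in zip(base_meta, base_layers, base_bgs):
            t = transform_object(layer, scale, (dx, dy), rot)
            images.append(_compose(t, bg, luminance_target, contrast_target))
            labels.append(cls)
            ids.append(f"{kind}{lv:g}_{cls}_{i:03d}")
            meta.append(
                {"scale": scale, "dx": dx, "dy": dy, "rotation": rot, "yaw": np.nan, "identity": i}
            )
        n = len(images)
        out[float(lv)] = StimulusSet(
            images=np.stack(images).astype(np.float32),
            class_labels=labels,
            partition_tags=["test"] * n,
            transform_meta=pd.DataFrame(meta),
            stimulus_ids=ids,
        )
    return out
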