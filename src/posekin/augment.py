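"""Annotation-consistent image preprocessing and augmentation.

Photometric operators (grayscale, hue, saturation, brightness, exposure,
contrast normalization, blur, pixel noise, box-local lighting) never touch
coordinates; geometric operators (the resize modes) move keypoints and
boxes through exactly the same affine map as the pixels, degrading
visibility to v=0 for keypoints cropped out of frame.  Every ``apply`` call
records the sampled parameters of each operator in a provenance record so
any augmented image is reproducible from (config, seed).

Transfer functions, since names alone underdetermine them: brightness is an
additive offset as a fraction of full scale; exposure is a multiplicative
gain applied to gamma-linearized intensity; hue and saturation act in HSV
space, hue as a fractional rotation of the wheel, saturation as a gain.

Images are HxWx3 uint8 RGB numpy arrays throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import exposure as skexposure
from skimage.color import hsv2rgb, rgb2hsv

from .annotation import BoundingBox, Keypoint, Pose

__all__ = [
    "ResizeSpec",
    "AugmentationConfig",
    "apply",
    "contrast_ops",
    "noise_inject",
    "bbox_local_adjust",
    "resize_with_poses",
]

ResizeMode = Literal["stretch", "fill_center_crop", "fit_pad_black", "fit_pad_white"]


@dataclass(frozen=True)
class ResizeSpec:
    """Target resolution and the strategy for reaching it."""

    target: tuple[int, int] = (560, 140)     # (width, height)
    mode: ResizeMode = "stretch"

    def __post_init__(self) -> None:
        if self.target[0] <= 0 or self.target[1] <= 0:
            raise ValueError("target dimensions must be positive")


@dataclass(frozen=True)
class AugmentationConfig:
    """Operator ranges; defaults follow the training-time recipe.

    Fractions are of full scale (brightness, exposure) or of the parameter's
    natural unit (hue: fraction of the wheel; saturation: relative gain).
    ``blur_px`` is a Gaussian sigma applied when > 0; ``blur_kernels`` lists
    odd box-kernel sizes, one sampled per image when non-empty.  Both blur
    knobs are independent.  ``resize=None`` disables the geometric stage.
    """

    grayscale_prob: float = 0.15
    hue_range: float = 0.15
    saturation_range: float = 0.25
    brightness_range: float = 0.15
    exposure_range: tuple[float, float] = (0.001, 0.10)
    blur_px: float = 2.5
    blur_kernels: tuple[int, ...] = (3, 5, 7)
    noise_frac: float = 0.001
    bbox_brightness_range: float = 0.15
    bbox_exposure_range: float = 0.10
    resize: ResizeSpec | None = None
    contrast_mode: Literal["none", "stretch", "hist_eq", "adaptive_eq"] = "none"
    adaptive_eq_tile: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grayscale_prob", "hue_range", "saturation_range",
                     "brightness_range", "noise_frac",
                     "bbox_brightness_range", "bbox_exposure_range"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.exposure_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"exposure_range must be an interval within [0, 1], got {self.exposure_range}")
        if any(k % 2 == 0 or k < 1 for k in self.blur_kernels):
            raise ValueError("blur kernel sizes must be odd positive integers")


def _as_float(image: np.ndarray) -> np.ndarray:
    return image.astype(np.float64) / 255.0

def _as_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    lum = _as_float(image) @ np.array([0.2126, 0.7152, 0.0722])
    return _as_uint8(np.repeat(lum[:, :, None], 3, axis=2))


def hue_shift(image: np.ndarray, delta: float) -> np.ndarray:
    hsv = rgb2hsv(_as_float(image))
    hsv[:, :, 0] = (hsv[:, :, 0] + delta) % 1.0
    return _as_uint8(hsv2rgb(hsv))


def saturation_adjust(image: np.ndarray, delta: float) -> np.ndarray:
    hsv = rgb2hsv(_as_float(image))
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] * (1.0 + delta), 0.0, 1.0)
    return _as_uint8(hsv2rgb(hsv))


def brightness_adjust(image: np.ndarray, delta: float) -> np.ndarray:
    return _as_uint8(_as_float(image) + delta)


_GAMMA = 2.2

def exposure_adjust(image: np.ndarray, gain_delta: float) -> np.ndarray:
    """Multiplicative gain (1 + gain_delta) on gamma-linearized intensity."""
    linear = _as_float(image) ** _GAMMA
    return _as_uint8(np.clip(linear * (1.0 + gain_delta), 0.0, 1.0) ** (1.0 / _GAMMA))


def gaussian_blur(image: np.ndarray, sigma: float) -> np.ndarray:
    out = np.stack(
        [ndimage.gaussian_filter(image[:, :, c].astype(np.float64), sigma) for c in range(3)],
        axis=2,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def box_blur(image: np.ndarray, kernel: int) -> np.ndarray:
    out = np.stack(
        [ndimage.uniform_filter(image[:, :, c].astype(np.float64), size=kernel) for c in range(3)],
        axis=2,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def contrast_ops(image: np.ndarray, mode: str, adaptive_tile: int = 8) -> np.ndarray:
    """Contrast normalization: min-max stretch, global or tile-local
    histogram equalization.  A constant image passes through stretch
    unchanged (zero dynamic range is not an error)."""
    if mode == "none":
        return image.copy()
    if mode == "stretch":
        out = image.astype(np.float64).copy()
        for c in range(image.shape[2]):
            lo, hi = float(out[:, :, c].min()), float(out[:, :, c].max())
            if hi > lo:
                out[:, :, c] = (out[:, :, c] - lo) * (255.0 / (hi - lo))
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if mode == "hist_eq":
        # one global histogram over all channels, by design
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return _as_uint8(skexposure.equalize_hist(image))
    if mode == "adaptive_eq":
        h, w = image.shape[:2]
        kernel = (max(1, h // adaptive_tile), max(1, w // adaptive_tile))
        return _as_uint8(skexposure.equalize_adapthist(image, kernel_size=kernel))
    raise ValueError(f"unknown contrast mode {mode!r}")


def noise_inject(image: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Replace exactly round(frac × #pixels) pixels with uniform random colors.

    Positions are drawn without replacement from the supplied generator, so
    the altered-pixel count is exact and the output reproducible.
    """
    if not (0.0 <= frac <= 1.0):
        raise ValueError(f"noise fraction must be in [0, 1], got {frac}")
    h, w = image.shape[:2]
    n = int(round(frac * h * w))
    out = image.copy()
    if n == 0:
        return out
    flat = rng.choice(h * w, size=n, replace=False)
    rows, cols = np.unravel_index(flat, (h, w))
    colors = rng.integers(0, 256, size=(n, image.shape[2]), dtype=np.uint8)
    # a sampled color may equal the original; force a visible change
    same = np.all(colors == out[rows, cols], axis=1)
    colors[same] = colors[same] ^ 0x80
    out[rows, cols] = colors
    return out


def bbox_local_adjust(
    image: np.ndarray,
    box: BoundingBox,
    brightness_delta: float = 0.0,
    exposure_delta: float = 0.0,
) -> np.ndarray:
    """Brightness/exposure restricted to the box region; outside pixels are
    bit-identical.  ``box`` is in pixel coordinates."""
    if box.w <= 0 or box.h <= 0:
        raise ValueError("degenerate box")
    h, w = image.shape[:2]
    x0, y0, x1, y1 = box.xyxy
    c0, r0 = max(0, int(math.floor(x0))), max(0, int(math.floor(y0)))
    c1, r1 = min(w, int(math.ceil(x1))), min(h, int(math.ceil(y1)))
    out = image.copy()
    if r1 <= r0 or c1 <= c0:
        return out
    patch = out[r0:r1, c0:c1]
    if brightness_delta != 0.0:
        patch = brightness_adjust(patch, brightness_delta)
    if exposure_delta != 0.0:
        patch = exposure_adjust(patch, exposure_delta)
    out[r0:r1, c0:c1] = patch
    return out


def _resize_map(src: tuple[int, int], spec: ResizeSpec):
    """Affine pixel map (sx, sy, ox, oy): new = old * s - o, plus the
    intermediate resized dimensions needed to build the image."""
    w, h = src
    tw, th = spec.target
    if spec.mode == "stretch":
        return tw / w, th / h, 0.0, 0.0, (tw, th)
    if spec.mode == "fill_center_crop":
        s = max(tw / w, th / h)
        rw, rh = max(tw, int(round(w * s))), max(th, int(round(h * s)))
        return s, s, (rw - tw) / 2.0, (rh - th) / 2.0, (rw, rh)
    if spec.mode in ("fit_pad_black", "fit_pad_white"):
        s = min(tw / w, th / h)
        rw, rh = min(tw, int(round(w * s))), min(th, int(round(h * s)))
        return s, s, -((tw - rw) / 2.0), -((th - rh) / 2.0), (rw, rh)
    raise ValueError(f"unknown resize mode {spec.mode!r}")


def resize_with_poses(
    image: np.ndarray,
    poses: Sequence[Pose],
    spec: ResizeSpec,
) -> tuple[np.ndarray, list[Pose]]:
    """Resize pixels and poses through one shared affine map.

    Poses are normalized with respect to the input image and come back
    normalized with respect to the target.  Keypoints mapped outside the
    target frame (center-crop modes) are set to v=0.
    """
    h, w = image.shape[:2]
    tw, th = spec.target
    sx, sy, ox, oy, (rw, rh) = _resize_map((w, h), spec)
    resized = np.asarray(Image.fromarray(image).resize((rw, rh), Image.BILINEAR))
    if spec.mode == "stretch":
        out = resized
    elif spec.mode == "fill_center_crop":
        c0, r0 = int(round(ox)), int(round(oy))
        out = resized[r0 : r0 + th, c0 : c0 + tw]
    else:
        fill = 0 if spec.mode == "fit_pad_black" else 255
        out = np.full((th, tw, image.shape[2]), fill, dtype=np.uint8)
        c0, r0 = int(round(-ox)), int(round(-oy))
        out[r0 : r0 + rh, c0 : c0 + rw] = resized

    new_poses = []
    for pose in poses:
        kps = []
        for kp in pose.keypoints:
            x_px = kp.x * w * sx - ox
            y_px = kp.y * h * sy - oy
            v = kp.v
            if v > 0 and not (0.0 <= x_px <= tw and 0.0 <= y_px <= th):
                v = 0
            kps.append(Keypoint(x_px / tw, y_px / th, v))
        bx0, by0, bx1, by1 = pose.box.xyxy
        nx0 = min(max(bx0 * w * sx - ox, 0.0), tw)
        nx1 = min(max(bx1 * w * sx - ox, 0.0), tw)
        ny0 = min(max(by0 * h * sy - oy, 0.0), th)
        ny1 = min(max(by1 * h * sy - oy, 0.0), th)
        box = BoundingBox.from_xyxy(nx0 / tw, ny0 / th, nx1 / tw, ny1 / th)
        new_poses.append(dc_replace(pose, box=box, keypoints=tuple(kps)))
    return out, new_poses


def apply(
    image: np.ndarray,
    poses: Sequence[Pose],
    config: AugmentationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[Pose], dict]:
    """Run the full augmentation recipe on one image.

    Returns (augmented image, transformed poses, provenance).  The
    provenance record lists every operator applied with its sampled
    parameters; replaying it through the same code path reproduces the
    output exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    h, w = image.shape[:2]
    out = image
    ops: list[dict] = []

    if config.grayscale_prob > 0 and rng.random() < config.grayscale_prob:
        out = to_grayscale(out)
        ops.append({"op": "grayscale"})
    if config.hue_range > 0:
        delta = float(rng.uniform(-config.hue_range, config.hue_range))
        out = hue_shift(out, delta)
        ops.append({"op": "hue", "delta": delta})
    if config.saturation_range > 0:
        delta = float(rng.uniform(-config.saturation_range, config.saturation_range))
        out = saturation_adjust(out, delta)
        ops.append({"op": "saturation", "delta": delta})
    if config.brightness_range > 0:
        delta = float(rng.uniform(-config.brightness_range, config.brightness_range))
        out = brightness_adjust(out, delta)
        ops.append({"op": "brightness", "delta": delta})
    lo, hi = config.exposure_range
    if hi > 0:
        mag = float(rng.uniform(lo, hi))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out = exposure_adjust(out, sign * mag)
        ops.append({"op": "exposure", "gain_delta": sign * mag})
    if config.contrast_mode != "none":
        out = contrast_ops(out, config.contrast_mode, config.adaptive_eq_tile)
        ops.append({"op": "contrast", "mode": config.contrast_mode})
    if config.blur_px > 0:
        out = gaussian_blur(out, config.blur_px)
        ops.append({"op": "gaussian_blur", "sigma": config.blur_px})
    if config.blur_kernels:
        kernel = int(rng.choice(config.blur_kernels))
        out = box_blur(out, kernel)
        ops.append({"op": "box_blur", "kernel": kernel})
    if config.noise_frac > 0:
        out = noise_inject(out, config.noise_frac, rng)
        ops.append({"op": "noise", "frac": config.noise_frac})
    if config.bbox_brightness_range > 0 or config.bbox_exposure_range > 0:
        for pose in poses:
            b = float(rng.uniform(-config.bbox_brightness_range, config.bbox_brightness_range))
            e = float(rng.uniform(-config.bbox_exposure_range, config.bbox_exposure_range))
            box_px = BoundingBox(pose.box.cx * w, pose.box.cy * h, pose.box.w * w, pose.box.h * h)
            out = bbox_local_adjust(out, box_px, brightness_delta=b, exposure_delta=e)
            ops.append({"op": "bbox_adjust", "brightness": b, "exposure": e})

    new_poses = list(poses)
    if config.resize is not None:
        out, new_poses = resize_with_poses(out, new_poses, config.resize)
        ops.append({"op": "resize", "target": list(config.resize.target), "mode": config.resize.mode})

    provenance = {"seed": config.seed, "input_size": [w, h], "ops": ops}
    return out, new_poses, provenance
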