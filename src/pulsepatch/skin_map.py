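"""Naive-Bayes skin segmentation in Cb-Cr chromaticity space.

Skin tones of all ethnicities cluster tightly in the Cb-Cr plane once the
luma component is discarded, so a 2-D histogram over (Cb, Cr) trained from a
small set of masked images yields a serviceable per-pixel skin posterior.
The posterior follows Bayes' rule over histogram counts:

    p(skin | Cb, Cr) = p(Cb, Cr | skin) p(skin) / p(Cb, Cr)

with p(Cb, Cr | skin) = h_skin / N_skin, p(Cb, Cr) = h_total / N_total and
p(skin) ~= N_skin / N_total, which algebraically reduces to the count ratio
h_skin / h_total.  Patches whose mean posterior falls below a threshold
(default 0.7) are discarded as non-skin.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SkinHistogramModel",
    "rgb_to_cbcr",
    "ycbcr_to_rgb",
    "rgb_luma",
    "train_skin_model",
    "skin_posterior",
    "skin_probability_map",
    "filter_skin_patches",
]

# BT.601 full-range RGB -> YCbCr coefficients.
_KR, _KG, _KB = 0.299, 0.587, 0.114


def rgb_to_cbcr(rgb: np.ndarray) -> np.ndarray:
    """Convert 8-bit RGB to (Cb, Cr) chroma, BT.601 full range.

    Parameters
    ----------
    rgb
        ``(..., 3)`` array in [0, 255].

    Returns
    -------
    ``(..., 2)`` float array with Cb, Cr in [0, 255]; an achromatic input
    maps to (128, 128).
    """
    rgb = np.asarray(rgb, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    y = _KR * r + _KG * g + _KB * b
    cb = 128.0 + (b - y) / (2.0 * (1.0 - _KB))
    cr = 128.0 + (r - y) / (2.0 * (1.0 - _KR))
    out = np.stack([cb, cr], axis=-1)
    return np.clip(out, 0.0, 255.0)


def rgb_luma(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luma of an RGB array, rounded to integer grayscale."""
    rgb = np.asarray(rgb, dtype=float)
    y = _KR * rgb[..., 0] + _KG * rgb[..., 1] + _KB * rgb[..., 2]
    return np.rint(y)


def ycbcr_to_rgb(y: np.ndarray, cb: np.ndarray, cr: np.ndarray) -> np.ndarray:
    """Inverse BT.601 full-range conversion, clipped to [0, 255]."""
    y = np.asarray(y, dtype=float)
    cb = np.asarray(cb, dtype=float) - 128.0
    cr = np.asarray(cr, dtype=float) - 128.0
    r = y + 2.0 * (1.0 - _KR) * cr
    b = y + 2.0 * (1.0 - _KB) * cb
    g = (y - _KR * r - _KB * b) / _KG
    return np.clip(np.stack([r, g, b], axis=-1), 0.0, 255.0)


@dataclass
class SkinHistogramModel:
    """2-D Cb-Cr count histograms for skin and for all pixels.

    ``h_skin[i, j] <= h_total[i, j]`` element-wise; ``h_skin`` sums to
    ``n_skin`` and ``h_total`` to ``n_total``.  ``smoothing`` is an optional
    additive (Laplace) count applied symmetrically to both histograms when
    evaluating the posterior; the default 0 treats unseen bins as non-skin.
    """

    h_skin: np.ndarray
    h_total: np.ndarray
    bin_count: int = 64
    smoothing: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h_skin = np.asarray(self.h_skin, dtype=float)
        self.h_total = np.asarray(self.h_total, dtype=float)
        if self.h_skin.shape != (self.bin_count, self.bin_count):
            raise ValueError("h_skin shape does not match bin_count")
        if self.h_skin.shape != self.h_total.shape:
            raise ValueError("histogram shapes differ")
        if np.any(self.h_skin > self.h_total):
            raise ValueError("h_skin exceeds h_total in some bin")

    @property
    def n_skin(self) -> float:
        return float(self.h_skin.sum())

    @property
    def n_total(self) -> float:
        return float(self.h_total.sum())

    @property
    def bin_width(self) -> float:
        return 256.0 / self.bin_count

    def bin_index(self, cbcr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (..., 2) Cb-Cr values to histogram bin indices."""
        cbcr = np.asarray(cbcr, dtype=float)
        idx = np.clip((cbcr / self.bin_width).astype(int), 0, self.bin_count - 1)
        return idx[..., 0], idx[..., 1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_count": self.bin_count,
                "smoothing": self.smoothing,
                "h_skin": self.h_skin.astype(int).tolist(),
                "h_total": self.h_total.astype(int).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SkinHistogramModel":
        d = json.loads(text)
        return cls(
            h_skin=np.array(d["h_skin"], dtype=float),
            h_total=np.array(d["h_total"], dtype=float),
            bin_count=int(d["bin_count"]),
            smoothing=float(d.get("smoothing", 0.0)),
        )


def train_skin_model(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    bin_count: int = 64,
    smoothing: float = 0.0,
) -> SkinHistogramModel:
    """Accumulate Cb-Cr histograms from RGB images with binary skin masks.

    Raises
    ------
    ValueError
        If no skin pixel is present across the whole training set, or an
        image/mask pair is misaligned.
    """
    if len(images) != len(masks):
        raise ValueError("images and masks must pair up")
    h_skin = np.zeros((bin_count, bin_count))
    h_total = np.zeros((bin_count, bin_count))
    width = 256.0 / bin_count
    for img, mask in zip(images, masks):
        img = np.asarray(img)
        mask = np.asarray(mask, dtype=bool)
        if img.shape[:2] != mask.shape:
            raise ValueError("image and mask shapes differ")
        cbcr = rgb_to_cbcr(img.reshape(-1, 3))
        idx = np.clip((cbcr / width).astype(int), 0, bin_count - 1)
        flat = idx[:, 0] * bin_count + idx[:, 1]
        h_total += np.bincount(flat, minlength=bin_count * bin_count).reshape(
            bin_count, bin_count
        )
        skin_flat = flat[mask.reshape(-1)]
        h_skin += np.bincount(skin_flat, minlength=bin_count * bin_count).reshape(
            bin_count, bin_count
        )
    if h_skin.sum() == 0:
        raise ValueError("training set contains no skin pixels")
    return SkinHistogramModel(h_skin, h_total, bin_count=bin_count, smoothing=smoothing)


def skin_posterior(model: SkinHistogramModel, cbcr: np.ndarray) -> np.ndarray:
    """Posterior probability of skin for (Cb, Cr) value(s), via Bayes' rule.

    Evaluates the full likelihood x prior / evidence expression over the
    histogram counts (with optional symmetric Laplace smoothing); bins never
    observed in training get probability 0.  Result clamped to [0, 1].
    """
    cbcr = np.asarray(cbcr, dtype=float)
    scalar = cbcr.ndim == 1
    i, j = model.bin_index(cbcr)
    s = model.smoothing
    n_bins = model.bin_count**2
    n_skin = model.n_skin + s * n_bins
    n_total = model.n_total + s * n_bins
    hs = model.h_skin[i, j] + s
    ht = model.h_total[i, j] + s
    likelihood = hs / n_skin
    prior = n_skin / n_total
    evidence = ht / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        post = likelihood * prior / evidence
    post = np.where(ht > 0, post, 0.0)
    post = np.clip(post, 0.0, 1.0)
    return float(post) if scalar else post


def skin_probability_map(model: SkinHistogramModel, frame: np.ndarray) -> np.ndarray:
    """Per-pixel skin posterior (the SPM) for one RGB frame."""
    cbcr = rgb_to_cbcr(frame)
    return skin_posterior(model, cbcr)


def filter_skin_patches(
    label_maps: np.ndarray,
    frames: np.ndarray,
    model: SkinHistogramModel,
    n_patches: int,
    threshold: float = 0.7,
    return_scores: bool = False,
):
    """Keep patches whose mean skin posterior is at least ``threshold``.

    A patch's score is the mean posterior over its member pixels within a
    frame, averaged across the frames where the patch is non-empty; this
    keeps the patch set fixed over the clip rather than re-deciding per
    frame.

    Parameters
    ----------
    label_maps
        ``(T, H, W)`` integer maps assigning each pixel to a triangle id
        (-1 = no patch), as produced by :func:`pulsepatch.patch_mesh.track_patches`.
    frames
        ``(T, H, W, 3)`` uint8 RGB frames.
    model
        Trained :class:`SkinHistogramModel`.
    n_patches
        Total number of triangle ids.
    threshold
        Minimum mean posterior to keep a patch (default 0.7).

    Returns
    -------
    Sorted array of kept patch ids; with ``return_scores=True`` also the
    per-patch score array (NaN for patches empty on every frame).
    """
    n_frames = label_maps.shape[0]
    score_sum = np.zeros(n_patches)
    frame_cnt = np.zeros(n_patches)
    for t in range(n_frames):
        labels = label_maps[t].reshape(-1)
        inside = labels >= 0
        if not inside.any():
            continue
        spm = skin_probability_map(model, frames[t]).reshape(-1)
        sums = np.bincount(labels[inside], weights=spm[inside], minlength=n_patches)
        counts = np.bincount(labels[inside], minlength=n_patches)
        nz = counts > 0
        score_sum[nz] += sums[nz] / counts[nz]
        frame_cnt[nz] += 1
    scores = np.full(n_patches, np.nan)
    seen = frame_cnt > 0
    scores[seen] = score_sum[seen] / frame_cnt[seen]
    if not seen.all():
        warnings.warn(
            f"{int((~seen).sum())} patch(es) empty on every frame; excluded",
            stacklevel=2,
        )
    kept = np.flatnonzero(seen & (scores >= threshold))
    if return_scores:
        return kept, scores
    return kept
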