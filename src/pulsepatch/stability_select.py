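"""Size-stability patch selection via the interquartile range.

A patch whose pixel count fluctuates over the clip (eye blinks, nose
self-occlusion under yaw, frame-boundary clipping) injects broadband noise
into its intensity trace.  The frame-to-frame count differences

    C = (N_2 - N_1, ..., N_K - N_{K-1})

are put on a common scale by the weight ``K / sqrt(sum_i N_i)`` so that
patches of different area are comparable, and the spread of the weighted
series is summarized by the interquartile range Q3 - Q1.  Only the patches
with the smallest IQRs (top 50% by default) are kept for pulse extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ChangeSeries", "change_series", "select_stable"]


@dataclass
class ChangeSeries:
    """Pixel-count change series of one patch and its stability summary."""

    raw: np.ndarray
    weighted: np.ndarray
    iqr: float


def change_series(counts: Sequence[float]) -> ChangeSeries:
    """Normalized pixel-count change series of a patch.

    Parameters
    ----------
    counts
        Per-frame pixel counts ``N = (N_1 ... N_K)``, K >= 3.

    Raises
    ------
    ValueError
        If K < 3 or the patch is dead (all counts zero).
    """
    n = np.asarray(counts, dtype=float)
    if n.ndim != 1 or len(n) < 3:
        raise ValueError("need a count series of length >= 3")
    total = n.sum()
    if total <= 0:
        raise ValueError("dead patch: pixel counts sum to zero")
    raw = np.diff(n)
    weight = len(n) / math.sqrt(total)
    weighted = weight * raw
    q1, q3 = np.percentile(weighted, [25, 75])  # linear ("type 7") quartiles
    return ChangeSeries(raw=raw, weighted=weighted, iqr=float(q3 - q1))


def select_stable(
    patches: Sequence[ChangeSeries],
    keep_fraction: float = 0.5,
    ids: Sequence[int] | None = None,
) -> np.ndarray:
    """Keep the patches with the smallest IQR.

    Patches are ranked ascending by IQR and the top ``ceil(keep_fraction * n)``
    are kept; ties are broken in favor of the smaller patch id so the
    selection is deterministic.

    Parameters
    ----------
    patches
        One :class:`ChangeSeries` per candidate patch.
    keep_fraction
        Fraction of patches to keep (default 0.5 — the top 50% most stable).
    ids
        Patch ids aligned with ``patches``; defaults to 0..n-1.

    Returns
    -------
    Sorted array of kept patch ids.
    """
    if len(patches) == 0:
        raise ValueError("no patches to select from")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if ids is None:
        ids = np.arange(len(patches))
    ids = np.asarray(ids)
    if len(ids) != len(patches):
        raise ValueError("ids must align with patches")
    iqrs = np.array([p.iqr for p in patches])
    order = np.lexsort((ids, iqrs))
    n_keep = math.ceil(keep_fraction * len(patches))
    return np.sort(ids[order[:n_keep]])
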