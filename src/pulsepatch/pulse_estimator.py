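"""Pulse extraction by pairwise ICA over patch traces and majority voting.

Each kept patch contributes one raw observation: the mean green-channel
intensity over its pixels per frame (green because hemoglobin absorption
peaks around 520-580 nm).  Any two patches i, j see the same underlying
pulse p(t) and illumination w(t) through different location gains,

    P_i(t) = a_i p(t) + b_i w(t),    P_j(t) = a_j p(t) + b_j w(t),

a 2x2 linear mixture that FastICA can invert up to sign/scale/permutation.
Each randomly sampled pair yields a pulse hypothesis that votes for the
frequency bin holding its highest spectral peak inside the 0.7-4 Hz band;
the bin with the most votes gives the pulse frequency f_HR and the heart
rate HR = 60 f_HR.  Majority voting makes the estimate robust to pairs
contaminated by residual noise sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import FrameStack

__all__ = [
    "RawTrace",
    "HRHypothesis",
    "HREstimate",
    "NoPulseError",
    "extract_traces",
    "condition_trace",
    "ica_pair",
    "hypothesis_from_pair",
    "estimate_hr",
]

PULSE_BAND = (0.7, 4.0)  # Hz
VOTE_BIN_WIDTH = 1.0 / 30.0  # Hz; native resolution of a 30-s clip
# Minimum in-band peak-to-in-band-total PSD ratio for a component to count
# as periodic at all; below it the hypothesis abstains.  Calibrated against
# white-noise components at the default Welch settings (10-s Hann segments
# zero-padded to a 0.01 Hz grid): their ratio stays below ~0.011, while even
# a weak oscillation (tone amplitude half the noise std) clears 0.02.
ABSTAIN_PEAK_FRACTION = 0.02


class NoPulseError(RuntimeError):
    """No patch pair produced a usable pulse hypothesis."""


@dataclass
class RawTrace:
    """Mean green intensity of one patch per frame."""

    patch_id: int
    values: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("trace contains non-finite values")


@dataclass
class HRHypothesis:
    pair: tuple[int, int]
    voted_bin: int
    peak_freq: float
    peak_power: float
    freqs: np.ndarray = field(repr=False)
    psd: np.ndarray = field(repr=False)


@dataclass
class HREstimate:
    f_hr: float
    hr_bpm: float
    vote_histogram: np.ndarray
    bin_edges: np.ndarray
    n_pairs: int
    hypotheses: list = field(repr=False, default_factory=list)


def extract_traces(
    frame_stack: FrameStack, label_maps: np.ndarray, kept_ids
) -> list[RawTrace]:
    """Per-patch mean green traces over the clip.

    Frames where a patch is empty (off-frame or landmarks missing) are
    filled by linear interpolation from neighbouring frames.

    Raises
    ------
    ValueError
        If fewer than 2 patches are requested — ICA needs at least a pair
        of observations.
    """
    kept_ids = np.asarray(kept_ids, dtype=int)
    if len(kept_ids) < 2:
        raise ValueError("insufficient observations for ICA (need >= 2 patches)")
    n_frames = frame_stack.n_frames
    n_patches = int(label_maps.max()) + 1
    green = frame_stack.frames[..., 1].astype(float)
    sums = np.zeros((n_patches, n_frames))
    counts = np.zeros((n_patches, n_frames))
    for t in range(n_frames):
        labels = label_maps[t].reshape(-1)
        inside = labels >= 0
        if not inside.any():
            continue
        sums[:, t] = np.bincount(
            labels[inside], weights=green[t].reshape(-1)[inside], minlength=n_patches
        )
        counts[:, t] = np.bincount(labels[inside], minlength=n_patches)
    traces = []
    frame_idx = np.arange(n_frames)
    for pid in kept_ids:
        has = counts[pid] > 0
        if not has.any():
            raise ValueError(f"patch {pid} empty on every frame")
        vals = np.empty(n_frames)
        vals[has] = sums[pid, has] / counts[pid, has]
        if not has.all():
            vals[~has] = np.interp(frame_idx[~has], frame_idx[has], vals[has])
        traces.append(RawTrace(int(pid), vals, frame_stack.frame_rate))
    return traces


def condition_trace(
    values: np.ndarray, frame_rate: float, detrend_window_s: float = 10.0
) -> np.ndarray:
    """Detrend (subtract a moving average) and z-score a trace.

    FastICA requires centered inputs, and the slow illumination drift would
    otherwise dominate the mixture; a 10-s moving average removes it without
    touching the >= 0.7 Hz pulse band.
    """
    values = np.asarray(values, dtype=float)
    win = max(3, int(round(detrend_window_s * frame_rate)))
    win = min(win, len(values))
    baseline = uniform_filter1d(values, size=win, mode="nearest")
    out = values - baseline
    std = out.std()
    if std > 0:
        out = out / std
    return out


def ica_pair(
    trace_i: np.ndarray, trace_j: np.ndarray, seed: int = 0
) -> np.ndarray | None:
    """Unmix a pair of conditioned traces with FastICA.

    Returns a ``(2, T)`` source array, or None when the pair is degenerate
    (near-collinear traces) or FastICA fails to converge.
    """
    x = np.asarray(trace_i, dtype=float)
    y = np.asarray(trace_j, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces must have equal length")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant trace in pair; skipped", stacklevel=2)
        return None
    rho = float(np.corrcoef(x, y)[0, 1])
    if abs(rho) > 0.999:
        warnings.warn("collinear trace pair; skipped", stacklevel=2)
        return None
    ica = FastICA(
        n_components=2,
        random_state=int(seed) % (2**31),
        max_iter=500,
        whiten="unit-variance",
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(np.column_stack([x, y]))
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        return None
    return sources.T


def _welch(values: np.ndarray, frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with 10-s Hann segments, 50% overlap, zero-padded to a
    ~0.01 Hz frequency grid."""
    n = len(values)
    nperseg = min(n, int(round(10.0 * frame_rate)))
    nfft = max(nperseg, int(round(frame_rate / 0.01)))
    return sps.welch(
        values, fs=frame_rate, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, nfft=nfft,
    )


def vote_bin_edges(band: tuple[float, float] = PULSE_BAND) -> np.ndarray:
    """Edges of the voting bins tiling the pulse band."""
    n_bins = int(np.ceil((band[1] - band[0]) / VOTE_BIN_WIDTH))
    return band[0] + VOTE_BIN_WIDTH * np.arange(n_bins + 1)


def hypothesis_from_pair(
    components: np.ndarray,
    frame_rate: float,
    band: tuple[float, float] = PULSE_BAND,
    abstain_peak_fraction: float = ABSTAIN_PEAK_FRACTION,
) -> HRHypothesis | None:
    """Pick the pulse component of an unmixed pair and let it vote.

    The component with the larger in-band peak-to-total power ratio is taken
    as the pulse; its highest in-band peak selects a voting bin.  Returns
    None (abstains) when neither component shows in-band power concentrated
    enough to look periodic.
    """
    components = np.asarray(components, dtype=float)
    if components.ndim != 2 or components.shape[0] != 2:
        raise ValueError("components must be (2, T)")
    best = None
    for comp in components:
        freqs, psd = _welch(comp, frame_rate)
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        total = psd.sum()
        inband_total = psd[in_band].sum()
        if total <= 0 or inband_total <= 0:
            continue
        k = np.argmax(psd[in_band])
        peak_power = psd[in_band][k]
        ratio = peak_power / total
        if best is None or ratio > best[0]:
            best = (ratio, peak_power / inband_total, freqs[in_band][k], peak_power, freqs, psd)
    if best is None or best[1] < abstain_peak_fraction:
        return None
    _, _, f_peak, peak_power, freqs, psd = best
    edges = vote_bin_edges(band)
    voted = int(np.clip((f_peak - band[0]) / VOTE_BIN_WIDTH, 0, len(edges) - 2))
    return HRHypothesis(
        pair=(-1, -1),
        voted_bin=voted,
        peak_freq=float(f_peak),
        peak_power=float(peak_power),
        freqs=freqs,
        psd=psd,
    )


def resolve_vote_tie(votes: np.ndarray, peak_power: np.ndarray) -> int:
    """Winning bin: most votes; ties go to the larger summed peak power."""
    votes = np.asarray(votes)
    tied = np.flatnonzero(votes == votes.max())
    return int(tied[np.argmax(np.asarray(peak_power)[tied])])


def estimate_hr(
    traces: list[RawTrace],
    n_pairs: int = 100,
    seed: int = 0,
    band: tuple[float, float] = PULSE_BAND,
) -> HREstimate:
    """Estimate HR from patch traces by pairwise-ICA majority voting.

    ``min(n_pairs, C(n, 2))`` distinct patch pairs are sampled without
    replacement (seeded); each contributes at most one vote.  Ties between
    bins are broken by the larger summed peak power.

    Raises
    ------
    ValueError
        With fewer than 2 traces.
    NoPulseError
        If every sampled pair abstained or failed to unmix.
    """
    if len(traces) < 2:
        raise ValueError("insufficient observations for ICA (need >= 2 traces)")
    frame_rate = traces[0].frame_rate
    conditioned = [condition_trace(tr.values, frame_rate) for tr in traces]
    n = len(traces)
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng = np.random.default_rng(seed)
    if len(all_pairs) > n_pairs:
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        pairs = [all_pairs[k] for k in sorted(idx)]
    else:
        pairs = all_pairs
    edges = vote_bin_edges(band)
    votes = np.zeros(len(edges) - 1)
    power = np.zeros(len(edges) - 1)
    hypotheses = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-pair skips are expected
        for i, j in pairs:
            sources = ica_pair(
                conditioned[i], conditioned[j], seed=int(rng.integers(2**31))
            )
            if sources is None:
                continue
            hyp = hypothesis_from_pair(sources, frame_rate, band=band)
            if hyp is None:
                continue
            hyp.pair = (traces[i].patch_id, traces[j].patch_id)
            votes[hyp.voted_bin] += 1
            power[hyp.voted_bin] += hyp.peak_power
            hypotheses.append(hyp)
    if not hypotheses:
        raise NoPulseError("no pulse found: all patch-pair hypotheses abstained")
    winner = resolve_vote_tie(votes, power)
    f_hr = float((edges[winner] + edges[winner + 1]) / 2)
    return HREstimate(
        f_hr=f_hr,
        hr_bpm=60.0 * f_hr,
        vote_histogram=votes,
        bin_edges=edges,
        n_pairs=len(pairs),
        hypotheses=hypotheses,
    )
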