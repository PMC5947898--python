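"""Evaluation arithmetic for HR estimation.

Spectral quality of a pulse trace is scored as the energy near the
ground-truth frequency plus its first harmonic over the remaining in-band
energy (the pulse-band SNR).  Agreement between predicted and reference HR
is summarized by RMSE, the error mean and spread Me +/- SDe, Bland-Altman
95% limits of agreement Me +/- 1.96 SDe, the Pearson correlation, and the
well-estimation rate (fraction of clips with absolute error strictly below
5 bpm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SNRReport", "AgreementReport", "snr", "agreement", "bland_altman_plot"]

PULSE_BAND = (0.7, 4.0)  # Hz; plausible human HR span 42-240 bpm
WELL_ESTIMATE_BPM = 5.0


@dataclass
class SNRReport:
    e_gt: float
    e_first_harmonic: float
    e_remaining: float
    snr: float
    band_halfwidth: float
    infinite: bool = False


@dataclass
class AgreementReport:
    rmse: float
    me: float
    sde: float
    loa_low: float
    loa_high: float
    pearson_r: float
    pearson_defined: bool
    well_rate: float
    n: int


def snr(
    freqs: np.ndarray,
    psd: np.ndarray,
    f_gt: float,
    band_halfwidth: float = 0.1,
    band: tuple[float, float] = PULSE_BAND,
) -> SNRReport:
    """Pulse-band SNR of a power spectrum given the true pulse frequency.

    Energy within ``band_halfwidth`` of ``f_gt`` and of its first harmonic
    ``2 f_gt`` counts as signal; everything else inside ``band`` is noise:
    ``snr = (E_gt + E_1st_h) / E_remaining``.  If no energy remains outside
    the signal bands the report carries an infinite sentinel.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs.shape != psd.shape:
        raise ValueError("freqs and psd must align")
    if not (freqs[0] <= f_gt <= freqs[-1] and 2 * f_gt <= freqs[-1]):
        raise ValueError("f_gt and its first harmonic must lie inside the spectrum")
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    gt_band = np.abs(freqs - f_gt) <= band_halfwidth
    h_band = np.abs(freqs - 2 * f_gt) <= band_halfwidth
    e_gt = float(psd[in_band & gt_band].sum())
    e_h = float(psd[in_band & h_band & ~gt_band].sum())
    e_rem = float(psd[in_band & ~gt_band & ~h_band].sum())
    if e_rem == 0:
        return SNRReport(e_gt, e_h, e_rem, math.inf, band_halfwidth, infinite=True)
    return SNRReport(e_gt, e_h, e_rem, (e_gt + e_h) / e_rem, band_halfwidth)


def agreement(pred, truth) -> AgreementReport:
    """Agreement statistics between predicted and reference HR (bpm).

    ``me`` and ``sde`` are the mean and sample (n-1) standard deviation of
    the signed errors pred - truth; the limits of agreement are
    ``me +/- 1.96 sde``.  An error of exactly 5 bpm does **not** count as
    well-estimated (strict inequality).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be 1-D and equal length")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least 2 paired measurements")
    err = pred - truth
    me = float(err.mean())
    sde = float(err.std(ddof=1))
    rmse = float(np.sqrt(np.mean(err**2)))
    well = float(np.mean(np.abs(err) < WELL_ESTIMATE_BPM))
    defined = np.std(pred) > 0 and np.std(truth) > 0
    r = float(stats.pearsonr(pred, truth).statistic) if defined else float("nan")
    return AgreementReport(
        rmse=rmse,
        me=me,
        sde=sde,
        loa_low=me - 1.96 * sde,
        loa_high=me + 1.96 * sde,
        pearson_r=r,
        pearson_defined=bool(defined),
        well_rate=well,
        n=n,
    )


def bland_altman_plot(pred, truth, ax=None, title: str | None = None):
    """Bland-Altman plot: per-clip difference vs the mean of the two
    measurements, with the mean difference and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    rep = agreement(pred, truth)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mean = (pred + truth) / 2
    diff = pred - truth
    ax.scatter(mean, diff, s=18, color="k")
    ax.axhline(rep.me, color="r", lw=1)
    for y in (rep.loa_low, rep.loa_high):
        ax.axhline(y, color="b", ls="--", lw=1)
    ax.set_xlabel("mean of methods (bpm)")
    ax.set_ylabel("difference (bpm)")
    if title:
        ax.set_title(title)
    return ax
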