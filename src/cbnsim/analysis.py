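"""Spike-train correlogram analysis and summary metrics.

Cross-correlograms accumulate target spikes at lags relative to every
reference spike within a +-window/2 span (default 20 ms total), binned at
``bin_width``.  Two normalisations are carried: a rate variant
(counts / (n_ref * bin_width), spikes/s) and a probability-per-bin variant
(counts / n_ref); they differ exactly by the bin width.  The baseline is
the mean of the rate variant over a flat pre-event window (default
[-10, -5] ms).

The summary metrics mirror the field's convention for inhibitory-input
correlograms: ``e`` is the fractional elevation above baseline in the
pre-spike window (disinhibition caused by the presynaptic refractory
period), ``i`` the fractional suppression below baseline just after the
spike, and ``t_half`` the time for the suppression to recover halfway back
to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic_inputs import SpikeTrain

__all__ = [
    "Correlogram",
    "CorrMetrics",
    "cross_correlogram",
    "autocorrelogram",
    "correlogram_metrics",
    "rate_code_slope",
    "pause_psth",
    "pool_correlograms",
    "write_correlogram_csv",
]

#: Default analysis windows, ms.
BASELINE_WINDOW = (-10.0, -5.0)
E_WINDOW = (-5.0, 0.0)  # half-open: [-5, 0)
I_WINDOW = (0.0, 5.0)  # closed: [0, +5]
SMOOTH_BINS = 3  # boxcar width for the half-recovery crossing


@dataclass
class Correlogram:
    """Binned, normalised spike-time histogram around reference spikes."""

    bin_width: float  # ms
    lags: np.ndarray  # ms, bin centers, symmetric about 0
    rate: np.ndarray  # spikes/s variant
    probability: np.ndarray  # probability-per-bin variant
    n_ref: int
    baseline: float  # spikes/s, mean rate over the baseline window
    baseline_window: tuple[float, float] = BASELINE_WINDOW

    def window_mask(self, lo: float, hi: float, closed_hi: bool = True) -> np.ndarray:
        """Boolean mask over lag bins within [lo, hi] (or [lo, hi))."""
        half = self.bin_width / 2
        hi_ok = self.lags <= hi + half * 1e-9 if closed_hi else self.lags < hi - half * 1e-9
        return (self.lags >= lo - half * 1e-9) & hi_ok


@dataclass(frozen=True)
class CorrMetrics:
    """Excitation/inhibition/half-decay summary of a correlogram.

    ``e``: fractional increase of the pre-spike peak above baseline.
    ``i``: fractional decrease of the post-spike trough below baseline
    (1 = complete suppression).  ``t_half``: ms from the trough until the
    deficit first recovers to half of (baseline - trough); NaN when i = 0.
    """

    e: float
    i: float
    t_half: float
    baseline: float
    e_window: tuple[float, float] = E_WINDOW
    i_window: tuple[float, float] = I_WINDOW
    smooth_bins: int = SMOOTH_BINS


def _lag_pairs(
    ref: np.ndarray, target: np.ndarray, half_s: float, duration: float
) -> tuple[np.ndarray, int]:
    """All target-minus-reference lags within +-half_s, vectorised.

    Reference spikes closer than half_s to either end of the recording are
    dropped.  Returns (lags in seconds, number of usable reference spikes).
    """
    usable = ref[(ref >= half_s) & (ref <= duration - half_s)]
    if usable.size == 0:
        return np.empty(0), 0
    lo = np.searchsorted(target, usable - half_s, side="left")
    hi = np.searchsorted(target, usable + half_s, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0), int(usable.size)
    # Flat indices of the concatenated [lo_j, hi_j) ranges.
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    flat = np.arange(total) - np.repeat(starts, counts) + np.repeat(lo, counts)
    lags = target[flat] - np.repeat(usable, counts)
    return lags, int(usable.size)


def cross_correlogram(
    ref: SpikeTrain,
    target: SpikeTrain,
    window: float = 20.0,
    bin_width: float = 0.1,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
) -> Correlogram:
    """Histogram of target spikes around each reference spike.

    ``window`` is the total span in ms (lags cover +-window/2); the lag grid
    is centred so one bin is centred on zero.  Normalised per reference
    spike, as a rate (per bin width, spikes/s) and as a probability per bin.
    """
    if len(ref) == 0:
        raise ValueError("reference train is empty")
    if len(target) == 0:
        raise ValueError("target train is empty")
    half_ms = window / 2.0
    n_half = int(round(half_ms / bin_width))
    edges_ms = (np.arange(2 * n_half + 2) - n_half - 0.5) * bin_width
    lags_ms = (edges_ms[:-1] + edges_ms[1:]) / 2.0
    duration = min(ref.duration, target.duration)
    # Collect pairs over the full histogram extent (the outermost bins are
    # centred on +-window/2 and reach half a bin beyond it).
    half_ext_s = (n_half + 0.5) * bin_width * 1e-3
    lag_s, n_ref = _lag_pairs(ref.times, target.times, half_ext_s, duration)
    if n_ref == 0:
        raise ValueError("no reference spikes far enough from the record edges")
    counts, _ = np.histogram(lag_s * 1e3, bins=edges_ms)
    prob = counts / n_ref
    rate = prob / (bin_width * 1e-3)
    base_mask = (lags_ms >= baseline_window[0] - bin_width * 1e-9) & (
        lags_ms <= baseline_window[1] + bin_width * 1e-9
    )
    baseline = float(rate[base_mask].mean()) if base_mask.any() else float("nan")
    return Correlogram(
        bin_width=bin_width,
        lags=lags_ms,
        rate=rate,
        probability=prob,
        n_ref=n_ref,
        baseline=baseline,
        baseline_window=baseline_window,
    )


def autocorrelogram(
    train: SpikeTrain, window: float = 20.0, bin_width: float = 0.1
) -> Correlogram:
    """Correlogram of a train against itself, self-pairs included.

    The probability variant equals 1 in the lag-0 bin (every reference spike
    pairs with itself), which is the conventional normalisation check.
    """
    return cross_correlogram(train, train, window=window, bin_width=bin_width)


def correlogram_metrics(
    c: Correlogram,
    e_window: tuple[float, float] = E_WINDOW,
    i_window: tuple[float, float] = I_WINDOW,
    smooth_bins: int = SMOOTH_BINS,
) -> CorrMetrics:
    """Excitation ``e``, inhibition ``i`` and half-decay ``t_half``.

    ``e`` and ``i`` are read from the raw rate variant over the pre-spike
    [-5, 0) ms and post-spike [0, +5] ms windows; ``t_half`` is measured on
    a ``smooth_bins``-wide boxcar-smoothed rate to stabilise the
    half-recovery crossing.
    """
    if not np.isfinite(c.baseline) or c.baseline <= 0:
        raise ValueError("correlogram baseline is undefined or non-positive")
    e_mask = c.window_mask(*e_window, closed_hi=False)
    i_mask = c.window_mask(*i_window, closed_hi=True)
    e = max(0.0, float(c.rate[e_mask].max() - c.baseline) / c.baseline)
    trough_idx_local = int(np.argmin(c.rate[i_mask]))
    trough_idx = int(np.flatnonzero(i_mask)[trough_idx_local])
    trough = float(c.rate[trough_idx])
    i = max(0.0, (c.baseline - trough) / c.baseline)
    i = min(i, 1.0)
    if i == 0.0:
        return CorrMetrics(e=e, i=0.0, t_half=float("nan"), baseline=c.baseline,
                           e_window=e_window, i_window=i_window,
                           smooth_bins=smooth_bins)
    kern = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(c.rate, kern, mode="same")
    half_level = trough + (c.baseline - trough) / 2.0
    after = smooth[trough_idx:]
    above = np.flatnonzero(after >= half_level)
    t_half = float(above[0]) * c.bin_width if above.size else float("nan")
    if t_half == 0.0:
        t_half = c.bin_width  # recovery within one bin resolves at bin width
    return CorrMetrics(e=e, i=i, t_half=t_half, baseline=c.baseline,
                       e_window=e_window, i_window=i_window,
                       smooth_bins=smooth_bins)


def pool_correlograms(correlograms: list[Correlogram]) -> Correlogram:
    """Combine correlograms computed on the same lag grid.

    Counts and reference-spike numbers are summed, which is equivalent to a
    single correlogram over the concatenated reference trains; useful for
    pooling same-size inputs to improve the signal-to-noise of (e, i,
    t_half) estimates.
    """
    if not correlograms:
        raise ValueError("nothing to pool")
    c0 = correlograms[0]
    for c in correlograms[1:]:
        if c.bin_width != c0.bin_width or c.lags.size != c0.lags.size:
            raise ValueError("correlograms must share their lag grid")
    n_ref = sum(c.n_ref for c in correlograms)
    counts = sum(c.probability * c.n_ref for c in correlograms)
    prob = counts / n_ref
    rate = prob / (c0.bin_width * 1e-3)
    base_mask = (c0.lags >= c0.baseline_window[0] - c0.bin_width * 1e-9) & (
        c0.lags <= c0.baseline_window[1] + c0.bin_width * 1e-9
    )
    return Correlogram(
        bin_width=c0.bin_width,
        lags=c0.lags,
        rate=rate,
        probability=prob,
        n_ref=n_ref,
        baseline=float(rate[base_mask].mean()),
        baseline_window=c0.baseline_window,
    )


def rate_code_slope(
    input_rates: np.ndarray, output_rates: np.ndarray
) -> float:
    """Least-squares slope of output firing rate against input firing rate."""
    x = np.asarray(input_rates, float)
    y = np.asarray(output_rates, float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("need >= 2 paired rate points")
    if np.ptp(x) == 0:
        raise ValueError("input rates are degenerate (all equal)")
    return float(np.polyfit(x, y, 1)[0])


def pause_psth(
    cbn_spikes: SpikeTrain,
    pause_onsets: np.ndarray,
    window: tuple[float, float] = (-10.0, 20.0),
    bin_width: float = 0.5,
    baseline_window: float = 5.0,
    peak_time: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Pause-aligned PSTH normalised to the pre-pause baseline rate.

    Parameters
    ----------
    pause_onsets
        Pause onset times, seconds.
    window
        (pre, post) extent of the histogram around each onset, ms.
    baseline_window
        Baseline is the mean rate over this many ms immediately before onset.
    peak_time
        If given (ms after onset, e.g. taken from the 100%-paused
        condition), the normalised peak is read at that lag; otherwise at
        the maximum over lags in (0, window[1]].

    Returns
    -------
    (lags_ms, normalized_psth, normalized_peak, peak_lag_ms)
    """
    onsets = np.asarray(pause_onsets, float)
    if onsets.size == 0:
        raise ValueError("need at least one pause onset")
    lo, hi = window
    edges_ms = np.arange(lo, hi + bin_width / 2, bin_width)
    lags_ms = (edges_ms[:-1] + edges_ms[1:]) / 2.0
    half_s = max(abs(lo), abs(hi)) * 1e-3
    usable = onsets[(onsets >= half_s) & (onsets <= cbn_spikes.duration - half_s)]
    if usable.size == 0:
        raise ValueError("no pause onsets far enough from the record edges")
    lo_i = np.searchsorted(cbn_spikes.times, usable + lo * 1e-3)
    hi_i = np.searchsorted(cbn_spikes.times, usable + hi * 1e-3)
    counts_per = hi_i - lo_i
    total = int(counts_per.sum())
    starts = np.concatenate(([0], np.cumsum(counts_per)[:-1]))
    flat = np.arange(total) - np.repeat(starts, counts_per) + np.repeat(lo_i, counts_per)
    lags = (cbn_spikes.times[flat] - np.repeat(usable, counts_per)) * 1e3
    counts, _ = np.histogram(lags, bins=edges_ms)
    rate = counts / (usable.size * bin_width * 1e-3)  # spikes/s per bin
    base_mask = (lags_ms >= -baseline_window) & (lags_ms < 0)
    baseline = float(rate[base_mask].mean())
    if baseline <= 0:
        raise ValueError("pre-pause baseline rate is zero")
    norm = rate / baseline
    post = (lags_ms > 0) & (lags_ms <= hi)
    if peak_time is None:
        peak_idx = int(np.flatnonzero(post)[np.argmax(norm[post])])
    else:
        peak_idx = int(np.argmin(np.abs(lags_ms - peak_time)))
    return lags_ms, norm, float(norm[peak_idx]), float(lags_ms[peak_idx])


def write_correlogram_csv(path: str | Path, c: Correlogram, **extra_meta) -> None:
    """Export as CSV (lag_ms, rate_sps, probability) with a metadata header."""
    meta = {
        "bin_ms": c.bin_width,
        "window_ms": float(c.lags[-1] - c.lags[0] + c.bin_width),
        "n_ref": c.n_ref,
        "baseline_sps": c.baseline,
        "baseline_window_ms": c.baseline_window,
        **extra_meta,
    }
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("lag_ms,rate_sps,probability\n")
        for lag, r, p in zip(c.lags, c.rate, c.probability):
            fh.write(f"{lag:.6f},{float(r)!r},{float(p)!r}\n")
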