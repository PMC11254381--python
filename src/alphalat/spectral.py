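"""Time-frequency power estimation.

The estimator uses a frequency-dependent sliding window of ``n_cycles``
cycles (300 ms at 10 Hz for 3 cycles), stepped every 10 ms: each segment is
demeaned, multiplied by a Hanning taper, zero-padded to the next power of
two, Fourier-transformed, and the squared magnitude at the padded-FFT bin
nearest the target frequency is recorded at the window center (scaled by
the taper gain ``2/sum(taper)`` so a unit-amplitude sinusoid reads near 1
regardless of window length).  Center
times where the full window does not fit inside the epoch are NaN.  Power
values at the two planar gradiometer channels of one location are summed by
:func:`combine_planar`.  No baseline normalisation is applied anywhere:
downstream modulation indices are self-normalising power ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EpochSet, TFRPower

DEFAULT_FREQS = np.arange(2.0, 31.0)


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


def single_window_power(segment: np.ndarray, freq: float, fs: float) -> float:
    """Reference power of one already-extracted segment at one frequency.

    Direct implementation of the per-window recipe (demean, Hanning taper,
    zero-pad to next power of two, FFT, squared magnitude at the nearest
    bin).  Used as the elementary oracle for :func:`compute_tfr`.
    """
    seg = np.asarray(segment, dtype=float)
    seg = seg - seg.mean()
    taper = np.hanning(len(seg))
    nfft = _next_pow2(len(seg))
    spec = np.fft.rfft(seg * taper, n=nfft)
    bins = np.fft.rfftfreq(nfft, 1.0 / fs)
    b = int(np.argmin(np.abs(bins - freq)))
    gain = 2.0 / taper.sum()
    return float(np.abs(gain * spec[b]) ** 2)


def compute_tfr(epochs: EpochSet, freqs=None, n_cycles: int = 3,
                time_step: float = 0.010, tmin: float | None = None,
                tmax: float | None = None) -> TFRPower:
    """Sliding-window Hanning-taper TFR of power.

    Parameters
    ----------
    epochs : EpochSet
        Input trials x sensors x samples.
    freqs : array-like of float, optional
        Target frequencies in Hz; defaults to the 2-30 Hz grid in 1 Hz steps.
    n_cycles : int
        Window length in cycles of the target frequency.
    time_step : float
        Spacing of window centers in seconds (must be a multiple of the
        sample interval).
    tmin, tmax : float, optional
        Restrict window centers to this interval (inclusive); useful when
        only a sub-window (e.g. the pre-target interval) is analysed.
    """
    if epochs.n_trials == 0:
        raise ValueError("empty trial set")
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    fs = epochs.sampling_rate
    t = epochs.times
    n_samples = len(t)

    step = time_step * fs
    if abs(step - round(step)) > 1e-9:
        raise ValueError(
            f"time_step {time_step} s is not a whole number of samples at "
            f"{fs} Hz")
    # centers on the absolute time_step grid (multiples of time_step)
    ratio = t / time_step
    on_grid = np.abs(ratio - np.round(ratio)) < 1e-6
    centers = np.flatnonzero(on_grid)
    if tmin is not None:
        centers = centers[t[centers] >= tmin - 1e-12]
    if tmax is not None:
        centers = centers[t[centers] <= tmax + 1e-12]
    if len(centers) == 0:
        raise ValueError("no window centers inside the epoch")
    times_out = t[centers]

    n_trials, n_sensors, _ = epochs.data.shape
    power = np.full((n_trials, n_sensors, len(freqs), len(centers)), np.nan)

    # window layout per frequency: which centers fit, window length, FFT bin
    layout = []
    for fi, f in enumerate(freqs):
        L = int(round(n_cycles / f * fs))
        if L < 2 or L > n_samples:
            continue
        starts = centers - L // 2
        valid = (starts >= 0) & (starts + L <= n_samples)
        if not valid.any():
            continue
        layout.append((fi, float(f), L, valid, starts[valid]))
    if not layout:
        raise ValueError(
            "no frequency's analysis window fits inside the epoch")

    # The zero-padded FFT bin b of a demeaned, tapered segment is
    #   sum_l (x[l] - mean(x)) taper[l] e^{-2i pi b l / nfft}
    # i.e. a correlation of x with the tapered complex exponential, minus the
    # segment mean times the kernel sum.  Both pieces are convolutions along
    # time: they are evaluated in the frequency domain against a single
    # forward FFT of the data (shared across frequencies and kernels) and
    # sampled at the window-start positions.  Trials are processed in chunks
    # to bound the size of the inverse-FFT temporaries.
    l_max = max(L for _, _, L, _, _ in layout)
    nconv = _next_pow2(n_samples + l_max - 1)
    kspecs = []
    for fi, f, L, valid, vstarts in layout:
        nfft = _next_pow2(L)
        bins = np.fft.rfftfreq(nfft, 1.0 / fs)
        b = int(np.argmin(np.abs(bins - f)))
        taper = np.hanning(L)
        kernel = (2.0 / taper.sum()) * taper * np.exp(
            -2j * np.pi * b * np.arange(L) / nfft)
        mean_kernel = np.full(L, 1.0 / L)
        # correlation at lag s = convolution with the reversed kernel,
        # read from the full convolution at offset s + L - 1
        kr_f = np.fft.rfft(np.real(kernel)[::-1], nconv)
        ki_f = np.fft.rfft(np.imag(kernel)[::-1], nconv)
        km_f = np.fft.rfft(mean_kernel, nconv)
        kspecs.append((fi, valid, vstarts + L - 1, kr_f, ki_f, km_f,
                       kernel.sum()))

    chunk = max(1, 2 ** 22 // max(1, n_sensors * nconv))
    for lo in range(0, n_trials, chunk):
        hi = min(lo + chunk, n_trials)
        dspec = np.fft.rfft(epochs.data[lo:hi], nconv, axis=-1)
        for fi, valid, pos, kr_f, ki_f, km_f, ksum in kspecs:
            re = np.fft.irfft(dspec * kr_f, nconv, axis=-1)[..., pos]
            im = np.fft.irfft(dspec * ki_f, nconv, axis=-1)[..., pos]
            mu = np.fft.irfft(dspec * km_f, nconv, axis=-1)[..., pos]
            spec_re = re - mu * ksum.real
            spec_im = im - mu * ksum.imag
            power[lo:hi, :, fi, valid] = spec_re ** 2 + spec_im ** 2
    return TFRPower(power=power, freqs=freqs, times=times_out,
                    sensor_meta=epochs.sensor_meta.copy(), combined=False)


def combine_planar(tfr: TFRPower) -> TFRPower:
    """Sum power over the two planar channels of each sensor location."""
    if tfr.combined:
        raise ValueError("TFR is already pair-combined")
    meta = tfr.sensor_meta
    required = {"pair_id", "hemisphere", "planar_channel_index"}
    if not required <= set(meta.columns):
        raise ValueError("sensor_meta lacks planar pairing columns")
    groups = meta.groupby(["pair_id", "hemisphere"], sort=True)
    rows = []
    combined = []
    for (pid, hemi), g in groups:
        if len(g) != 2:
            raise ValueError(
                f"location (pair {pid}, {hemi}) has {len(g)} channels, "
                "expected exactly 2")
        idx = g.index.to_numpy()
        combined.append(tfr.power[:, idx[0]] + tfr.power[:, idx[1]])
        rows.append((f"P{int(pid):02d}{hemi[0].upper()}", hemi, pid))
    power = np.stack(combined, axis=1)
    sensor_meta = pd.DataFrame(rows, columns=["label", "hemisphere", "pair_id"])
    return TFRPower(power=power, freqs=tfr.freqs, times=tfr.times,
                    sensor_meta=sensor_meta, combined=True)


def band_window_average(tfr: TFRPower, band=(8.0, 13.0),
                        window=(-0.850, 0.0), trial_selector=None) -> np.ndarray:
    """Mean power per sensor over trials, a closed frequency band and a
    closed time window.

    ``trial_selector`` may be a boolean mask or an index array; ``None``
    selects all trials.  Raises on an empty trial selection or when the band
    or window misses the grids.
    """
    if trial_selector is None:
        trials = np.arange(tfr.power.shape[0])
    else:
        trial_selector = np.asarray(trial_selector)
        if trial_selector.dtype == bool:
            trials = np.flatnonzero(trial_selector)
        else:
            trials = trial_selector
    if len(trials) == 0:
        raise ValueError("empty trial selection")
    fsel = (tfr.freqs >= band[0] - 1e-9) & (tfr.freqs <= band[1] + 1e-9)
    if not fsel.any():
        raise ValueError(f"band {band} does not intersect the frequency grid")
    tsel = (tfr.times >= window[0] - 1e-9) & (tfr.times <= window[1] + 1e-9)
    if not tsel.any():
        raise ValueError(f"window {window} outside the time axis")
    sub = tfr.power[np.ix_(trials, np.arange(tfr.power.shape[1]),
                           np.flatnonzero(fsel), np.flatnonzero(tsel))]
    return sub.mean(axis=(0, 2, 3))
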