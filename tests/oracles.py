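"""Independent signal-processing oracles used by the test suite.

Everything here is deliberately simple and self-contained (Welch PSD,
band-power ratios, envelope autocorrelation) so it cannot share bugs with
the package's own feature pipeline.
"""

import numpy as np
from scipy import signal as sps


def welch_psd(x, fs):
    f, p = sps.welch(x, fs=fs, nperseg=min(len(x), 512))
    return f, p


def psd_loglog_slope(x, fs, f_lo=1.0, f_hi=40.0):
    """Least-squares slope of log10(PSD) vs log10(f)."""
    f, p = welch_psd(x, fs)
    m = (f >= f_lo) & (f <= f_hi) & (p > 0)
    return np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]


def band_power_fraction(x, fs, lo, hi):
    f, p = welch_psd(x, fs)
    total = np.trapezoid(p, f)
    m = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[m], f[m]) / total)


def envelope(x, fs, lo=20.0, hi=None, smooth_s=0.05):
    """Rectified, smoothed envelope of the band-passed signal."""
    hi = hi or 0.45 * fs
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    env = np.abs(sps.sosfiltfilt(sos, x))
    win = max(int(smooth_s * fs), 1)
    return np.convolve(env, np.ones(win) / win, mode="same")


def autocorr(x):
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    return ac / max(ac[0], 1e-12)


def envelope_periodicity(x, fs, lag_lo_s=0.2, lag_hi_s=1.5, lo=20.0):
    """(peak lag s, peak height) of the envelope autocorrelation."""
    ac = autocorr(envelope(x, fs, lo=lo))
    lo_i, hi_i = int(lag_lo_s * fs), min(int(lag_hi_s * fs), ac.size - 1)
    seg = ac[lo_i:hi_i]
    i = int(np.argmax(seg))
    return (lo_i + i) / fs, float(seg[i])


def slow_event_stats(x, fs):
    """(event rate Hz, median event width s) of slow deflections."""
    sos = sps.butter(4, 5.0, btype="lowpass", fs=fs, output="sos")
    slow = sps.sosfiltfilt(sos, x)
    thr = 0.5 * np.max(np.abs(slow))
    above = np.abs(slow) > thr
    edges = np.flatnonzero(np.diff(above.astype(int)) == 1)
    widths = []
    for e in edges:
        stop = e
        while stop < above.size and above[stop]:
            stop += 1
        widths.append((stop - e) / fs)
    rate = edges.size / (x.size / fs)
    return rate, (float(np.median(widths)) if widths else 0.0)


def rule_classify(x, fs):
    """Band-power + envelope-periodicity decision rule over the artifact
    taxonomy; used to certify that the synthetic classes are separable."""
    from scipy import stats

    x = np.asarray(x, dtype=float)

    # electrode faults: impulsive jumps/steps (heavy-tailed sample-to-sample
    # differences) or flat-line dropout (near-zero variance region)
    w = int(0.2 * fs)
    roll = np.lib.stride_tricks.sliding_window_view(x, w)[::w].std(axis=1)
    flat = np.any(roll < 0.15 * np.median(roll))
    if flat or stats.kurtosis(np.diff(x)) > 20:
        return "ELEC"

    hi_frac = band_power_fraction(x, fs, 20, 80)
    if hi_frac >= 0.4:
        env = envelope(x, fs, lo=20, hi=80)
        cv = env.std() / (env.mean() + 1e-12)
        if cv < 0.55:
            return "MUSC"
        _, height = envelope_periodicity(x, fs)
        return "RC" if height >= 0.6 else "CHEW"

    if band_power_fraction(x, fs, 8.5, 11.5) >= 0.35:
        return "SHIV"

    rate, _ = slow_event_stats(x, fs)
    return "BLINK" if rate >= 1.5 else "EYEM"
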