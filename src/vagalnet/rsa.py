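"""Porges-Bohrer respiratory sinus arrhythmia (PB_RSA) from R-R intervals.

The metric quantifies cardiac vagal tone as the natural log of heart-period
variance in the spontaneous-breathing frequency band. The processing chain,
applied to a beat-to-beat R-R interval series (milliseconds):

1. time the sequential R-R intervals (input);
2. resample the intervals onto an evenly spaced 500 ms grid;
3. detrend with a 21-point cubic moving polynomial (local least-squares
   template subtracted from the series);
4. band-pass the residual to the adult respiratory band, 0.12-0.40 Hz;
5. take the natural log of the filtered-signal variance in sequential
   30 s epochs and average the epochs.

On stationary heart-period data the result is equivalent to integrating
spectral power over the same band, which the tests exploit as an oracle.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "RRSeries",
    "HeartPeriodTimeSeries",
    "RSAResult",
    "rr_to_time_series",
    "moving_polynomial_detrend",
    "bandpass_filter",
    "epoch_ln_variance",
    "compute_pb_rsa",
    "welch_band_power",
    "read_rr_csv",
    "write_rsa_result",
]

#: adult spontaneous-breathing band (Hz); configurable for other age groups
ADULT_RSA_BAND = (0.12, 0.40)


@dataclasses.dataclass(frozen=True)
class RRSeries:
    """Beat-to-beat heart periods in milliseconds.

    ``intervals[k]`` is the heart period between beat k and beat k+1, so the
    instantaneous heart-period function is piecewise constant: it takes the
    value ``intervals[k]`` on ``[beat_times[k], beat_times[k+1])``.
    """

    intervals: np.ndarray  # ms, length n
    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1 or iv.size < 2:
            raise ValueError("need at least 2 R-R intervals")
        if not np.all(iv > 0):
            raise ValueError("all R-R intervals must be positive")
        object.__setattr__(self, "intervals", iv)

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative milliseconds from the first beat (length n+1)."""
        return np.concatenate(([0.0], np.cumsum(self.intervals)))

    @property
    def duration_ms(self) -> float:
        return float(np.sum(self.intervals))


@dataclasses.dataclass(frozen=True)
class HeartPeriodTimeSeries:
    """Evenly sampled heart-period signal (ms per sample)."""

    values: np.ndarray
    sample_interval: float = 500.0  # ms; 500 ms = 2 Hz
    start_time: float = 0.0  # ms, left edge of the first bin

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(v > 0):
            raise ValueError("heart-period samples must be positive")
        object.__setattr__(self, "values", v)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.sample_interval


@dataclasses.dataclass(frozen=True)
class RSAResult:
    epoch_ln_variances: np.ndarray  # ln(ms^2), NaN where epoch was flagged
    pb_rsa: float  # mean of unflagged epoch ln-variances
    mean_heart_rate: float  # beats per minute
    n_epochs: int
    epoch_flags: np.ndarray  # True where epoch variance below floor
    flags: frozenset  # quality markers for the whole recording


# -- step 2: resampling ------------------------------------------------------

def rr_to_time_series(rr: RRSeries, sample_interval: float = 500.0) -> HeartPeriodTimeSeries:
    """Resample R-R intervals onto an even grid by time-weighted averaging.

    Each output sample is the average of the piecewise-constant instantaneous
    heart-period function over its bin, computed exactly from the running
    integral (total time is conserved). A trailing partial bin is discarded.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    total = rr.duration_ms
    if total < 2 * sample_interval:
        raise ValueError(
            f"recording ({total:.0f} ms) shorter than two sample intervals"
        )
    n_bins = int(total // sample_interval)
    edges = np.arange(n_bins + 1) * sample_interval
    # running integral of h(t): piecewise linear, slope = interval value
    cum = np.concatenate(([0.0], np.cumsum(rr.intervals * rr.intervals)))
    cum_at_edges = np.interp(edges, rr.beat_times, cum)
    values = np.diff(cum_at_edges) / sample_interval
    return HeartPeriodTimeSeries(values=values, sample_interval=sample_interval)


# -- step 3: moving-polynomial detrend ---------------------------------------

def _local_poly_value(x: np.ndarray, lo: int, hi: int, i: int, order: int) -> float:
    """Least-squares polynomial over x[lo:hi], evaluated at index i."""
    pos = np.arange(lo, hi, dtype=float) - i
    coef = np.polynomial.polynomial.polyfit(pos, x[lo:hi], order)
    return float(coef[0])


def moving_polynomial_detrend(
    values: np.ndarray | HeartPeriodTimeSeries,
    window: int = 21,
    order: int = 3,
) -> np.ndarray:
    """Subtract a moving local-polynomial template (slow-trend removal).

    The template at each sample is a least-squares polynomial of the given
    order fit over the centered window and evaluated at the center — the
    Savitzky-Golay smoother. Near the edges the window is truncated
    asymmetrically rather than discarding samples, so the residual series
    has the same length as the input.
    """
    x = values.values if isinstance(values, HeartPeriodTimeSeries) else np.asarray(values, float)
    if window % 2 == 0 or window < order + 2:
        raise ValueError("window must be odd and exceed the polynomial order")
    n = x.size
    if n < window:
        raise ValueError(f"series length {n} shorter than window {window}")
    half = window // 2
    template = signal.savgol_filter(x, window, order)
    for i in range(half):
        template[i] = _local_poly_value(x, 0, i + half + 1, i, order)
        j = n - 1 - i
        template[j] = _local_poly_value(x, j - half, n, j, order)
    return x - template


# -- step 4: band-pass filter ------------------------------------------------

def bandpass_filter(
    values: np.ndarray,
    low: float = ADULT_RSA_BAND[0],
    high: float = ADULT_RSA_BAND[1],
    fs: float = 2.0,
    numtaps: int | None = None,
) -> np.ndarray:
    """Zero-phase FIR band-pass along axis 0.

    A linear-phase FIR (Hamming-windowed sinc) is applied forward and
    backward, giving zero phase and squaring the magnitude response. With
    the default tap count the two-pass response is within a few percent of
    unity across the passband and attenuates 0.06 Hz and 0.55 Hz signals by
    far more than 90% for the adult band at 2 Hz sampling. The tap count is
    reduced automatically for short series (the reflect padding used by
    filtfilt needs ~3 filter lengths of signal).
    """
    x = np.asarray(values, dtype=float)
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high < fs/2 = {fs / 2}")
    n = x.shape[0]
    max_taps = (n - 1) // 3
    if max_taps % 2 == 0:
        max_taps -= 1
    taps = min(numtaps if numtaps is not None else 127, max_taps)
    if taps < 9:
        raise ValueError(f"series too short ({n} samples) to band-pass")
    b = signal.firwin(taps, [low, high], pass_zero=False, fs=fs)
    return signal.filtfilt(b, [1.0], x, axis=0, padlen=min(3 * taps, n - 1))


# -- step 5: epoch log-variance ----------------------------------------------

def epoch_ln_variance(
    values: np.ndarray,
    fs: float = 2.0,
    epoch_seconds: float = 30.0,
    var_floor: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """ln of sample variance (ddof=1) over sequential non-overlapping epochs.

    Returns (ln_variances, flags). Epochs whose variance falls below
    ``var_floor`` (ms^2) are flagged and get NaN instead of ln(~0); the
    trailing incomplete epoch is discarded.
    """
    x = np.asarray(values, dtype=float)
    n_per = int(round(epoch_seconds * fs))
    if x.size < n_per:
        raise ValueError(f"series ({x.size} samples) shorter than one {epoch_seconds:.0f} s epoch")
    n_ep = x.size // n_per
    ep = x[: n_ep * n_per].reshape(n_ep, n_per)
    variances = ep.var(axis=1, ddof=1)
    flags = variances < var_floor
    ln_vars = np.where(flags, np.nan, np.log(np.maximum(variances, var_floor)))
    return ln_vars, flags


# -- full chain ---------------------------------------------------------------

def compute_pb_rsa(
    rr: RRSeries,
    sample_interval: float = 500.0,
    detrend_window: int = 21,
    detrend_order: int = 3,
    band: tuple[float, float] = ADULT_RSA_BAND,
    epoch_seconds: float = 30.0,
    var_floor: float = 1e-8,
) -> RSAResult:
    """Full PB_RSA chain: resample, detrend, band-pass, epoch ln-variance.

    ``pb_rsa`` is the mean of the unflagged epoch ln-variances (ln ms^2);
    ``mean_heart_rate`` is 60000 / mean R-R interval (bpm). When every epoch
    is below the variance floor (e.g. a metronomic heart) pb_rsa is NaN and
    the recording is flagged rather than raising.
    """
    if rr.duration_ms < 60_000:
        raise ValueError("recording must span at least 60 s")
    ts = rr_to_time_series(rr, sample_interval=sample_interval)
    resid = moving_polynomial_detrend(ts, window=detrend_window, order=detrend_order)
    filt = bandpass_filter(resid, band[0], band[1], fs=ts.fs)
    ln_vars, ep_flags = epoch_ln_variance(
        filt, fs=ts.fs, epoch_seconds=epoch_seconds, var_floor=var_floor
    )
    flags: set[str] = set()
    if ep_flags.any():
        flags.add("near_zero_variance_epoch")
    if ep_flags.all():
        flags.add("all_epochs_near_zero_variance")
        pb = float("nan")
    else:
        pb = float(np.nanmean(ln_vars))
    return RSAResult(
        epoch_ln_variances=ln_vars,
        pb_rsa=pb,
        mean_heart_rate=float(60_000.0 / np.mean(rr.intervals)),
        n_epochs=int(ln_vars.size),
        epoch_flags=ep_flags,
        flags=frozenset(flags),
    )


def welch_band_power(values: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Integrated Welch power (signal variance) over a frequency band.

    Independent spectral route to the band variance; on stationary series
    ln of this quantity should agree with pb_rsa.
    """
    x = np.asarray(values, dtype=float)
    f, p = signal.welch(x, fs=fs, nperseg=min(x.size, 256), detrend="constant")
    mask = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[mask], f[mask]))


# -- I/O -----------------------------------------------------------------------

def read_rr_csv(path) -> RRSeries:
    """Read R-R intervals from CSV: either an ``rr_ms`` column of intervals
    or a ``t_ms`` column of cumulative beat times."""
    df = pd.read_csv(path)
    if "rr_ms" in df.columns:
        return RRSeries(intervals=df["rr_ms"].to_numpy(float))
    if "t_ms" in df.columns:
        return RRSeries(intervals=np.diff(df["t_ms"].to_numpy(float)))
    raise ValueError(f"{path}: expected an 'rr_ms' or 't_ms' column")


def write_rsa_result(result: RSAResult, path) -> None:
    """Write per-epoch ln-variances plus a summary row as CSV."""
    rows = [
        {"epoch": i, "ln_variance": lv, "flagged": bool(fl)}
        for i, (lv, fl) in enumerate(zip(result.epoch_ln_variances, result.epoch_flags))
    ]
    rows.append(
        {
            "epoch": "summary",
            "ln_variance": result.pb_rsa,
            "flagged": ";".join(sorted(result.flags)),
            "mean_heart_rate_bpm": result.mean_heart_rate,
            "n_epochs": result.n_epochs,
        }
    )
    pd.DataFrame(rows).to_csv(path, index=False)
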