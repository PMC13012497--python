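"""Band-power feature extraction from pre-awakening EEG.

The pipeline mirrors standard sleep-EEG practice: each multichannel segment
is robust-detrended with a second-order polynomial (iteratively reweighted
least squares, so large transients do not bend the fit), cut to the 120 s
immediately preceding the alarm, converted to a one-sided power spectral
density with Welch's method (4-s Hamming windows, 90% overlap, density
scaling), and integrated over the delta (0.5-4 Hz) and gamma (25-50 Hz)
bands with the trapezoidal rule.  Band powers are natural-log transformed;
the gamma/delta ratio is the difference of the two log tables, so the
log-ratio identity ratio = gamma - delta holds exactly by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import signal

__all__ = [
    "BandDefinition",
    "EEGSegment",
    "DELTA",
    "GAMMA",
    "DEFAULT_BANDS",
    "robust_detrend",
    "extract_prealarm_window",
    "welch_psd",
    "band_power",
    "extract_features",
]

#: floor applied to nonpositive integrated band powers before the log
POWER_FLOOR = float(np.finfo(float).eps)


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")


DELTA = BandDefinition("delta", 0.5, 4.0)
GAMMA = BandDefinition("gamma", 25.0, 50.0)
DEFAULT_BANDS = {"delta": DELTA, "gamma": GAMMA}


@dataclass
class EEGSegment:
    """One pre-awakening EEG epoch.

    data is channels x samples in microvolts; ``alarm_index`` marks the
    sample of alarm onset (segments typically run 2 s past it).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    alarm_index: int

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not (0 <= self.alarm_index <= self.data.shape[1]):
            raise ValueError("alarm_index outside the segment")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def robust_detrend(segment: EEGSegment, order: int = 2, n_iter: int = 3,
                   threshold: float = 3.0) -> EEGSegment:
    """Remove a polynomial trend per channel by iteratively reweighted fits.

    Samples deviating more than ``threshold`` robust SDs from the current
    fit receive Tukey-biweight downweights, so the polynomial tracks the
    slow drift rather than artifacts.  A constant channel detrends to zeros.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    n = segment.n_samples
    if n < order + 2:
        raise ValueError(f"need at least {order + 2} samples for order {order}")
    t = np.linspace(-1.0, 1.0, n)
    out = np.empty_like(segment.data)
    for ci, x in enumerate(segment.data):
        w = np.ones(n)
        coefs = npoly.polyfit(t, x, order)
        for _ in range(n_iter):
            resid = x - npoly.polyval(t, coefs)
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if scale <= 0:
                break
            u = resid / (threshold * scale)
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            if w.sum() < order + 2:
                break
            coefs = npoly.polyfit(t, x, order, w=np.sqrt(w))
        out[ci] = x - npoly.polyval(t, coefs)
    return replace(segment, data=out)


def extract_prealarm_window(segment: EEGSegment, window: float = 120.0) -> EEGSegment:
    """The last ``window`` seconds of data ending exactly at alarm onset."""
    if window <= 0:
        raise ValueError("window must be positive")
    n_win = int(round(window * segment.fs))
    if segment.alarm_index < n_win:
        raise ValueError(
            f"only {segment.alarm_index / segment.fs:.1f} s of pre-alarm data, "
            f"need {window:.1f} s"
        )
    sl = slice(segment.alarm_index - n_win, segment.alarm_index)
    return replace(segment, data=segment.data[:, sl], alarm_index=n_win)


def welch_psd(segment: EEGSegment, window_len: float = 4.0,
              overlap: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (Hamming taper, density scaling).

    Returns (freqs, psd) with psd shaped channels x frequencies; the
    frequency resolution is 1/window_len.  Density scaling means the
    integral of the PSD over frequency approximates the signal variance.
    """
    nperseg = int(round(window_len * segment.fs))
    if nperseg > segment.n_samples:
        raise ValueError(
            f"window of {window_len} s exceeds segment of {segment.duration:.1f} s"
        )
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    freqs, psd = signal.welch(
        segment.data,
        fs=segment.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=False,
        scaling="density",
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Trapezoidal integral of the PSD over [f_lo, f_hi], per channel.

    The PSD is linearly interpolated onto the exact band edges so the
    integral does not depend on how the frequency grid is phased relative
    to the band.
    """
    psd = np.atleast_2d(psd)
    if band.f_lo < freqs[0] or band.f_hi > freqs[-1]:
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz outside PSD range "
            f"[{freqs[0]}, {freqs[-1]}] Hz"
        )
    inside = (freqs > band.f_lo) & (freqs < band.f_hi)
    grid = np.concatenate(([band.f_lo], freqs[inside], [band.f_hi]))
    lo_val = np.array([np.interp(band.f_lo, freqs, ch) for ch in psd])
    hi_val = np.array([np.interp(band.f_hi, freqs, ch) for ch in psd])
    vals = np.concatenate(
        [lo_val[:, None], psd[:, inside], hi_val[:, None]], axis=1
    )
    return np.trapezoid(vals, grid, axis=1)


def extract_features(
    dataset,
    bands: dict[str, BandDefinition] | None = None,
    window: float = 120.0,
    detrend_order: int = 2,
    window_len: float = 4.0,
    overlap: float = 0.9,
) -> dict[str, pd.DataFrame]:
    """Log band-power tables {delta, gamma, ratio} from raw segments.

    Expects ``dataset.segments`` mapping record_id -> EEGSegment with at
    least ``window`` seconds before the alarm.  Nonpositive integrated
    powers are floored at machine epsilon and flagged with a warning; the
    ratio table is computed as log(gamma) - log(delta) so the identity is
    exact.
    """
    bands = dict(bands or DEFAULT_BANDS)
    if "delta" not in bands or "gamma" not in bands:
        raise ValueError("bands must include 'delta' and 'gamma'")
    if dataset.segments is None or not dataset.segments:
        raise ValueError("dataset has no raw segments attached")
    record_ids = list(dataset.records["record_id"])
    missing = [r for r in record_ids if r not in dataset.segments]
    if missing:
        raise ValueError(f"records without segments: {missing[:5]}")
    labels = None
    rows = {name: [] for name in bands}
    floored = 0
    for rid in record_ids:
        seg = dataset.segments[rid]
        if labels is None:
            labels = list(seg.channel_labels)
        seg = robust_detrend(seg, order=detrend_order)
        seg = extract_prealarm_window(seg, window=window)
        freqs, psd = welch_psd(seg, window_len=window_len, overlap=overlap)
        for name, band in bands.items():
            p = band_power(freqs, psd, band)
            nonpos = p <= 0
            if nonpos.any():
                floored += int(nonpos.sum())
                p = np.where(nonpos, POWER_FLOOR, p)
            rows[name].append(np.log(p))
    if floored:
        warnings.warn(
            f"{floored} nonpositive band powers floored at {POWER_FLOOR:.3g}"
        )
    idx = pd.Index(record_ids, name="record_id")
    tables = {
        name: pd.DataFrame(np.vstack(vals), index=idx, columns=labels)
        for name, vals in rows.items()
    }
    tables["ratio"] = tables["gamma"] - tables["delta"]
    return tables
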