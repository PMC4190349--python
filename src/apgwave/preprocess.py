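"""Pre-processing chain for acceleration photoplethysmogram (APG) analysis.

The raw fingertip photoplethysmogram (PPG) ``X[n]`` is band-pass filtered
with a zero-phase second-order Butterworth filter (default 0.5–15 Hz: the
pulse's energy lies below ~20 Hz, while baseline wander sits below 0.5 Hz
and mains interference far above the band).  The APG ``Z[n]`` is the second
derivative of the filtered PPG, computed with the three-point centred
stencil.  For a-wave detection the negative lobes (b, d waves) are clipped
to zero and the result squared, emphasising the large positive a-wave
excursions over the diastolic wave and residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError, InputError

__all__ = [
    "PPGRecord",
    "FilteredPPG",
    "APGSignal",
    "SquaredSignal",
    "bandpass_filter",
    "second_derivative",
    "clip_negative",
    "square",
    "preprocess",
]


def _as_float_array(samples) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"expected a 1-D sample array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class PPGRecord:
    """A uniformly sampled single-channel PPG time series.

    Parameters
    ----------
    samples : array-like
        Raw PPG samples in arbitrary amplitude units.
    fs : float
        Sampling rate in Hz (the study device sampled at 200 Hz).
    record_id : str
        Free-text label used in reports.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self):
        arr = _as_float_array(self.samples)
        if arr.size < 3:
            raise InputError(f"record needs >= 3 samples, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise InputError("record contains NaN or Inf samples")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class FilteredPPG:
    """Band-pass filtered PPG ``S[n]`` with its pass band in Hz."""

    samples: np.ndarray
    fs: float
    band: tuple[float, float] = (0.5, 15.0)


@dataclass(frozen=True)
class APGSignal:
    """Second derivative ``Z[n]`` of the filtered PPG (the APG).

    ``clipped`` records whether negative lobes have been zeroed (a-wave
    detection path); b-wave localization must use the unclipped APG because
    b is negative by definition.
    """

    samples: np.ndarray
    fs: float
    clipped: bool = False


@dataclass(frozen=True)
class SquaredSignal:
    """Squared clipped APG ``y[n]`` feeding the moving-average stage."""

    samples: np.ndarray
    fs: float


def bandpass_filter(rec: PPGRecord, f1: float = 0.5, f2: float = 15.0) -> FilteredPPG:
    """Zero-phase second-order Butterworth band-pass filter.

    Applied forward and backward (``sosfiltfilt``) so waveform features keep
    their sample positions; the effective magnitude response is the squared
    Butterworth response.

    Raises
    ------
    ConfigurationError
        If the band is empty or exceeds Nyquist.
    InputError
        If the record is too short for the filter's edge padding.
    """
    if not (0 < f1 < f2 < rec.fs / 2):
        raise ConfigurationError(
            f"invalid band ({f1}, {f2}) Hz for fs={rec.fs} Hz: need 0 < f1 < f2 < fs/2"
        )
    sos = signal.butter(2, [f1, f2], btype="bandpass", fs=rec.fs, output="sos")
    # sosfiltfilt pads with ~3x the filter order; demand a little headroom
    if rec.n <= 18:
        raise InputError(f"record too short to filter ({rec.n} samples)")
    out = signal.sosfiltfilt(sos, rec.samples)
    return FilteredPPG(samples=out, fs=rec.fs, band=(f1, f2))


def second_derivative(fp: FilteredPPG) -> APGSignal:
    """Three-point centred second difference, scaled by 1/T^2.

    Interior samples follow ``Z[n] = (S[n+1] - 2 S[n] + S[n-1]) / T^2``; the
    two boundary samples replicate their nearest interior value so the APG
    keeps the PPG's length and time base.
    """
    s = fp.samples
    if s.size < 5:
        raise InputError(f"need >= 5 samples for the second derivative, got {s.size}")
    T = 1.0 / fp.fs
    z = np.empty_like(s)
    z[1:-1] = (s[2:] - 2.0 * s[1:-1] + s[:-2]) / (T * T)
    z[0] = z[1]
    z[-1] = z[-2]
    return APGSignal(samples=z, fs=fp.fs, clipped=False)


def clip_negative(apg: APGSignal) -> APGSignal:
    """Cancel the negative APG waves (b, d): ``Z[n] = 0 if Z[n] < 0``."""
    return APGSignal(samples=np.maximum(apg.samples, 0.0), fs=apg.fs, clipped=True)


def square(apg: APGSignal) -> SquaredSignal:
    """Square the clipped APG: ``y[n] = Z[n]^2``."""
    if not apg.clipped:
        raise ConfigurationError("square() expects the clipped (nonnegative) APG")
    return SquaredSignal(samples=apg.samples * apg.samples, fs=apg.fs)


def preprocess(rec: PPGRecord, f1: float = 0.5, f2: float = 15.0):
    """Full chain: filter -> second derivative -> (clip -> square).

    Returns
    -------
    (SquaredSignal, APGSignal)
        The squared clipped signal for block generation and the *unclipped*
        APG retained for b-wave localization and amplitude reporting.
    """
    filt = bandpass_filter(rec, f1, f2)
    apg = second_derivative(filt)
    y = square(clip_negative(apg))
    return y, apg
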