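"""A-wave detection with two event-related moving averages (TERMA).

A short centred moving average ``MA_peak`` (window W1, the expected a-wave
duration, default 175 ms) and a long one ``MA_beat`` (window W2, roughly one
beat, default 1000 ms) are computed over the squared clipped APG.  Samples
where ``MA_peak`` exceeds the dynamic threshold ``THR1 = MA_beat + alpha``
form *blocks of interest*; blocks narrower than ``THR2`` samples are
rejected as noise, and each surviving block contributes exactly one a wave
at the argmax of the squared signal inside it.

Because every stage is homogeneous in the input amplitude and THR1 scales
with the signal when the offset fraction beta is 0 (the optimized
configuration), the detector is amplitude scale-invariant — the property
that lets it track non-stationary and low-amplitude recordings where fixed
thresholds fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .preprocess import APGSignal, PPGRecord, SquaredSignal, preprocess

__all__ = [
    "TermaParams",
    "MovingAverages",
    "Block",
    "FiducialAnnotations",
    "ms_to_odd_samples",
    "moving_average",
    "compute_offset",
    "generate_blocks",
    "reject_blocks",
    "locate_a_waves",
    "detect_a",
]

#: Minimum record duration (s) so the beat-scale window W2 is applicable.
MIN_RECORD_S = 2.0

#: Anticipated a-wave duration (ms), the default block-width threshold THR2.
#: The a wave occupies roughly the systolic (QRS-equivalent) duration of
#: 100 +/- 20 ms in healthy adults; blocks narrower than this are noise.
A_WAVE_MS = 100.0


@dataclass(frozen=True)
class TermaParams:
    """Detector parameters; defaults are the brute-force optimum
    (band 0.5–15 Hz, W1 = 175 ms, W2 = 1000 ms, beta = 0)."""

    f1_hz: float = 0.5
    f2_hz: float = 15.0
    w1_ms: float = 175.0
    w2_ms: float = 1000.0
    beta_percent: float = 0.0

    def __post_init__(self):
        if not 0 < self.f1_hz < self.f2_hz:
            raise ConfigurationError(f"need 0 < f1 < f2, got {self.f1_hz}, {self.f2_hz}")
        if not 0 < self.w1_ms < self.w2_ms:
            raise ConfigurationError(f"need 0 < w1_ms < w2_ms, got {self.w1_ms}, {self.w2_ms}")
        if self.beta_percent < 0:
            raise ConfigurationError(f"beta_percent must be >= 0, got {self.beta_percent}")


@dataclass(frozen=True)
class MovingAverages:
    """The two moving averages plus the dynamic threshold THR1 = MA_beat + alpha."""

    ma_peak: np.ndarray
    ma_beat: np.ndarray
    alpha: float
    thr1: np.ndarray


@dataclass(frozen=True)
class Block:
    """Half-open index interval [start, stop) where MA_peak exceeds THR1."""

    start: int
    stop: int

    @property
    def width(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class FiducialAnnotations:
    """Per-beat a-wave and b-wave sample indices (0-based).

    ``b_indices`` may be shorter than ``a_indices`` when the b search runs
    off the end of the record for trailing beats.
    """

    a_indices: np.ndarray
    b_indices: np.ndarray
    fs: float

    def __post_init__(self):
        a = np.asarray(self.a_indices, dtype=int)
        b = np.asarray(self.b_indices, dtype=int)
        for name, arr in (("a", a), ("b", b)):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise InputError(f"{name} indices must be strictly increasing")
        object.__setattr__(self, "a_indices", a)
        object.__setattr__(self, "b_indices", b)


def ms_to_odd_samples(duration_ms: float, fs: float) -> int:
    """Convert a duration to the nearest odd number of samples.

    The two window sizes are rounded to the nearest odd integer so the
    moving averages are centred.  Ties (even sample counts, equidistant
    from two odd integers) resolve upward: 175 ms @ 200 Hz -> 35,
    1000 ms @ 200 Hz -> 201, 100 ms @ 200 Hz -> 21.
    """
    if duration_ms <= 0 or fs <= 0:
        raise ConfigurationError("duration_ms and fs must be positive")
    w = duration_ms * fs / 1000.0
    # nearest odd 2m+1 with m = round-half-up((w-1)/2)
    m = math.floor((w - 1.0) / 2.0 + 0.5)
    return max(2 * m + 1, 1)


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centred arithmetic moving average with an odd window.

    Near the edges the window shrinks to the available samples, so the
    output has the input's length.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ConfigurationError(f"window must be a positive odd integer, got {window}")
    if window > y.size:
        raise ConfigurationError(f"window {window} exceeds signal length {y.size}")
    h = window // 2
    c = np.concatenate(([0.0], np.cumsum(y)))
    idx = np.arange(y.size)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, y.size)
    return (c[hi] - c[lo]) / (hi - lo)


def compute_offset(y: np.ndarray, beta_percent: float) -> float:
    """Offset alpha = (beta/100) * mean(y).

    The brute-force optimum found beta = 0 — the a wave is prominent enough
    that no offset above the beat-scale average is needed.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise InputError("cannot compute the offset of an empty signal")
    return (beta_percent / 100.0) * float(np.mean(y))


def generate_blocks(ma_peak: np.ndarray, thr1: np.ndarray) -> list[Block]:
    """Maximal runs where ``ma_peak > thr1`` (strict), as half-open blocks.

    Strict comparison matters: with beta = 0, silent stretches have
    ``ma_peak == thr1 == 0`` and must not form blocks.
    """
    ma_peak = np.asarray(ma_peak, dtype=float)
    thr1 = np.asarray(thr1, dtype=float)
    if ma_peak.shape != thr1.shape:
        raise InputError(f"length mismatch: {ma_peak.shape} vs {thr1.shape}")
    above = ma_peak > thr1
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [above.size]))
    return [Block(int(s), int(e)) for s, e in zip(starts, stops)]


def reject_blocks(blocks: list[Block], thr2: int) -> list[Block]:
    """Keep blocks at least ``thr2`` samples wide (a-wave-width test THR2)."""
    if thr2 < 1:
        raise ConfigurationError(f"thr2 must be >= 1 sample, got {thr2}")
    return [b for b in blocks if b.width >= thr2]


def locate_a_waves(blocks: list[Block], y: np.ndarray) -> np.ndarray:
    """One a wave per accepted block: argmax of y over [start, stop).

    Ties break to the earliest sample.  ``y`` is the squared clipped APG the
    blocks were generated from, so the maximum absolute value and the
    maximum coincide.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty(len(blocks), dtype=int)
    for i, b in enumerate(blocks):
        if not (0 <= b.start < b.stop <= y.size):
            raise InputError(f"block [{b.start}, {b.stop}) outside signal of length {y.size}")
        out[i] = b.start + int(np.argmax(y[b.start:b.stop]))
    return out


def compute_moving_averages(y: SquaredSignal, params: TermaParams) -> MovingAverages:
    """Both moving averages and the dynamic threshold for a squared signal."""
    w1 = ms_to_odd_samples(params.w1_ms, y.fs)
    w2 = ms_to_odd_samples(params.w2_ms, y.fs)
    ma_peak = moving_average(y.samples, w1)
    ma_beat = moving_average(y.samples, w2)
    alpha = compute_offset(y.samples, params.beta_percent)
    return MovingAverages(ma_peak=ma_peak, ma_beat=ma_beat, alpha=alpha, thr1=ma_beat + alpha)


def detect_a(
    rec: PPGRecord,
    params: TermaParams | None = None,
    thr2_samples: int | None = None,
    argmax_on: str = "squared",
) -> tuple[FiducialAnnotations, APGSignal]:
    """Run the full TERMA a-wave detection chain on a raw PPG record.

    Parameters
    ----------
    rec : PPGRecord
    params : TermaParams, optional
        Defaults to the optimized configuration.
    thr2_samples : int, optional
        Width threshold THR2; defaults to the anticipated a-wave duration
        (100 ms) in samples.  The event window W1 itself would be too
        strict: blocks narrow as the heart rate rises (MA_beat climbs when
        beats pack densely), and at high rates valid a-wave blocks drop
        below W1 samples.
    argmax_on : {"squared", "abs_apg"}
        Signal used for the within-block argmax.

    Returns
    -------
    (FiducialAnnotations, APGSignal)
        Detected a waves (b list empty) and the unclipped APG, retained for
        the downstream b-wave search.
    """
    params = params or TermaParams()
    if rec.duration_s < MIN_RECORD_S:
        raise InputError(
            f"record of {rec.duration_s:.2f} s is shorter than the {MIN_RECORD_S} s minimum"
        )
    y, apg = preprocess(rec, params.f1_hz, params.f2_hz)
    mas = compute_moving_averages(y, params)
    if thr2_samples is None:
        thr2_samples = ms_to_odd_samples(A_WAVE_MS, rec.fs)
    blocks = reject_blocks(generate_blocks(mas.ma_peak, mas.thr1), thr2_samples)
    if argmax_on == "squared":
        target = y.samples
    elif argmax_on == "abs_apg":
        target = np.abs(apg.samples)
    else:
        raise ConfigurationError(f"argmax_on must be 'squared' or 'abs_apg', got {argmax_on!r}")
    a_idx = locate_a_waves(blocks, target)
    ann = FiducialAnnotations(a_indices=a_idx, b_indices=np.array([], dtype=int), fs=rec.fs)
    return ann, apg
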