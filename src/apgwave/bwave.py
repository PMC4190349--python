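"""B-wave localization on the unclipped APG.

The b wave is the first local minimum of the APG after the a wave.  For
each detected a wave the offsets ``k`` from ``k_min`` (8 ms) to ``k_max``
(136 ms) are scanned left to right and the first strict local minimum —
``APG[a+k] < APG[a+k-1]`` and ``APG[a+k] < APG[a+k+1]`` — is taken.
Plateaus (equal neighbours) do not qualify.  If no interior local minimum
exists in the window (e.g. the APG falls monotonically throughout), the
argmin over the window is returned so that every a wave that fits in the
record keeps one b wave.  B-wave amplitudes are negative on well-formed
beats (the wave lies under the baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .preprocess import APGSignal
from .terma import FiducialAnnotations

__all__ = ["BWaveParams", "detect_b", "detect_ab_pairs", "b_over_a_ratio"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BWaveParams:
    """Search-window bounds after the a wave, in milliseconds."""

    k_min_ms: float = 8.0
    k_max_ms: float = 136.0

    def __post_init__(self):
        if not 0 < self.k_min_ms < self.k_max_ms:
            raise ConfigurationError(
                f"need 0 < k_min_ms < k_max_ms, got {self.k_min_ms}, {self.k_max_ms}"
            )


def detect_ab_pairs(
    apg: APGSignal, a_indices: np.ndarray, params: BWaveParams | None = None
) -> list[tuple[int, int]]:
    """(a, b) index pairs; beats whose search window overruns the record are skipped.

    ``apg`` must be the unclipped second derivative — clipping is an
    a-detection device only and would erase the (negative) b wave.
    """
    if apg.clipped:
        raise ConfigurationError("b-wave search requires the unclipped APG")
    params = params or BWaveParams()
    z = apg.samples
    k_min = max(int(round(params.k_min_ms * apg.fs / 1000.0)), 1)
    k_max = int(round(params.k_max_ms * apg.fs / 1000.0))
    pairs: list[tuple[int, int]] = []
    for a in np.asarray(a_indices, dtype=int):
        if a + k_min + 1 >= z.size:
            log.info("a wave at sample %d too close to record end; no b wave", a)
            continue
        hi = min(k_max, z.size - 2 - a)  # need a+k+1 in bounds
        b = None
        for k in range(k_min, hi + 1):
            i = a + k
            if z[i] < z[i - 1] and z[i] < z[i + 1]:
                b = i
                break
        if b is None:
            # no interior strict local minimum: take the window-edge minimum
            win = z[a + k_min : a + hi + 1]
            b = a + k_min + int(np.argmin(win))
        pairs.append((int(a), int(b)))
    return pairs


def detect_b(
    apg: APGSignal, a_indices: np.ndarray, params: BWaveParams | None = None
) -> np.ndarray:
    """B-wave sample indices, one per a wave where the search window fits."""
    return np.array([b for _, b in detect_ab_pairs(apg, a_indices, params)], dtype=int)


def annotate(apg: APGSignal, ann: FiducialAnnotations, params: BWaveParams | None = None) -> FiducialAnnotations:
    """Return annotations with b waves filled in from the a waves."""
    b = detect_b(apg, ann.a_indices, params)
    return FiducialAnnotations(a_indices=ann.a_indices, b_indices=b, fs=ann.fs)


def b_over_a_ratio(apg: APGSignal, a_index: int, b_index: int) -> float:
    """Amplitude ratio b/a on the unclipped APG (uninterpreted accessor)."""
    return float(apg.samples[b_index] / apg.samples[a_index])
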