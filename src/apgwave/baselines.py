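"""Nine fixed-threshold a-wave detectors used as the benchmark field.

These are the classical QRS-style detectors (amplitude+slope, first
derivative, first+second derivative, digital filter families) transplanted
to the APG, each with the threshold values previously tuned for APG data:

====  =============================================  ==========================
name  feature transform                              thresholds
====  =============================================  ==========================
AF1   S[n] = X[n+1] - X[n-1]                         0.31*max(X), 0.0001, -0.001
AF2   S of the rectified/floored amplitude signal    0.21*max(X), 0.75
AF3   S[n] = X[n+1] - X[n-1], slope*amplitude gate   62
FD1   S[n] = -2X[n-2] - X[n-1] + X[n+1] + 2X[n+2]    0.099*max(S)
FD2   S[n] = X[n+1] - X[n-1]                         150
FS1   1.3|X'| + 1.1|X''| (wide stencils)             154.5
FS2   smoothed |X'| + |X''|                          0.1*max, 0.8*max (text)
DF1   4-sample differentiator + [1,4,6,4,1] low-pass 21
DF2   3-pt MA, low-pass residual squared, gated      1, 0.006*max (text)
====  =============================================  ==========================

Detectors whose thresholds are fractions of a signal maximum adapt to the
amplitude of each record; those with absolute thresholds (AF3, FD2, FS1,
DF1) do not, which is why they break down on non-stationary or
low-amplitude recordings — the finding the TERMA detector addresses.

The sources never state how supra-threshold samples map to beat marks, so
a shared localization rule is applied: supra-threshold samples closer than
200 ms (below any plausible beat interval) merge into one event, marked at
the argmax of the APG within the merged span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .preprocess import APGSignal, FilteredPPG, PPGRecord, bandpass_filter, second_derivative

__all__ = [
    "BaselineSpec",
    "FeatureSignal",
    "BASELINE_NAMES",
    "get_spec",
    "compute_baseline_feature",
    "run_baseline",
    "apg_from_record",
    "describe_amplitude_dependence",
]

#: Merge window for clustering supra-threshold samples into one event.
CLUSTER_MS = 200.0


@dataclass(frozen=True)
class BaselineSpec:
    """Registry entry: threshold values and which of them are relative
    (scale with the max of a derived signal) vs absolute."""

    name: str
    thresholds: dict
    relative: frozenset


@dataclass(frozen=True)
class FeatureSignal:
    samples: np.ndarray
    name: str


_REGISTRY = {
    "AF1": BaselineSpec("AF1", {"thr1": 0.31, "thr2": 0.0001, "thr3": -0.001}, frozenset({"thr1"})),
    "AF2": BaselineSpec("AF2", {"thr1": 0.21, "thr2": 0.75}, frozenset({"thr1"})),
    "AF3": BaselineSpec("AF3", {"thr1": 62.0}, frozenset()),
    "FD1": BaselineSpec("FD1", {"thr1": 0.099}, frozenset({"thr1"})),
    "FD2": BaselineSpec("FD2", {"thr1": 150.0}, frozenset()),
    "FS1": BaselineSpec("FS1", {"thr1": 154.5}, frozenset()),
    "FS2": BaselineSpec("FS2", {"thr1": 0.1, "thr2": 0.8}, frozenset({"thr1", "thr2"})),
    "DF1": BaselineSpec("DF1", {"thr1": 21.0}, frozenset()),
    "DF2": BaselineSpec("DF2", {"thr1": 1.0, "thr2": 0.006}, frozenset({"thr2"})),
}

#: Table-derived alternates where the running text and the results table disagree.
_TABLE3_PROFILE = {
    "FS2": {"thr1": 0.55, "thr2": 0.47},
    "DF2": {"thr1": 1.0, "thr2": 0.06},
}

BASELINE_NAMES = tuple(_REGISTRY)


def get_spec(name: str, profile: str = "text", overrides: dict | None = None) -> BaselineSpec:
    key = name.upper()
    if key not in _REGISTRY:
        raise ConfigurationError(f"unknown baseline {name!r}; known: {', '.join(_REGISTRY)}")
    spec = _REGISTRY[key]
    thr = dict(spec.thresholds)
    if profile == "table3" and key in _TABLE3_PROFILE:
        thr.update(_TABLE3_PROFILE[key])
    elif profile not in ("text", "table3"):
        raise ConfigurationError(f"unknown threshold profile {profile!r}")
    if overrides:
        thr.update(overrides)
    return BaselineSpec(spec.name, thr, spec.relative)


def _pad_edges(interior: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Replicate nearest interior values over the lo/hi edge samples."""
    out = interior
    if lo:
        out[:lo] = out[lo]
    if hi:
        out[-hi:] = out[-hi - 1]
    return out


def _first_diff(x: np.ndarray) -> np.ndarray:
    s = np.zeros_like(x)
    s[1:-1] = x[2:] - x[:-2]
    return _pad_edges(s, 1, 1)


def _second_diff2(x: np.ndarray) -> np.ndarray:
    s = np.zeros_like(x)
    s[2:-2] = x[4:] - 2.0 * x[2:-2] + x[:-4]
    return _pad_edges(s, 2, 2)


def _five_point_slope(x: np.ndarray) -> np.ndarray:
    s = np.zeros_like(x)
    s[2:-2] = -2.0 * x[:-4] - x[1:-3] + x[3:-1] + 2.0 * x[4:]
    return _pad_edges(s, 2, 2)


def _centred_mean(x: np.ndarray, half: int) -> np.ndarray:
    w = 2 * half + 1
    s = np.convolve(x, np.ones(w) / w, mode="same")
    # convolve's implicit zero padding is replaced by edge replication
    s[:half] = s[half]
    s[-half:] = s[-half - 1]
    return s


def _df1_filter(x: np.ndarray) -> np.ndarray:
    x1 = np.zeros_like(x)
    x1[4:] = x[4:] - x[:-4]
    x1[:4] = x1[4]
    s = np.zeros_like(x)
    s[4:] = x1[4:] + 4.0 * x1[3:-1] + 6.0 * x1[2:-2] + 4.0 * x1[1:-3] + x1[:-4]
    s[:4] = s[4]
    return s


def _df2_chain(x: np.ndarray, thr1: float, m: int = 3):
    x1 = np.zeros_like(x)
    x1[1:-1] = x[:-2] + 2.0 * x[1:-1] + x[2:]
    _pad_edges(x1, 1, 1)
    x2 = _centred_mean(x1, m)
    x3 = (x1 - x2) ** 2
    x4 = _centred_mean(x3, m)
    gate = np.zeros_like(x, dtype=bool)
    gate[m:-m] = (x1[m:-m] - x1[:-2 * m]) * (x1[m:-m] - x1[2 * m:]) > thr1
    x5 = np.where(gate, x4, 0.0)
    return x5


def compute_baseline_feature(name: str, x: APGSignal) -> FeatureSignal:
    """The final pre-threshold feature signal of a baseline detector.

    Length-preserving; edge samples replicate their nearest interior value
    (same policy as the derivative stage).
    """
    z = x.samples
    key = name.upper()
    if z.size < 9:
        raise ConfigurationError(f"signal too short ({z.size}) for the baseline stencils")
    if key in ("AF1", "AF3", "FD2"):
        s = _first_diff(z)
    elif key == "AF2":
        spec = get_spec("AF2")
        x1 = np.abs(z)
        x2 = np.maximum(x1, spec.thresholds["thr1"] * np.max(z))
        s = _first_diff(x2)
    elif key == "FD1":
        s = _five_point_slope(z)
    elif key == "FS1":
        s = 1.3 * np.abs(_first_diff(z)) + 1.1 * np.abs(_second_diff2(z))
    elif key == "FS2":
        x1 = np.abs(_first_diff(z))
        x2 = np.zeros_like(x1)
        x2[1:-1] = (x1[:-2] + 2.0 * x1[1:-1] + x1[2:]) / 4.0
        _pad_edges(x2, 1, 1)
        x3 = np.abs(_second_diff2(z))
        s = x2 + x3
    elif key == "DF1":
        s = _df1_filter(z)
    elif key == "DF2":
        s = _df2_chain(z, _REGISTRY["DF2"].thresholds["thr1"])
    else:
        raise ConfigurationError(f"unknown baseline {name!r}")
    return FeatureSignal(samples=s, name=key)


def _candidate_mask(spec: BaselineSpec, x: APGSignal, feature: np.ndarray, fs: float) -> np.ndarray:
    z = x.samples
    t = spec.thresholds
    key = spec.name
    if key == "AF1":
        # amplitude AND slope above thresholds AND the slope falling below
        # THR3 within the following 50 ms
        w50 = max(int(round(0.05 * fs)), 1)
        pad = np.concatenate([feature, np.full(w50, np.inf)])
        fwd_min = np.lib.stride_tricks.sliding_window_view(pad, w50 + 1).min(axis=1)
        return (z >= t["thr1"] * np.max(z)) & (feature >= t["thr2"]) & (fwd_min < t["thr3"])
    if key == "AF2":
        return feature > t["thr2"]
    if key == "AF3":
        return (feature >= t["thr1"]) & (feature * z > 0)
    if key == "FD1":
        peak = np.max(feature)
        if peak <= 0:  # silent signal: a relative threshold of 0 detects nothing
            return np.zeros_like(feature, dtype=bool)
        return feature >= t["thr1"] * peak
    if key == "FD2":
        return feature > t["thr1"]
    if key == "FS1":
        return feature >= t["thr1"]
    if key == "FS2":
        # onset regions above THR1 kept only if the region peaks above THR2
        peak = np.max(feature)
        mask = feature > t["thr1"] * peak
        keep = np.zeros_like(mask)
        for s, e in _runs(mask):
            if feature[s:e].max() >= t["thr2"] * peak:
                keep[s:e] = True
        return keep
    if key == "DF1":
        return feature > t["thr1"]
    if key == "DF2":
        return feature > t["thr2"] * np.max(feature)
    raise ConfigurationError(f"unknown baseline {key!r}")


def _runs(mask: np.ndarray):
    """Maximal True runs of a boolean mask as (start, stop) pairs."""
    if not mask.any():
        return []
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def run_baseline(
    name: str,
    x: APGSignal,
    fs: float | None = None,
    profile: str = "text",
    overrides: dict | None = None,
) -> np.ndarray:
    """A-wave indices from one fixed-threshold detector.

    Supra-threshold samples closer than 200 ms are merged into one event;
    each event is marked at the argmax of the APG within its span.
    """
    fs = fs or x.fs
    spec = get_spec(name, profile, overrides)
    feature = compute_baseline_feature(spec.name, x).samples
    mask = _candidate_mask(spec, x, feature, fs)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return np.array([], dtype=int)
    gap = int(round(CLUSTER_MS / 1000.0 * fs))
    splits = np.flatnonzero(np.diff(idx) >= gap) + 1
    out = []
    for grp in np.split(idx, splits):
        s, e = grp[0], grp[-1] + 1
        out.append(s + int(np.argmax(x.samples[s:e])))
    return np.asarray(out, dtype=int)


def apg_from_record(
    rec: PPGRecord, filtered: bool = True, f1: float = 0.5, f2: float = 15.0
) -> APGSignal:
    """APG input for the baselines.

    Default: the same band-passed second derivative the TERMA detector
    sees, for a like-for-like comparison.  ``filtered=False`` differentiates
    the raw PPG instead.
    """
    if filtered:
        fp = bandpass_filter(rec, f1, f2)
    else:
        fp = FilteredPPG(samples=rec.samples, fs=rec.fs, band=(0.0, rec.fs / 2))
    return second_derivative(fp)


def describe_amplitude_dependence(
    rec: PPGRecord,
    name: str,
    scales: tuple = (1.0, 0.5, 0.1),
    profile: str = "text",
) -> dict:
    """Detection counts (and indices) of one detector under amplitude scaling.

    ``name`` may be any baseline or ``"terma"`` (included for contrast: with
    beta = 0 its indices are identical at every positive scale).
    """
    from .preprocess import PPGRecord as _Rec
    from .terma import detect_a

    result = {"detector": name, "scales": list(scales), "counts": {}, "indices": {}}
    for c in scales:
        scaled = _Rec(samples=rec.samples * c, fs=rec.fs, record_id=f"{rec.record_id}x{c}")
        if name.lower() == "terma":
            ann, _ = detect_a(scaled)
            idx = ann.a_indices
        else:
            idx = run_baseline(name, apg_from_record(scaled), profile=profile)
        result["counts"][c] = int(idx.size)
        result["indices"][c] = idx
    return result
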