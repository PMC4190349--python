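"""CSV readers/writers for signals, annotations and run configuration.

Signal files are two-column CSV ``time_s,ppg`` (sampling rate inferred from
the time column, which must be uniform to 1 ppm) or headerless
single-column sample streams with the rate supplied by the caller.
Annotation files are CSV rows ``sample_index,time_s,label,amplitude`` with
0-based indices and labels restricted to ``a``/``b``; on well-formed beats
a-wave amplitudes are positive and b-wave amplitudes negative (measured
from the APG baseline).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError
from .preprocess import APGSignal, PPGRecord
from .terma import FiducialAnnotations

__all__ = [
    "read_ppg",
    "write_ppg",
    "read_annotations",
    "write_annotations",
    "load_config",
]

log = logging.getLogger(__name__)

_UNIFORMITY_PPM = 1.0


def read_ppg(path, fs: float | None = None, record_id: str | None = None) -> PPGRecord:
    """Load a PPG record from CSV.

    Two-column files with a ``time_s,ppg`` header carry their own sampling
    rate; single-column files need ``fs``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    rid = record_id if record_id is not None else path.stem
    if first.replace(" ", "").lower().startswith("time_s,"):
        df = pd.read_csv(path)
        if df.isna().any().any():
            raise InputError(f"{path}: NaN rows in signal file")
        tcol = df.iloc[:, 0].to_numpy(dtype=float)
        x = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(tcol)
        if dt.size == 0 or np.any(dt <= 0):
            raise InputError(f"{path}: time column not strictly increasing")
        ref = np.median(dt)
        bad = np.flatnonzero(np.abs(dt - ref) / ref > _UNIFORMITY_PPM * 1e-6)
        if bad.size:
            k = int(bad[0])
            raise InputError(
                f"{path}: non-uniform sampling at row {k + 1}: gap {dt[k]:.9f} s "
                f"vs expected {ref:.9f} s"
            )
        return PPGRecord(samples=x, fs=1.0 / ref, record_id=rid)
    if fs is None:
        raise ConfigurationError(f"{path}: single-column file requires an explicit fs")
    vals = pd.read_csv(path, header=None).iloc[:, 0].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise InputError(f"{path}: NaN rows in signal file")
    return PPGRecord(samples=vals, fs=fs, record_id=rid)


def write_ppg(rec: PPGRecord, path) -> None:
    t = np.arange(rec.n) / rec.fs
    pd.DataFrame({"time_s": t, "ppg": rec.samples}).to_csv(path, index=False, float_format="%.12g")


def write_annotations(ann: FiducialAnnotations, apg: APGSignal, path) -> None:
    """Write detected waves with their (signed) APG amplitudes.

    Logged warning (not an error) if a beat violates the sign convention —
    a above the baseline, b below.
    """
    rows = []
    for label, indices in (("a", ann.a_indices), ("b", ann.b_indices)):
        for i in indices:
            amp = float(apg.samples[i])
            if (label == "a" and amp <= 0) or (label == "b" and amp >= 0):
                log.warning("%s wave at sample %d has unexpected sign: %g", label, i, amp)
            rows.append({"sample_index": int(i), "time_s": i / ann.fs, "label": label, "amplitude": amp})
    df = pd.DataFrame(rows, columns=["sample_index", "time_s", "label", "amplitude"])
    df.to_csv(path, index=False, float_format="%.12g")


def read_annotations(path, fs: float | None = None) -> tuple[FiducialAnnotations, pd.DataFrame]:
    """Read an annotation CSV back into FiducialAnnotations (plus raw rows)."""
    df = pd.read_csv(path)
    required = {"sample_index", "time_s", "label"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: annotation file missing columns {required - set(df.columns)}")
    bad = set(df["label"].unique()) - {"a", "b"}
    if bad:
        raise InputError(f"{path}: unknown labels {sorted(bad)}")
    if fs is None:
        nz = df[df["sample_index"] > 0]
        if len(nz):
            fs = float((nz["sample_index"] / nz["time_s"]).median())
        else:
            raise ConfigurationError(f"{path}: cannot infer fs from annotations; pass fs")
    a = np.sort(df.loc[df["label"] == "a", "sample_index"].to_numpy(dtype=int))
    b = np.sort(df.loc[df["label"] == "b", "sample_index"].to_numpy(dtype=int))
    return FiducialAnnotations(a_indices=a, b_indices=b, fs=fs), df


def load_config(path) -> dict:
    """YAML run configuration (flat keys mirroring the CLI flags)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg
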