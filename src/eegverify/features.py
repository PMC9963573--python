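"""Welch PSD feature extraction.

Each 7.5 s segment becomes an 855-dimensional feature vector: the Welch
power spectral density at the integer frequencies 1..45 Hz for each of the
19 channels, flattened channel-major (all 45 bins of Fp1, then Fp2, ...).
The estimator uses 1 s Hamming windows with 0.5 s overlap — 14 windows per
segment at 500 Hz — with no detrending and one-sided density scaling, so a
500-sample window gives exactly 1 Hz bin spacing.

Features come in two scales: ``raw`` (uV^2/Hz) and ``dB``
(``10*log10(raw)``), which turns multiplicative day-to-day gain drift into
additive offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import preprocess_recording
from .recording import CHANNELS_1020, N_CHANNELS, DataError, Segment

__all__ = [
    "FMIN_HZ", "FMAX_HZ", "FREQ_BINS_HZ", "N_FEATURES",
    "SegmentFeatures", "FeatureStore",
    "welch_psd", "segment_features", "to_decibel", "assemble_features",
]

WELCH_WIN_S = 1.0
WELCH_OVERLAP_S = 0.5
FMIN_HZ = 1.0
FMAX_HZ = 45.0
FREQ_BINS_HZ = np.arange(1, 46, dtype=float)  # 45 integer bins
N_FEATURES = N_CHANNELS * len(FREQ_BINS_HZ)  # 19 * 45 = 855


def welch_psd(seg: Segment, win_s: float = WELCH_WIN_S,
              overlap_s: float = WELCH_OVERLAP_S, fmin_hz: float = FMIN_HZ,
              fmax_hz: float = FMAX_HZ) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel Welch PSD restricted to ``[fmin_hz, fmax_hz]``.

    Returns ``(freqs, psd)`` with ``psd`` of shape ``(19, n_bins)`` in
    uV^2/Hz (one-sided). A symmetric (MATLAB-style) Hamming taper is used;
    the periodograms of the half-overlapping windows are averaged without
    detrending.
    """
    nperseg = int(round(win_s * seg.fs))
    noverlap = int(round(overlap_s * seg.fs))
    if abs(win_s * seg.fs - nperseg) > 1e-9:
        raise DataError(f"win_s*fs must be an integer, got {win_s * seg.fs}")
    if noverlap >= nperseg:
        raise DataError("overlap_s must be smaller than win_s")
    if seg.data.shape[1] < nperseg:
        raise DataError(
            f"segment of {seg.data.shape[1]} samples shorter than the "
            f"{nperseg}-sample Welch window"
        )
    window = signal.windows.hamming(nperseg, sym=True)
    freqs, psd = signal.welch(seg.data, fs=seg.fs, window=window,
                              noverlap=noverlap, nfft=nperseg,
                              detrend=False, scaling="density", axis=1)
    keep = (freqs >= fmin_hz - 1e-9) & (freqs <= fmax_hz + 1e-9)
    return freqs[keep], psd[:, keep]


@dataclass(frozen=True)
class SegmentFeatures:
    """One segment's flattened, channel-major PSD feature vector."""

    subject_id: str
    session_index: int
    segment_index: int
    values: np.ndarray  # length 855
    scale: str  # "raw" | "dB"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise DataError(f"feature vector must have length {N_FEATURES}")
        if self.scale not in ("raw", "dB"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.scale == "raw" and np.any(v <= 0):
            raise DataError("raw PSD features must be strictly positive")
        object.__setattr__(self, "values", v)


def segment_features(seg: Segment, scale: str = "raw") -> SegmentFeatures:
    """Welch features of one segment, flattened channel-major."""
    _, psd = welch_psd(seg)
    feats = SegmentFeatures(
        subject_id=seg.subject_id,
        session_index=seg.session_index,
        segment_index=seg.segment_index,
        values=psd.reshape(-1),
        scale="raw",
    )
    return to_decibel(feats) if scale == "dB" else feats


def to_decibel(features: "SegmentFeatures | FeatureStore"):
    """Convert raw-scale features to decibels (``10*log10``); invertible.

    Non-positive raw values raise rather than being floored — they would
    indicate a broken upstream estimate.
    """
    if isinstance(features, FeatureStore):
        return features.to_decibel()
    if features.scale != "raw":
        raise DataError("to_decibel expects raw-scale features")
    if np.any(features.values <= 0):
        raise DataError("cannot convert non-positive PSD values to dB")
    return replace(features, values=10.0 * np.log10(features.values),
                   scale="dB")


def from_decibel(features: "SegmentFeatures") -> "SegmentFeatures":
    """Inverse of :func:`to_decibel`."""
    if features.scale != "dB":
        raise DataError("from_decibel expects dB-scale features")
    return replace(features, values=10.0 ** (features.values / 10.0),
                   scale="raw")


_COLUMNS = [f"f{i + 1}" for i in range(N_FEATURES)]


@dataclass
class FeatureStore:
    """All feature vectors of a cohort, indexed by (subject, session, segment).

    Thin wrapper over a DataFrame whose index is the triple and whose 855
    columns ``f1..f855`` follow the channel-major bin order.
    """

    df: pd.DataFrame
    scale: str

    @classmethod
    def from_features(cls, feats: list[SegmentFeatures]) -> "FeatureStore":
        if not feats:
            raise DataError("empty feature list")
        scale = feats[0].scale
        if any(f.scale != scale for f in feats):
            raise DataError("mixed feature scales in one store")
        index = pd.MultiIndex.from_tuples(
            [(f.subject_id, f.session_index, f.segment_index) for f in feats],
            names=["subject", "session", "segment"],
        )
        df = pd.DataFrame(np.stack([f.values for f in feats]), index=index,
                          columns=_COLUMNS)
        return cls(df=df.sort_index(), scale=scale)

    def __len__(self) -> int:
        return len(self.df)

    def to_decibel(self) -> "FeatureStore":
        if self.scale != "raw":
            raise DataError("store is not raw-scale")
        if (self.df.values <= 0).any():
            raise DataError("cannot convert non-positive PSD values to dB")
        return FeatureStore(df=10.0 * np.log10(self.df), scale="dB")

    def from_decibel(self) -> "FeatureStore":
        if self.scale != "dB":
            raise DataError("store is not dB-scale")
        return FeatureStore(df=10.0 ** (self.df / 10.0), scale="raw")

    def select(self, subject_id: str,
               sessions: list[int] | None = None) -> pd.DataFrame:
        """Rows of one subject, optionally restricted to given sessions."""
        sub = self.df.xs(subject_id, level="subject", drop_level=False)
        if sessions is not None:
            mask = sub.index.get_level_values("session").isin(sessions)
            sub = sub[mask]
        return sub

    def counts(self) -> pd.Series:
        """Segments per (subject, session)."""
        return self.df.groupby(level=["subject", "session"]).size()

    def save(self, path: str | Path) -> None:
        """Persist as CSV (index columns + f1..f855) for interchange."""
        out = self.df.copy()
        out.insert(0, "scale", self.scale)
        out.to_csv(path)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureStore":
        df = pd.read_csv(path, index_col=["subject", "session", "segment"])
        scale = str(df.pop("scale").iloc[0])
        return cls(df=df, scale=scale)


def assemble_features(cohort, scale: str = "raw", *,
                      allow_missing: bool = False,
                      preprocess_kwargs: dict | None = None) -> FeatureStore:
    """Run the preprocessing chain over a cohort and collect all features.

    Iterates the cohort manifest, conditions each recording
    (filter -> crop -> CAR -> 7.5 s segments) and extracts Welch features.
    Failures are collected into a completeness report; unless
    ``allow_missing`` the run aborts listing every missing recording.
    """
    kw = preprocess_kwargs or {}
    feats: list[SegmentFeatures] = []
    missing: list[str] = []
    for entry in cohort.manifest:
        sid, sess = entry["subject_id"], entry["session_index"]
        try:
            rec = cohort.get_recording(sid, sess)
            for seg in preprocess_recording(rec, **kw):
                feats.append(segment_features(seg, scale="raw"))
        except (KeyError, OSError, DataError) as exc:
            missing.append(f"{sid}/s{sess}: {exc}")
    if missing and not allow_missing:
        raise DataError(
            "missing or unreadable recordings:\n  " + "\n  ".join(missing)
        )
    store = FeatureStore.from_features(feats)
    return store.to_decibel() if scale == "dB" else store
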