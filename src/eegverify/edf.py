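"""Minimal EDF (European Data Format) reader/writer for 10-20 EEG.

Implements the subset of the EDF specification this package needs: one
continuous multi-channel recording, 1 s data records, int16 samples with
per-channel physical scaling in microvolts. No pre-installed library in
the target environment reads EDF, hence this small self-contained
implementation. Round-trip fidelity is limited by the format's 16-bit
quantization (tested to that contract).

Channels may be stored in any order; the reader maps them back to the
canonical 10-20 order and fails loudly when labels are missing or the
sampling rate disagrees with expectation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import CHANNELS_1020, N_CHANNELS, DataError, Recording

__all__ = ["read_edf", "write_edf"]

_HDR = 256  # bytes in the fixed header and per-signal header block


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a recording as EDF with 1 s data records.

    The duration must be an integer number of seconds and the sampling
    rate an integer; physical min/max are set per channel from the data
    (symmetric), digital range is the full +/-32767.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise DataError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n = rec.n_samples
    if n % fs != 0:
        raise DataError("EDF writer requires a whole number of seconds")
    n_records = n // fs

    data = rec.data
    # the header stores physical extrema as 8 ASCII chars; digitize with the
    # value the header will actually carry, padded so data stay in range
    def _fit8(v: float) -> float:
        for fmt in (".6g", ".5g", ".2e"):
            s = format(v, fmt)
            if len(s) <= 8:
                return float(s)
        raise DataError(f"cannot encode physical range {v}")  # pragma: no cover

    phys_max = np.array([
        _fit8(v) for v in
        np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.0001])
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round(data / scale[:, None]).astype("<i2")

    header = b"".join([
        _ascii(0, 8),  # version
        _ascii(f"{rec.subject_id} {rec.role}", 80),  # patient id
        _ascii(f"session {rec.session_index}", 80),  # recording id
        _ascii("01.01.00", 8), _ascii("00.00.00", 8),  # start date/time
        _ascii(_HDR * (1 + N_CHANNELS), 8),  # header bytes
        _ascii("", 44),  # reserved
        _ascii(n_records, 8),
        _ascii(1, 8),  # record duration, s
        _ascii(N_CHANNELS, 4),
    ])
    sig_header = b"".join([
        b"".join(_ascii(ch, 16) for ch in CHANNELS_1020),  # labels
        b"".join(_ascii("AgAgCl electrode", 80) for _ in range(N_CHANNELS)),
        b"".join(_ascii("uV", 8) for _ in range(N_CHANNELS)),
        b"".join(_ascii(f"{phys_min[c]:.7g}"[:8], 8) for c in range(N_CHANNELS)),
        b"".join(_ascii(f"{phys_max[c]:.7g}"[:8], 8) for c in range(N_CHANNELS)),
        b"".join(_ascii(dig_min, 8) for _ in range(N_CHANNELS)),
        b"".join(_ascii(dig_max, 8) for _ in range(N_CHANNELS)),
        b"".join(_ascii("", 80) for _ in range(N_CHANNELS)),  # prefiltering
        b"".join(_ascii(fs, 8) for _ in range(N_CHANNELS)),  # samples/record
        b"".join(_ascii("", 32) for _ in range(N_CHANNELS)),  # reserved
    ])
    # data records: for each second, each channel's fs samples
    records = digital.reshape(N_CHANNELS, n_records, fs).transpose(1, 0, 2)
    Path(path).write_bytes(header + sig_header + records.tobytes())


def read_edf(path: str | Path, expected_fs: float | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` in canonical channel order.

    Fails with an explicit message when expected 10-20 labels are missing
    or the sampling rate disagrees with ``expected_fs``.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HDR:
        raise DataError(f"{path}: truncated EDF header")

    def field_(off: int, width: int) -> str:
        return raw[off:off + width].decode("ascii", "replace").strip()

    header_bytes = int(field_(184, 8))
    n_records = int(field_(236, 8))
    record_dur = float(field_(244, 8))
    ns = int(field_(252, 4))
    base = _HDR
    labels = [field_(base + 16 * i, 16) for i in range(ns)]
    off = base + ns * 16 + ns * 80 + ns * 8
    phys_min = np.array([float(field_(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    phys_max = np.array([float(field_(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dig_min = np.array([float(field_(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dig_max = np.array([float(field_(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8 + ns * 80
    samples_per_record = [int(field_(off + 8 * i, 8)) for i in range(ns)]

    missing = [ch for ch in CHANNELS_1020 if ch not in labels]
    if missing:
        raise DataError(f"{path}: missing channel labels {missing}")
    if len(set(samples_per_record)) != 1:
        raise DataError(f"{path}: heterogeneous sampling rates not supported")
    fs = samples_per_record[0] / record_dur
    if expected_fs is not None and abs(fs - expected_fs) > 1e-6:
        raise DataError(f"{path}: sampling rate {fs} != expected {expected_fs}")

    spr = samples_per_record[0]
    payload = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected_len = n_records * ns * spr
    if len(payload) < expected_len:
        raise DataError(f"{path}: truncated data records")
    records = payload[:expected_len].reshape(n_records, ns, spr)
    digital = records.transpose(1, 0, 2).reshape(ns, n_records * spr)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - scale * dig_min
    physical = digital * scale[:, None] + offset[:, None]

    order = [labels.index(ch) for ch in CHANNELS_1020]
    subject = field_(8, 80).split()
    sid = subject[0] if subject else "unknown"
    role = subject[1] if len(subject) > 1 and subject[1] in ("genuine", "impostor") else "genuine"
    sess_txt = field_(88, 80).split()
    sess = int(sess_txt[1]) if len(sess_txt) > 1 and sess_txt[1].isdigit() else 1
    return Recording(subject_id=sid, session_index=sess,
                     data=physical[order], fs=fs, role=role)
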