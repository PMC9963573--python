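"""Synthetic multi-session resting-state EEG cohorts.

Real multi-session EEG biometric corpora are rarely public, so this module
synthesizes one with the statistical structure the verification analysis
relies on:

* **stable inter-individual traits** — each subject gets a fixed spectral
  signature: an individual alpha peak (centre frequency, bandwidth,
  occipitally dominant topography), a 1/f aperiodic background with a
  subject-specific exponent, and a broad beta bump;
* **intra-individual session drift** — each session multiplies every
  channel's amplitude by a log-normal day-to-day gain (electrode montage,
  impedance) and shifts alpha band power by a log-normal factor
  (vigilance, mental state), on top of fresh measurement noise and 50 Hz
  mains interference;
* **randomness that is fully hierarchical** — ``master_seed`` spawns
  per-subject seeds which spawn per-session seeds, so adding a subject or
  session never perturbs previously generated data.

Signals are produced by inverse spectral synthesis: a target one-sided PSD
is built per channel, given independent uniform random phases, and inverted
with an FFT, so the realized Welch PSD of the output matches the target
within sampling error — a property the test suite asserts directly.
"""

from __future__ import annotations

import json
import shutil
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .recording import CHANNELS_1020, N_CHANNELS, ConfigurationError, Recording

__all__ = [
    "CohortConfig",
    "SubjectSignature",
    "SessionEffect",
    "Cohort",
    "draw_signature",
    "draw_session_effect",
    "target_psd",
    "synthesize_session",
    "generate_cohort",
]

# Relative alpha-bump topography over the canonical montage: strongest over
# the occiput, fading toward frontopolar sites.
_ALPHA_TOPOGRAPHY = {
    "Fp1": 0.20, "Fp2": 0.20,
    "F7": 0.25, "F3": 0.25, "Fz": 0.25, "F4": 0.25, "F8": 0.25,
    "T3": 0.40, "C3": 0.40, "Cz": 0.40, "C4": 0.40, "T4": 0.40,
    "T5": 0.60, "P3": 0.70, "Pz": 0.70, "P4": 0.70, "T6": 0.60,
    "O1": 1.00, "O2": 1.00,
}
_BASE_TOPOGRAPHY = np.array([_ALPHA_TOPOGRAPHY[ch] for ch in CHANNELS_1020])

# Population-level defaults (resting eyes-open adult EEG, in uV^2/Hz):
# occipital alpha peak height ~25, aperiodic background ~20 at 1 Hz with
# exponent ~1.2 and a knee below 1 Hz, small beta bump at 20 Hz.
_ALPHA_POWER = 25.0
_ALPHA_PEAK_MEAN = 10.0
_ALPHA_PEAK_SD = 1.2
_ALPHA_BW_MEAN = 1.0
_ONE_OVER_F_SCALE = 20.0
_ONE_OVER_F_EXP_MEAN = 1.2
_ONE_OVER_F_EXP_SD = 0.2
_BETA_POWER = 1.5
_BETA_CENTER = 20.0
_BETA_BW = 4.0
_NOISE_FLOOR = 0.5
_LINE_AMP = 2.0
_LINE_HZ = 50.0


@dataclass(frozen=True)
class CohortConfig:
    """Cohort geometry and variability knobs.

    ``sigma_subject`` scales every inter-subject standard deviation
    (0 makes all subjects spectrally identical — the chance-level limit);
    ``sigma_session`` is the log-SD of the per-session, per-channel
    amplitude gain (0 removes all session-to-session drift).
    """

    n_genuine: int = 29
    n_sessions: int = 20
    n_impostors: int = 23
    duration_s: float = 220.0
    fs: float = 500.0
    sigma_session: float = 0.2
    sigma_subject: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 210.0:
            raise ConfigurationError(
                "duration_s must be >= 210 s (30 s settling + 180 s analysis)"
            )
        if self.fs <= 140.0:
            raise ConfigurationError("fs must exceed 140 Hz")
        if min(self.n_genuine, self.n_sessions) < 1 or self.n_impostors < 0:
            raise ConfigurationError("cohort counts out of range")
        if self.sigma_session < 0 or self.sigma_subject < 0:
            raise ConfigurationError("sigma values must be non-negative")

    @classmethod
    def paper_scale(cls, master_seed: int = 0, **kw) -> "CohortConfig":
        """Full study geometry: 29 genuine x 20 sessions + 23 impostors."""
        return cls(n_genuine=29, n_sessions=20, n_impostors=23,
                   master_seed=master_seed, **kw)

    @classmethod
    def desk_scale(cls, master_seed: int = 0, **kw) -> "CohortConfig":
        """Small geometry for tests: 8 genuine x 12 sessions + 5 impostors."""
        return cls(n_genuine=8, n_sessions=12, n_impostors=5,
                   master_seed=master_seed, **kw)


@dataclass(frozen=True)
class SubjectSignature:
    """A subject's stable spectral traits."""

    subject_id: str
    alpha_peak_hz: float
    alpha_bandwidth_hz: float
    alpha_gain_per_channel: np.ndarray  # 19 peak heights, uV^2/Hz
    one_over_f_exponent: float
    one_over_f_scale: float  # uV^2/Hz at 1 Hz
    beta_gain: float
    rng_seed: int

    def __post_init__(self) -> None:
        if not (7.0 <= self.alpha_peak_hz <= 13.0):
            raise ConfigurationError("alpha_peak_hz must lie in [7, 13]")
        if not (0.5 < self.one_over_f_exponent <= 2.5):
            raise ConfigurationError("1/f exponent must lie in (0.5, 2.5]")
        gains = np.asarray(self.alpha_gain_per_channel, dtype=float)
        if gains.shape != (N_CHANNELS,) or np.any(gains <= 0):
            raise ConfigurationError("alpha gains must be 19 positive values")
        if self.one_over_f_scale <= 0 or self.beta_gain <= 0:
            raise ConfigurationError("spectral gains must be positive")
        object.__setattr__(self, "alpha_gain_per_channel", gains)


@dataclass(frozen=True)
class SessionEffect:
    """One session's multiplicative drift and noise state."""

    session_index: int
    channel_gain: np.ndarray  # 19 amplitude factors
    alpha_power_shift: float
    noise_scale: float  # flat floor, uV^2/Hz
    line_noise_amp: float  # uV

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ConfigurationError("session_index must be >= 1")
        g = np.asarray(self.channel_gain, dtype=float)
        if g.shape != (N_CHANNELS,) or np.any(g <= 0):
            raise ConfigurationError("channel_gain must be 19 positive factors")
        if self.alpha_power_shift <= 0 or self.noise_scale < 0 or self.line_noise_amp < 0:
            raise ConfigurationError("session effect values out of range")
        object.__setattr__(self, "channel_gain", g)


def _subject_entropy(subject_id: str, seed: int) -> np.random.SeedSequence:
    # CRC of the id keeps the map stable across runs and Python processes
    # (the builtin hash is salted).
    return np.random.SeedSequence(entropy=seed,
                                  spawn_key=(zlib.crc32(subject_id.encode()),))


def draw_signature(subject_id: str, config: CohortConfig, seed: int) -> SubjectSignature:
    """Draw a subject's stable spectral signature.

    Deterministic given ``(subject_id, seed)``. All inter-subject standard
    deviations scale with ``config.sigma_subject``; at 0 every subject gets
    the population-mean signature.
    """
    ss = _subject_entropy(subject_id, seed)
    rng = np.random.default_rng(ss)
    s = config.sigma_subject
    z = rng.standard_normal(5)
    peak = float(np.clip(_ALPHA_PEAK_MEAN + _ALPHA_PEAK_SD * s * z[0], 7.0, 13.0))
    bandwidth = float(_ALPHA_BW_MEAN * np.exp(0.2 * s * z[1]))
    exponent = float(np.clip(_ONE_OVER_F_EXP_MEAN + _ONE_OVER_F_EXP_SD * s * z[2],
                             0.51, 2.5))
    scale = float(_ONE_OVER_F_SCALE * np.exp(0.3 * s * z[3]))
    beta = float(_BETA_POWER * np.exp(0.3 * s * z[4]))
    chan_z = rng.standard_normal(N_CHANNELS)
    gains = _ALPHA_POWER * _BASE_TOPOGRAPHY * np.exp(0.4 * s * chan_z)
    return SubjectSignature(
        subject_id=subject_id,
        alpha_peak_hz=peak,
        alpha_bandwidth_hz=bandwidth,
        alpha_gain_per_channel=gains,
        one_over_f_exponent=exponent,
        one_over_f_scale=scale,
        beta_gain=beta,
        rng_seed=int(ss.generate_state(1)[0]),
    )


def draw_session_effect(session_index: int, config: CohortConfig,
                        rng: np.random.Generator) -> SessionEffect:
    """Draw one session's drift state from ``rng``.

    Channel gains are log-normal with log-SD ``sigma_session`` (amplitude
    drift from montage/impedance differences); alpha band power drifts with
    log-SD ``1.5 * sigma_session`` (vigilance state).
    """
    ss = config.sigma_session
    channel_gain = np.exp(ss * rng.standard_normal(N_CHANNELS))
    alpha_shift = float(np.exp(1.5 * ss * rng.standard_normal()))
    noise = float(_NOISE_FLOOR * np.exp(0.5 * ss * rng.standard_normal()))
    line = float(_LINE_AMP * np.exp(0.5 * ss * rng.standard_normal()))
    return SessionEffect(
        session_index=session_index,
        channel_gain=channel_gain,
        alpha_power_shift=alpha_shift,
        noise_scale=noise,
        line_noise_amp=line,
    )


def target_psd(sig: SubjectSignature, eff: SessionEffect,
               freqs: np.ndarray) -> np.ndarray:
    """Target one-sided PSD (uV^2/Hz), shape ``(19, len(freqs))``.

    Per channel: aperiodic ``scale * f^-exponent`` background (flat below a
    1 Hz knee), Gaussian alpha bump at the subject's peak scaled by the
    session's band-power shift, broad beta bump, flat noise floor — the sum
    multiplied by the squared per-channel session amplitude gain. The 50 Hz
    mains component is added in the time domain, not here.
    """
    f = np.asarray(freqs, dtype=float)
    aperiodic = sig.one_over_f_scale * np.maximum(f, 1.0) ** (-sig.one_over_f_exponent)
    alpha_shape = np.exp(-0.5 * ((f - sig.alpha_peak_hz) / sig.alpha_bandwidth_hz) ** 2)
    beta_shape = np.exp(-0.5 * ((f - _BETA_CENTER) / _BETA_BW) ** 2)
    base = (aperiodic[None, :]
            + eff.alpha_power_shift * sig.alpha_gain_per_channel[:, None] * alpha_shape[None, :]
            + sig.beta_gain * beta_shape[None, :]
            + eff.noise_scale)
    return eff.channel_gain[:, None] ** 2 * base


def synthesize_session(sig: SubjectSignature, eff: SessionEffect,
                       config: CohortConfig,
                       rng: np.random.Generator | None = None,
                       role: str = "genuine") -> Recording:
    """Synthesize one recording by random-phase inverse spectral synthesis.

    The rFFT coefficient at bin k is given magnitude
    ``sqrt(S(f_k) * fs * N / 2)`` and an independent uniform phase, so the
    periodogram of the output equals the target PSD in expectation of the
    phase draw (exactly, here, since magnitudes are deterministic).
    """
    if rng is None:
        rng = np.random.default_rng(sig.rng_seed + eff.session_index)
    n = int(round(config.duration_s * config.fs))
    if n <= 0:
        raise ConfigurationError("duration_s * fs must be positive")
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    spectrum = target_psd(sig, eff, freqs)  # (19, n//2+1)
    mag = np.sqrt(spectrum * config.fs * n / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=mag.shape)
    coeffs = mag * np.exp(1j * phases)
    coeffs[:, 0] = 0.0  # no DC
    if n % 2 == 0:
        coeffs[:, -1] = mag[:, -1]  # Nyquist bin must be real
    data = np.fft.irfft(coeffs, n=n, axis=1)
    if eff.line_noise_amp > 0:
        t = np.arange(n) / config.fs
        line_phase = rng.uniform(0.0, 2.0 * np.pi)
        data += eff.line_noise_amp * np.sin(2.0 * np.pi * _LINE_HZ * t + line_phase)
    return Recording(
        subject_id=sig.subject_id,
        session_index=eff.session_index,
        data=data,
        fs=config.fs,
        role=role,
    )


@dataclass
class Cohort:
    """A generated cohort: manifest plus recordings (in memory or on disk)."""

    config: CohortConfig
    manifest: list[dict] = field(default_factory=list)
    recordings: dict[tuple[str, int], Recording] = field(default_factory=dict)
    out_dir: Path | None = None

    @property
    def genuine_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.manifest:
            if e["role"] == "genuine":
                seen.setdefault(e["subject_id"])
        return list(seen)

    @property
    def impostor_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.manifest:
            if e["role"] == "impostor":
                seen.setdefault(e["subject_id"])
        return list(seen)

    def get_recording(self, subject_id: str, session_index: int) -> Recording:
        key = (subject_id, session_index)
        if key in self.recordings:
            return self.recordings[key]
        entry = next((e for e in self.manifest
                      if e["subject_id"] == subject_id
                      and e["session_index"] == session_index), None)
        if entry is None or not entry.get("path"):
            raise KeyError(f"no recording for {key}")
        from .edf import read_edf
        rec = read_edf(Path(entry["path"]), expected_fs=self.config.fs)
        return Recording(subject_id=subject_id, session_index=session_index,
                         data=rec.data, fs=rec.fs, role=entry["role"])


def _iter_cohort_entries(config: CohortConfig):
    """Yield (subject_id, session_index, role, subject_index) in manifest order."""
    width = max(2, len(str(config.n_genuine)))
    for i in range(config.n_genuine):
        sid = f"sub{i + 1:0{width}d}"
        for sess in range(1, config.n_sessions + 1):
            yield sid, sess, "genuine", i
    iwidth = max(2, len(str(max(config.n_impostors, 1))))
    for j in range(config.n_impostors):
        yield f"imp{j + 1:0{iwidth}d}", 1, "impostor", config.n_genuine + j


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> Cohort:
    """Generate the full cohort.

    With ``out_dir`` set, writes one EDF file per recording plus a
    ``manifest.json`` and keeps nothing in memory; otherwise recordings stay
    in memory. Bit-for-bit reproducible from ``config.master_seed``; a
    partial disk write is cleaned up before the error propagates.
    """
    cohort = Cohort(config=config)
    out_path: Path | None = None
    written: list[Path] = []
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        cohort.out_dir = out_path
    try:
        for sid, sess, role, subj_idx in _iter_cohort_entries(config):
            subj_ss = np.random.SeedSequence(entropy=config.master_seed,
                                             spawn_key=(subj_idx,))
            subj_seed = int(subj_ss.generate_state(1)[0])
            sig = draw_signature(sid, config, subj_seed)
            sess_ss = np.random.SeedSequence(entropy=config.master_seed,
                                             spawn_key=(subj_idx, sess))
            rng = np.random.default_rng(sess_ss)
            eff = draw_session_effect(sess, config, rng)
            rec = synthesize_session(sig, eff, config, rng=rng, role=role)
            entry = {
                "subject_id": sid,
                "session_index": sess,
                "role": role,
                "seed": int(sess_ss.generate_state(1)[0]),
                "path": None,
            }
            if out_path is not None:
                from .edf import write_edf
                fname = out_path / f"{sid}_s{sess:02d}.edf"
                write_edf(fname, rec)
                written.append(fname)
                entry["path"] = str(fname)
            else:
                cohort.recordings[(sid, sess)] = rec
            cohort.manifest.append(entry)
        if out_path is not None:
            manifest_file = out_path / "manifest.json"
            manifest_file.write_text(json.dumps(cohort.manifest, indent=1))
            written.append(manifest_file)
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
    return cohort


def load_cohort(out_dir: str | Path, config: CohortConfig) -> Cohort:
    """Re-open a cohort previously written with ``generate_cohort(out_dir=...)``."""
    out_path = Path(out_dir)
    manifest = json.loads((out_path / "manifest.json").read_text())
    return Cohort(config=config, manifest=manifest, out_dir=out_path)
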