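"""EEG ingestion and signal conditioning.

Recordings enter as EDF files or plain delimited text, are band-pass
filtered (zero-phase Butterworth), resampled to a common 128 Hz rate, and
re-referenced to the average reference (the instantaneous mean across
channels is subtracted from every channel).  A simple absolute-amplitude
window-rejection mask stands in for manual/ICA artifact screening, which
is inherently non-reproducible; it is disabled by default.

Channel labels are normalised through the 10-20 old/new alias table
(T3<->T7, T4<->T8, T5<->P7, T6<->P8) so that region maps can be written in
either nomenclature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "MONTAGE_19",
    "CHANNEL_ALIASES",
    "normalize_label",
    "EEGRecording",
    "PreprocessConfig",
    "load_recording",
    "save_recording_text",
    "preprocess",
    "reject_windows",
]

#: Old-nomenclature -> modern 10-20 labels (same scalp positions).
CHANNEL_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

#: The standard 19-channel montage, in normalised nomenclature.
MONTAGE_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

_CANONICAL = {ch.upper(): ch for ch in MONTAGE_19}


def normalize_label(label: str) -> str:
    """Map a channel label to modern 10-20 nomenclature.

    Unknown labels pass through unchanged (with their case preserved) so
    non-standard montages remain loadable.
    """
    clean = label.strip()
    up = clean.upper()
    up = CHANNEL_ALIASES.get(up.capitalize(), up.capitalize()).upper()
    return _CANONICAL.get(up, clean)


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    original_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs={self.fs} must be positive")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows for {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels after normalisation")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(normalize_label(label))]


@dataclass
class PreprocessConfig:
    """Signal-conditioning parameters.

    Defaults follow the acquisition described for the target datasets:
    0.1–100 Hz pass band, 128 Hz analysis rate, average reference.  The
    upper band edge is capped at ``0.45 * target_fs`` when it would exceed
    the Nyquist limit of the analysis rate (a 100 Hz edge cannot survive
    resampling to 128 Hz); the cap is logged.
    """

    band_low_hz: float = 0.1
    band_high_hz: float = 100.0
    target_fs: float = 128.0
    rereference: str = "average"  # or "none"
    filter: bool = True
    filter_order: int = 4
    artifact_abs_threshold_uv: float | None = None  # disabled by default

    def __post_init__(self) -> None:
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("band_low_hz must be < band_high_hz")
        if self.rereference not in ("average", "none"):
            raise ValueError(f"unknown rereference {self.rereference!r}")


def _parse_text(path: Path) -> EEGRecording:
    fs = None
    labels: list[str] | None = None
    subject = path.stem
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip().lower()
                    if key in ("fs", "sampling_rate", "sfreq"):
                        fs = float(value)
                    elif key in ("channels", "labels"):
                        labels = [c.strip() for c in value.split(",")]
                    elif key in ("subject", "subject_id"):
                        subject = value.strip()
                continue
            if labels is None and any(c.isalpha() for c in line):
                labels = [c.strip() for c in line.replace(",", " ").split()]
                continue
            rows.append([float(v) for v in line.replace(",", " ").split()])
    if fs is None:
        raise ValueError(f"{path}: no sampling rate found (need a '# fs: <Hz>' line)")
    if not rows:
        raise ValueError(f"{path}: no samples found")
    data = np.asarray(rows, dtype=float).T  # rows are samples, columns channels
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    if len(labels) != data.shape[0]:
        raise ValueError(
            f"{path}: {len(labels)} labels for {data.shape[0]} data columns"
        )
    return _finalize_labels(data, fs, labels, subject)


def _finalize_labels(data, fs, raw_labels, subject) -> EEGRecording:
    normalized, originals = [], {}
    for lab in raw_labels:
        norm = normalize_label(lab)
        if norm not in MONTAGE_19:
            logger.warning("unknown channel label %r kept as-is", lab)
        if norm != lab:
            originals[norm] = lab
        normalized.append(norm)
    return EEGRecording(
        data=data,
        fs=fs,
        channel_labels=normalized,
        subject_id=subject,
        original_labels=originals,
    )


def _load_edf(path: Path) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return _finalize_labels(data, float(raw.info["sfreq"]), list(raw.ch_names), path.stem)


def load_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read an EDF or delimited-text recording.

    Text files carry ``#``-prefixed metadata lines (``# fs: 128``,
    ``# channels: Fp1, Fp2, ...``) or a header row of labels, then one row
    of channel values per sample.  Labels are normalised through the
    old/new 10-20 alias table, retaining the original spelling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "text"
    if format == "edf":
        return _load_edf(path)
    if format in ("text", "delimited-text", "txt", "tsv", "csv"):
        return _parse_text(path)
    raise ValueError(f"unknown recording format {format!r}")


def save_recording_text(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording in the delimited-text layout read by this module."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject: {rec.subject_id}\n")
        fh.write(f"# fs: {rec.fs:g}\n")
        fh.write(f"# channels: {', '.join(rec.channel_labels)}\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter="\t")
    return path


def _resample(data: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    if math.isclose(fs, target_fs):
        return data
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)


def preprocess(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Band-pass filter, resample, then average-reference a recording.

    The filter is a zero-phase (forward-backward) Butterworth of the
    configured order, applied at the original rate; the band edges are
    capped below the post-resampling Nyquist frequency when needed.  After
    the average reference the cross-channel mean is zero at every sample.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.target_fs > rec.fs:
        raise ValueError(
            f"target_fs={cfg.target_fs} exceeds recording rate {rec.fs}"
        )
    data = rec.data
    high = cfg.band_high_hz
    cap = 0.45 * cfg.target_fs
    if cfg.filter and high >= cfg.target_fs / 2:
        logger.warning(
            "band_high %.6g Hz >= Nyquist of target rate %.6g Hz; capping at %.6g Hz",
            high, cfg.target_fs, cap,
        )
        high = cap
    if cfg.filter:
        sos = sps.butter(
            cfg.filter_order,
            [max(cfg.band_low_hz, 1e-6), min(high, 0.499 * rec.fs)],
            btype="bandpass",
            fs=rec.fs,
            output="sos",
        )
        data = sps.sosfiltfilt(sos, data, axis=1)
    data = _resample(data, rec.fs, cfg.target_fs)
    if cfg.rereference == "average":
        data = data - data.mean(axis=0, keepdims=True)
    return replace(
        rec, data=np.ascontiguousarray(data), fs=cfg.target_fs,
        channel_labels=list(rec.channel_labels),
    )


def reject_windows(
    rec: EEGRecording, window_samples: int, abs_threshold_uv: float | None
) -> np.ndarray:
    """Keep-mask over consecutive non-overlapping windows.

    A window is rejected when any channel exceeds ``abs_threshold_uv`` in
    absolute amplitude anywhere inside it.  ``None`` disables rejection
    (all-true mask).  Raises if every window would be rejected.
    """
    n_windows = rec.n_samples // window_samples
    if n_windows < 1:
        raise ValueError("recording shorter than one window")
    if abs_threshold_uv is None:
        return np.ones(n_windows, dtype=bool)
    if abs_threshold_uv <= 0:
        raise ValueError("abs_threshold_uv must be positive or None")
    trimmed = rec.data[:, : n_windows * window_samples]
    peaks = np.abs(trimmed).reshape(rec.n_channels, n_windows, window_samples).max(
        axis=(0, 2)
    )
    keep = peaks <= abs_threshold_uv
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info(
            "reject_windows: %d/%d windows rejected at %.6g uV",
            n_rej, n_windows, abs_threshold_uv,
        )
    if not keep.any():
        raise ValueError(
            f"all {n_windows} windows exceed {abs_threshold_uv} uV; "
            "review the artifact threshold"
        )
    return keep
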