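"""Recording containers, EDF/TSV input, and the standard EEG preprocessing steps.

The preprocessing chain used by the pipeline is: channel selection ->
broadband bandpass (0.5-45 Hz) -> average reference -> per-band bandpass ->
fixed-length epoching. Filtering is zero-phase (forward-backward 4th-order
Butterworth, effective 8th order), so filtering and average-referencing
commute and no group delay is introduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import _edf

#: The 19 electrodes of the international 10-20 system used for analysis.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz",
    "T3", "T4", "T5", "T6", "C3", "C4", "Cz",
    "P3", "P4", "Pz", "O1", "O2",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band: half-open interval (low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band {self.name}: ({self.low}, {self.high}) Hz")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz is not below the "
                f"Nyquist frequency {fs / 2} Hz"
            )


#: Canonical EEG analysis bands.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}

#: Broadband range used for the initial filter and the full-band analysis.
FULL_BAND = BandDefinition("full", 0.5, 45.0)

ALL_BANDS: dict[str, BandDefinition] = {"full": FULL_BAND, **BANDS}


def get_band(name: str) -> BandDefinition:
    try:
        return ALL_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known bands: {', '.join(ALL_BANDS)}"
        ) from None


@dataclass
class MultichannelRecording:
    """Continuous multichannel signals in microvolts.

    data : channels x samples array
    fs : sampling rate in Hz
    channel_names : one name per row of ``data``
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochedRecording:
    """Non-overlapping fixed-length epochs: epochs x channels x samples."""

    data: np.ndarray
    fs: float
    epoch_length: float
    channel_names: list[str]
    band: BandDefinition = field(default=FULL_BAND)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be epochs x channels x samples")
        expected = self.epoch_length * self.fs
        if abs(self.data.shape[2] - expected) > 1e-9:
            raise ValueError(
                f"epoch has {self.data.shape[2]} samples, expected "
                f"{expected} ({self.epoch_length} s at {self.fs} Hz)"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def read_edf(path: str | Path) -> MultichannelRecording:
    """Load an EDF file with per-channel physical calibration applied.

    Channels must share a single sampling rate; annotation channels are
    dropped by the reader.
    """
    data, fs, names = _edf.read_edf(path)
    return MultichannelRecording(data=data, fs=fs, channel_names=names)


def write_edf(rec: MultichannelRecording, path: str | Path, **kwargs) -> None:
    """Write a recording as 16-bit EDF (physical units microvolts)."""
    _edf.write_edf(path, rec.data, rec.fs, rec.channel_names, **kwargs)


def read_tsv(path: str | Path, fs: float) -> MultichannelRecording:
    """Read a samples x channels TSV with a header row of channel names."""
    df = pd.read_csv(path, sep="\t")
    return MultichannelRecording(
        data=df.to_numpy(dtype=np.float64).T,
        fs=fs,
        channel_names=[str(c) for c in df.columns],
    )


def write_tsv(rec: MultichannelRecording, path: str | Path) -> None:
    pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def _canonical(label: str) -> str:
    """Channel-label normalization across EDF dialects.

    Case-insensitive; strips a leading "EEG " transducer prefix and reference
    suffixes such as "-REF" or "-LE".
    """
    s = label.strip().upper()
    if s.startswith("EEG "):
        s = s[4:]
    for suffix in ("-REF", "-LE", "-AVG", "-A1", "-A2"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    return s.strip()


def select_channels(
    rec: MultichannelRecording, names: list[str]
) -> MultichannelRecording:
    """Return the requested channels, re-ordered to match ``names``.

    Matching is case-insensitive with common EDF affixes stripped. Missing
    channels raise a ``KeyError`` listing every absent name.
    """
    available = {}
    for idx, label in enumerate(rec.channel_names):
        available.setdefault(_canonical(label), idx)
    missing = [nm for nm in names if _canonical(nm) not in available]
    if missing:
        raise KeyError(
            "channels not found in recording: " + ", ".join(missing)
        )
    rows = [available[_canonical(nm)] for nm in names]
    return MultichannelRecording(
        data=rec.data[rows].copy(), fs=rec.fs, channel_names=list(names)
    )


def bandpass_filter(
    rec: MultichannelRecording, band: BandDefinition, order: int = 4
) -> MultichannelRecording:
    """Zero-phase Butterworth bandpass (applied forward and backward).

    The quoted ``order`` is the one-pass order; the forward-backward
    application doubles the effective order and cancels the group delay, so
    the output is exactly as long as the input and phase-aligned with it.
    """
    band.validate_for(rec.fs)
    sos = butter(order, [band.low, band.high], btype="bandpass", fs=rec.fs,
                 output="sos")
    filtered = sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=filtered)


def rereference_average(rec: MultichannelRecording) -> MultichannelRecording:
    """Subtract the instantaneous mean across channels (common average
    reference); idempotent."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def segment_epochs(
    rec: MultichannelRecording,
    epoch_length_s: float,
    band: BandDefinition = FULL_BAND,
) -> EpochedRecording:
    """Cut the recording into consecutive non-overlapping epochs from sample 0.

    A trailing remainder shorter than one epoch is dropped.
    """
    n_per = epoch_length_s * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"epoch length {epoch_length_s} s is not a whole number of "
            f"samples at {rec.fs} Hz"
        )
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        raise ValueError(
            f"recording ({rec.duration:.3f} s) is shorter than one "
            f"epoch ({epoch_length_s} s)"
        )
    trimmed = rec.data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochedRecording(
        data=epochs.copy(),
        fs=rec.fs,
        epoch_length=float(epoch_length_s),
        channel_names=list(rec.channel_names),
        band=band,
    )


def preprocess(
    rec: MultichannelRecording,
    channels: list[str] | None = None,
    bands: list[str] | None = None,
    epoch_length_s: float = 2.0,
) -> dict[str, EpochedRecording]:
    """Full preprocessing chain; returns epoched data keyed by band name.

    Order: channel selection -> broadband 0.5-45 Hz filter -> average
    reference -> per-band filter -> epoching. The "full" band re-uses the
    broadband signal without a second filter pass. Artifact cleaning (the
    expert ICA step of clinical practice) is deliberately not automated; a
    cleaned recording can be passed straight into this function.
    """
    band_defs = [get_band(b) for b in (bands or list(ALL_BANDS))]
    if channels is not None:
        rec = select_channels(rec, channels)
    broadband = rereference_average(bandpass_filter(rec, FULL_BAND))
    out: dict[str, EpochedRecording] = {}
    for band in band_defs:
        sig = broadband if band.name == "full" else bandpass_filter(broadband, band)
        out[band.name] = segment_epochs(sig, epoch_length_s, band=band)
    return out


def save_epochs(epoched: EpochedRecording, out_dir: str | Path, stem: str) -> Path:
    """Store an epoch block as a flat TSV (epoch*sample rows x channels) with
    a JSON sidecar describing fs, band, epoch length, and channel names."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    flat = epoched.data.transpose(0, 2, 1).reshape(-1, epoched.n_channels)
    data_path = out_dir / f"{stem}.tsv"
    pd.DataFrame(flat, columns=epoched.channel_names).to_csv(
        data_path, sep="\t", index=False, float_format="%.6f"
    )
    sidecar = {
        "fs": epoched.fs,
        "band": epoched.band.name,
        "band_low_hz": epoched.band.low,
        "band_high_hz": epoched.band.high,
        "epoch_length_s": epoched.epoch_length,
        "n_epochs": epoched.n_epochs,
        "channel_names": epoched.channel_names,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return data_path


def load_epochs(data_path: str | Path) -> EpochedRecording:
    """Inverse of :func:`save_epochs`."""
    data_path = Path(data_path)
    sidecar = json.loads(data_path.with_suffix(".json").read_text())
    df = pd.read_csv(data_path, sep="\t")
    n_per = int(round(sidecar["epoch_length_s"] * sidecar["fs"]))
    flat = df.to_numpy(dtype=np.float64)
    data = flat.reshape(sidecar["n_epochs"], n_per, -1).transpose(0, 2, 1)
    band = BandDefinition(
        sidecar["band"], sidecar["band_low_hz"], sidecar["band_high_hz"]
    )
    return EpochedRecording(
        data=data,
        fs=sidecar["fs"],
        epoch_length=sidecar["epoch_length_s"],
        channel_names=[str(c) for c in sidecar["channel_names"]],
        band=band,
    )
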