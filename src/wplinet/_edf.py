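"""Minimal EDF (European Data Format) reader/writer for 16-bit continuous recordings.

Implements the fixed-width ASCII header plus int16 little-endian data records
of the original EDF specification (Kemp et al. 1992). Only the features a
continuous scalp-EEG pipeline needs are supported: one uniform sampling rate
across ordinary signals, physical calibration per channel, and annotation
channels skipped on read. Writing uses a 1-second data record and per-channel
physical min/max, so the round-trip error is at most one quantization step
(physical range / 65535).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

_HDR = 256  # bytes in the fixed part of the header

_ANNOTATION_LABELS = {"EDF ANNOTATIONS", "BDF ANNOTATIONS"}


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    # EDF physical min/max are 8-char ASCII; use the densest representation
    for fmt in (f"{x:.6g}", f"{x:.5g}", f"{x:.4g}", f"{x:.3g}"):
        if len(fmt) <= width:
            return fmt
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    physical_dimension: str = "uV",
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write ``data`` (channels x samples, physical units) as 16-bit EDF.

    The record duration is 1 s, so ``fs`` must be a whole number of Hz and the
    recording a whole number of seconds.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match data rows")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s record
    if n_samp % spr != 0:
        raise ValueError(
            f"recording length ({n_samp} samples) is not a whole number of "
            f"1-s records at {spr} Hz"
        )
    n_rec = n_samp // spr

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(_HDR * (1 + n_ch)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_field(nm, 16) for nm in channel_names),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(physical_dimension, 8) for _ in range(n_ch)),
            b"".join(_field(_fmt_float(v), 8) for v in pmin),
            b"".join(_field(_fmt_float(v), 8) for v in pmax),
            b"".join(_field(str(dmin), 8) for _ in range(n_ch)),
            b"".join(_field(str(dmax), 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )

    gain = (pmax - pmin) / (dmax - dmin)
    digital = np.rint((data - pmin[:, None]) / gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")
    # records x channels x samples-per-record interleaving
    records = digital.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(records.tobytes())


def _parse_floats(raw: bytes, n: int, width: int, what: str) -> np.ndarray:
    out = np.empty(n)
    for i in range(n):
        s = raw[i * width : (i + 1) * width].decode("ascii", "replace").strip()
        try:
            out[i] = float(s)
        except ValueError as exc:
            raise ValueError(f"invalid EDF {what} field: {s!r}") from exc
    return out


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; return (channels x samples physical data, fs, names).

    Annotation channels are dropped. All remaining channels must share one
    sampling rate; otherwise a ``ValueError`` naming the conflicting rates is
    raised.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HDR:
        raise ValueError(f"{path}: not a valid EDF file (header truncated)")
    try:
        n_rec = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        n_sig = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise ValueError(f"{path}: unreadable EDF header") from exc
    if n_sig <= 0:
        raise ValueError(f"{path}: EDF header declares {n_sig} signals")
    sig_hdr_len = n_sig * 256
    if len(raw) < _HDR + sig_hdr_len:
        raise ValueError(f"{path}: signal headers truncated")
    sh = raw[_HDR : _HDR + sig_hdr_len]

    def block(offset: int, width: int) -> bytes:
        start = offset * n_sig
        return sh[start : start + n_sig * width]

    labels = [
        block(0, 16)[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(n_sig)
    ]
    pmin = _parse_floats(block(16 + 80 + 8, 8), n_sig, 8, "physical minimum")
    pmax = _parse_floats(block(16 + 80 + 8 + 8, 8), n_sig, 8, "physical maximum")
    dmin = _parse_floats(block(16 + 80 + 8 + 16, 8), n_sig, 8, "digital minimum")
    dmax = _parse_floats(block(16 + 80 + 8 + 24, 8), n_sig, 8, "digital maximum")
    spr = _parse_floats(
        block(16 + 80 + 8 + 32 + 80, 8), n_sig, 8, "samples per record"
    ).astype(int)

    keep = [i for i, lb in enumerate(labels) if lb.upper() not in _ANNOTATION_LABELS]
    if not keep:
        raise ValueError(f"{path}: no signal channels (annotations only)")
    if n_rec <= 0:
        raise ValueError(f"{path}: zero-length record (n_records={n_rec})")
    if rec_dur <= 0:
        raise ValueError(f"{path}: non-positive record duration {rec_dur}")

    rates = sorted({spr[i] / rec_dur for i in keep})
    if len(rates) > 1:
        raise ValueError(
            f"{path}: channels have differing sampling rates: "
            + ", ".join(f"{r:g} Hz" for r in rates)
        )
    fs = rates[0]

    rec_len = int(spr.sum())  # int16 words per data record
    payload = np.frombuffer(
        raw, dtype="<i2", offset=_HDR + sig_hdr_len, count=n_rec * rec_len
    )
    offsets = np.concatenate([[0], np.cumsum(spr)])
    records = payload.reshape(n_rec, rec_len)
    out = np.empty((len(keep), n_rec * spr[keep[0]]))
    names = []
    for row, i in enumerate(keep):
        dig = records[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(np.float64)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        out[row] = (dig - dmin[i]) * gain + pmin[i]
        names.append(labels[i])
    return out, float(fs), names
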