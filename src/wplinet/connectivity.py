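"""Weighted phase lag index (wPLI) connectivity.

The wPLI between two signals weights each observed phase difference by the
magnitude of the imaginary part of their cross-spectrum:

    wPLI = |E[Im Y]| / E[|Im Y|],      Y_t = a_i(t) * conj(a_j(t))

where a_i, a_j are the analytic (Hilbert) signals of the band-filtered
channels. Zero-lag coupling has Im Y = 0 and contributes nothing, which is
what makes the index robust to volume conduction: a source seen
instantaneously at two scalp electrodes cannot inflate it. Values lie in
[0, 1]; 1 means the sign of the lagged interaction is perfectly consistent
over time.

The expectation is taken over time samples within one 2-s epoch (after
trimming the Hilbert edge region); the subject-level matrix is the mean over
epochs. Both levels are kept, because group statistics can be formed at
either level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .io_preproc import BandDefinition, EpochedRecording, FULL_BAND

#: Fraction of samples discarded at each epoch edge before taking the
#: expectation, to suppress Hilbert transform edge artifacts.
EDGE_TRIM_FRACTION = 0.05


@dataclass
class ConnectivityMatrix:
    """Subject-level wPLI network for one band, with the epoch stack retained.

    weights : channels x channels symmetric matrix, zero diagonal, entries in [0, 1];
        equals ``epoch_stack.mean(axis=0)``
    epoch_stack : epochs x channels x channels block of per-epoch matrices
    """

    weights: np.ndarray
    band: BandDefinition
    n_epochs: int
    epoch_stack: np.ndarray
    channel_names: list[str]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        if w.min() < 0 or w.max() > 1 + 1e-12:
            raise ValueError("wPLI weights must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(
            self.weights, index=self.channel_names, columns=self.channel_names
        ).to_csv(path, sep="\t", float_format="%.8f")
        sidecar = {
            "band": self.band.name,
            "band_low_hz": self.band.low,
            "band_high_hz": self.band.high,
            "n_epochs": self.n_epochs,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConnectivityMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
            band = BandDefinition(
                meta["band"], meta["band_low_hz"], meta["band_high_hz"]
            )
            n_epochs = int(meta["n_epochs"])
        else:
            band, n_epochs = FULL_BAND, 1
        w = df.to_numpy(dtype=np.float64)
        return cls(
            weights=w,
            band=band,
            n_epochs=n_epochs,
            epoch_stack=w[None, :, :],
            channel_names=[str(c) for c in df.columns],
        )


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal along the last axis: Re = input, Im = Hilbert transform."""
    x = np.asarray(x, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("analytic_signal requires finite input")
    return hilbert(x, axis=-1)


def wpli_pair(a_i: np.ndarray, a_j: np.ndarray) -> float:
    """wPLI of two complex (analytic) series; 0 when the imaginary
    cross-spectrum vanishes identically (the 0/0 zero-lag case)."""
    a_i = np.asarray(a_i)
    a_j = np.asarray(a_j)
    if a_i.shape != a_j.shape:
        raise ValueError(f"length mismatch: {a_i.shape} vs {a_j.shape}")
    im = np.imag(a_i * np.conj(a_j))
    denom = np.abs(im).mean()
    # 0/0 guard with a relative floor: rounding noise in the elementwise
    # complex products is O(eps * |a_i||a_j|) even when Im Y is exactly zero
    tol = 64 * np.finfo(np.float64).eps * (np.abs(a_i) * np.abs(a_j)).mean()
    if denom <= tol:
        return 0.0
    return float(np.abs(im.mean()) / denom)


def _trim_slice(n_samples: int) -> slice:
    k = int(np.floor(EDGE_TRIM_FRACTION * n_samples))
    return slice(k, n_samples - k if k else n_samples)


def wpli_matrix(epoched: EpochedRecording) -> ConnectivityMatrix:
    """Per-epoch wPLI over all unordered channel pairs, plus the epoch mean.

    Each epoch is Hilbert-transformed per channel; the first and last 5% of
    samples are excluded from the expectation.
    """
    if epoched.n_epochs < 1:
        raise ValueError("need at least one epoch")
    n_ch = epoched.n_channels
    if n_ch < 2:
        raise ValueError("need at least two channels")
    sl = _trim_slice(epoched.data.shape[2])
    stack = np.empty((epoched.n_epochs, n_ch, n_ch))
    for e in range(epoched.n_epochs):
        a = analytic_signal(epoched.data[e])[:, sl]
        # Im(a_i conj(a_j)) for all pairs at once; antisymmetric in (i, j)
        im = (a[:, None, :] * np.conj(a[None, :, :])).imag
        num = np.abs(im.mean(axis=-1))
        den = np.abs(im).mean(axis=-1)
        mag = np.abs(a)
        tol = 64 * np.finfo(np.float64).eps * (mag @ mag.T) / a.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > tol, num / den, 0.0)
        np.fill_diagonal(w, 0.0)
        stack[e] = 0.5 * (w + w.T)  # numerically enforce symmetry
    weights = stack.mean(axis=0)
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(
        weights=np.clip(weights, 0.0, 1.0),
        band=epoched.band,
        n_epochs=epoched.n_epochs,
        epoch_stack=stack,
        channel_names=list(epoched.channel_names),
    )
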