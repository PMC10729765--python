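"""Synthetic multichannel EEG with controllable band-specific phase-lagged coupling.

Each channel is a sum over the five canonical bands of band-limited Gaussian
processes riding on 1/f background noise. Coupling between a channel pair in
one band is modeled with a shared narrowband source: both channels mix the
common source into their band component, the second channel's copy rotated
in phase by a fixed lag (rotation of the analytic signal, so the lag is
constant across the band). ``strength`` is the fraction of the band
component's *power* contributed by the shared source — amplitude weights are
sqrt(strength) and sqrt(1-strength) so total variance is preserved. A zero
lag produces coupling that wPLI must ignore (the volume-conduction null);
a quarter-cycle lag at strength 1 drives wPLI to its upper limit.

Cohorts assign every subject a sub-seed spawned from the master seed
(``numpy.random.SeedSequence.spawn``, a counter-based scheme), so any single
subject's recording is reproducible in isolation. Group A and group B use
per-band coupling strengths ``strength_a``/``strength_b``; between-subject
variability is a small Gaussian jitter on the strength.

What this emulates — and what it does not: band-limited rhythms with 1/f
background and lagged shared sources, at the study geometry (19 channels of
the 10-20 system, 500 Hz, 20 min). It does not model volume-conduction
forward physics, eye/muscle artifacts, or epileptiform morphology.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .io_preproc import (
    BANDS,
    CHANNELS_1020,
    BandDefinition,
    MultichannelRecording,
    write_edf,
    write_tsv,
)

#: Default fraction of band-component power from the shared source, per group.
#: Group A plays the patient role: weaker delta coupling, stronger
#: alpha/beta/gamma coupling, no theta difference.
DEFAULT_STRENGTHS: dict[str, tuple[float, float]] = {
    "delta": (0.25, 0.55),
    "theta": (0.40, 0.40),
    "alpha": (0.55, 0.25),
    "beta": (0.55, 0.25),
    "gamma": (0.55, 0.25),
}

#: Coupled channel pairs per band (disjoint within a band; valid for >= 8
#: channels). Chosen once so every band has its own edge set.
DEFAULT_PAIRS: dict[str, tuple[tuple[int, int], ...]] = {
    "delta": ((0, 1), (2, 3), (4, 5)),
    "theta": ((1, 2), (3, 4), (5, 6)),
    "alpha": ((0, 2), (1, 3), (6, 7)),
    "beta": ((0, 3), (2, 5), (4, 7)),
    "gamma": ((1, 4), (3, 6), (5, 7)),
}

#: Phase lags cycled over a band's coupled pairs; all well away from 0 and pi.
DEFAULT_LAGS = (math.pi / 2, math.pi / 3, 2 * math.pi / 3)

#: Between-subject SD of the coupling strength.
DEFAULT_SUBJECT_SD = 0.05


@dataclass(frozen=True)
class CouplingSpec:
    """One phase-lagged shared source between two channels in one band."""

    pair: tuple[int, int]
    band: BandDefinition
    lag: float
    strength: float

    def __post_init__(self) -> None:
        i, j = self.pair
        if i == j:
            raise ValueError(f"coupling pair must be two distinct channels, got {self.pair}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError(f"coupling strength must be in [0, 1], got {self.strength}")
        if not -math.pi < self.lag <= math.pi:
            raise ValueError(f"lag must lie in (-pi, pi], got {self.lag}")

    def validate_channels(self, n_channels: int) -> None:
        for c in self.pair:
            if not 0 <= c < n_channels:
                raise ValueError(
                    f"coupling channel index {c} out of range for {n_channels} channels"
                )


@dataclass(frozen=True)
class BandEffect:
    """Per-band group coupling: strengths for group A and B on a pair set."""

    band: str
    strength_a: float
    strength_b: float
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for s in (self.strength_a, self.strength_b):
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"strength must be in [0, 1], got {s}")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")


def default_band_effects(n_channels: int = 19) -> list[BandEffect]:
    if n_channels < 8:
        raise ValueError("default band effects need at least 8 channels")
    return [
        BandEffect(band, *DEFAULT_STRENGTHS[band], pairs=DEFAULT_PAIRS[band])
        for band in BANDS
    ]


@dataclass
class CohortConfig:
    """Study-geometry defaults: 10 vs 5 subjects, 19 channels, 500 Hz, 20 min."""

    n_group_a: int = 10
    n_group_b: int = 5
    n_channels: int = 19
    fs: float = 500.0
    duration: float = 1200.0
    band_effects: list[BandEffect] | None = None
    noise_exponent: float = 1.0
    noise_amp: float = 1.0
    subject_sd: float = DEFAULT_SUBJECT_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration x fs must be an integer sample count, got {n}"
            )
        if self.band_effects is None:
            self.band_effects = default_band_effects(self.n_channels)

    def resolved(self) -> dict:
        return {
            "n_group_a": self.n_group_a,
            "n_group_b": self.n_group_b,
            "n_channels": self.n_channels,
            "fs": self.fs,
            "duration": self.duration,
            "noise_exponent": self.noise_exponent,
            "noise_amp": self.noise_amp,
            "subject_sd": self.subject_sd,
            "seed": self.seed,
            "band_effects": [
                {
                    "band": e.band,
                    "strength_a": e.strength_a,
                    "strength_b": e.strength_b,
                    "pairs": [list(p) for p in e.pairs],
                }
                for e in self.band_effects
            ],
        }


def fast_config(**overrides) -> CohortConfig:
    """Reduced geometry for quick runs: 8 channels, 250 Hz, 2 min."""
    kwargs = dict(n_channels=8, fs=250.0, duration=120.0)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _narrowband(rng: np.random.Generator, n: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Unit-variance Gaussian noise confined to the band by spectral masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band.low) | (f > band.high)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _rotate_phase(x: np.ndarray, lag: float) -> np.ndarray:
    """Delay the signal's phase by ``lag`` radians via analytic-signal rotation."""
    if lag == 0.0:
        return x
    return np.real(hilbert(x) * np.exp(-1j * lag))


def generate_recording(
    n_channels: int,
    fs: float,
    duration: float,
    couplings: list[CouplingSpec] | None = None,
    noise_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
    noise_amp: float = 1.0,
    amplitude_uv: float = 10.0,
) -> MultichannelRecording:
    """One synthetic recording; deterministic given the seed.

    Per band, each channel gets a private narrowband source; every
    ``CouplingSpec`` replaces a power fraction ``strength`` of both member
    channels' band component with a common source (the second member's copy
    phase-rotated by ``lag``). Strength fractions touching the same channel
    within one band must sum to at most 1.
    """
    couplings = couplings or []
    n = duration * fs
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"duration x fs must be an integer sample count, got {n}")
    n = int(round(n))
    for cp in couplings:
        cp.validate_channels(n_channels)
    rng = _rng(seed)

    data = np.zeros((n_channels, n))
    for band in BANDS.values():
        band_cps = [cp for cp in couplings if cp.band.name == band.name]
        shared_load = np.zeros(n_channels)
        comp = np.zeros((n_channels, n))
        # shared sources first (fixed draw order keeps cohorts reproducible)
        for cp in band_cps:
            i, j = cp.pair
            shared_load[i] += cp.strength
            shared_load[j] += cp.strength
            src = _narrowband(rng, n, fs, band)
            amp = math.sqrt(cp.strength)
            comp[i] += amp * src
            comp[j] += amp * _rotate_phase(src, cp.lag)
        if shared_load.max() > 1 + 1e-12:
            bad = int(np.argmax(shared_load))
            raise ValueError(
                f"channel {bad} receives total shared power {shared_load[bad]:.3f} "
                f"> 1 in band {band.name}"
            )
        for c in range(n_channels):
            comp[c] += math.sqrt(max(0.0, 1.0 - shared_load[c])) * _narrowband(
                rng, n, fs, band
            )
        data += comp
    for c in range(n_channels):
        data[c] += noise_amp * _pink(rng, n, fs, noise_exponent)
    data *= amplitude_uv

    if n_channels == len(CHANNELS_1020):
        names = list(CHANNELS_1020)
    else:
        names = [f"CH{c + 1:02d}" for c in range(n_channels)]
    return MultichannelRecording(data=data, fs=fs, channel_names=names)


def subject_couplings(
    config: CohortConfig, group: str, rng: np.random.Generator
) -> list[CouplingSpec]:
    """Materialize one subject's coupling specs with between-subject jitter."""
    specs = []
    for effect in config.band_effects:
        base = effect.strength_a if group == "A" else effect.strength_b
        for k, pair in enumerate(effect.pairs):
            jitter = rng.normal(0.0, config.subject_sd) if config.subject_sd else 0.0
            specs.append(
                CouplingSpec(
                    pair=tuple(pair),
                    band=BANDS[effect.band],
                    lag=DEFAULT_LAGS[k % len(DEFAULT_LAGS)],
                    strength=float(np.clip(base + jitter, 0.0, 1.0)),
                )
            )
    return specs


def generate_cohort(config: CohortConfig) -> list[tuple[MultichannelRecording, str]]:
    """Labeled recordings: ``n_group_a`` with label "A" then ``n_group_b``
    with label "B"; per-subject sub-seeds spawned from the master seed."""
    n_total = config.n_group_a + config.n_group_b
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    cohort = []
    for idx, child in enumerate(children):
        group = "A" if idx < config.n_group_a else "B"
        rng = np.random.default_rng(child)
        specs = subject_couplings(config, group, rng)
        rec = generate_recording(
            n_channels=config.n_channels,
            fs=config.fs,
            duration=config.duration,
            couplings=specs,
            noise_exponent=config.noise_exponent,
            seed=rng,
            noise_amp=config.noise_amp,
        )
        cohort.append((rec, group))
    return cohort


def write_cohort(
    config: CohortConfig, out_dir: str | Path, fmt: str = "edf"
) -> Path:
    """Generate and store a cohort plus a JSON manifest.

    The manifest lists subject id, group, master seed + subject index, and
    the relative file path; it is the hand-off point between simulation and
    the analysis pipeline.
    """
    if fmt not in ("edf", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for idx, (rec, group) in enumerate(generate_cohort(config)):
        sid = f"sub-{idx + 1:03d}"
        fname = f"{sid}.{fmt}"
        if fmt == "edf":
            write_edf(rec, out_dir / fname, patient_id=sid)
        else:
            write_tsv(rec, out_dir / fname)
        entries.append(
            {
                "subject": sid,
                "group": group,
                "seed": config.seed,
                "subject_index": idx,
                "path": fname,
                "fs": rec.fs,
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(
        json.dumps({"config": config.resolved(), "subjects": entries}, indent=2)
    )
    return manifest
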