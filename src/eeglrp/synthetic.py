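"""Synthetic two-class resting-state EEG cohorts.

Each subject is a sum of three stationary components per channel:

* pink (1/f^beta) background noise, synthesised in the frequency domain;
* band-limited Gaussian oscillations (white noise bandpassed to each
  configured band) with per-channel random phase — the delta/theta/alpha/beta
  structure of eyes-closed EEG, with alpha dominant;
* white sensor noise.

Class effects are planted as multiplicative band-amplitude scalings on named
channels of class-1 (patient) subjects, emulating localized band-power group
differences.  A mild lognormal per-subject gain models between-subject
amplitude variability.

Every subject is reproducible from the cohort spec alone: the per-subject
random stream is seeded by (cohort seed, class, subject index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io import EEGRecording, write_edf, write_manifest
from .montage import Montage, standard_montage

#: default planted-effect channels: fronto-central, centro-parietal, occipital
DEFAULT_EFFECT_CHANNELS = ("FCz", "CPz", "Oz", "O1", "O2")


@dataclass(frozen=True)
class ClassEffect:
    """Band-power scaling applied to class-1 subjects on named channels."""

    band: tuple[float, float]  # Hz
    channels: tuple[str, ...]
    power_scale: float  # multiplies the band's oscillation amplitude

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"invalid band {self.band}")
        if self.power_scale <= 0:
            raise ValueError("power_scale must be positive")
        object.__setattr__(self, "channels", tuple(self.channels))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (two balanced classes)."""

    n_per_class: int
    montage: Montage = field(default_factory=standard_montage)
    fs: float = 200.0
    duration: float = 180.0  # seconds per subject
    background_exponent: float = 1.0  # beta of the 1/f^beta background
    background_amplitude: float = 8.0  # uV RMS of the background
    #: (band in Hz, RMS amplitude in uV) of each oscillation
    bands: tuple[tuple[tuple[float, float], float], ...] = (
        ((1.0, 4.0), 4.0),
        ((4.0, 8.0), 4.0),
        ((8.0, 13.0), 8.0),
        ((13.0, 30.0), 2.0),
    )
    effects: tuple[ClassEffect, ...] = ()
    sensor_noise: float = 1.0  # uV RMS white noise
    subject_gain_sigma: float = 0.2  # lognormal sigma of per-subject band gain
    band_limit: tuple[float, float] = (1.0, 55.0)  # final band limitation, Hz
    broadband: bool = False  # emit unfiltered wideband data (e.g. at 1000 Hz)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        max_band = max(high for (low, high), _ in self.bands)
        if self.fs <= 2 * max_band:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest band edge {max_band}"
            )
        names = set(self.montage.channel_names)
        for eff in self.effects:
            unknown = [c for c in eff.channels if c not in names]
            if unknown:
                raise KeyError(f"effect channels not in montage: {unknown}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _pink_noise(rng, n_ch, n_samp, exponent, fs) -> np.ndarray:
    """1/f^beta noise per channel via random-phase spectral synthesis."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = amp * (
        rng.standard_normal((n_ch, freqs.size))
        + 1j * rng.standard_normal((n_ch, freqs.size))
    )
    x = np.fft.irfft(spectrum, n=n_samp, axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def _band_noise(rng, n_ch, n_samp, band, fs) -> np.ndarray:
    """Unit-RMS Gaussian noise bandpassed to ``band`` (zero-phase)."""
    low, high = band
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n_samp)), axis=1)
    rms = x.std(axis=1, keepdims=True)
    return x / np.where(rms > 0, rms, 1.0)


def _bands_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def generate_subject(
    spec: CohortSpec, class_label: int, subject_index: int
) -> EEGRecording:
    """Deterministically synthesise one subject's recording."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    if not 0 <= subject_index < spec.n_per_class:
        raise IndexError(
            f"subject_index {subject_index} out of range for "
            f"n_per_class={spec.n_per_class}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), class_label, subject_index])
    )
    n_ch, n_samp = len(spec.montage), spec.n_samples

    x = spec.background_amplitude * _pink_noise(
        rng, n_ch, n_samp, spec.background_exponent, spec.fs
    )
    for band, base_amplitude in spec.bands:
        amp = np.full(n_ch, float(base_amplitude))
        if class_label == 1:
            for eff in spec.effects:
                if _bands_overlap(band, eff.band):
                    amp[spec.montage.indices(eff.channels)] *= eff.power_scale
        # per-subject, per-band amplitude variability (common to all channels)
        amp = amp * rng.lognormal(mean=0.0, sigma=spec.subject_gain_sigma)
        x += amp[:, None] * _band_noise(rng, n_ch, n_samp, band, spec.fs)
    x += spec.sensor_noise * rng.standard_normal((n_ch, n_samp))

    if not spec.broadband:
        # the "already preprocessed" dialect: band-limited and
        # common-average-referenced, as a cleaned clinical recording would be
        low = spec.band_limit[0]
        high = min(spec.band_limit[1], 0.45 * spec.fs)
        sos = sps.butter(4, [low, high], btype="bandpass", fs=spec.fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
        if x.shape[0] > 1:
            x = x - x.mean(axis=0, keepdims=True)

    return EEGRecording(
        subject_id=f"sub-{class_label}{subject_index:03d}",
        label=class_label,
        montage=spec.montage,
        fs=spec.fs,
        signal=x,
    )


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """All 2 * n_per_class recordings, class 0 (controls) first."""
    return [
        generate_subject(spec, label, i)
        for label in (0, 1)
        for i in range(spec.n_per_class)
    ]


def demo_effects(
    power_scale: float = 3.0,
    band: tuple[float, float] = (8.0, 13.0),
    channels: tuple[str, ...] = DEFAULT_EFFECT_CHANNELS,
) -> tuple[ClassEffect, ...]:
    """Alpha-band patient effect at fronto-central/centro-parietal/occipital
    channels — the planted analogue of localized resting-state group
    differences."""
    return (ClassEffect(band=band, channels=channels, power_scale=power_scale),)


def write_cohort(recordings: list[EEGRecording], out_dir, *, seed: int | None = None) -> Path:
    """One EDF per subject plus ``manifest.csv`` and ``montage.csv``.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.subject_id}.edf"
        write_edf(rec, out_dir / fname)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "class": rec.label,
                "filename": fname,
                "fs": rec.fs,
                "seed": seed,
            }
        )
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    recordings[0].montage.to_csv(out_dir / "montage.csv")
    return manifest
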