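"""Synthetic noisy measurements for testing the corner-frequency extractor.

Emulates the artefacts of a shaker-table transmittance measurement read out
through a piezoelectric sensor: multiplicative lognormal amplitude noise,
narrowband contamination at mains-frequency (60 Hz) harmonics, and the
one-pole high-pass roll-off of the charge-amplifier chain (7 Hz minimum
frequency).  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transfer_model import ResponseCurve

__all__ = ["SyntheticMeasurement", "synth_measurement", "one_pole_highpass"]

MAINS_HZ = 60.0
SENSOR_HIGHPASS_HZ = 7.0


@dataclass(frozen=True)
class SyntheticMeasurement:
    """Noisy normalized compression magnitude on a frequency grid."""

    frequencies: np.ndarray
    magnitude: np.ndarray
    seed: int
    noise_sd: float
    mains_amp: float
    highpass_hz: float

    @property
    def magnitude_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(self.magnitude)

    def as_curve(self) -> ResponseCurve:
        """Magnitude-only view as a zero-phase response curve."""
        return ResponseCurve(
            frequencies=self.frequencies,
            transmittance=self.magnitude.astype(complex),
        )


def one_pole_highpass(frequencies, corner_hz: float) -> np.ndarray:
    """|H(f)| of a one-pole high-pass; identity for ``corner_hz = 0``."""
    f = np.asarray(frequencies, dtype=float)
    if corner_hz <= 0:
        return np.ones_like(f)
    x = f / corner_hz
    return x / np.sqrt(1.0 + x * x)


def synth_measurement(
    curve: ResponseCurve,
    seed: int,
    noise_sd: float = 0.1,
    mains_amp: float = 0.5,
    highpass_hz: float = SENSOR_HIGHPASS_HZ,
) -> SyntheticMeasurement:
    """Corrupt a clean transmittance curve into a synthetic measurement.

    The clean magnitude is multiplied by ``exp(N(0, noise_sd))`` per point,
    the grid point nearest each 60 Hz harmonic is inflated by
    ``(1 + mains_amp)``, and the sensor high-pass is applied.  With all
    three corruptions disabled the output equals the clean magnitude.
    """
    f = curve.frequencies
    mag = curve.magnitude.copy()
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        mag *= np.exp(rng.normal(0.0, noise_sd, mag.size))
    if mains_amp > 0:
        k = 1
        while MAINS_HZ * k <= f[-1]:
            fm = MAINS_HZ * k
            if fm >= f[0]:
                mag[np.argmin(np.abs(f - fm))] *= 1.0 + mains_amp
            k += 1
    mag *= one_pole_highpass(f, highpass_hz)
    return SyntheticMeasurement(
        frequencies=f,
        magnitude=mag,
        seed=seed,
        noise_sd=noise_sd,
        mains_amp=mains_amp,
        highpass_hz=highpass_hz,
    )
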