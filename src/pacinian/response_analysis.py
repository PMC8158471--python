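"""Scalar filter characteristics and parametric design sweeps.

The corpuscle acts as a mechanical high-pass filter for compression: its
passband plateau, 3 dB corner and resonance peaks summarise the response.
The lightly damped ladder produces narrow resonance spikes superimposed on
a smooth broadband backbone, so all level-based definitions here operate on
a running-median *backbone* of the magnitude curve (window of a quarter
decade), which is insensitive to spikes regardless of where they fall:

* plateau: maximum of the backbone over the evaluated band;
* corner: lowest frequency at which the backbone first comes within 3 dB
  of the plateau, located by log-frequency linear interpolation;
* resonance: first strict local maximum of the raw magnitude (prominence
  over 0.5 dB) above the corner.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .layer_parameters import CorpuscleDesign, with_materials
from .transfer_model import ResponseCurve, TransferModel, default_grid, frequency_response

__all__ = [
    "CornerNotFoundError",
    "SweepResult",
    "magnitude_backbone",
    "corner_frequency_3db",
    "resonance_frequency",
    "static_transmittance",
    "parametric_sweep",
]

#: Width of the running-median backbone window, in decades.
BACKBONE_WINDOW_DECADES = 0.25

#: Minimum prominence (dB) for a local maximum to count as a resonance.
RESONANCE_PROMINENCE_DB = 0.5


class CornerNotFoundError(ValueError):
    """The magnitude curve never comes within 3 dB of its plateau."""


def magnitude_backbone(curve: ResponseCurve) -> np.ndarray:
    """Spike-robust running-median of ``magnitude_db`` (quarter-decade
    window, shrinking symmetrically at the band edges)."""
    f, db = curve.frequencies, curve.magnitude_db
    if f.size < 3:
        return db.copy()
    points_per_decade = (f.size - 1) / np.log10(f[-1] / f[0])
    w = int(points_per_decade * BACKBONE_WINDOW_DECADES) // 2 * 2 + 1
    w = max(5, w)
    return (
        pd.Series(db).rolling(w, center=True, min_periods=1).median().to_numpy()
    )


def corner_frequency_3db(curve: ResponseCurve) -> float:
    """Lowest frequency at which the response first comes within 3 dB of
    its passband plateau.

    The plateau is the maximum of the magnitude backbone over the band; the
    crossing of ``plateau - 3 dB`` is interpolated linearly in log f.  The
    curve should span at least a decade so that a plateau is identifiable.
    """
    f, db = curve.frequencies, curve.magnitude_db
    if f.size < 8 or f[-1] / f[0] < 10.0:
        raise ValueError("curve must cover at least one decade")
    if not np.any(np.isfinite(db)):
        raise CornerNotFoundError("all-zero or undefined magnitude")
    bb = magnitude_backbone(curve)
    plateau = np.nanmax(bb)
    target = plateau - 3.0
    above = np.where(bb >= target)[0]
    if above.size == 0:
        raise CornerNotFoundError("response never reaches plateau - 3 dB")
    i = above[0]
    if i == 0:
        return float(f[0])
    x0, x1 = np.log10(f[i - 1]), np.log10(f[i])
    y0, y1 = bb[i - 1], bb[i]
    return float(10.0 ** (x0 + (target - y0) * (x1 - x0) / (y1 - y0)))


def resonance_frequency(curve: ResponseCurve) -> Optional[float]:
    """Frequency of the first resonance peak above the 3 dB corner.

    A resonance is a strict local maximum of the raw magnitude with at
    least 0.5 dB prominence.  Returns ``None`` for monotone (peak-free)
    responses.
    """
    f, db = curve.frequencies, curve.magnitude_db
    try:
        fc = corner_frequency_3db(curve)
    except (ValueError, CornerNotFoundError):
        fc = f[0]
    peaks, _ = find_peaks(db, prominence=RESONANCE_PROMINENCE_DB)
    peaks = peaks[f[peaks] > fc]
    return float(f[peaks[0]]) if peaks.size else None


def static_transmittance(model: TransferModel) -> float:
    """Closed-form ``s = 0`` limit of the transmittance: the spring-only
    ladder ``K_L, K_M, K_sc, K_Pc``.

    Any layer with a disabled matrix (``K_M = 0``) breaks the static load
    path, giving exactly zero.
    """
    core = model.core
    g = 1.0 / core.K_sc + 1.0 / core.K_Pc
    total = 1.0
    for coeff in model.layers:
        if coeff.K_M == 0.0:
            return 0.0
        g_s = 1.0 / coeff.K_M
        total *= g / (g_s + g)
        g = 1.0 / (coeff.K_L + 1.0 / (g_s + g))
    return total


_SWEEPABLE = ("viscosity", "modulus", "n_layers", "matrix")


@dataclass(frozen=True)
class SweepResult:
    """Corner frequencies (and full curves) as one parameter is varied."""

    parameter: str
    values: tuple
    corner_frequencies: tuple
    curves: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter_value": self.values, "corner_hz": self.corner_frequencies}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def _apply(base: CorpuscleDesign, parameter: str, value) -> CorpuscleDesign:
    if parameter == "viscosity":
        return with_materials(base, fluid_viscosity=float(value))
    if parameter == "modulus":
        # one build material: lamella, matrix and core moduli scale together
        scale = float(value) / base.materials.lamella_modulus
        design = with_materials(
            base,
            lamella_modulus=float(value),
            matrix_modulus=base.materials.matrix_modulus * scale,
        )
        if base.core_modulus is not None:
            design = replace(design, core_modulus=base.core_modulus * scale)
        return design
    if parameter == "n_layers":
        return replace(base, n_layers=int(value))
    if parameter == "matrix":
        return replace(base, matrix_enabled=bool(value))
    raise ValueError(f"unknown sweep parameter {parameter!r}; one of {_SWEEPABLE}")


def parametric_sweep(
    base: CorpuscleDesign,
    parameter: str,
    values: Sequence,
    fmin: float = 1.0,
    fmax: float = 30e3,
    points: int = 400,
) -> SweepResult:
    """Rebuild the model per parameter value and extract the 3 dB corner.

    For modulus sweeps the grid is rescaled per value by
    ``sqrt(E / E_base)``: a uniform rescaling of every stiffness shifts the
    response along the frequency axis by exactly that factor, so the scaled
    grid keeps the corner inside the evaluated band at identical relative
    resolution.
    """
    corners: List[float] = []
    curves: List[ResponseCurve] = []
    for value in values:
        design = _apply(base, parameter, value)
        scale = 1.0
        if parameter == "modulus":
            scale = float(np.sqrt(float(value) / base.materials.lamella_modulus))
        grid = default_grid(fmin * scale, fmax * scale, points)
        curve = frequency_response(TransferModel.from_design(design), grid)
        corners.append(corner_frequency_3db(curve))
        curves.append(curve)
    return SweepResult(
        parameter=parameter,
        values=tuple(values),
        corner_frequencies=tuple(corners),
        curves=tuple(curves),
    )
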