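"""Complex-compliance cascade of the layered corpuscle.

Each layer is a Kelvin-Voigt element with an in-branch mass and a parallel
lamellar spring; the core is a Kelvin-Voigt element with an in-branch mass
and a series spring.  With ``s = j 2 pi f`` the branch compliance of layer
``i`` is::

    G_si(s) = 1 / (M_i s^2 + B_i s + K_Mi)

and the driving-point compliance of the structure seen at layer ``i`` obeys
the outward recursion (parallel spring => stiffnesses add, series elements
=> compliances add)::

    G_i(s) = 1 / (K_Li + 1 / (G_si(s) + G_{i-1}(s)))
    G_0(s) = 1/K_sc + 1 / (M_c s^2 + B_sc s + K_Pc)

The compression transmitted from the outermost layer ``N`` to the core is
the product of the interlayer ratios::

    X_0/X_N = prod_{m=1..N}  G_{m-1} / (G_{m-1} + G_sm)

This module evaluates the cascade on the ``s = j 2 pi f`` contour only; the
mass term sits inside the branch impedance exactly as written above, and
the companion nodal-network solver in :mod:`pacinian.oracle` replicates the
same topology as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .layer_parameters import (
    CoreCoefficients,
    CorpuscleDesign,
    LayerCoefficients,
    build_layer_stack,
)

__all__ = [
    "PoleError",
    "TransferModel",
    "ResponseCurve",
    "branch_compliance",
    "core_compliance",
    "layer_compliance",
    "interlayer_transmittance",
    "cascade_transmittance",
    "frequency_response",
    "default_grid",
]


class PoleError(ZeroDivisionError):
    """A compliance denominator is exactly zero at the evaluated frequency."""


@dataclass(frozen=True)
class TransferModel:
    """Immutable ladder network: core plus layers indexed 1..N innermost
    to outermost."""

    layers: tuple
    core: CoreCoefficients

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @classmethod
    def from_design(cls, design: CorpuscleDesign) -> "TransferModel":
        layers, core = build_layer_stack(design)
        return cls(layers=tuple(layers), core=core)


def branch_compliance(coeff: LayerCoefficients, s: complex) -> complex:
    """Kelvin-Voigt-with-mass branch compliance ``1/(M s^2 + B s + K_M)``."""
    den = coeff.M * s * s + coeff.B * s + coeff.K_M
    if den == 0:
        raise PoleError(f"branch pole at s={s}")
    return 1.0 / den


def core_compliance(core: CoreCoefficients, s: complex) -> complex:
    """Core compliance ``G_0 = 1/K_sc + 1/(M_c s^2 + B_sc s + K_Pc)``."""
    den = core.M_c * s * s + core.B_sc * s + core.K_Pc
    if den == 0:
        raise PoleError(f"core branch pole at s={s}")
    return 1.0 / core.K_sc + 1.0 / den


def layer_compliance(model: TransferModel, i: int, s: complex) -> complex:
    """Driving-point compliance ``G_i`` seen at layer ``i`` (``i = 0`` is
    the core), by the outward recursion."""
    if not 0 <= i <= model.n_layers:
        raise IndexError(f"layer index {i} outside 0..{model.n_layers}")
    g = core_compliance(model.core, s)
    for m in range(1, i + 1):
        coeff = model.layers[m - 1]
        inner = branch_compliance(coeff, s) + g
        if inner == 0:
            raise PoleError(f"series-path pole at layer {m}, s={s}")
        g = 1.0 / (coeff.K_L + 1.0 / inner)
    return g


def interlayer_transmittance(model: TransferModel, i: int, s: complex) -> complex:
    """Compression ratio ``X_{i-1}/X_i = G_{i-1} / (G_si + G_{i-1})``.

    Not bounded by 1 in magnitude: near resonances of the inner structure
    the ratio can exceed unity.
    """
    if not 1 <= i <= model.n_layers:
        raise IndexError(f"layer index {i} outside 1..{model.n_layers}")
    g_inner = layer_compliance(model, i - 1, s)
    g_s = branch_compliance(model.layers[i - 1], s)
    den = g_s + g_inner
    if den == 0:
        raise PoleError(f"transmittance pole at layer {i}, s={s}")
    return g_inner / den


def cascade_transmittance(model: TransferModel, s: complex) -> complex:
    """Core-to-outer compression ratio ``X_0/X_N`` as the iterated product
    of interlayer ratios; the empty product (``N = 0``) is exactly 1."""
    g = core_compliance(model.core, s)
    total = 1.0 + 0.0j
    for coeff in model.layers:
        g_s = branch_compliance(coeff, s)
        den = g_s + g
        if den == 0:
            raise PoleError(f"transmittance pole at s={s}")
        total *= g / den
        g = 1.0 / (coeff.K_L + 1.0 / den)
    return total


@dataclass(frozen=True)
class ResponseCurve:
    """Complex transmittance sampled on a monotone frequency grid."""

    frequencies: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        t = np.asarray(self.transmittance, dtype=complex)
        if f.shape != t.shape:
            raise ValueError("frequencies and transmittance must have equal length")
        if f.size and np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "transmittance", t)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.transmittance)

    @property
    def magnitude_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(self.magnitude)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.transmittance))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "re_transmittance": self.transmittance.real,
                "im_transmittance": self.transmittance.imag,
                "magnitude_db": self.magnitude_db,
                "phase_deg": self.phase_deg,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "ResponseCurve":
        df = pd.read_csv(path)
        return cls(
            frequencies=df["frequency_hz"].to_numpy(),
            transmittance=(
                df["re_transmittance"].to_numpy()
                + 1j * df["im_transmittance"].to_numpy()
            ),
        )


#: Log-grid start frequencies are nudged off round numbers so that grid
#: points never coincide with exact (undamped) poles.
_GRID_NUDGE = 1e-4


def default_grid(fmin: float, fmax: float, points: int = 400) -> np.ndarray:
    """Log-spaced frequency grid with an irrational-ratio start offset."""
    if not (fmin > 0 and fmax > fmin and points >= 1):
        raise ValueError("need 0 < fmin < fmax and points >= 1")
    return np.logspace(np.log10(fmin) + _GRID_NUDGE, np.log10(fmax), int(points))


def frequency_response(model: TransferModel, grid: Sequence[float]) -> ResponseCurve:
    """Evaluate the cascade at ``s = j 2 pi f`` for every grid frequency.

    Purely pointwise: refining the grid never changes values at shared
    frequencies.  An exact pole at an isolated grid point is recorded as a
    NaN transmittance rather than raised.
    """
    f = np.asarray(grid, dtype=float)
    if f.size == 0 or np.any(f < 0) or np.any(np.diff(f) <= 0):
        raise ValueError("grid must be non-empty, non-negative, strictly increasing")
    out = np.empty(f.shape, dtype=complex)
    for k, fk in enumerate(f):
        try:
            out[k] = cascade_transmittance(model, 1j * 2.0 * np.pi * fk)
        except PoleError:
            out[k] = np.nan
    return ResponseCurve(frequencies=f, transmittance=out)
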