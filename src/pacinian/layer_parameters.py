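"""Lumped parameters of lamellar layers and the inner core.

The corpuscle is idealised as a cylindrical core wrapped in ``N`` concentric
layers; each layer is one elastic lamella (thickness ``T``) trapping a film
of viscous fluid (gap ``H``) against its inner neighbour.  Geometry and
material properties are condensed into four lumped coefficients per layer:

``K_L``
    lamellar bending/membrane stiffness of the shell, from a simply
    supported cylindrical membrane (Timoshenko beam theory):
    ``K_L = (E_L A T / R) (1 + 4 L^2 / (pi^2 R^2))^2``
``B``
    squeeze-film viscous resistance of the fluid gap (lubrication theory):
    ``B = (12 mu L^2 A / (pi^2 H)) (1 + 4 L^2 / (pi^2 R^2))``
``K_M``
    stiffness of the sparse interlamellar matrix tethering adjacent
    lamellae, a linear elastic film: ``K_M = E_M A / H``
``M``
    mass of the entire layer: thin lamellar shell plus the trapped fluid
    annulus inward of it.

The load area ``A`` is taken as the projected area ``2 R L`` of the cylinder
normal to a diametral load, and ``R`` is the mid-surface radius of the
lamella.  Both are modelling conventions (the source theory leaves them
open) and can be overridden on a per-design basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

__all__ = [
    "MaterialSet",
    "LayerGeometry",
    "CorpuscleDesign",
    "LayerCoefficients",
    "CoreCoefficients",
    "lamellar_stiffness",
    "viscous_resistance",
    "matrix_stiffness",
    "layer_mass",
    "build_layer_stack",
    "CORE_SERIES_STIFFNESS_RATIO",
]

#: Ratio K_sc / K_Pc used by the default core heuristic (stiff series
#: coupling of the core to the innermost fluid branch).
CORE_SERIES_STIFFNESS_RATIO = 10.0


def _require_positive(name: str, value: float, strict: bool = True) -> None:
    if strict and not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value}")
    if not strict and value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class MaterialSet:
    """Material properties shared by the lamellae and trapped fluid.

    Units: moduli in Pa, viscosity in Pa*s, densities in kg/m^3.
    ``matrix_modulus`` may be exactly zero (matrix disabled).
    """

    lamella_modulus: float
    matrix_modulus: float
    fluid_viscosity: float
    lamella_density: float
    fluid_density: float

    def __post_init__(self):
        _require_positive("lamella_modulus", self.lamella_modulus)
        _require_positive("matrix_modulus", self.matrix_modulus, strict=False)
        _require_positive("fluid_viscosity", self.fluid_viscosity)
        _require_positive("lamella_density", self.lamella_density)
        _require_positive("fluid_density", self.fluid_density)


@dataclass(frozen=True)
class LayerGeometry:
    """Geometry of a single layer, strict SI (metres and square metres).

    ``mean_radius`` is the mid-surface radius of the lamella.  ``load_area``
    defaults to the projected-area convention ``2 R L``.
    """

    mean_radius: float
    lamella_thickness: float
    fluid_gap: float
    cylinder_length: float
    load_area: float = None  # type: ignore[assignment]

    def __post_init__(self):
        _require_positive("mean_radius", self.mean_radius)
        # zero thickness = degenerate massless/stiffness-free lamella
        _require_positive("lamella_thickness", self.lamella_thickness, strict=False)
        _require_positive("fluid_gap", self.fluid_gap)
        _require_positive("cylinder_length", self.cylinder_length)
        if self.load_area is None:
            object.__setattr__(
                self, "load_area", 2.0 * self.mean_radius * self.cylinder_length
            )
        _require_positive("load_area", self.load_area)


@dataclass(frozen=True)
class LayerCoefficients:
    """Lumped parameters of one layer (SI: N/m, N*s/m, kg)."""

    K_L: float
    K_M: float
    B: float
    M: float

    def __post_init__(self):
        for name in ("K_L", "K_M", "B", "M"):
            _require_positive(name, getattr(self, name), strict=False)


@dataclass(frozen=True)
class CoreCoefficients:
    """Lumped parameters of the core: series spring ``K_sc`` feeding a
    Kelvin-Voigt branch ``(M_c, B_sc, K_Pc)`` to ground."""

    K_sc: float
    K_Pc: float
    B_sc: float
    M_c: float

    def __post_init__(self):
        for name in ("K_sc", "K_Pc", "B_sc", "M_c"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class CorpuscleDesign:
    """Full geometric and material description of a corpuscle.

    ``lamella_thickness`` and ``fluid_gap`` may be scalars (uniform layers)
    or sequences of length ``n_layers``.  ``core_modulus`` defaults to the
    lamella modulus (one build material); ``core_override`` bypasses the
    core heuristic entirely.
    """

    core_radius: float
    n_layers: int
    lamella_thickness: Union[float, Sequence[float]]
    fluid_gap: Union[float, Sequence[float]]
    length: float
    materials: MaterialSet
    core_modulus: Optional[float] = None
    core_density: Optional[float] = None
    matrix_enabled: bool = True
    core_override: Optional[CoreCoefficients] = None
    name: str = field(default="", compare=False)

    def __post_init__(self):
        _require_positive("core_radius", self.core_radius)
        _require_positive("length", self.length)
        if self.n_layers < 0:
            raise ValueError(f"n_layers must be >= 0, got {self.n_layers}")
        for attr in ("lamella_thickness", "fluid_gap"):
            v = getattr(self, attr)
            if not isinstance(v, (int, float)):
                v = tuple(float(x) for x in v)
                if len(v) != self.n_layers:
                    raise ValueError(
                        f"{attr}: expected {self.n_layers} per-layer values, got {len(v)}"
                    )
                object.__setattr__(self, attr, v)
        if self.core_modulus is not None:
            _require_positive("core_modulus", self.core_modulus)
        if self.core_density is not None:
            _require_positive("core_density", self.core_density)

    def _per_layer(self, attr: str, i: int) -> float:
        v = getattr(self, attr)
        return float(v) if isinstance(v, (int, float)) else v[i - 1]

    def layer_geometry(self, i: int) -> LayerGeometry:
        """Geometry of layer ``i`` (1-based, innermost first).

        Layers tile outward from the core surface; the mid-surface radius is
        ``R_i = R_c + sum_{k<=i}(H_k + T_k) - T_i/2``.
        """
        if not 1 <= i <= self.n_layers:
            raise IndexError(f"layer index {i} outside 1..{self.n_layers}")
        r = self.core_radius
        for k in range(1, i + 1):
            r += self._per_layer("fluid_gap", k) + self._per_layer("lamella_thickness", k)
        r -= self._per_layer("lamella_thickness", i) / 2.0
        return LayerGeometry(
            mean_radius=r,
            lamella_thickness=self._per_layer("lamella_thickness", i),
            fluid_gap=self._per_layer("fluid_gap", i),
            cylinder_length=self.length,
        )


def _curvature_bracket(geom: LayerGeometry) -> float:
    L, R = geom.cylinder_length, geom.mean_radius
    return 1.0 + 4.0 * L**2 / (math.pi**2 * R**2)


def lamellar_stiffness(geom: LayerGeometry, lamella_modulus: float) -> float:
    """Bending/membrane stiffness ``K_L`` of one lamella (N/m equivalent).

    Simply supported cylindrical membrane:
    ``K_L = (E_L A T / R)(1 + 4 L^2/(pi^2 R^2))^2``.
    """
    if lamella_modulus < 0:
        raise ValueError("lamella_modulus must be >= 0")
    return (
        lamella_modulus
        * geom.load_area
        * geom.lamella_thickness
        / geom.mean_radius
        * _curvature_bracket(geom) ** 2
    )


def viscous_resistance(geom: LayerGeometry, fluid_viscosity: float) -> float:
    """Squeeze-film damping ``B`` of the fluid gap.

    Lubrication theory: ``B = (12 mu L^2 A/(pi^2 H))(1 + 4 L^2/(pi^2 R^2))``.
    """
    if fluid_viscosity < 0:
        raise ValueError("fluid_viscosity must be >= 0")
    return (
        12.0
        * fluid_viscosity
        * geom.cylinder_length**2
        * geom.load_area
        / (math.pi**2 * geom.fluid_gap)
        * _curvature_bracket(geom)
    )


def matrix_stiffness(geom: LayerGeometry, matrix_modulus: float) -> float:
    """Interlamellar matrix stiffness ``K_M = E_M A / H`` (linear elastic)."""
    if matrix_modulus < 0:
        raise ValueError("matrix_modulus must be >= 0")
    return matrix_modulus * geom.load_area / geom.fluid_gap


def layer_mass(geom: LayerGeometry, lamella_density: float, fluid_density: float) -> float:
    """Mass of the entire layer: thin lamellar shell plus the fluid annulus
    trapped inward of it, both referenced to the mid-surface radius:
    ``M = rho_s 2 pi R T L + rho_f 2 pi R H L``.

    The thin-shell lamella term is exact at the mid-surface radius; the
    fluid term overestimates the true annulus volume by a relative error of
    about ``(T + H) / (2 R)``.
    """
    if lamella_density < 0 or fluid_density < 0:
        raise ValueError("densities must be >= 0")
    shell = 2.0 * math.pi * geom.mean_radius * geom.cylinder_length
    return shell * (
        lamella_density * geom.lamella_thickness + fluid_density * geom.fluid_gap
    )


def layer_coefficients(geom: LayerGeometry, mat: MaterialSet, matrix_enabled: bool = True) -> LayerCoefficients:
    """All four lumped coefficients of a single layer."""
    e_m = mat.matrix_modulus if matrix_enabled else 0.0
    return LayerCoefficients(
        K_L=lamellar_stiffness(geom, mat.lamella_modulus),
        K_M=matrix_stiffness(geom, e_m),
        B=viscous_resistance(geom, mat.fluid_viscosity),
        M=layer_mass(geom, mat.lamella_density, mat.fluid_density),
    )


def default_core(design: CorpuscleDesign) -> CoreCoefficients:
    """Core heuristic used when no explicit core coefficients are given.

    The core is treated as a homogeneous cylinder of the lamella material:
    ``K_Pc = E_c A_c / R_c`` with ``A_c = 2 R_c L``, a stiff series coupling
    ``K_sc = 10 K_Pc``, squeeze-film damping evaluated with the film height
    set to the core radius, and ``M_c = rho_c pi R_c^2 L``.
    """
    mat = design.materials
    e_c = design.core_modulus if design.core_modulus is not None else mat.lamella_modulus
    rho_c = design.core_density if design.core_density is not None else mat.lamella_density
    geom = LayerGeometry(
        mean_radius=design.core_radius,
        lamella_thickness=design.core_radius,
        fluid_gap=design.core_radius,
        cylinder_length=design.length,
    )
    k_pc = e_c * geom.load_area / design.core_radius
    return CoreCoefficients(
        K_sc=CORE_SERIES_STIFFNESS_RATIO * k_pc,
        K_Pc=k_pc,
        B_sc=viscous_resistance(geom, mat.fluid_viscosity),
        M_c=rho_c * math.pi * design.core_radius**2 * design.length,
    )


def build_layer_stack(design: CorpuscleDesign):
    """Coefficients for every layer (innermost first) plus the core.

    Returns ``(layers, core)`` where ``layers`` is a list of
    ``LayerCoefficients`` of length ``design.n_layers``.  Radii must tile
    strictly outward; the per-layer ``T``/``H`` invariants guarantee this
    for positive values, and the check guards pathological overrides.
    """
    layers = []
    prev_r = design.core_radius
    for i in range(1, design.n_layers + 1):
        geom = design.layer_geometry(i)
        if geom.mean_radius <= prev_r:
            raise ValueError(f"layer {i}: radii must strictly increase outward")
        prev_r = geom.mean_radius
        layers.append(layer_coefficients(geom, design.materials, design.matrix_enabled))
    core = design.core_override if design.core_override is not None else default_core(design)
    return layers, core


def with_materials(design: CorpuscleDesign, **changes) -> CorpuscleDesign:
    """Copy of ``design`` with selected material fields replaced."""
    return replace(design, materials=replace(design.materials, **changes))
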