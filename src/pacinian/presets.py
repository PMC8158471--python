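"""Reference parameter sets: the biological corpuscle and the 3D-printable
artificial design.

Biological ranges (lamella thickness 0.1-0.4 um, interlamellar spacing
1-8 um, 20-60 layers) are collapsed to their midpoints so that the preset
is directly runnable; any value can still be overridden through a design
config.  The biological interlamellar-matrix modulus of 1 Pa follows the
collagen-based parameterisation established for the real cell; the printed
preset keeps the same matrix-to-lamella stiffness contrast (1:1000) since
no separate measurement exists for the printed interlayer tethering.
"""

from __future__ import annotations

from dataclasses import replace

from .layer_parameters import CorpuscleDesign, MaterialSet

__all__ = ["biological", "printed", "get_preset", "PRESET_NAMES"]

PRESET_NAMES = ("biological", "printed")


def biological(n_layers: int = 30) -> CorpuscleDesign:
    """Typical biological corpuscle: kPa-stiff collagenous lamellae, a few
    mPa*s interlamellar fluid, tens of sub-micron layers, 1 mm length."""
    return CorpuscleDesign(
        name="biological",
        core_radius=15e-6,
        n_layers=n_layers,
        lamella_thickness=0.25e-6,
        fluid_gap=4e-6,
        length=1e-3,
        materials=MaterialSet(
            lamella_modulus=1e3,
            matrix_modulus=1.0,
            fluid_viscosity=3e-3,
            lamella_density=1000.0,
            fluid_density=1000.0,
        ),
    )


def printed(n_layers: int = 5) -> CorpuscleDesign:
    """Stereolithography-printable design: cured-resin lamellae (5.5 MPa)
    trapping uncured resin (4.5 Pa*s), mm-scale layers, 2 cm length."""
    if not 1 <= n_layers <= 5:
        raise ValueError("printed design supports 1 to 5 layers")
    return CorpuscleDesign(
        name="printed",
        core_radius=4e-3,
        n_layers=n_layers,
        lamella_thickness=1e-3,
        fluid_gap=2e-3,
        length=2e-2,
        materials=MaterialSet(
            lamella_modulus=5.5e6,
            matrix_modulus=5.5e3,
            fluid_viscosity=4.5,
            lamella_density=1100.0,
            fluid_density=1100.0,
        ),
    )


def get_preset(name: str, n_layers: int = None) -> CorpuscleDesign:
    """Look up a preset by name, optionally with a different layer count."""
    if name == "biological":
        return biological() if n_layers is None else biological(n_layers)
    if name == "printed":
        return printed() if n_layers is None else printed(n_layers)
    raise KeyError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
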