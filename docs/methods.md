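# Methods

## The model

The Pacinian corpuscle is modelled as a one-dimensional ladder of lumped
mechanical elements. A cylindrical core (radius `R_c`, length `L`) is
wrapped in `N` concentric layers; each layer is an elastic lamella of
thickness `T` trapping a film of viscous fluid of height `H` against its
inner neighbour, with sparse elastic tethers (the interlamellar matrix)
bridging the gap. A diametral compression applied to the outermost lamella
is transmitted inward through the fluid films; the question the model
answers is how much of that compression reaches the core, as a function of
stimulus frequency.

Each layer contributes four lumped coefficients:

- lamellar stiffness, simply supported cylindrical membrane
  (Timoshenko beam theory):
  `K_L = (E_L A T / R) (1 + 4L²/(π²R²))²`
- squeeze-film viscous resistance (lubrication theory):
  `B = (12 μ L² A / (π² H)) (1 + 4L²/(π²R²))`
- interlamellar matrix stiffness (linear elastic film): `K_M = E_M A / H`
- layer mass `M = ρ_s 2πRTL + ρ_f 2πRHL` (lamellar shell plus the fluid
  annulus trapped inward of it).

`R` is the mid-surface radius of the lamella; layers tile outward as
`R_i = R_{i−1} + T/2 + H + T/2`. The load area is the projected area
`A = 2RL` of the cylinder normal to a diametral load; it is a modelling
convention and can be overridden per design.

These coefficient laws are used verbatim from the lumped
corpuscle-modelling tradition this package implements. Two caveats are
worth stating plainly. First, their unit balance is unconventional — the
damping law scales as `1/H` where textbook squeeze-film lubrication gives
`1/H³` — and this package deliberately does not "repair" them: the
companion network validator checks the implementation of this algebra, not
an independent physical derivation. Second, a consequence of the `1/H`
damping at millimetre and micron gap heights is that the ladder is
strongly underdamped: the frequency response carries narrow, tall
resonance spikes, the corner of the printable design is set mainly by
layer inertia, and fluid viscosity shifts the corner only minutely
(monotonically, but by parts in 10⁷ per decade of viscosity). The
analysis layer is designed around this (see "Extraction" below).

### The compliance cascade

With `s = j2πf`, each layer's Kelvin–Voigt-with-mass branch has compliance
`G_si = 1/(M s² + B s + K_M)`, and the driving-point compliance of the
structure seen at layer `i` follows the outward recursion

    G_i = 1 / (K_Li + 1/(G_si + G_{i−1})),
    G_0 = 1/K_sc + 1/(M_c s² + B_sc s + K_Pc),

i.e. the lamellar spring acts in parallel (stiffnesses add) and the core's
series spring in series (compliances add). The compression transmittance
from the outermost layer to the core is the product of interlayer ratios

    X_0/X_N = Π_{m=1..N} G_{m−1} / (G_{m−1} + G_sm),

with the empty product equal to 1. Evaluation is restricted to the
imaginary axis (steady sinusoidal stimulation); exact poles raise a typed
`PoleError` (a lone pole on a grid is recorded as a missing point), and
default grids start at a slightly irrational offset so log-spaced points
never sit exactly on undamped poles.

### The core heuristic

The core's four coefficients have no published closed form in this model
family. When no `core_override` is supplied, the package treats the core
as a homogeneous cylinder of the lamella material: `K_Pc = E_c A_c/R_c`
with `A_c = 2R_cL`, a stiff series coupling `K_sc = 10 K_Pc`, squeeze-film
damping evaluated with the film height set to `R_c`, and
`M_c = ρ_c πR_c² L`. For the 5-layer printable preset this places the
first resonance of the core/inner-layer mass chain at about 1.65 kHz.
Physical artificial corpuscles of this design have been reported to show
their core mass resonance at 5–7 kHz, which would require an effective
core-path stiffness about seven times stiffer than the homogeneous-resin
heuristic provides; since no principled derivation of such a stiffness is
available, the heuristic is kept honest and the discrepancy documented
rather than fitted away. Users with measured or independently derived
core coefficients should pass them through `core_override`.

## Presets

Two reference designs ship with the package (strict SI internally; configs
accept unit strings like `"5.5 MPa"`, `"2 cm"`):

| parameter           | biological | printed |
|---------------------|-----------:|--------:|
| lamella modulus     | 1 kPa      | 5.5 MPa |
| fluid viscosity     | 3 mPa·s    | 4.5 Pa·s|
| lamella thickness   | 0.25 µm    | 1 mm    |
| fluid gap           | 4 µm       | 2 mm    |
| core radius         | 15 µm      | 4 mm    |
| length              | 1 mm       | 2 cm    |
| layers              | 30         | 1–5     |
| matrix modulus      | 1 Pa       | 5.5 kPa |
| densities           | 1000 kg/m³ | 1100 kg/m³ |

Biological ranges (0.1–0.4 µm thickness, 1–8 µm spacing, 20–60 layers) are
collapsed to midpoints for a runnable default. The biological matrix
modulus of 1 Pa follows the collagen-based parameterisation of the real
cell; the printed design has no measured matrix modulus, so it keeps the
same 1:1000 matrix-to-lamella contrast. The core modulus defaults to the
lamella modulus (a single build material), and the printed densities are
those of cured/uncured stereolithography resin.

## Extraction

Because the underdamped ladder decorates its smooth broadband response
with narrow cancellation spikes (30–50 dB, often only one or two grid
points wide, with multi-dB skirts), all level-based summaries operate on a
*backbone*: a running median of `magnitude_db` over a quarter-decade
window, which tracks every broadband feature but is insensitive to narrow
spikes wherever they fall.

- **Plateau**: maximum of the backbone over the evaluated band.
- **3 dB corner**: lowest frequency at which the backbone first comes
  within 3 dB of the plateau, interpolated linearly in log-frequency.
  On an analytic one-pole high-pass sampled at 400 points over three
  decades this recovers the true corner to 0.03%; doubling grid density
  moves the printed-design corner by under 1%.
- **Resonance**: first strict local maximum of the *raw* magnitude with at
  least 0.5 dB prominence above the corner (`None` for monotone curves).
  Broad damped-oscillator peaks are located within one grid step of the
  closed-form `√(K/M − B²/2M²)/2π`.
- **Static transmittance**: closed-form spring-only ladder at `s = 0`;
  exactly zero when any layer's matrix is disabled (no static load path).

Default response grids are 400 log-spaced points, 1 Hz–10 kHz for the
printed preset and 0.1 Hz–10 kHz for the biological one. Parametric
sweeps extend the band so the corner stays measurable: to 30 kHz for the
printed design and 300 kHz for the biological preset (whose corner under
this coefficient family sits near 90 kHz — far above the real cell's
physiological tuning, a direct consequence of the underdamped coefficient
laws noted above). Modulus sweeps rescale the grid per value by
`√(E/E_base)`: a uniform stiffness rescaling shifts the whole response by
exactly that frequency factor, so the scaled grid keeps constant relative
resolution without moving the corner out of band.

## Validation

The central correctness property is that the O(N) compliance recursion
equals a dense solve of the full nodal dynamic-stiffness system assembled
from the same topology (grounded lamellar springs, interlayer
Kelvin–Voigt-with-mass branches, core series spring and grounded core
branch). The validator prescribes unit displacement at the outer node and
solves for the core displacement, with one step of iterative refinement.
Randomized ladders for this check are drawn log-uniformly over a few
decades around the printed-design scale: the equivalence is algebraically
exact, and keeping the draw conditioning bounded lets double precision
resolve it to ~1e-11 instead of drowning it in round-off. The static
spring ladder is cross-checked against the network solve at `s = 0`, and
the transmittance is verified invariant under uniform rescaling of all
coefficients.

## Synthetic measurements

`synth_measurement` emulates a shaker-table read-out for testing the
corner extractor: multiplicative lognormal amplitude noise, inflation of
the grid points nearest each 60 Hz mains harmonic, and the one-pole 7 Hz
high-pass of a charge-amplifier chain, all deterministic per seed. It
models amplitude corruption only — no phase noise, no frequency-dependent
sensor calibration error, no drift between sweeps — so extractor-recovery
results bound robustness to amplitude artefacts, not to every failure mode
of a physical rig. Under its default settings (σ = 0.1 lognormal,
50% mains inflation) the median corner recovered over 100 seeds stays
within 1% of the clean-curve corner.

## Known limitations

- Small displacements only: no lamella–lamella contact, no nonlinear or
  anisotropic materials, no temperature dependence.
- No time-domain simulation; the evaluation contour is `s = j2πf`.
- The in-branch mass convention is taken from the model family as-is; a
  Newtonian nodal-inertia formulation could differ above the core
  resonance.
- The core heuristic and load-area convention are explicit assumptions
  isolated behind overridable fields; conclusions that depend on absolute
  core resonance placement should use measured core coefficients.
- Mechanotransduction (ion channels, spiking) and fabrication are out of
  scope: the model ends at mechanical compression of the core.
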