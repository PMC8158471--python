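"""Independent brute-force validation of the compliance cascade.

The recursion in :mod:`pacinian.transfer_model` is an O(N) elimination of
the ladder network.  This module assembles the same network as an explicit
nodal dynamic-stiffness system and solves it with a dense linear solve; the
two routes must agree to near machine precision.  The network deliberately
mirrors the in-branch mass convention of the cascade equations — it
validates the implementation of that algebra, not an independent physical
derivation.

Topology (node ``N`` is driven with unit displacement):

* every layer node ``i`` carries a grounded lamellar spring ``K_Li``;
* adjacent nodes ``i`` and ``i-1`` are linked by the branch impedance
  ``k_i(s) = M_i s^2 + B_i s + K_Mi``;
* the core node ``0`` connects through the series spring ``K_sc`` to an
  internal node ``c`` grounded through ``M_c s^2 + B_sc s + K_Pc``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layer_parameters import CoreCoefficients, LayerCoefficients
from .transfer_model import PoleError, TransferModel, cascade_transmittance

__all__ = [
    "NetworkSystem",
    "full_dynamic_stiffness",
    "assemble_network",
    "driving_point_compliance",
    "solve_network",
    "static_spring_ladder",
    "random_model",
    "equivalence_suite",
]


@dataclass(frozen=True)
class NetworkSystem:
    """Constrained dynamic-stiffness system ``K x = b`` with unknowns
    ordered ``[x_c, x_0, x_1, ..., x_{N-1}]`` and ``x_N = 1`` prescribed."""

    matrix: np.ndarray
    rhs: np.ndarray

    @property
    def n_unknowns(self) -> int:
        return self.matrix.shape[0]


def _branch_impedance(c, s: complex) -> complex:
    return c.M * s * s + c.B * s + c.K_M


def full_dynamic_stiffness(model: TransferModel, s: complex) -> np.ndarray:
    """Unconstrained symmetric dynamic-stiffness matrix over the nodes
    ``[c, 0, 1, ..., N]``."""
    n = model.n_layers
    core = model.core
    size = n + 2

    def idx(node):  # node "c" -> 0, node i -> i + 1
        return 0 if node == "c" else node + 1

    K = np.zeros((size, size), dtype=complex)
    kv = core.M_c * s * s + core.B_sc * s + core.K_Pc
    K[idx("c"), idx("c")] += kv + core.K_sc
    K[idx("c"), idx(0)] -= core.K_sc
    K[idx(0), idx("c")] -= core.K_sc
    K[idx(0), idx(0)] += core.K_sc
    for i in range(1, n + 1):
        k_i = _branch_impedance(model.layers[i - 1], s)
        K[idx(i - 1), idx(i - 1)] += k_i
        K[idx(i - 1), idx(i)] -= k_i
        K[idx(i), idx(i - 1)] -= k_i
        K[idx(i), idx(i)] += k_i
        K[idx(i), idx(i)] += model.layers[i - 1].K_L
    return K


def assemble_network(model: TransferModel, s: complex) -> NetworkSystem:
    """Constrained nodal system at complex frequency ``s``: prescribing
    ``x_N = 1`` drops the last row and moves its column to the RHS."""
    K = full_dynamic_stiffness(model, s)
    return NetworkSystem(matrix=K[:-1, :-1], rhs=-K[:-1, -1])


def driving_point_compliance(model: TransferModel, s: complex) -> complex:
    """Compliance ``x_N / F_N`` at the outermost node from the full matrix
    solve; the brute-force counterpart of the compliance recursion."""
    K = full_dynamic_stiffness(model, s)
    b = np.zeros(K.shape[0], dtype=complex)
    b[-1] = 1.0
    return complex(_refined_solve(K, b, s)[-1])


def _refined_solve(K: np.ndarray, b: np.ndarray, s: complex) -> np.ndarray:
    """Dense solve with one step of iterative refinement.

    Coefficient magnitudes in a ladder can span many orders, so a plain
    LU solve may lose a digit or two to conditioning; a single residual
    correction restores it at negligible cost.
    """
    try:
        x = np.linalg.solve(K, b)
        x += np.linalg.solve(K, b - K @ x)
    except np.linalg.LinAlgError as exc:
        raise PoleError(f"singular network at s={s}") from exc
    return x


def solve_network(model: TransferModel, s: complex) -> complex:
    """Displacement ratio ``X_0 / X_N`` from the full nodal solve
    (ground truth for :func:`cascade_transmittance`)."""
    if model.n_layers == 0:
        return 1.0 + 0.0j
    system = assemble_network(model, s)
    x = _refined_solve(system.matrix, system.rhs, s)
    return complex(x[1])  # node 0


def static_spring_ladder(model: TransferModel) -> float:
    """Closed-form ``s = 0`` transmittance of the spring-only ladder,
    eliminated from the core outward; exactly 0 if any ``K_M`` vanishes."""
    core = model.core
    g = 1.0 / core.K_sc + 1.0 / core.K_Pc
    total = 1.0
    for coeff in model.layers:
        if coeff.K_M == 0.0:
            return 0.0
        den = 1.0 / coeff.K_M + g
        total *= g / den
        g = 1.0 / (coeff.K_L + 1.0 / den)
    return total


def random_model(rng: np.random.Generator, max_layers: int = 6) -> TransferModel:
    """Random valid ladder for the equivalence suite.

    Coefficients are drawn log-uniformly over a few decades around the
    printed-design scale.  The spread is deliberately kept moderate: the
    recursion/solve equivalence is algebraically exact, and bounded
    conditioning lets float64 resolve it to well below 1e-9 instead of
    drowning it in round-off.
    """
    n = int(rng.integers(0, max_layers + 1))

    def lu(lo, hi):
        return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))

    layers = [
        LayerCoefficients(
            K_L=lu(1e1, 1e5), K_M=lu(1e0, 1e4), B=lu(1e-4, 1e0), M=lu(1e-5, 1e-2)
        )
        for _ in range(n)
    ]
    core = CoreCoefficients(
        K_sc=lu(1e2, 1e7), K_Pc=lu(1e2, 1e6), B_sc=lu(1e-4, 1e0), M_c=lu(1e-5, 1e-2)
    )
    return TransferModel(layers=tuple(layers), core=core)


def equivalence_suite(
    trials: int = 50,
    frequencies_per_trial: int = 10,
    seed: int = 0,
    max_layers: int = 6,
) -> float:
    """Max relative error between the recursion and the nodal solve over
    randomized models and frequencies.  The central correctness property of
    the repository: errors above ~1e-9 indicate an implementation defect."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(trials):
        model = random_model(rng, max_layers=max_layers)
        for _ in range(frequencies_per_trial):
            f = 10.0 ** rng.uniform(0.0, 4.0)
            s = 1j * 2.0 * np.pi * f
            a = cascade_transmittance(model, s)
            b = solve_network(model, s)
            scale = max(abs(a), abs(b), 1e-300)
            worst = max(worst, abs(a - b) / scale)
    return worst
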