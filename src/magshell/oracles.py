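"""Independent verification paths for the harmonic solution.

Three cross-checks, none of which shares matrix-assembly code with
:mod:`magshell.solver`:

* :func:`transfer_matrix_solution` re-derives the eight coefficients by an
  impedance-ladder recursion: the (growing, decaying) amplitude pair is
  propagated region by region across each interface with closed-form 2x2
  continuity maps.  The propagation is *two-sided* -- outward from the
  organelle interior and inward from the far field, matched in the cytoplasm
  by a 2x2 solve -- because a one-directional ladder loses roughly seven
  significant digits crossing both near-insulating membranes, while each
  one-membrane half-ladder stays accurate to ~1e-9 relative.

* :func:`check_residuals` substitutes any solution back into the eight
  continuity equations and reports normalised residuals.

* :func:`schwan_limit` is the classical first-order shelled-sphere
  (single-shell) closed form, an asymptotic low-frequency check for the
  organelle-free cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import MagneticStimulus, TwoShellCell
from .solver import ForcingField, HarmonicSolution, assemble_boundary_system

__all__ = [
    "ResidualReport",
    "INTERFACE_NAMES",
    "transfer_matrix_solution",
    "check_residuals",
    "schwan_limit",
]

INTERFACE_NAMES: tuple[str, ...] = (
    "cell_outer",       # R+  (regions 0|1)
    "cell_inner",       # R-  (regions 1|2)
    "organelle_outer",  # r+  (regions 2|3)
    "organelle_inner",  # r-  (regions 3|4)
)

_ABS_FLOOR = 1e-30  # SI floor for residual normalisation


# ---------------------------------------------------------------------------
# Transfer-matrix (impedance-ladder) oracle
# ---------------------------------------------------------------------------

def _cross(c: complex, d: complex, x: float, S_from: complex, S_to: complex,
           forced: bool) -> tuple[complex, complex]:
    """Map the amplitude pair across one interface at nondimensional radius x.

    Continuity of the potential gives P = c*x + d/x^2 on both sides;
    continuity of the normal current (applied radial field -E0 sin cos,
    normalised by E0*R+) gives W_to = (S_from/S_to)*(W_from - 1) + 1 with
    W = -c + 2d/x^3.  Solving the pair for the target region:
    c_to = (2P/x - W_to)/3, d_to = x^3 (P/x + W_to)/3.  The ``forced`` flag
    drops the inhomogeneous term so the same map can propagate the
    homogeneous solution of the affine recursion.
    """
    P = c * x + d / x**2
    W = -c + 2.0 * d / x**3
    if forced:
        W_to = (S_from / S_to) * (W - 1.0) + 1.0
    else:
        W_to = (S_from / S_to) * W
    return (2.0 * P / x - W_to) / 3.0, x**3 * (P / x + W_to) / 3.0


def transfer_matrix_solution(
    cell: TwoShellCell, stimulus: MagneticStimulus
) -> HarmonicSolution:
    """Solve the degree-1 problem by a two-sided impedance ladder.

    Algorithmically independent of :func:`magshell.solver.solve`: no 8x8
    system is assembled.  The inner unknown is the growing amplitude c4 of
    the organelle interior, the outer unknown the decaying amplitude d0 of
    the extracellular scattered potential; each half-ladder is affine in its
    unknown, and the two are fixed by matching the cytoplasm amplitude pair.
    """
    forcing = ForcingField.from_stimulus(stimulus)
    omega = stimulus.omega
    if omega == 0.0 or forcing.E0 == 0:
        return HarmonicSolution(
            coefficients=np.zeros(8, dtype=complex),
            forcing=forcing,
            cell=cell,
            omega=omega,
        )

    S = cell.complex_conductivities(omega)
    Rp = cell.cell_shell.outer_radius
    xRp, xRm, xrp, xrm = (rad / Rp for rad in cell.interface_radii)
    if any(abs(s) == 0.0 for s in S):
        raise np.linalg.LinAlgError("zero complex conductivity: singular ladder")

    def inner_side(c4: complex, forced: bool):
        """Region 4 -> 3 -> 2; returns cytoplasm pair and membrane pair."""
        c3, d3 = _cross(c4, 0j, xrm, S[4], S[3], forced)
        c2, d2 = _cross(c3, d3, xrp, S[3], S[2], forced)
        return np.array([c2, d2]), (c3, d3)

    def outer_side(d0: complex, forced: bool):
        """Region 0 -> 1 -> 2; returns cytoplasm pair and membrane pair."""
        c1, d1 = _cross(0j, d0, xRp, S[0], S[1], forced)
        c2, d2 = _cross(c1, d1, xRm, S[1], S[2], forced)
        return np.array([c2, d2]), (c1, d1)

    u_in, _ = inner_side(1.0 + 0j, forced=False)
    w_in, _ = inner_side(0j, forced=True)
    u_out, _ = outer_side(1.0 + 0j, forced=False)
    w_out, _ = outer_side(0j, forced=True)

    # Match c4*u_in + w_in = d0*u_out + w_out in the cytoplasm.
    M = np.array([[u_in[0], -u_out[0]], [u_in[1], -u_out[1]]], dtype=complex)
    c4, d0 = np.linalg.solve(M, w_out - w_in)

    cyto_in, (c3, d3) = inner_side(c4, forced=True)
    cyto_out, (c1, d1) = outer_side(d0, forced=True)
    c2, d2 = (cyto_in + cyto_out) / 2.0  # the two sides agree to solve precision

    scale = forcing.E0 * Rp  # ladder works in E0*R+ units
    coeff = np.array([d0, c1, d1, c2, d2, c3, d3, c4], dtype=complex) * scale
    return HarmonicSolution(coefficients=coeff, forcing=forcing, cell=cell, omega=omega)


# ---------------------------------------------------------------------------
# Residual checking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualReport:
    """Normalised residuals of the eight continuity equations.

    Each residual is |lhs - rhs| / max(|lhs|, |rhs|, floor): relative where
    the quantities are appreciable, absolute (against a 1e-30 SI floor) where
    both sides vanish.
    """

    potential_residuals: dict[str, float]
    current_residuals: dict[str, float]
    condition_estimate: float
    max_residual: float = field(init=False)

    def __post_init__(self) -> None:
        worst = max(
            [*self.potential_residuals.values(), *self.current_residuals.values()],
            default=0.0,
        )
        object.__setattr__(self, "max_residual", worst)

    def to_dict(self) -> dict:
        return {
            "potential_residuals": dict(self.potential_residuals),
            "current_residuals": dict(self.current_residuals),
            "max_residual": self.max_residual,
            "condition_estimate": self.condition_estimate,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _rel(lhs: complex, rhs: complex) -> float:
    return float(abs(lhs - rhs) / max(abs(lhs), abs(rhs), _ABS_FLOOR))


def check_residuals(solution: HarmonicSolution) -> ResidualReport:
    """Substitute a solution into all eight boundary equations.

    The continuity expressions are evaluated directly from the region
    coefficients (not through the assembled matrix), so this is a genuine
    back-substitution check for either solver route.
    """
    cell = solution.cell
    omega = solution.omega
    S = cell.complex_conductivities(omega)
    Rp = cell.cell_shell.outer_radius
    xs = [rad / Rp for rad in cell.interface_radii]
    E0Rp = solution.forcing.E0 * Rp

    pot: dict[str, float] = {}
    cur: dict[str, float] = {}
    for name, x, (out_r, in_r) in zip(
        INTERFACE_NAMES, xs, ((0, 1), (1, 2), (2, 3), (3, 4))
    ):
        co, do = solution.region_coefficients(out_r)
        ci, di = solution.region_coefficients(in_r)
        pot[name] = _rel(co * x + do / x**2, ci * x + di / x**2)
        # normal current ~ S * (-dV/dr - j omega A_r); in E0*R+ scaling the
        # applied radial term is -E0*R+ on both sides.
        j_out = S[out_r] * (-co + 2.0 * do / x**3 - E0Rp)
        j_in = S[in_r] * (-ci + 2.0 * di / x**3 - E0Rp)
        cur[name] = _rel(j_out, j_in)

    if omega > 0.0 and solution.forcing.E0 != 0:
        M, _ = assemble_boundary_system(cell, omega, solution.forcing)
        cond = float(np.linalg.cond(M))
    else:
        cond = 1.0
    return ResidualReport(pot, cur, cond)


# ---------------------------------------------------------------------------
# Closed-form single-shell (Schwan) limit
# ---------------------------------------------------------------------------

def schwan_limit(cell: TwoShellCell, stimulus: MagneticStimulus) -> complex:
    """First-order shelled-sphere limit of the cell transmembrane phasor.

    For a single thin, poorly conducting membrane the maximal transmembrane
    potential approaches ``1.5 * E0 * R+ / (1 + j omega tau)`` with membrane
    charging time ``tau = R+ * (epsilon_1 / D) * (1/sigma_2 + 1/(2 sigma_0))``
    built from the membrane capacitance per unit area and the cytoplasmic and
    extracellular resistivities.  The phase is -90° (induction) minus
    arctan(omega tau) (membrane charging).

    This is an asymptotic check for the organelle-free cell only; the
    organelle regions of ``cell`` are ignored.
    """
    forcing = ForcingField.from_stimulus(stimulus)
    Rp = cell.cell_shell.outer_radius
    c_m = cell.media[1].permittivity / cell.cell_shell.thickness  # F/m^2
    sigma_cyto = cell.media[2].conductivity
    sigma_ext = cell.media[0].conductivity
    if sigma_cyto <= 0.0 or sigma_ext <= 0.0:
        raise ValueError("Schwan limit requires conducting cytoplasm and exterior")
    tau = Rp * c_m * (1.0 / sigma_cyto + 1.0 / (2.0 * sigma_ext))
    return 1.5 * forcing.E0 * Rp / (1.0 + 1j * stimulus.omega * tau)


def schwan_time_constant(cell: TwoShellCell) -> float:
    """Membrane charging time constant tau (seconds) used by :func:`schwan_limit`."""
    Rp = cell.cell_shell.outer_radius
    c_m = cell.media[1].permittivity / cell.cell_shell.thickness
    return Rp * c_m * (
        1.0 / cell.media[2].conductivity + 1.0 / (2.0 * cell.media[0].conductivity)
    )
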