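"""Quasi-static boundary-value solver for the degree-1 harmonic.

Physics
-------
A sinusoidal magnetic field ``B = B0 e^{j omega t} z'`` (time convention
``e^{+j omega t}``) induces an electric field ``E = -j omega A - grad V``,
where ``A`` is the coil's magnetic vector potential and the scalar potential
``V`` accounts for charge accumulating at the dielectric interfaces.  In each
homogeneous region ``V`` satisfies Laplace's equation.  For a cell whose
centre sits a distance ``C`` off the coil axis, the part of ``A`` that is
uniform over the cell has radial component proportional to
``sin(theta) cos(phi)``; it is the only forcing with a nonzero normal
component on the spherical interfaces, so only the degree-1, order-1
spherical harmonic is excited and

    V_n(r, theta, phi) = (c_n * (r/R+) + d_n * (R+/r)^2) * sin(theta) cos(phi)

in region ``n``, with ``c_0 = 0`` (the far field is unperturbed) and
``d_4 = 0`` (the potential is finite at the origin).  The eight remaining
complex coefficients follow from continuity of ``V`` and of the normal
current density ``S_n * E_r`` across the four interfaces, with
``S_n = sigma_n + j omega epsilon_n``.

Conventions
-----------
The uniform induced-field amplitude is ``E0 = -j omega B0 C / 2``
(so ``|E0| = omega B0 C / 2`` and ``arg E0 = -90°``: pure Faraday lag).
The azimuth origin of the reporting frame is placed at the depolarised
equatorial lobe of the membranes, which corresponds to an applied radial
field ``-E0 sin(theta) cos(phi)``; the choice is a pure rotation set by
where the cell sits around the coil axis, and it makes the phase of the
transmembrane phasor directly comparable with the phase of ``B``
(a low-frequency cell membrane reads close to -90°).

Transmembrane potentials are defined outer-minus-inner:
``psi = V(outer surface) - V(inner surface)``.  Both are proportional to
``sin(theta) cos(phi)``; the factor in front is the *amplitude coefficient*,
whose modulus is the maximal polarisation over the sphere and whose argument
is the reported phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import MagneticStimulus, TwoShellCell

__all__ = [
    "ForcingField",
    "HarmonicSolution",
    "TransmembranePotential",
    "IllConditionedSystemWarning",
    "COEFFICIENT_NAMES",
    "CONDITION_WARNING_THRESHOLD",
    "assemble_boundary_system",
    "solve",
    "potential_at",
    "transmembrane_cell",
    "transmembrane_organelle",
    "cell_potential",
    "organelle_potential",
    "amplitude_and_phase",
]

#: Order of the solved coefficient vector: the decaying amplitude of region 0,
#: then growing/decaying pairs of regions 1-3, then the growing amplitude of
#: region 4.  All in volts (the radial profile uses the nondimensional radius
#: x = r / R+).
COEFFICIENT_NAMES: tuple[str, ...] = ("D0", "C1", "D1", "C2", "D2", "C3", "D3", "C4")

CONDITION_WARNING_THRESHOLD = 1e12


class IllConditionedSystemWarning(UserWarning):
    """The assembled boundary system is close to singular."""


@dataclass(frozen=True)
class ForcingField:
    """Complex amplitude of the uniform induced field at the cell centre."""

    E0: complex

    @classmethod
    def from_stimulus(cls, stimulus: MagneticStimulus) -> "ForcingField":
        omega = stimulus.omega
        return cls(E0=-1j * omega * stimulus.B0 * stimulus.axis_offset / 2.0)

    @property
    def magnitude(self) -> float:
        return abs(self.E0)


def assemble_boundary_system(
    cell: TwoShellCell, omega: float, forcing: ForcingField
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the 8x8 complex boundary system ``M u = b``.

    Unknowns are ordered per :data:`COEFFICIENT_NAMES`.  Rows 0-3 impose
    continuity of the potential at the four interfaces (R+, R-, r+, r-,
    outermost first); rows 4-7 impose continuity of the normal current
    density ``S * (-dV/dr - j omega A_r)`` there.  The coil's vector
    potential is itself continuous, so the forcing appears only through the
    jump in complex conductivity and the right-hand side is proportional to
    ``forcing.E0``.

    Radii are nondimensionalised by the cell outer radius and the current
    rows are scaled by the larger adjacent admittance, which keeps the
    condition number of the system modest (~1e5 at standard parameters)
    despite membrane/bulk conductivity ratios of 1e6 and more.

    A condition-number estimate above ``CONDITION_WARNING_THRESHOLD`` emits
    :class:`IllConditionedSystemWarning`; an exactly singular system
    surfaces as ``numpy.linalg.LinAlgError`` from the solve.
    """
    S = cell.complex_conductivities(omega)
    Rp = cell.cell_shell.outer_radius
    x = np.array(cell.interface_radii) / Rp  # (x_R+, x_R-, x_r+, x_r-)
    E0Rp = forcing.E0 * Rp

    M = np.zeros((8, 8), dtype=complex)
    b = np.zeros(8, dtype=complex)

    # Potential continuity; region pairs (outer, inner) at each interface are
    # (0,1), (1,2), (2,3), (3,4).  Column layout: [d0, c1, d1, c2, d2, c3, d3, c4].
    M[0, 0] = 1.0 / x[0] ** 2
    M[0, 1] = -x[0]
    M[0, 2] = -1.0 / x[0] ** 2

    M[1, 1] = x[1]
    M[1, 2] = 1.0 / x[1] ** 2
    M[1, 3] = -x[1]
    M[1, 4] = -1.0 / x[1] ** 2

    M[2, 3] = x[2]
    M[2, 4] = 1.0 / x[2] ** 2
    M[2, 5] = -x[2]
    M[2, 6] = -1.0 / x[2] ** 2

    M[3, 5] = x[3]
    M[3, 6] = 1.0 / x[3] ** 2
    M[3, 7] = -x[3]

    # Current continuity: S_out*(-c_out + 2 d_out/x^3) - S_in*(-c_in + 2 d_in/x^3)
    #                     = (S_out - S_in) * E0 * R+   (applied field -E0 sin cos)
    M[4, 0] = S[0] * 2.0 / x[0] ** 3
    M[4, 1] = S[1]
    M[4, 2] = -S[1] * 2.0 / x[0] ** 3
    b[4] = (S[0] - S[1]) * E0Rp

    M[5, 1] = -S[1]
    M[5, 2] = S[1] * 2.0 / x[1] ** 3
    M[5, 3] = S[2]
    M[5, 4] = -S[2] * 2.0 / x[1] ** 3
    b[5] = (S[1] - S[2]) * E0Rp

    M[6, 3] = -S[2]
    M[6, 4] = S[2] * 2.0 / x[2] ** 3
    M[6, 5] = S[3]
    M[6, 6] = -S[3] * 2.0 / x[2] ** 3
    b[6] = (S[2] - S[3]) * E0Rp

    M[7, 5] = -S[3]
    M[7, 6] = S[3] * 2.0 / x[3] ** 3
    M[7, 7] = S[4]
    b[7] = (S[3] - S[4]) * E0Rp

    for i, (p, q) in enumerate(((0, 1), (1, 2), (2, 3), (3, 4))):
        s = max(abs(S[p]), abs(S[q]))
        if s > 0.0:
            M[4 + i] /= s
            b[4 + i] /= s

    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > CONDITION_WARNING_THRESHOLD:
        warnings.warn(
            f"boundary system condition estimate {cond:.3e} exceeds "
            f"{CONDITION_WARNING_THRESHOLD:.0e}",
            IllConditionedSystemWarning,
            stacklevel=2,
        )
    return M, b


@dataclass(frozen=True)
class HarmonicSolution:
    """The eight solved coefficients defining V in all five regions.

    ``coefficients`` follows :data:`COEFFICIENT_NAMES` and is expressed in
    volts against the nondimensional radius ``x = r / R+``.
    """

    coefficients: np.ndarray
    forcing: ForcingField
    cell: TwoShellCell
    omega: float

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=complex)
        if coeff.shape != (8,):
            raise ValueError(f"expected 8 coefficients, got shape {coeff.shape}")
        if not np.all(np.isfinite(coeff)):
            raise ValueError("coefficients must all be finite")
        object.__setattr__(self, "coefficients", coeff)

    def region_coefficients(self, region: int) -> tuple[complex, complex]:
        """Growing/decaying pair ``(c_n, d_n)`` of a region, with the
        regularity zeros of regions 0 and 4 filled in."""
        d0, c1, d1, c2, d2, c3, d3, c4 = self.coefficients
        pairs = ((0j, d0), (c1, d1), (c2, d2), (c3, d3), (c4, 0j))
        return pairs[region]


def solve(cell: TwoShellCell, stimulus: MagneticStimulus) -> HarmonicSolution:
    """Solve the boundary system for a cell under a stimulus.

    The solution is linear in ``B0`` and in the coil-axis offset ``C``.
    A zero-frequency stimulus induces nothing (no Faraday induction) and
    short-circuits to the all-zero solution.
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
    M, b = assemble_boundary_system(cell, omega, forcing)
    coeff = np.linalg.solve(M, b)  # LinAlgError propagates on singularity
    return HarmonicSolution(coefficients=coeff, forcing=forcing, cell=cell, omega=omega)


def potential_at(
    solution: HarmonicSolution, r: float, theta: float, phi: float
) -> complex:
    """Complex scalar potential ``V`` (volts) at spherical point (r, theta, phi).

    Angles in radians.  The degree-1 harmonic vanishes at the origin, and the
    solution is continuous across every interface.
    """
    if r < 0.0:
        raise ValueError(f"radius must be >= 0, got {r!r}")
    if r == 0.0:
        return 0j
    region = solution.cell.region_of(r)
    c, d = solution.region_coefficients(region)
    x = r / solution.cell.cell_shell.outer_radius
    return (c * x + d / x**2) * math.sin(theta) * math.cos(phi)


def _membrane_coefficient(
    solution: HarmonicSolution, region: int, outer_x: float, inner_x: float
) -> complex:
    """Amplitude coefficient of V(outer) - V(inner) across one thin membrane.

    Evaluated from the membrane region's own coefficients with the small
    radius difference factored out, so no precision is lost to subtractive
    cancellation when the shell is thin.
    """
    c, d = solution.region_coefficients(region)
    dx = outer_x - inner_x
    # c*(xo - xi) + d*(1/xo^2 - 1/xi^2); the second bracket equals
    # -(xo - xi)(xo + xi)/(xo^2 xi^2).
    return c * dx - d * dx * (outer_x + inner_x) / (outer_x**2 * inner_x**2)


def _cell_coefficient(solution: HarmonicSolution) -> complex:
    Rp = solution.cell.cell_shell.outer_radius
    xo, xi = 1.0, solution.cell.cell_shell.inner_radius / Rp
    return _membrane_coefficient(solution, 1, xo, xi)


def _organelle_coefficient(solution: HarmonicSolution) -> complex:
    Rp = solution.cell.cell_shell.outer_radius
    xo = solution.cell.organelle_shell.outer_radius / Rp
    xi = solution.cell.organelle_shell.inner_radius / Rp
    return _membrane_coefficient(solution, 3, xo, xi)


@dataclass(frozen=True)
class TransmembranePotential:
    """Complex transmembrane potential of one membrane.

    ``psi(theta, phi) = amplitude_coefficient * sin(theta) cos(phi)``; the
    coefficient's modulus is the maximal polarisation over the sphere (the
    membrane is not polarised at the poles) and its argument is the phase
    relative to the applied magnetic field.
    """

    amplitude_coefficient: complex
    membrane: str  # "cell" | "organelle"

    def at(self, theta: float, phi: float) -> complex:
        """psi at angles (radians), in volts."""
        return self.amplitude_coefficient * math.sin(theta) * math.cos(phi)

    @property
    def max_amplitude_mV(self) -> float:
        return abs(self.amplitude_coefficient) * 1e3

    @property
    def phase_deg(self) -> float:
        """Phase in degrees in (-180, 180]; NaN for an unpolarised membrane."""
        return amplitude_and_phase(self.amplitude_coefficient)[1]


def cell_potential(solution: HarmonicSolution) -> TransmembranePotential:
    """Transmembrane potential of the cytoplasmic membrane, outer minus inner."""
    return TransmembranePotential(_cell_coefficient(solution), "cell")


def organelle_potential(solution: HarmonicSolution) -> TransmembranePotential:
    """Transmembrane potential of the organelle membrane, outer minus inner."""
    return TransmembranePotential(_organelle_coefficient(solution), "organelle")


def transmembrane_cell(solution: HarmonicSolution, theta: float, phi: float) -> complex:
    """psi_cell = V(R+, theta, phi) - V(R-, theta, phi), in volts."""
    return cell_potential(solution).at(theta, phi)


def transmembrane_organelle(
    solution: HarmonicSolution, theta: float, phi: float
) -> complex:
    """psi_org = V(r+, theta, phi) - V(r-, theta, phi), in volts."""
    return organelle_potential(solution).at(theta, phi)


def amplitude_and_phase(psi: complex) -> tuple[float, float]:
    """(magnitude in mV, phase in degrees) of a complex transmembrane potential.

    The phase is measured relative to the applied magnetic field and mapped to
    (-180, 180].  The phase of an exactly zero potential is undefined; that
    "no polarisation" outcome is signalled with a NaN phase.
    """
    magnitude = abs(psi) * 1e3
    if psi == 0:
        return magnitude, math.nan
    # math.atan2 rather than cmath.phase: the latter raises a spurious range
    # error when the angle underflows to a subnormal.
    phase = math.degrees(math.atan2(psi.imag, psi.real))
    if phase <= -180.0:  # negative-zero imaginary part lands on -180
        phase += 360.0
    return magnitude, phase
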