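"""Domain model: dielectric media, two-shell geometry, and the magnetic stimulus.

A spherical cell of outer radius ``R`` with a thin membrane of thickness ``D``
contains a single concentric spherical organelle (a mitochondrion) of outer
radius ``r`` with its own thin membrane of thickness ``d``.  The two membrane
shells divide space into five homogeneous, isotropic regions, numbered from
the outside in:

====== ============================ =============================
region medium                       parameters
====== ============================ =============================
0      extracellular medium         ``sigma_0``, ``epsilon_0``
1      cell (cytoplasmic) membrane  ``sigma_1``, ``epsilon_1``
2      cytoplasm                    ``sigma_2``, ``epsilon_2``
3      organelle membrane           ``sigma_3``, ``epsilon_3``
4      organelle interior           ``sigma_4``, ``epsilon_4``
====== ============================ =============================

Each region is characterised by a real conductivity sigma (S/m) and a real
dielectric permittivity epsilon (F/m, i.e. As/Vm).  Under sinusoidal
excitation at angular frequency omega the two combine into the complex
conductivity ``S = sigma + j*omega*epsilon``, which is how conduction and
displacement currents enter the boundary conditions on an equal footing.

The stimulus is a spatially uniform, sinusoidally alternating magnetic flux
density of amplitude ``B0`` directed along the axis of a circular coil whose
axis passes at a distance ``C`` from the cell centre.  Everything in this
module is stored in SI units; unit conversion for human-facing input/output
lives in :mod:`magshell.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DielectricMedium",
    "ShellGeometry",
    "TwoShellCell",
    "MagneticStimulus",
    "ParameterRange",
    "PARAMETER_TABLE",
    "PARAMETER_NAMES",
    "VARIABLE_PARAMETERS",
    "complex_conductivity",
    "standard_parameters",
    "standard_cell",
    "standard_stimulus",
    "build_cell",
    "build_stimulus",
    "cell_parameters",
    "random_cell",
]


# ---------------------------------------------------------------------------
# Dielectric media and geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DielectricMedium:
    """One homogeneous, isotropic region.

    Parameters
    ----------
    conductivity
        Ohmic conductivity sigma, in S/m.  Must be non-negative.
    permittivity
        Absolute dielectric permittivity epsilon, in F/m (As/Vm).
        Must be strictly positive.
    """

    conductivity: float
    permittivity: float

    def __post_init__(self) -> None:
        if not (self.conductivity >= 0.0):
            raise ValueError(
                f"conductivity must be >= 0 S/m, got {self.conductivity!r}"
            )
        if not (self.permittivity > 0.0):
            raise ValueError(
                f"permittivity must be > 0 F/m, got {self.permittivity!r}"
            )

    def complex_conductivity(self, omega: float) -> complex:
        """Complex conductivity ``S = sigma + j*omega*epsilon`` at ``omega`` (rad/s)."""
        if omega < 0.0:
            raise ValueError(f"omega must be >= 0, got {omega!r}")
        return self.conductivity + 1j * omega * self.permittivity


def complex_conductivity(medium: DielectricMedium, omega: float) -> complex:
    """Functional alias for :meth:`DielectricMedium.complex_conductivity`."""
    return medium.complex_conductivity(omega)


@dataclass(frozen=True)
class ShellGeometry:
    """A thin spherical shell: outer radius and thickness, both in metres.

    The inner radius is derived as ``outer_radius - thickness``.  The table
    radii of the model are interpreted as *outer* radii; for 5 nm membranes on
    micrometre spheres the distinction is numerically negligible, but a single
    convention has to be fixed.
    """

    outer_radius: float
    thickness: float

    def __post_init__(self) -> None:
        if not (self.thickness > 0.0):
            raise ValueError(f"thickness must be > 0 m, got {self.thickness!r}")
        if not (self.thickness < self.outer_radius):
            raise ValueError(
                f"thickness ({self.thickness!r} m) must be smaller than the "
                f"outer radius ({self.outer_radius!r} m)"
            )

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.thickness


@dataclass(frozen=True)
class TwoShellCell:
    """Five media plus the two shell geometries.

    ``media`` is ordered from region 0 (extracellular) to region 4 (organelle
    interior).  The organelle shell must lie strictly inside the cytoplasm,
    i.e. its outer radius must be smaller than the cell membrane's inner
    radius.
    """

    media: tuple[DielectricMedium, ...]
    cell_shell: ShellGeometry
    organelle_shell: ShellGeometry

    def __post_init__(self) -> None:
        if len(self.media) != 5:
            raise ValueError(f"exactly five media required, got {len(self.media)}")
        if not all(isinstance(m, DielectricMedium) for m in self.media):
            raise TypeError("media must be DielectricMedium instances")
        if not (self.organelle_shell.outer_radius < self.cell_shell.inner_radius):
            raise ValueError(
                "organelle must lie strictly inside the cytoplasm: outer radius "
                f"{self.organelle_shell.outer_radius!r} m is not smaller than the "
                f"cell membrane inner radius {self.cell_shell.inner_radius!r} m"
            )

    @property
    def interface_radii(self) -> tuple[float, float, float, float]:
        """The four interface radii (R+, R-, r+, r-), outermost first."""
        return (
            self.cell_shell.outer_radius,
            self.cell_shell.inner_radius,
            self.organelle_shell.outer_radius,
            self.organelle_shell.inner_radius,
        )

    def complex_conductivities(self, omega: float) -> np.ndarray:
        """Array of the five complex conductivities at ``omega``."""
        return np.array(
            [m.complex_conductivity(omega) for m in self.media], dtype=complex
        )

    def region_of(self, r: float) -> int:
        """Region index (0-4) containing radius ``r``; interfaces belong to the
        outer region (the potential is continuous, so the choice is cosmetic)."""
        if r < 0.0:
            raise ValueError(f"radius must be >= 0, got {r!r}")
        Rp, Rm, rp, rm = self.interface_radii
        if r >= Rp:
            return 0
        if r >= Rm:
            return 1
        if r >= rp:
            return 2
        if r >= rm:
            return 3
        return 4


@dataclass(frozen=True)
class MagneticStimulus:
    """Sinusoidal magnetic stimulus.

    Parameters
    ----------
    B0
        Magnetic flux density amplitude, tesla.
    frequency
        Field frequency, Hz.
    axis_offset
        Distance ``C`` between the cell centre and the coil axis, metres.
        The induced electric field at the cell scales linearly with it.
    """

    B0: float
    frequency: float
    axis_offset: float

    def __post_init__(self) -> None:
        if not (self.B0 >= 0.0):
            raise ValueError(f"B0 must be >= 0 T, got {self.B0!r}")
        if not (self.frequency >= 0.0):
            raise ValueError(f"frequency must be >= 0 Hz, got {self.frequency!r}")
        if not (self.axis_offset >= 0.0):
            raise ValueError(
                f"axis_offset must be >= 0 m, got {self.axis_offset!r}"
            )

    @property
    def omega(self) -> float:
        """Angular frequency ``2*pi*frequency`` in rad/s."""
        return 2.0 * math.pi * self.frequency

    def with_frequency(self, frequency: float) -> "MagneticStimulus":
        return replace(self, frequency=frequency)


# ---------------------------------------------------------------------------
# Parameter table: standard values and physiological ranges (SI units)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterRange:
    """Standard value and optional lower/upper physiological limits of one
    model parameter, together with the sampling scale used for fixtures."""

    name: str
    standard: float
    lower: float | None = None
    upper: float | None = None
    scale: str = "lin"  # "lin" | "log"

    def __post_init__(self) -> None:
        if self.scale not in ("lin", "log"):
            raise ValueError(f"scale must be 'lin' or 'log', got {self.scale!r}")
        if (self.lower is None) != (self.upper is None):
            raise ValueError(f"{self.name}: lower/upper must be given together")
        if self.lower is not None:
            if not (self.lower <= self.standard <= self.upper):
                raise ValueError(
                    f"{self.name}: standard value {self.standard!r} outside "
                    f"[{self.lower!r}, {self.upper!r}]"
                )

    @property
    def has_limits(self) -> bool:
        return self.lower is not None

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one value uniformly within the limits (log-uniform for 'log'
        scale).  A degenerate range (lower == upper) returns that exact value."""
        if not self.has_limits:
            return self.standard
        if self.lower == self.upper:
            return self.lower
        if self.scale == "log":
            return float(10.0 ** rng.uniform(math.log10(self.lower), math.log10(self.upper)))
        return float(rng.uniform(self.lower, self.upper))


# Conductivities are sampled log-uniformly (their limits span decades),
# everything else linearly.  All values SI.
PARAMETER_TABLE: dict[str, ParameterRange] = {
    p.name: p
    for p in (
        ParameterRange("sigma_0", 1.2, scale="log"),
        ParameterRange("sigma_1", 3e-7, 1.0e-8, 1.0e-6, scale="log"),
        ParameterRange("sigma_2", 0.3, 0.1, 1.0, scale="log"),
        ParameterRange("sigma_3", 3e-7, 1.0e-8, 1.0e-5, scale="log"),
        ParameterRange("sigma_4", 0.3, 0.1, 1.0, scale="log"),
        ParameterRange("epsilon_0", 6.4e-10),
        ParameterRange("epsilon_1", 4.4e-11, 1.8e-11, 8.8e-11),
        ParameterRange("epsilon_2", 6.4e-10, 3.5e-10, 7.0e-10),
        ParameterRange("epsilon_3", 4.4e-11, 1.8e-11, 8.8e-11),
        ParameterRange("epsilon_4", 6.4e-10, 3.5e-10, 7.0e-10),
        ParameterRange("R", 10e-6, 5e-6, 100e-6),
        ParameterRange("D", 5e-9, 3e-9, 7e-9),
        ParameterRange("r", 3e-6, 0.3e-6, 5e-6),
        ParameterRange("d", 5e-9, 1e-9, 8e-9),
        ParameterRange("B0", 2.0),
        ParameterRange("f", 10e3, 2e3, 200e3, scale="log"),
        # The coil-axis offset is not part of the published table; 10 mm is the
        # package default, calibrated once against the low-frequency closed
        # form (see docs/methods.md).  It is always exposed in configuration.
        ParameterRange("C", 10e-3),
    )
}

PARAMETER_NAMES: tuple[str, ...] = tuple(PARAMETER_TABLE)

#: Cell parameters with published lower/upper limits, i.e. the ones that are
#: varied in fixtures and parameter sweeps (the stimulus frequency is swept
#: separately).
VARIABLE_PARAMETERS: tuple[str, ...] = tuple(
    name
    for name, p in PARAMETER_TABLE.items()
    if p.has_limits and name != "f"
)

_CELL_KEYS = (
    "sigma_0", "sigma_1", "sigma_2", "sigma_3", "sigma_4",
    "epsilon_0", "epsilon_1", "epsilon_2", "epsilon_3", "epsilon_4",
    "R", "D", "r", "d",
)
_STIMULUS_KEYS = ("B0", "f", "C")


def standard_parameters() -> dict[str, float]:
    """All 17 model parameters at their standard values, in SI units."""
    return {name: p.standard for name, p in PARAMETER_TABLE.items()}


def build_cell(params: Mapping[str, float]) -> TwoShellCell:
    """Construct a :class:`TwoShellCell` from a flat parameter mapping (SI).

    ``params`` must contain the 14 cell keys (``sigma_0..4``,
    ``epsilon_0..4``, ``R``, ``D``, ``r``, ``d``); extra stimulus keys are
    ignored so a full 17-key set may be passed.
    """
    missing = [k for k in _CELL_KEYS if k not in params]
    if missing:
        raise KeyError(f"missing cell parameters: {missing}")
    media = tuple(
        DielectricMedium(params[f"sigma_{i}"], params[f"epsilon_{i}"])
        for i in range(5)
    )
    return TwoShellCell(
        media=media,
        cell_shell=ShellGeometry(params["R"], params["D"]),
        organelle_shell=ShellGeometry(params["r"], params["d"]),
    )


def build_stimulus(params: Mapping[str, float]) -> MagneticStimulus:
    """Construct a :class:`MagneticStimulus` from a flat parameter mapping (SI)."""
    missing = [k for k in _STIMULUS_KEYS if k not in params]
    if missing:
        raise KeyError(f"missing stimulus parameters: {missing}")
    return MagneticStimulus(
        B0=params["B0"], frequency=params["f"], axis_offset=params["C"]
    )


def cell_parameters(cell: TwoShellCell) -> dict[str, float]:
    """Inverse of :func:`build_cell`: flatten a cell back to its 14 parameters."""
    out: dict[str, float] = {}
    for i, m in enumerate(cell.media):
        out[f"sigma_{i}"] = m.conductivity
        out[f"epsilon_{i}"] = m.permittivity
    out["R"] = cell.cell_shell.outer_radius
    out["D"] = cell.cell_shell.thickness
    out["r"] = cell.organelle_shell.outer_radius
    out["d"] = cell.organelle_shell.thickness
    return out


def standard_cell() -> TwoShellCell:
    """The standard-parameter cell (R = 10 um, D = 5 nm, r = 3 um, d = 5 nm)."""
    return build_cell(standard_parameters())


def standard_stimulus() -> MagneticStimulus:
    """The standard stimulus: B0 = 2 T, f = 10 kHz, coil-axis offset 10 mm."""
    return build_stimulus(standard_parameters())


def random_cell(
    ranges: Mapping[str, ParameterRange] | Iterable[ParameterRange] | None = None,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    max_attempts: int = 1000,
) -> TwoShellCell:
    """Sample a random cell within the tabulated physiological limits.

    Parameters without limits keep their standard values.  Geometry draws that
    place the organelle outside the cytoplasm are rejected and redrawn; after
    ``max_attempts`` failed attempts a ``ValueError`` is raised (mutually
    unsatisfiable ranges).  For a fixed ``seed`` the result is reproducible.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if ranges is None:
        table = dict(PARAMETER_TABLE)
    elif isinstance(ranges, Mapping):
        table = dict(ranges)
    else:
        table = {p.name: p for p in ranges}

    params = standard_parameters()
    electrical = [k for k in _CELL_KEYS if k in table and k not in ("R", "D", "r", "d")]
    for key in electrical:
        params[key] = table[key].sample(rng)
    geom_keys = [k for k in ("R", "D", "r", "d") if k in table]
    for _ in range(max_attempts):
        for key in geom_keys:
            params[key] = table[key].sample(rng)
        try:
            return build_cell(params)
        except ValueError:
            continue
    raise ValueError(
        f"could not draw a valid geometry in {max_attempts} attempts; "
        "the supplied ranges appear mutually unsatisfiable"
    )
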