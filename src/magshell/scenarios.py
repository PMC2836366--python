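"""Computational experiments on the two-shell model.

Frequency responses, membrane-removal comparisons, parameter-by-frequency
sweeps, angular surface maps, and the low-frequency phase-transition radius
of the organelle.  All results come back as :class:`SweepResult` /
:class:`SurfaceMap` objects that carry the full resolved parameter set in
their metadata, so any table can be regenerated from its own file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from . import __version__
from .model import (
    MagneticStimulus,
    TwoShellCell,
    VARIABLE_PARAMETERS,
    build_cell,
    cell_parameters,
)
from .solver import (
    HarmonicSolution,
    amplitude_and_phase,
    cell_potential,
    organelle_potential,
    solve,
)

__all__ = [
    "SweepResult",
    "SurfaceMap",
    "BracketingError",
    "default_frequency_grid",
    "frequency_response",
    "remove_cell_membrane",
    "remove_organelle",
    "parameter_sweep",
    "phase_transition_radius",
    "surface_map",
]


class BracketingError(ValueError):
    """The supplied bracket does not contain a phase-regime crossing."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Tabular amplitude/phase of psi_cell and psi_org over one or two grids.

    ``table`` holds one row per grid point; ``metadata`` records the scenario
    label, the resolved parameter set and the package version.  CSV output
    places the metadata in ``#``-prefixed JSON header lines so the file is
    self-describing and round-trips losslessly.
    """

    table: pd.DataFrame
    metadata: dict

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}: {json.dumps(self.metadata[key])}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if not line.startswith("#"):
                break
            key, _, raw = line[1:].strip().partition(": ")
            meta[key] = json.loads(raw)
        body = [ln for ln in lines if not ln.startswith("#")]
        from io import StringIO

        table = pd.read_csv(StringIO("".join(body)))
        return cls(table=table, metadata=meta)

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {"metadata": self.metadata, "rows": self.table.to_dict(orient="records")},
            allow_nan=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


@dataclass
class SurfaceMap:
    """Angular map of one membrane's polarisation.

    ``amplitude`` is the complex transmembrane potential (volts) on the
    (theta, phi) grid; ``instantaneous_mV`` the real polarisation
    Re[psi * e^{j*time_phase}] in millivolts at the chosen instant of the
    cycle.  Values vanish at the poles and flip sign under a 180° azimuth
    shift.
    """

    theta_deg: np.ndarray
    phi_deg: np.ndarray
    amplitude: np.ndarray        # complex, shape (n_theta, n_phi)
    instantaneous_mV: np.ndarray  # real, same shape
    membrane: str
    time_phase_deg: float
    metadata: dict

    def to_csv(self, path) -> None:
        th, ph = np.meshgrid(self.theta_deg, self.phi_deg, indexing="ij")
        df = pd.DataFrame(
            {
                "theta_deg": th.ravel(),
                "phi_deg": ph.ravel(),
                "psi_real_V": self.amplitude.real.ravel(),
                "psi_imag_V": self.amplitude.imag.ravel(),
                "instantaneous_mV": self.instantaneous_mV.ravel(),
            }
        )
        with open(path, "w", newline="") as fh:
            for key in sorted(self.metadata):
                fh.write(f"# {key}: {json.dumps(self.metadata[key])}\n")
            df.to_csv(fh, index=False)

    def to_json(self, path=None) -> str:
        doc = json.dumps(
            {
                "metadata": self.metadata,
                "theta_deg": self.theta_deg.tolist(),
                "phi_deg": self.phi_deg.tolist(),
                "psi_real_V": self.amplitude.real.tolist(),
                "psi_imag_V": self.amplitude.imag.tolist(),
                "instantaneous_mV": self.instantaneous_mV.tolist(),
            }
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


def _metadata(cell: TwoShellCell, stimulus: MagneticStimulus, scenario: str, **extra) -> dict:
    params = cell_parameters(cell)
    params.update(B0=stimulus.B0, f=stimulus.frequency, C=stimulus.axis_offset)
    md = {"scenario": scenario, "parameters": params, "version": __version__}
    md.update(extra)
    return md


# ---------------------------------------------------------------------------
# Frequency response
# ---------------------------------------------------------------------------

def default_frequency_grid(
    f_min: float = 2e3, f_max: float = 200e3, points_per_decade: int = 60
) -> np.ndarray:
    """Log-spaced frequency grid, 60 points per decade by default."""
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    n = max(2, int(round(points_per_decade * math.log10(f_max / f_min))) + 1)
    return np.logspace(math.log10(f_min), math.log10(f_max), n)


def _row(solution: HarmonicSolution) -> dict[str, float]:
    psi_c = cell_potential(solution).amplitude_coefficient
    psi_o = organelle_potential(solution).amplitude_coefficient
    amp_c, ph_c = amplitude_and_phase(psi_c)
    amp_o, ph_o = amplitude_and_phase(psi_o)
    ratio = amp_o / amp_c if amp_c > 0 else math.nan
    return {
        "psi_cell_mV": amp_c,
        "psi_cell_phase_deg": ph_c,
        "psi_org_mV": amp_o,
        "psi_org_phase_deg": ph_o,
        "amplitude_ratio": ratio,
        "phase_difference_deg": ph_o - ph_c,
    }


def frequency_response(
    cell: TwoShellCell, stimulus: MagneticStimulus, frequencies
) -> SweepResult:
    """Maximal amplitude and phase of both membranes per grid frequency.

    Also tabulates the organelle/cell amplitude ratio and the phase
    difference (organelle minus cell).  ``stimulus`` supplies B0 and the
    coil-axis offset; its own frequency is ignored in favour of the grid.
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency grid is empty")
    if np.any(freqs <= 0):
        raise ValueError("all grid frequencies must be > 0")
    rows = []
    for f in freqs:
        sol = solve(cell, stimulus.with_frequency(float(f)))
        rows.append({"frequency_hz": float(f), **_row(sol)})
    return SweepResult(
        table=pd.DataFrame(rows),
        metadata=_metadata(cell, stimulus, "frequency_response"),
    )


# ---------------------------------------------------------------------------
# Membrane-removal scenarios
# ---------------------------------------------------------------------------

def remove_cell_membrane(cell: TwoShellCell) -> TwoShellCell:
    """Replace regions 1 and 2 by the extracellular medium (S1 = S0, S2 = S0).

    Electrically this strips the cytoplasmic membrane and bathes the bare
    organelle in extracellular fluid; the geometry is untouched, so the
    (now virtual) cell interfaces carry no conductivity jump.  Idempotent.
    """
    m = cell.media
    return replace(cell, media=(m[0], m[0], m[0], m[3], m[4]))


def remove_organelle(cell: TwoShellCell) -> TwoShellCell:
    """Replace regions 3 and 4 by the cytoplasm medium (S3 = S2, S4 = S2).

    The organelle interfaces become virtual and the transmembrane potential
    across them vanishes identically.  Idempotent.
    """
    m = cell.media
    return replace(cell, media=(m[0], m[1], m[2], m[2], m[2]))


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def parameter_sweep(
    cell: TwoShellCell,
    stimulus: MagneticStimulus,
    parameter: str,
    values,
    frequencies=None,
) -> SweepResult:
    """2-D sweep: one tabulated cell parameter against frequency.

    ``parameter`` must be one of the varied table rows
    (:data:`magshell.model.VARIABLE_PARAMETERS`).  Every other parameter keeps
    the value it has in ``cell``.  Grid points whose geometry violates the
    model invariants (e.g. an organelle radius that no longer fits inside the
    cell) are flagged ``valid = False`` with NaN responses rather than
    silently dropped.
    """
    if parameter not in VARIABLE_PARAMETERS:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; expected one of "
            f"{VARIABLE_PARAMETERS}"
        )
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("value grid is empty")
    if frequencies is None:
        freqs = np.array([stimulus.frequency], dtype=float)
    else:
        freqs = np.asarray(list(frequencies), dtype=float)
    if freqs.size == 0:
        raise ValueError("frequency grid is empty")
    if np.any(freqs <= 0):
        raise ValueError("all grid frequencies must be > 0")

    base = cell_parameters(cell)
    rows = []
    nan_row = {k: math.nan for k in _row_keys()}
    for v in vals:
        params = dict(base)
        params[parameter] = float(v)
        try:
            swept = build_cell(params)
        except ValueError:
            for f in freqs:
                rows.append(
                    {parameter: float(v), "frequency_hz": float(f), "valid": False,
                     **nan_row}
                )
            continue
        for f in freqs:
            sol = solve(swept, stimulus.with_frequency(float(f)))
            rows.append(
                {parameter: float(v), "frequency_hz": float(f), "valid": True,
                 **_row(sol)}
            )
    return SweepResult(
        table=pd.DataFrame(rows),
        metadata=_metadata(cell, stimulus, "parameter_sweep", parameter=parameter),
    )


def _row_keys() -> tuple[str, ...]:
    return (
        "psi_cell_mV", "psi_cell_phase_deg", "psi_org_mV", "psi_org_phase_deg",
        "amplitude_ratio", "phase_difference_deg",
    )


# ---------------------------------------------------------------------------
# Phase-transition radius
# ---------------------------------------------------------------------------

def phase_transition_radius(
    cell: TwoShellCell,
    stimulus: MagneticStimulus,
    bracket: tuple[float, float] = (0.3e-6, 5e-6),
    tolerance: float = 0.01e-6,
) -> float:
    """Organelle outer radius (m) at which the low-frequency phase regime flips.

    At a low probe frequency (carried by ``stimulus``; 1 kHz is the usual
    choice) a large organelle polarises with a ~-90° lag, a small one with a
    ~+90° advance.  The regimes are classified by the sign of the imaginary
    part of the organelle amplitude coefficient, and the crossing radius is
    refined by bisection to ``tolerance``.  Scale-free in B0 and C.

    Raises :class:`BracketingError` when both bracket endpoints fall in the
    same regime.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")
    base = cell_parameters(cell)

    def classify(radius: float) -> float:
        params = dict(base)
        params["r"] = float(radius)
        sol = solve(build_cell(params), stimulus)
        return organelle_potential(sol).amplitude_coefficient.imag

    g_lo, g_hi = classify(lo), classify(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if math.copysign(1.0, g_lo) == math.copysign(1.0, g_hi):
        raise BracketingError(
            f"no phase-regime crossing in bracket [{lo!r}, {hi!r}] m: the "
            "endpoint phases lie in the same regime"
        )
    return float(bisect(classify, lo, hi, xtol=tolerance))


# ---------------------------------------------------------------------------
# Surface maps
# ---------------------------------------------------------------------------

def surface_map(
    solution: HarmonicSolution,
    membrane: str = "cell",
    n_theta: int = 37,
    n_phi: int = 73,
    time_phase: float = 0.0,
) -> SurfaceMap:
    """Instantaneous polarisation map Re[psi(theta, phi) e^{j*time_phase}].

    ``time_phase`` is in radians.  Zeros at the poles, extrema on the
    equator at phi = 0° and 180° with opposite signs.
    """
    if membrane not in ("cell", "organelle"):
        raise ValueError(f"membrane must be 'cell' or 'organelle', got {membrane!r}")
    psi = (
        cell_potential(solution)
        if membrane == "cell"
        else organelle_potential(solution)
    ).amplitude_coefficient
    theta = np.linspace(0.0, 180.0, n_theta)
    phi = np.linspace(0.0, 360.0, n_phi)
    pattern = np.outer(
        np.sin(np.radians(theta)), np.cos(np.radians(phi))
    )
    amplitude = psi * pattern
    instantaneous = np.real(amplitude * np.exp(1j * time_phase)) * 1e3
    md = {
        "membrane": membrane,
        "time_phase_deg": math.degrees(time_phase),
        "frequency_hz": solution.omega / (2.0 * math.pi),
        "version": __version__,
    }
    return SurfaceMap(
        theta_deg=theta,
        phi_deg=phi,
        amplitude=amplitude,
        instantaneous_mV=instantaneous,
        membrane=membrane,
        time_phase_deg=math.degrees(time_phase),
        metadata=md,
    )
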