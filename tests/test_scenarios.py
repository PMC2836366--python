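"""Scenario reproduction: frequency response, shielding, sweeps, maps."""

import math

import numpy as np
import pytest

from magshell import (
    BracketingError,
    cell_potential,
    frequency_response,
    organelle_potential,
    parameter_sweep,
    phase_transition_radius,
    remove_cell_membrane,
    remove_organelle,
    solve,
    surface_map,
    transfer_matrix_solution,
    transmembrane_organelle,
)
from magshell.model import MagneticStimulus
from magshell.scenarios import default_frequency_grid


class TestFrequencyResponse:
    def test_single_point_grid_equals_direct_solve(self, cell, stimulus):
        result = frequency_response(cell, stimulus, [10e3])
        sol = solve(cell, stimulus)
        row = result.table.iloc[0]
        assert row["psi_cell_mV"] == pytest.approx(
            cell_potential(sol).max_amplitude_mV, rel=1e-14
        )
        assert row["psi_org_mV"] == pytest.approx(
            organelle_potential(sol).max_amplitude_mV, rel=1e-14
        )

    def test_organelle_amplitude_increases_with_frequency_in_band(self, cell, stimulus):
        grid = default_frequency_grid(2e3, 200e3, points_per_decade=40)
        amps = frequency_response(cell, stimulus, grid).table["psi_org_mV"].to_numpy()
        assert np.all(np.diff(amps) > 0)

    def test_shielding_inequality_up_to_200khz(self, cell, stimulus):
        grid = default_frequency_grid(2e3, 200e3, points_per_decade=20)
        table = frequency_response(cell, stimulus, grid).table
        assert np.all(table["psi_org_mV"] < table["psi_cell_mV"])

    def test_rejects_empty_or_nonpositive_grids(self, cell, stimulus):
        with pytest.raises(ValueError):
            frequency_response(cell, stimulus, [])
        with pytest.raises(ValueError):
            frequency_response(cell, stimulus, [0.0, 1e3])


class TestMembraneRemoval:
    def test_remove_cell_membrane_is_idempotent(self, cell):
        once = remove_cell_membrane(cell)
        assert remove_cell_membrane(once) == once
        assert once.media[1] == once.media[0] and once.media[2] == once.media[0]
        assert once.cell_shell == cell.cell_shell  # geometry untouched

    def test_remove_organelle_is_idempotent(self, cell):
        once = remove_organelle(cell)
        assert remove_organelle(once) == once
        assert once.media[3] == once.media[2] and once.media[4] == once.media[2]

    def test_bare_organelle_polarises_more(self, cell, stimulus):
        """The cytoplasmic membrane shields the organelle throughout the
        2-200 kHz band."""
        bare = remove_cell_membrane(cell)
        for freq in default_frequency_grid(2e3, 200e3, points_per_decade=10):
            stim = stimulus.with_frequency(freq)
            intact_amp = organelle_potential(solve(cell, stim)).max_amplitude_mV
            bare_amp = organelle_potential(solve(bare, stim)).max_amplitude_mV
            assert intact_amp < bare_amp

    def test_virtual_organelle_shell_carries_no_interfacial_charge(self, cell, stimulus):
        """With the organelle media set to cytoplasm, the interior is
        homogeneous: no scattered dipole arises at the virtual interfaces
        (d3 = 0, c2 = c3 = c4) and the potential drop across the virtual
        5 nm shell is just the smooth local gradient, far below the intact
        organelle's polarisation."""
        sol = solve(remove_organelle(cell), stimulus)
        c2, d2 = sol.region_coefficients(2)
        c3, d3 = sol.region_coefficients(3)
        c4, _ = sol.region_coefficients(4)
        assert abs(d3) <= 1e-12 * abs(c3)
        assert abs(c3 - c2) <= 1e-12 * abs(c2)
        assert abs(c4 - c2) <= 1e-12 * abs(c2)
        virtual = abs(transmembrane_organelle(sol, math.pi / 2, 0.0))
        intact = abs(transmembrane_organelle(solve(cell, stimulus), math.pi / 2, 0.0))
        assert virtual < 0.05 * intact

    def test_organelle_barely_affects_cell_membrane(self, cell, stimulus):
        for freq in (2e3, 10e3, 50e3, 200e3):
            stim = stimulus.with_frequency(freq)
            with_org = cell_potential(solve(cell, stim)).max_amplitude_mV
            without = cell_potential(solve(remove_organelle(cell), stim)).max_amplitude_mV
            assert abs(without - with_org) / with_org < 0.01

    def test_removed_membrane_matches_single_shell_oracle(self, cell, stimulus):
        """Stripping the cell membrane must reduce the problem to a bare
        single-shell organelle; the ladder oracle agrees closely."""
        bare = remove_cell_membrane(cell)
        a = organelle_potential(solve(bare, stimulus)).amplitude_coefficient
        b = organelle_potential(transfer_matrix_solution(bare, stimulus)).amplitude_coefficient
        assert abs(a - b) / abs(b) < 1e-9


class TestParameterSweep:
    def test_single_point_grid_equals_direct_solve(self, cell, stimulus):
        result = parameter_sweep(cell, stimulus, "r", [3e-6], [10e3])
        sol = solve(cell, stimulus)
        assert result.table.iloc[0]["psi_org_mV"] == pytest.approx(
            organelle_potential(sol).max_amplitude_mV, rel=1e-12
        )

    def test_organelle_membrane_thickness_is_insignificant(self, cell, stimulus):
        result = parameter_sweep(
            cell, stimulus, "d", np.linspace(1e-9, 8e-9, 8), [10e3]
        )
        amps = result.table["psi_org_mV"]
        assert (amps.max() - amps.min()) / amps.mean() < 0.05

    def test_cell_membrane_conductivity_is_insignificant(self, cell, stimulus):
        result = parameter_sweep(
            cell, stimulus, "sigma_1", np.logspace(-8, -6, 9), [10e3]
        )
        amps = result.table["psi_org_mV"]
        assert (amps.max() - amps.min()) / amps.mean() < 0.05

    def test_unknown_parameter_rejected(self, cell, stimulus):
        with pytest.raises(ValueError, match="unknown sweep parameter"):
            parameter_sweep(cell, stimulus, "sigma_9", [1.0], [10e3])

    def test_empty_grid_rejected(self, cell, stimulus):
        with pytest.raises(ValueError):
            parameter_sweep(cell, stimulus, "r", [], [10e3])

    def test_invalid_geometry_flagged_not_dropped(self, cell, stimulus):
        result = parameter_sweep(cell, stimulus, "r", [2e-6, 20e-6], [10e3])
        table = result.table
        assert len(table) == 2
        good = table[table["r"] == 2e-6].iloc[0]
        bad = table[table["r"] == 20e-6].iloc[0]
        assert bool(good["valid"]) and np.isfinite(good["psi_org_mV"])
        assert not bool(bad["valid"]) and np.isnan(bad["psi_org_mV"])

    def test_metadata_carries_full_provenance(self, cell, stimulus):
        result = parameter_sweep(cell, stimulus, "r", [3e-6], [10e3])
        params = result.metadata["parameters"]
        assert params["sigma_1"] == 3e-7 and params["B0"] == 2.0
        assert result.metadata["parameter"] == "r"


class TestPhaseTransitionRadius:
    def test_crossing_near_one_micron(self, cell, stimulus):
        radius = phase_transition_radius(cell, stimulus.with_frequency(1e3))
        assert radius == pytest.approx(1.1e-6, abs=0.15e-6)

    def test_invariant_under_field_scaling(self, cell, stimulus):
        low = stimulus.with_frequency(1e3)
        r1 = phase_transition_radius(cell, low)
        doubled = MagneticStimulus(2 * low.B0, low.frequency, 2 * low.axis_offset)
        r2 = phase_transition_radius(cell, doubled)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_bracket_without_crossing_raises(self, cell, stimulus):
        with pytest.raises(BracketingError):
            phase_transition_radius(cell, stimulus.with_frequency(1e3),
                                    bracket=(2e-6, 5e-6))


class TestSurfaceMap:
    def test_poles_unpolarised_and_equator_extremal(self, cell, stimulus):
        sol = solve(cell, stimulus)
        surface = surface_map(sol, "cell", n_theta=19, n_phi=25)
        mv = surface.instantaneous_mV
        peak = np.abs(mv).max()
        assert np.abs(mv[0]).max() <= 1e-12 * peak  # theta = 0
        assert np.abs(mv[-1]).max() <= 1e-9 * peak  # theta = 180
        equator = mv[9]  # theta = 90
        imax = np.argmax(np.abs(equator))
        assert surface.phi_deg[imax] % 180.0 == pytest.approx(0.0)

    def test_antisymmetric_under_half_turn(self, cell, stimulus):
        sol = solve(cell, stimulus)
        surface = surface_map(sol, "organelle", n_theta=9, n_phi=13)
        # phi grid spans 0..360 in 13 points -> phi + 180 deg is 6 indices on
        half = 6
        a = surface.amplitude[:, : half + 1]
        b = surface.amplitude[:, half : 2 * half + 1]
        assert np.allclose(a, -b, atol=1e-18)

    def test_scales_linearly_with_field_intensity(self, cell, stimulus):
        sol1 = solve(cell, stimulus)
        sol2 = solve(cell, MagneticStimulus(2 * stimulus.B0, stimulus.frequency,
                                            stimulus.axis_offset))
        m1 = surface_map(sol1, "cell", 9, 13).instantaneous_mV
        m2 = surface_map(sol2, "cell", 9, 13).instantaneous_mV
        assert np.allclose(m2, 2 * m1, rtol=1e-12, atol=1e-30)

    def test_equator_extrema_have_opposite_signs(self, cell, stimulus):
        sol = solve(cell, stimulus)
        surface = surface_map(sol, "cell", n_theta=19, n_phi=25, time_phase=math.pi / 2)
        equator = surface.instantaneous_mV[9]
        assert equator[0] * equator[12] < 0  # phi = 0 vs phi = 180
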