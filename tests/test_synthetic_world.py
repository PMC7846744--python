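"""Synthetic climate worlds, virtual species and the true range-change oracle."""

import numpy as np
import pytest

from amocrange import (
    NicheSpec,
    ScenarioSpec,
    WorldSpec,
    compute_bioclim,
    generate_climate_world,
    generate_virtual_species,
    horizon_mean,
    true_range_change,
)
from amocrange.errors import ConfigurationError, GenerationError
from amocrange.synthetic_world import HOSING_FORCINGS_SV, default_scenarios


class TestScenarioSpecs:
    def test_default_forcings(self):
        scens = {s.label: s for s in default_scenarios()}
        assert scens["D"].forcing_sv == 0.68
        assert scens["A"].forcing_sv == 0.11
        assert scens["RCP85"].forcing_sv == 0.0
        assert HOSING_FORCINGS_SV == {
            "RCP85": 0.0, "A": 0.11, "B": 0.22, "C": 0.34, "D": 0.68
        }

    def test_invalid_forcing_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec(label="X", forcing_sv=0.5)

    def test_hosing_terms_forbidden_without_forcing(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec(label="RCP85", forcing_sv=0.0, precip_anomaly=-0.2)

    def test_ramp_shape(self):
        s = ScenarioSpec(label="D", forcing_sv=0.68,
                         hosing_cooling_amplitude=1.0,
                         hosing_region=("Afrotropical",))
        assert s.ramp(2019) == 0.0
        assert s.ramp(2045) == pytest.approx(0.5)
        assert s.ramp(2090) == 1.0  # anomaly persists after the window


class TestGenerateClimateWorld:
    def test_determinism_bit_identical(self):
        spec = WorldSpec(grid_shape=(10, 20), n_realms=2, seed=5)
        w1 = generate_climate_world(spec)
        w2 = generate_climate_world(spec)
        assert w1.obs_baseline == w2.obs_baseline
        for label in w1.scenarios:
            assert w1.scenarios[label] == w2.scenarios[label]

    def test_physical_invariants_hold(self, small_world):
        for cube in [small_world.obs_baseline, small_world.model_baseline,
                     *small_world.scenarios.values()]:
            cube.validate()

    def test_zero_forcing_scenario_matches_model_baseline_statistics(self):
        scen = (ScenarioSpec(label="RCP85", forcing_sv=0.0, warming_rate=0.0),)
        spec = WorldSpec(grid_shape=(12, 24), n_realms=2, seed=9,
                         scenario_specs=scen)
        w = generate_climate_world(spec)
        for var in ("tmean", "prec"):
            base = w.model_baseline.data[var].mean(axis=0)
            traj = w.scenarios["RCP85"].data[var].mean(axis=0)
            # same expectation: cellwise difference within 3 SE of the means
            n1 = w.model_baseline.data[var].shape[0]
            n2 = w.scenarios["RCP85"].data[var].shape[0]
            se = np.sqrt(w.model_baseline.data[var].var(axis=0) / n1
                         + w.scenarios["RCP85"].data[var].var(axis=0) / n2)
            frac_within = (np.abs(base - traj) < 3 * se + 1e-9).mean()
            assert frac_within > 0.99

    def test_hosing_locality_outside_region(self, small_world):
        """Cells outside the hosing realm have the same expected trajectory
        in hosing scenarios as in the control."""
        w = small_world
        region = w.realm_mask.mask_for("Afrotropical")
        outside = ~region
        late = slice(-20, None)  # strongest anomaly years
        ctrl = w.scenarios["RCP85"].data["tmean"][late].mean(axis=(0, 1))
        hos = w.scenarios["D"].data["tmean"][late].mean(axis=(0, 1))
        diff_out = np.abs((ctrl - hos)[outside]).mean()
        diff_in = np.abs((ctrl - hos)[region]).mean()
        assert diff_out < 0.2  # noise only
        assert diff_in > 0.4  # cooling anomaly present (1.0 degC/Sv * 0.68 Sv)

    def test_hosing_drying_inside_region(self, small_world):
        w = small_world
        region = w.realm_mask.mask_for("Afrotropical")
        late = slice(-20, None)
        ctrl = w.scenarios["RCP85"].data["prec"][late].mean(axis=(0, 1))
        hos = w.scenarios["D"].data["prec"][late].mean(axis=(0, 1))
        ratio = (hos / ctrl)[region].mean()
        assert ratio < 0.65  # ~ -0.7/Sv * 0.68 Sv anomaly

    def test_unknown_hosing_realm_rejected(self):
        scen = (ScenarioSpec(label="A", forcing_sv=0.11,
                             hosing_cooling_amplitude=0.5,
                             hosing_region=("Atlantis",), precip_anomaly=-0.1),)
        with pytest.raises(ConfigurationError, match="Atlantis"):
            generate_climate_world(WorldSpec(grid_shape=(6, 12), n_realms=2,
                                             seed=1, scenario_specs=scen))

    def test_injected_bias_recoverable(self, small_world):
        """Model-baseline minus observed-baseline climatology approximates
        the injected bias field."""
        w = small_world
        diff = (w.model_baseline.data["tmean"].mean(axis=0)
                - w.obs_baseline.data["tmean"].mean(axis=0))
        err = np.abs(diff - w.injected_bias["tmean"])
        assert err.mean() < 0.3  # noise of two 31-year means


class TestVirtualSpecies:
    def test_every_species_satisfies_invariants(self, small_world, small_species):
        mask = small_world.realm_mask
        for sp in small_species:
            assert len(sp.presence_cells) >= 50
            realms = np.unique(mask.realm_of_cells(sp.presence_cells))
            assert len(realms) == 1
            assert mask.names[realms[0]] == sp.realm
            assert np.all(sp.sigma > 0)
            assert 0 < sp.suitability_threshold < 1

    def test_generation_deterministic(self, small_world):
        a = generate_virtual_species(small_world, 4, seed=3)
        b = generate_virtual_species(small_world, 4, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.presence_cells, y.presence_cells)
            np.testing.assert_array_equal(x.mu, y.mu)

    def test_suitability_is_one_at_optimum(self, small_world, small_species):
        sp = small_species[0]
        stack = small_world.baseline_bioclim()
        # craft a stack whose first cell matches the optimum exactly
        for i, v in enumerate(stack.data):
            stack.data[v] = stack.data[v].copy()
            stack.data[v].ravel()[0] = sp.mu[i]
        s = sp.suitability(stack)
        assert s[0] == pytest.approx(1.0)

    def test_infinite_breadth_covers_whole_realm(self, small_world, small_species):
        import dataclasses

        sp = small_species[0]
        wide = dataclasses.replace(sp, sigma=np.full(5, 1e12))
        stack = small_world.baseline_bioclim()
        realm_cells = small_world.realm_mask.cells_for(sp.realm)
        s = wide.suitability(stack, realm_cells)
        assert np.allclose(s, 1.0)

    def test_presence_is_thresholded_suitability(self, small_world, small_species):
        stack = small_world.baseline_bioclim()
        mask = small_world.realm_mask
        for sp in small_species:
            cells = mask.cells_for(sp.realm)
            s = sp.suitability(stack, cells)
            expected = cells[s >= sp.suitability_threshold]
            np.testing.assert_array_equal(sp.presence_cells, expected)

    def test_unplaceable_species_raises_with_realm(self, small_world):
        impossible = NicheSpec(breadth_range=(1e-6, 2e-6),
                               threshold_range=(0.98, 0.99), max_retries=5)
        with pytest.raises(GenerationError, match="realm"):
            generate_virtual_species(small_world, 2, niche_spec=impossible, seed=1)


class TestTrueRangeChange:
    def test_identity_climate_gives_zero(self, small_world, small_species):
        stack = small_world.baseline_bioclim()
        for sp in small_species:
            for disp in ("full", "none"):
                assert true_range_change(sp, stack, disp,
                                         small_world.realm_mask) == 0.0

    def test_impossible_climate_gives_total_loss(self, small_world, small_species):
        stack = small_world.baseline_bioclim()
        hot = type(stack)(
            grid=stack.grid,
            data={v: stack.data[v] + 1e6 for v in stack.data},
        )
        sp = small_species[0]
        assert true_range_change(sp, hot, "full", small_world.realm_mask) == 1.0

    def test_dispersal_ordering_by_enumeration(self, small_world, small_species):
        """q(none) >= q(full) for every species x scenario x horizon."""
        w = small_world
        for scen in ("RCP85", "D"):
            clim = horizon_mean(w.scenarios[scen], 2070, width=30)
            stack = compute_bioclim(clim)
            for sp in small_species:
                q_full = true_range_change(sp, stack, "full", w.realm_mask)
                q_none = true_range_change(sp, stack, "none", w.realm_mask)
                assert q_none >= q_full
                assert 0.0 <= q_none <= 1.0
                assert q_full <= 1.0
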