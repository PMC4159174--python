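"""Deterministic and stochastic simulation against closed-form oracles."""

import numpy as np
import pytest

from senesim.network import build_reference_network
from senesim.simulate import (
    SimulationSettings,
    project_observables,
    simulate_deterministic,
    simulate_stochastic,
)

from .conftest import birth_death_model, linear_decay_model, two_state_cycle


class TestDeterministic:
    def test_exponential_decay_closed_form(self):
        m = linear_decay_model(rate=1.0, x0=1.0)
        traj = simulate_deterministic(m, settings=SimulationSettings(duration=1.0, interval_size=0.1))
        assert traj.states[-1, 0] == pytest.approx(np.exp(-1.0), rel=1e-5)

    def test_no_irradiation_keeps_basal_state(self, coarse_settings):
        """Without the damage impulse the network sits at its basal state."""
        m = build_reference_network(irradiation_amplitude=0.0)
        traj = simulate_deterministic(m, settings=coarse_settings)
        y0 = traj.observables[0]
        drift = np.abs(traj.observables - y0).max(axis=0) / np.maximum(np.abs(y0), 1e-12)
        assert drift.max() < 0.05

    def test_irradiated_run_shows_senescence_dynamics(self, reference_trajectory):
        tr = reference_trajectory
        dd = tr.observable("DNA-damage")
        # damage spikes within the first day and decays well below the peak by day 4
        assert dd.max() > 10 * dd[0]
        assert tr.times[dd.argmax()] < 1.0
        assert dd[tr.at_time(4.0)] < 0.25 * dd.max()
        # old mitochondrial pool accumulates while new-pool potential falls after ~day 5
        assert tr.state("X21")[-1] > 1.0
        psi_new = tr.state("X22")
        assert psi_new[-1] < 0.6 * psi_new[tr.at_time(5.0)]
        # total mass increases
        mass = tr.observable("Mitochondrial-Mass")
        assert mass[-1] > 1.5 * mass[0]

    def test_conserved_totals_constant_within_tolerance(self, reference_model, reference_trajectory):
        from senesim.network import conservation_analysis

        laws, _ = conservation_analysis(reference_model)
        for law in laws:
            cols = [reference_model.species_index[s] for s in law]
            w = np.array([law[s] for s in law], dtype=float)
            totals = reference_trajectory.states[:, cols] @ w
            assert np.abs(totals - totals[0]).max() / totals[0] < 1e-6

    def test_reporting_grid_does_not_alter_solution(self, reference_model):
        s1 = SimulationSettings(duration=5.0, interval_size=0.1)
        s2 = SimulationSettings(duration=5.0, interval_size=0.05)
        t1 = simulate_deterministic(reference_model, settings=s1)
        t2 = simulate_deterministic(reference_model, settings=s2)
        y2 = t2.observables[::2]
        rel = np.abs(t1.observables - y2) / np.maximum(np.abs(y2), 1e-9)
        assert rel.max() < 1e-4

    def test_out_of_bounds_parameters_rejected(self, reference_model):
        p = reference_model.parameter_vector()
        p[0] = 2e4
        with pytest.raises(ValueError, match="within"):
            simulate_deterministic(reference_model, p)
        p[0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_deterministic(reference_model, p)


class TestObservables:
    def test_identity_scaling_single_component(self, reference_model, reference_trajectory):
        obs = project_observables(reference_trajectory, reference_model.observables)
        j = [o.name for o in reference_model.observables].index("Akt-pS473")
        i = reference_model.species_index["X2"]
        assert np.allclose(obs[:, j], reference_trajectory.states[:, i])

    def test_mass_observable_is_pool_sum(self, reference_model, reference_trajectory):
        tr = reference_trajectory
        total = tr.state("X20") + tr.state("X21")
        assert np.allclose(tr.observable("Mitochondrial-Mass"), total)

    def test_scaling_factor_multiplies(self, reference_model, reference_trajectory):
        import copy

        defs = copy.deepcopy(reference_model.observables)
        defs[0].scaling_factor = 2.0
        doubled = project_observables(reference_trajectory, defs)
        assert np.allclose(doubled[:, 0], 2.0 * reference_trajectory.observables[:, 0])

    def test_missing_species_raises_key_error(self, reference_trajectory):
        from senesim.network import ObservableDef

        with pytest.raises(KeyError):
            project_observables(reference_trajectory, [ObservableDef("Y", "ghost", ("X99",))])


class TestStochastic:
    def test_birth_death_stationary_mean(self):
        b, d, omega = 5.0, 1.0, 200.0
        m = birth_death_model(birth=b, death=d, x0=b / d)
        settings = SimulationSettings(duration=20.0, interval_size=0.1, seed=3, omega=omega)
        runs = simulate_stochastic(m, settings=settings, n_runs=20)
        # discard the first 5 days, average counts over time and runs
        tail = np.concatenate([r.states[r.times >= 5.0, 0] for r in runs.runs])
        assert tail.mean() == pytest.approx(b / d * omega, rel=0.05)

    def test_fixed_seed_reproducible(self, reference_model):
        settings = SimulationSettings(duration=0.5, interval_size=0.05, seed=7, omega=200)
        a = simulate_stochastic(reference_model, settings=settings, n_runs=2)
        b = simulate_stochastic(reference_model, settings=settings, n_runs=2)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.states, rb.states)

    def test_counts_are_nonnegative_integers(self, reference_model):
        settings = SimulationSettings(duration=0.5, interval_size=0.1, seed=1, omega=100)
        runs = simulate_stochastic(reference_model, settings=settings, n_runs=1)
        states = runs.runs[0].states
        assert np.all(states >= 0)
        assert np.allclose(states, np.rint(states))

    def test_conserved_totals_exact_in_counts(self, reference_model):
        from senesim.network import conservation_analysis

        settings = SimulationSettings(duration=1.0, interval_size=0.1, seed=2, omega=500)
        runs = simulate_stochastic(reference_model, settings=settings, n_runs=1)
        laws, _ = conservation_analysis(reference_model)
        st = runs.runs[0].states
        for law in laws:
            cols = [reference_model.species_index[s] for s in law]
            w = np.array([law[s] for s in law], dtype=float)
            totals = st[:, cols] @ w
            assert np.all(totals == totals[0])

    def test_absorbing_state_ends_run_quietly(self):
        m = linear_decay_model(rate=5.0, x0=1.0)
        settings = SimulationSettings(duration=10.0, interval_size=0.5, seed=1, omega=10)
        runs = simulate_stochastic(m, settings=settings, n_runs=1)
        assert runs.runs[0].states[-1, 0] == 0.0


class TestExport:
    def test_trajectory_long_format_roundtrip(self, reference_model):
        from senesim.simulate import trajectory_from_frame

        traj = simulate_deterministic(reference_model,
                                      settings=SimulationSettings(duration=2.0,
                                                                  interval_size=0.5))
        df = traj.to_frame()
        back = trajectory_from_frame(df, traj.species_ids, traj.observable_names)
        np.testing.assert_allclose(back.states, traj.states, rtol=1e-12)
        np.testing.assert_allclose(back.observables, traj.observables, rtol=1e-12)

    def test_model_summary_tables(self, reference_model):
        tables = reference_model.summary_tables()
        assert len(tables["species"]) == 23
        assert len(tables["reactions"]) == 41
        assert tables["parameters"]["fixed"].sum() == 2  # the assumed IKK-beta pair
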