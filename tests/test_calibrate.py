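"""Chi-square scoring, multistart fitting, and CC/CV identifiability."""

import numpy as np
import pandas as pd
import pytest

from senesim.calibrate import (
    Dataset,
    ErrorModel,
    FitConfig,
    FitEnsemble,
    FitResult,
    aic,
    chi_square,
    identifiability_report,
    multistart_fit,
    read_dataset,
    write_dataset,
)
from senesim.datagen import GeneratorConfig, generate_dataset
from senesim.network import NetworkModel, ObservableDef, ReactionDef, SpeciesDef
from senesim.simulate import SimulationSettings

from .conftest import three_species_chain


def dataset_from(records):
    return Dataset(pd.DataFrame(records, columns=["time", "observable", "mean", "sd", "n"]))


FAST = SimulationSettings(duration=4.0, interval_size=0.5)


class TestChiSquare:
    def test_zero_when_simulation_equals_data(self):
        m = three_species_chain()
        cfg = GeneratorConfig(m, times=(0.5, 1.0, 2.0), noise_fraction=0.0, settings=FAST)
        ds = generate_dataset(cfg)
        assert chi_square(m, None, ds, settings=FAST) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_analytic_value(self):
        # model value 1.1 vs observed 1.0 under 10% error: ((0.1)/(0.1))^2 = 1
        m = three_species_chain()
        from senesim.simulate import simulate_deterministic

        tr = simulate_deterministic(m, settings=FAST, t_eval=np.array([0.0, 1.0]))
        sim = tr.observable("B")[-1]
        ds = dataset_from([(1.0, "Y1", sim / 1.1, 0.0, 5)])
        chi2 = chi_square(m, None, ds, ErrorModel(0.10), FAST)
        assert chi2 == pytest.approx(((sim - sim / 1.1) / (0.1 * sim / 1.1)) ** 2, rel=1e-9)

    def test_observable_gauge_invariance(self):
        """Rescaling an observable's data and its scaling factor leaves chi2
        unchanged (relative error model)."""
        m = three_species_chain()
        ds = generate_dataset(GeneratorConfig(m, times=(1.0, 2.0), noise_fraction=0.05,
                                              seed=3, settings=FAST))
        chi2_a = chi_square(m, None, ds, settings=FAST)
        m2 = m.copy()
        m2.observables[0].scaling_factor *= 7.0
        rec = ds.records.copy()
        sel = rec["observable"] == "Y1"
        rec.loc[sel, "mean"] *= 7.0
        rec.loc[sel, "sd"] *= 7.0
        chi2_b = chi_square(m2, None, Dataset(rec), settings=FAST)
        assert chi2_b == pytest.approx(chi2_a, rel=1e-9)

    def test_unknown_observable_raises(self):
        m = three_species_chain()
        ds = dataset_from([(1.0, "nope", 1.0, 0.1, 3)])
        with pytest.raises(KeyError, match="nope"):
            chi_square(m, None, ds, settings=FAST)

    def test_constraint_penalty_added(self, reference_model):
        ds = generate_dataset(GeneratorConfig(reference_model, times=(1.0,),
                                              noise_fraction=0.0,
                                              settings=SimulationSettings(interval_size=0.5,
                                                                          duration=2.0)))
        p = reference_model.parameter_vector()
        base = chi_square(reference_model, p, ds,
                          settings=SimulationSettings(interval_size=0.5, duration=2.0))
        i35 = reference_model.reaction_index["k35"]
        i36 = reference_model.reaction_index["k36"]
        p2 = p.copy()
        p2[i36] = p[i35] + 1.0  # violate k36 < k35
        with_pen = chi_square(reference_model, p2, ds,
                              settings=SimulationSettings(interval_size=0.5, duration=2.0))
        lam = reference_model.constraints[0].penalty_strength
        assert with_pen > base
        assert with_pen - lam * 1.0**2 < with_pen  # hinge term present

    def test_aic_convention(self):
        assert aic(10.0, 3) == 16.0


class TestDatasetIO:
    def test_roundtrip_lossless(self, tmp_path):
        m = three_species_chain()
        ds = generate_dataset(GeneratorConfig(m, times=(0.5, 1.5), seed=2, settings=FAST))
        p = tmp_path / "data.tsv"
        write_dataset(ds, str(p))
        ds2 = read_dataset(str(p))
        pd.testing.assert_frame_equal(ds.records.reset_index(drop=True), ds2.records)

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            dataset_from([(1.0, "Y1", 1.0, -0.1, 3)])
        with pytest.raises(ValueError):
            dataset_from([(1.0, "Y1", 1.0, 0.1, 0)])


class TestMultistartFit:
    def test_noiseless_start_at_truth_stays_at_truth(self):
        m = three_species_chain()
        ds = generate_dataset(GeneratorConfig(m, times=(0.5, 1.0, 2.0, 3.0),
                                              noise_fraction=0.0, settings=FAST))
        cfg = FitConfig(n_sequences=1, fits_per_sequence=1, seed=1, settings=FAST)
        ens = multistart_fit(m, ds, ["k1", "k2"], cfg)
        best = ens.best
        assert best.chi2 == pytest.approx(0.0, abs=1e-8)
        assert best.parameters["k1"] == pytest.approx(0.8, rel=1e-3)
        assert best.parameters["k2"] == pytest.approx(1.4, rel=1e-3)

    def test_recovery_from_perturbed_starts(self):
        m = three_species_chain()
        ds = generate_dataset(GeneratorConfig(m, times=(0.5, 1.0, 2.0, 3.0),
                                              noise_fraction=0.0, settings=FAST))
        start = {"k1": 0.8 * 10**0.3, "k2": 1.4 * 10**-0.25}
        cfg = FitConfig(n_sequences=2, fits_per_sequence=3, seed=5, settings=FAST)
        ens = multistart_fit(m, ds, ["k1", "k2"], cfg, start=start)
        assert ens.best.parameters["k1"] == pytest.approx(0.8, rel=0.01)
        assert ens.best.parameters["k2"] == pytest.approx(1.4, rel=0.01)

    def test_fixed_seed_reproducible(self):
        m = three_species_chain()
        ds = generate_dataset(GeneratorConfig(m, times=(1.0, 2.0), noise_fraction=0.05,
                                              seed=4, settings=FAST))
        cfg = FitConfig(n_sequences=2, fits_per_sequence=2, seed=9, settings=FAST)
        a = multistart_fit(m, ds, ["k1", "k2"], cfg)
        b = multistart_fit(m, ds, ["k1", "k2"], cfg)
        assert [f.chi2 for f in a.fits] == [f.chi2 for f in b.fits]
        assert a.best.parameters == b.best.parameters

    def test_best_fit_not_worse_than_truth(self):
        m = three_species_chain()
        ds = generate_dataset(GeneratorConfig(m, times=(0.5, 1.0, 2.0), noise_fraction=0.0,
                                              settings=FAST))
        cfg = FitConfig(n_sequences=1, fits_per_sequence=2, seed=2, settings=FAST)
        ens = multistart_fit(m, ds, ["k1"], cfg)
        truth_chi2 = chi_square(m, None, ds, settings=FAST)
        assert ens.best.chi2 <= truth_chi2 + 1e-9


class TestFitRounds:
    def test_freeze_and_refit_schedule(self):
        """Round 2 keeps the parameter frozen in round 1 at its fitted value
        and only refits the remainder."""
        from senesim.calibrate import fit_rounds

        m = three_species_chain()
        ds = generate_dataset(GeneratorConfig(m, times=(0.5, 1.0, 2.0, 3.0),
                                              noise_fraction=0.0, settings=FAST))
        cfg = FitConfig(n_sequences=1, fits_per_sequence=2, seed=4, settings=FAST)
        rounds = [{"freeze": ["k3", "k4"]}, {"freeze": ["k1"]}]
        out = fit_rounds(m, ds, rounds, cfg)
        assert len(out) == 2
        ens1, _ = out[0]
        ens2, _ = out[1]
        assert set(ens1.free_ids) == {"k1", "k2"}
        assert set(ens2.free_ids) == {"k2"}
        assert ens2.best.parameters["k2"] == pytest.approx(1.4, rel=0.02)


def _synthetic_ensemble(param_fn, n=50, seed=0):
    rng = np.random.default_rng(seed)
    fits = []
    for i in range(n):
        pars, chi2 = param_fn(rng, i)
        fits.append(FitResult(pars, chi2, chi2 + 2 * len(pars), 10, True))
    return FitEnsemble(fits, list(fits[0].parameters), seed)


class TestIdentifiability:
    def test_constant_product_pair_flagged(self):
        # k_a * k_b == 4 across fits: perfectly anticorrelated in log space
        def gen(rng, i):
            a = 10 ** rng.normal(0, 0.5)
            return {"k_a": a, "k_b": 4.0 / a, "k_c": 1.0 + 0.01 * rng.normal()}, rng.random()

        rep = identifiability_report(_synthetic_ensemble(gen), top_fraction=1.0)
        assert ("k_a", "k_b") in rep.tuples
        assert rep.non_identifiable["k_a"] and rep.non_identifiable["k_b"]
        assert not rep.non_identifiable["k_c"]

    def test_constant_parameter_identifiable(self):
        def gen(rng, i):
            return {"k_a": 2.0, "k_b": 10 ** rng.normal(0, 0.4)}, rng.random()

        rep = identifiability_report(_synthetic_ensemble(gen), top_fraction=1.0)
        assert rep.cv["k_a"] == pytest.approx(0.0, abs=1e-12)
        assert not rep.non_identifiable["k_a"]

    def test_correlated_but_tight_parameters_pass_cv_gate(self):
        # CC > 0.9 but CV below 0.25: not flagged
        def gen(rng, i):
            a = 1.0 + 0.05 * rng.normal()
            return {"k_a": a, "k_b": 2.0 - (a - 1.0)}, rng.random()

        rep = identifiability_report(_synthetic_ensemble(gen), top_fraction=1.0)
        assert max(rep.max_abs_cc.values()) > 0.9
        assert not any(rep.non_identifiable.values())

    def test_insufficient_sample_error(self):
        def gen(rng, i):
            return {"k_a": 1.0}, rng.random()

        ens = _synthetic_ensemble(gen, n=5)
        with pytest.raises(ValueError, match="at least 3"):
            identifiability_report(ens, top_fraction=0.2)

    def test_report_deterministic(self):
        def gen(rng, i):
            a = 10 ** rng.normal(0, 0.3)
            return {"k_a": a, "k_b": 1.0 / a}, rng.random()

        ens = _synthetic_ensemble(gen)
        r1 = identifiability_report(ens)
        r2 = identifiability_report(ens)
        assert r1.cv == r2.cv and r1.tuples == r2.tuples
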