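"""Population simulations: gamma sampling, mean matching, CV comparisons,
competition paths and the heterodimer population experiment."""

import numpy as np
import pytest

from rlscale import scaling as sc
from rlscale.params import (
    LigandParams,
    ModelKind,
    ParameterDomainError,
    ReceptorConfig,
)
from rlscale.population import (
    PopulationSpec,
    compare_ligands,
    constant_complex_inhibitor_path,
    default_al_panel,
    default_ala_panel,
    default_alb_panel,
    default_heterodimer_populations,
    heterodimer_population_experiment,
    match_mean_activity,
    sample_receptors,
    simulate_population,
)


def lig(c=1.0, kp=1.0, kf=1.0, e=1.0, name=None):
    return LigandParams(concentration=c, partial_affinity=kp, full_affinity=kf,
                        activity_rate=e, name=name)


class TestSampling:
    def test_moment_matching(self):
        # gamma(mean 1, sd 0.5) <=> shape 4, scale 0.25
        spec = PopulationSpec(n_cells=100_000, mean_a=1.0, sd_a=0.5, seed=11)
        a, b = sample_receptors(spec)
        assert b is None
        assert abs(a.mean() - 1.0) < 0.01
        assert abs(a.std() - 0.5) < 0.01

    def test_zero_sd_gives_constant_population(self):
        spec = PopulationSpec(n_cells=100, mean_a=2.0, sd_a=0.0, seed=0)
        a, _ = sample_receptors(spec)
        assert np.all(a == 2.0)

    def test_seed_reproducibility(self):
        spec = PopulationSpec(n_cells=1000, mean_a=1.0, sd_a=0.5,
                              mean_b=2.0, sd_b=1.0, seed=42)
        a1, b1 = sample_receptors(spec)
        a2, b2 = sample_receptors(spec)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_subunit_correlation_knob(self):
        spec = PopulationSpec(n_cells=50_000, mean_a=1.0, sd_a=0.5,
                              mean_b=1.0, sd_b=0.5, seed=1, correlation=0.8)
        a, b = sample_receptors(spec)
        assert np.corrcoef(a, b)[0, 1] > 0.7
        assert abs(a.mean() - 1.0) < 0.02

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterDomainError):
            PopulationSpec(mean_a=0.0)
        with pytest.raises(ParameterDomainError):
            PopulationSpec(mean_b=1.0)  # sd_b missing


class TestSimulatePopulation:
    def test_monomer_cv_equals_receptor_cv(self):
        """E is linear in A0, so the response CV reproduces the receptor CV
        for every ligand in the panel."""
        spec = PopulationSpec(n_cells=100_000, mean_a=1.0, sd_a=0.5, seed=3)
        cvs = [simulate_population(ModelKind.AL, ligand, spec).cv
               for ligand in default_al_panel()]
        sample_cv = float(np.std(sample_receptors(spec)[0]) /
                          np.mean(sample_receptors(spec)[0]))
        assert np.allclose(cvs, sample_cv, rtol=1e-12)
        assert cvs[0] == pytest.approx(0.5, abs=0.01)

    def test_zero_ligand_flagged_as_undefined_cv(self):
        spec = PopulationSpec(n_cells=100, seed=0)
        resp = simulate_population(ModelKind.AL, lig(c=0.0), spec)
        assert np.isnan(resp.cv)
        assert resp.mean == 0.0

    def test_bit_identical_reruns(self):
        spec = PopulationSpec(n_cells=1000, seed=9)
        r1 = simulate_population(ModelKind.ALA, lig(kf=0.1), spec)
        r2 = simulate_population(ModelKind.ALA, lig(kf=0.1), spec)
        assert np.array_equal(r1.responses, r2.responses)

    def test_delta_method_link(self):
        """For small receptor CV, CV(E) ~ S * CV(A0) within 10%."""
        spec = PopulationSpec(n_cells=100_000, mean_a=1.0, sd_a=0.05, seed=21)
        for kf in (1e-4, 1.0, 1e4):
            ligand = lig(kf=kf)
            resp = simulate_population(ModelKind.ALA, ligand, spec)
            s = sc.local_scaling(ModelKind.ALA, ligand, ReceptorConfig(1.0)).s
            assert resp.cv == pytest.approx(s * 0.05, rel=0.10)


class TestMeanMatching:
    def test_exact(self):
        spec = PopulationSpec(n_cells=10_000, seed=5)
        matched = match_mean_activity(ModelKind.ALA, lig(kf=0.3), spec, 1.0)
        resp = simulate_population(ModelKind.ALA, matched, spec)
        assert resp.mean == pytest.approx(1.0, abs=1e-12)

    def test_linear_in_target(self):
        spec = PopulationSpec(n_cells=1000, seed=5)
        e1 = match_mean_activity(ModelKind.ALA, lig(), spec, 1.0).activity_rate
        e2 = match_mean_activity(ModelKind.ALA, lig(), spec, 2.0).activity_rate
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_monomer_ec50_value(self):
        # constant population at the EC50: mean F = 0.5, so e = 2 * target
        spec = PopulationSpec(n_cells=10, sd_a=0.0, seed=0)
        matched = match_mean_activity(ModelKind.AL, lig(), spec, 1.0)
        assert matched.activity_rate == pytest.approx(2.0, rel=1e-12)

    def test_unmatchable_zero_complexes(self):
        spec = PopulationSpec(n_cells=10, seed=0)
        with pytest.raises(ParameterDomainError):
            match_mean_activity(ModelKind.AL, lig(c=0.0), spec, 1.0)


class TestCompareLigands:
    def test_monomer_panel_equal_cvs(self):
        spec = PopulationSpec(n_cells=50_000, seed=13)
        table = compare_ligands(ModelKind.AL, default_al_panel(), spec)
        assert table.attrs["cv_ratio"] == pytest.approx(1.0, abs=1e-3)
        assert np.allclose(table["mean"], 1.0, atol=1e-12)

    def test_homodimer_panel_twofold_bound(self):
        """Mean-matched ALA ligands spanning the occupancy regimes differ in
        CV by at most twofold, approaching the bound at the extremes."""
        spec = PopulationSpec(n_cells=100_000, seed=17)
        table = compare_ligands(ModelKind.ALA, default_ala_panel(), spec)
        ratio = table.attrs["cv_ratio"]
        assert ratio <= 2.0 * 1.01
        assert ratio > 1.8

    def test_sd_tracks_scaling(self):
        """Across a matched-mean panel the response SD correlates strongly
        with the scaling at the mean cell."""
        spec = PopulationSpec(n_cells=50_000, seed=17)
        table = compare_ligands(ModelKind.ALA, default_ala_panel(), spec)
        r = np.corrcoef(table["sd"], table["scaling_at_mean"])[0, 1]
        assert r > 0.95


class TestCompetitionPath:
    def test_cv_decreases_with_inhibitor_at_constant_complex(self):
        act = lig(c=0.1, kp=1.0, kf=0.1)
        inh = lig(c=0.0, kp=1.0, kf=10.0, e=0.0)
        spec = PopulationSpec(n_cells=20_000, seed=5)
        table = constant_complex_inhibitor_path(act, inh, spec,
                                                [0, 0.02, 0.05, 0.1])
        assert np.all(np.diff(table["cv"].to_numpy()) < 0)

    def test_unrestorable_complex_raises(self):
        act = lig(c=1.0, kp=1.0, kf=0.1)  # already at the response peak
        inh = lig(c=0.0, kp=1.0, kf=10.0, e=0.0)
        spec = PopulationSpec(n_cells=100, seed=5)
        with pytest.raises(ParameterDomainError):
            constant_complex_inhibitor_path(act, inh, spec, [0, 5.0])


@pytest.fixture(scope="module")
def heterodimer_table():
    pops = default_heterodimer_populations(n_cells=50_000, seed=7)
    return heterodimer_population_experiment(pops, default_alb_panel())


class TestHeterodimerExperiment:
    def test_balanced_population_stays_near_twofold(self, heterodimer_table):
        ratios = heterodimer_table.attrs["cv_ratio_per_population"]
        assert ratios[0] <= 2.0 * 1.1

    def test_extreme_population_exceeds_order_of_magnitude(self, heterodimer_table):
        """100-fold subunit imbalance with a variable abundant subunit and a
        tight limiting subunit spreads ligand CVs by more than tenfold."""
        ratios = heterodimer_table.attrs["cv_ratio_per_population"]
        assert ratios[3] > 10.0
        assert ratios[3] > ratios[0]

    def test_single_ligand_degenerates_to_one_cv_per_population(self):
        pops = default_heterodimer_populations(n_cells=2000, seed=7)[:2]
        table = heterodimer_population_experiment(pops, [lig(name="only")])
        assert len(table) == 2
        assert set(table.attrs["cv_ratio_per_population"].values()) == {1.0}

    def test_requires_two_subunit_specs(self):
        with pytest.raises(ParameterDomainError):
            heterodimer_population_experiment(
                [PopulationSpec(n_cells=10, seed=0)], [lig()]
            )
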