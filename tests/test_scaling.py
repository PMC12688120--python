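"""Local scaling metric: numeric log-derivative as ground truth, closed-form
accelerators, regime limits, invariances and parameter scans."""

import numpy as np
import pytest
from scipy.optimize import brentq

from rlscale import equilibria as eq
from rlscale import scaling as sc
from rlscale.params import (
    LigandParams,
    ModelKind,
    ParameterDomainError,
    ReceptorConfig,
)
from rlscale.population import competition_full_complex

from conftest import log_uniform, random_ligand


def lig(c=1.0, kp=1.0, kf=1.0, e=1.0):
    return LigandParams(concentration=c, partial_affinity=kp, full_affinity=kf,
                        activity_rate=e)


class TestMonomerScaling:
    def test_identically_one_on_log_grid(self):
        """The monomeric response is linear in A0, so S = 1 for every ligand
        parameter combination."""
        for kpc in np.logspace(-4, 4, 20):
            for a0 in np.logspace(-2, 2, 20):
                res = sc.local_scaling(ModelKind.AL, lig(kp=kpc), ReceptorConfig(a0))
                assert res.s == pytest.approx(1.0, abs=1e-6)

    def test_undefined_at_zero_ligand(self):
        with pytest.raises(sc.UndefinedScalingError):
            sc.local_scaling(ModelKind.AL, lig(c=0.0), ReceptorConfig(1.0))


class TestHomodimerScaling:
    def test_quadratic_regime(self):
        # K_P*C = 1, K_F*A0 << 1: F ~ A0^2, S -> 2
        res = sc.local_scaling(ModelKind.ALA, lig(kf=1e-6), ReceptorConfig(1.0))
        assert res.s == pytest.approx(2.0, abs=1e-3)

    def test_linear_regime(self):
        # K_F*A0 >> 1: most subunits pair up, S -> 1
        res = sc.local_scaling(ModelKind.ALA, lig(kf=1e8), ReceptorConfig(1.0))
        assert res.s == pytest.approx(1.0, abs=1e-3)

    def test_closed_form_endpoints_against_numeric(self):
        lo = sc.local_scaling(ModelKind.ALA, lig(kf=1e-8), ReceptorConfig(1.0))
        hi = sc.local_scaling(ModelKind.ALA, lig(kf=1e8), ReceptorConfig(1.0))
        assert sc.scaling_from_bound_fraction_ala(0.0) == 2.0
        assert sc.scaling_from_bound_fraction_ala(1.0) == 1.0
        assert lo.s == pytest.approx(2.0, abs=1e-4)
        assert hi.s == pytest.approx(1.0, abs=1e-4)

    def test_closed_form_matches_numeric_over_random_draws(self, rng):
        """S = 2/(1 + 2F/A0) agrees with the numeric log-derivative to 1e-4
        over 100 random ALA parameter draws."""
        for _ in range(100):
            ligand = random_ligand(rng)
            a0 = float(log_uniform(rng, 1e-2, 1e2))
            res = sc.local_scaling(ModelKind.ALA, ligand, ReceptorConfig(a0))
            assert res.s == pytest.approx(
                sc.scaling_from_bound_fraction_ala(res.bound_fraction), abs=1e-4
            )

    def test_rejects_bound_fraction_outside_unit_interval(self):
        with pytest.raises(ParameterDomainError):
            sc.scaling_from_bound_fraction_ala(1.5)

    def test_scaling_collapses_onto_bound_fraction(self):
        """Two ligands engineered to reach the same occupancy have the same
        scaling, whatever their individual parameters."""
        ref = sc.local_scaling(ModelKind.ALA, lig(kp=1.0, kf=2.0), ReceptorConfig(1.0))

        def f_at(kf):
            state = eq.solve_ala(lig(c=1.0, kp=10.0, kf=kf), ReceptorConfig(1.0))
            return 2 * state.species["F"] - ref.bound_fraction

        kf2 = brentq(f_at, 1e-8, 1e8, xtol=1e-14)
        other = sc.local_scaling(ModelKind.ALA, lig(kp=10.0, kf=kf2), ReceptorConfig(1.0))
        assert other.s == pytest.approx(ref.s, abs=1e-6)

    def test_monotone_nonincreasing_in_bound_fraction(self):
        table = sc.scan_scaling(ModelKind.ALA,
                                kp_c=np.logspace(-3, 3, 13),
                                kf_a0=np.logspace(-3, 3, 13))
        table = table.sort_values("bound_fraction")
        assert np.all(np.diff(table["S"].to_numpy()) <= 1e-4)


class TestInhibitorBreaksCollapse:
    def test_equal_complex_different_scaling(self):
        """A zero-activity competitor makes S depend on more than F_L: two
        settings with identical activator complex amounts differ in scaling
        by more than 0.05."""
        act = lig(c=0.1, kp=1.0, kf=0.1)
        inh0 = lig(c=0.0, kp=1.0, kf=10.0, e=0.0)
        inh = inh0.with_(concentration=0.1)
        a0 = 1.0

        def s_of(a, i):
            return float(sc.numeric_scaling(
                lambda m: competition_full_complex(a, i, a0 * m)
            ))

        f_target = float(competition_full_complex(act, inh0, a0))
        c_l = brentq(
            lambda c: float(
                competition_full_complex(act.with_(concentration=c), inh, a0)
            ) - f_target,
            0.1, 1.0,  # stay on the rising branch of the dose-response
        )
        matched = act.with_(concentration=c_l)
        assert float(competition_full_complex(matched, inh, a0)) == pytest.approx(
            f_target, rel=1e-9
        )
        assert abs(s_of(act, inh0) - s_of(matched, inh)) > 0.05


class TestHeterodimerScaling:
    def test_unoccupied_limit_is_linear(self):
        s_a, s_b = sc.scaling_alb_closed(ReceptorConfig(1.0, 1.0), 1e-12)
        assert s_a == pytest.approx(1.0, abs=1e-9)
        assert s_b == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_case(self):
        full = 2 - np.sqrt(3)
        s_a, s_b = sc.scaling_alb_closed(ReceptorConfig(1.0, 1.0), full)
        assert s_a == pytest.approx(1 / (1 + full), rel=1e-12)
        assert s_b == pytest.approx(s_a, rel=1e-12)
        res = sc.local_scaling(ModelKind.ALB_SEQ, lig(), ReceptorConfig(1.0, 1.0),
                               subunit="A")
        assert res.s == pytest.approx(1 / (1 + full), abs=1e-6)

    def test_abundant_subunit_scaling_vanishes_at_saturation(self):
        # saturating affinities with B >> A: extra B cannot raise F
        res = sc.local_scaling(
            ModelKind.ALB_SEQ, lig(kp=1e4, kf=1e4), ReceptorConfig(1.0, 100.0),
            subunit="B",
        )
        assert 0 <= res.s < 0.01

    def test_closed_forms_match_numeric_over_random_draws(self, rng):
        for _ in range(100):
            ligand = random_ligand(rng)
            receptors = ReceptorConfig(
                a_total=float(log_uniform(rng, 0.1, 10)),
                b_total=float(log_uniform(rng, 0.1, 10)),
            )
            res = sc.local_scaling(ModelKind.ALB_SEQ, ligand, receptors, subunit="A")
            full = float(eq.alb_seq_full_complex(
                ligand, receptors.a_total, receptors.b_total
            ))
            s_a, s_b = sc.scaling_alb_closed(receptors, full)
            assert res.s_a == pytest.approx(s_a, abs=1e-4)
            assert res.s_b == pytest.approx(s_b, abs=1e-4)

    def test_sum_rule(self, rng):
        """Perturbing both totals jointly gives S_A + S_B."""
        for _ in range(20):
            ligand = random_ligand(rng)
            receptors = ReceptorConfig(
                a_total=float(log_uniform(rng, 0.1, 10)),
                b_total=float(log_uniform(rng, 0.1, 10)),
            )
            res = sc.local_scaling(ModelKind.ALB_SEQ, ligand, receptors, subunit="both")
            assert res.s == pytest.approx(res.s_a + res.s_b, abs=1e-6)

    def test_subunit_b_requires_heterodimer(self):
        with pytest.raises(ParameterDomainError):
            sc.local_scaling(ModelKind.ALA, lig(), ReceptorConfig(1.0), subunit="B")


def test_activity_rate_independence_is_exact():
    """S never touches e: results for e = 1 and e = 7.3 are bit-identical."""
    for model, receptors in [
        (ModelKind.ALA, ReceptorConfig(1.0)),
        (ModelKind.ALB_SEQ, ReceptorConfig(1.0, 3.0)),
    ]:
        r1 = sc.local_scaling(model, lig(kf=0.3, e=1.0), receptors)
        r2 = sc.local_scaling(model, lig(kf=0.3, e=7.3), receptors)
        assert r1.s == r2.s


def test_nonlinear_response_rescales_scaling(rng):
    """With E = e F^n the scaling is exactly n times the linear value."""
    for _ in range(20):
        ligand = random_ligand(rng)
        receptors = ReceptorConfig(1.0)
        base = sc.local_scaling(ModelKind.ALA, ligand, receptors).s
        for n in (0.5, 2.0, 3.7):
            res = sc.local_scaling(ModelKind.ALA, ligand, receptors, exponent=n)
            assert res.s == pytest.approx(n * base, rel=1e-12)


class TestScan:
    def test_monomer_scan_constant(self):
        table = sc.scan_scaling(ModelKind.AL, kp_c=np.logspace(-4, 4, 9),
                                kf_a0=[1.0])
        assert np.allclose(table["S"], 1.0, atol=1e-6)

    def test_homodimer_scan_spans_one_to_two(self):
        table = sc.scan_scaling(ModelKind.ALA,
                                kp_c=np.logspace(-4, 4, 17),
                                kf_a0=np.logspace(-6, 6, 17))
        assert table["S"].min() >= 1.0 - 1e-4
        assert table["S"].max() <= 2.0 + 1e-4
        assert table["S"].min() == pytest.approx(1.0, abs=0.01)
        assert table["S"].max() == pytest.approx(2.0, abs=0.01)

    def test_heterodimer_scan_per_subunit_unit_interval(self):
        table = sc.scan_scaling(ModelKind.ALB_SEQ,
                                kp_c=np.logspace(-3, 3, 9),
                                kf_a0=np.logspace(-3, 3, 9),
                                ratios=[1e-3, 0.5, 1e3])
        for col in ("S_A", "S_B"):
            assert table[col].min() >= -1e-4
            assert table[col].max() <= 1.0 + 1e-4
        # near-zero scaling for the abundant subunit at saturation
        assert table.loc[table.a0_over_b0 == 1e3, "S_A"].min() < 0.01
        assert table.loc[table.a0_over_b0 == 1e-3, "S_B"].min() < 0.01

    def test_scan_schema(self):
        table = sc.scan_scaling(ModelKind.ALA, kp_c=[1.0], kf_a0=[1.0])
        assert list(table.columns) == [
            "model", "kp_c", "kf_a0", "a0_over_b0", "S", "S_A", "S_B",
            "bound_fraction",
        ]
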