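import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrkin.model import (
    ApparentParams,
    DegenerateCycleError,
    EquilibriumParams,
    RateParameters,
    apparent_post_params,
    build_coupled_scheme,
    build_single_substrate_scheme,
    cycle_closure,
    eq_to_rates,
    initial_rate_short_time,
    michaelis_constants,
    rates_to_eq,
)

positive_rates = st.floats(min_value=1e-6, max_value=1e4,
                           allow_nan=False, allow_infinity=False)


class TestRateParameters:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="kcat_E"):
            RateParameters(kcat_E=-1.0)

    def test_keq_properties(self, default_params):
        assert default_params.Keq_E == pytest.approx(2.0)
        assert default_params.Keq_ES == pytest.approx(3.0)

    def test_dict_roundtrip(self, default_params):
        d = default_params.to_dict()
        assert set(d) == {"k1", "k_m1", "kcat_E", "kcat_Estar",
                          "kE", "k_mE", "kES", "k_mES"}
        assert RateParameters.from_dict(d) == default_params


class TestCycleClosure:
    def test_symmetric_exchange(self):
        p = RateParameters(kE_fwd=0.5, kE_rev=0.5, kES_fwd=0.5, kES_rev=0.5,
                           k_off=1.0)
        assert cycle_closure(p) == pytest.approx(1.0)

    def test_table_like_ratio(self):
        # Keq(E)=7, Keq(ES)=76, k_off=10 -> 7/76*10
        p = RateParameters(kE_fwd=7.0, kE_rev=1.0, kES_fwd=76.0, kES_rev=1.0,
                           k_off=10.0)
        assert cycle_closure(p) == pytest.approx(7.0 / 76.0 * 10.0, rel=1e-12)
        assert cycle_closure(p) == pytest.approx(0.921052631578947, rel=1e-10)

    def test_zero_dissociation(self):
        p = RateParameters(k_off=0.0, kE_fwd=3.0, kE_rev=0.1)
        assert cycle_closure(p) == 0.0

    def test_degenerate_cycle_names_rate(self):
        with pytest.raises(DegenerateCycleError, match="kE_rev"):
            cycle_closure(RateParameters(kE_rev=0.0))
        with pytest.raises(DegenerateCycleError, match="kES_fwd"):
            cycle_closure(RateParameters(kES_fwd=0.0))

    @given(kE_fwd=positive_rates, kE_rev=positive_rates,
           kES_fwd=positive_rates, kES_rev=positive_rates,
           k_off=positive_rates)
    @settings(max_examples=50, deadline=None)
    def test_detailed_balance_around_cycle(self, kE_fwd, kE_rev, kES_fwd,
                                           kES_rev, k_off):
        """Products of rates around the closed cycle agree in both directions."""
        p = RateParameters(kE_fwd=kE_fwd, kE_rev=kE_rev, kES_fwd=kES_fwd,
                           kES_rev=kES_rev, k_off=k_off)
        k_off_star = cycle_closure(p)
        # E -> ES -> E*S -> E* -> E (k1 S, kES_fwd, k_off_star, kE_rev)
        # vs the reverse direction (kE_fwd, k1 S, kES_rev, k_off); the k1*S
        # factors cancel.
        fwd = kES_fwd * k_off_star * kE_rev
        rev = kE_fwd * kES_rev * k_off
        assert fwd == pytest.approx(rev, rel=1e-10)


class TestEquilibriumConversion:
    def test_symmetric(self):
        assert eq_to_rates(EquilibriumParams(Keq=1.0, kex=2.0)) == \
            pytest.approx((1.0, 1.0))

    def test_table_like_values(self):
        fwd, rev = eq_to_rates(EquilibriumParams(Keq=7.0, kex=0.0074))
        assert fwd == pytest.approx(0.006475, rel=1e-12)
        assert rev == pytest.approx(0.000925, rel=1e-12)

    @given(keq=st.floats(1e-4, 1e4), kex=st.floats(1e-6, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip(self, keq, kex):
        fwd, rev = eq_to_rates(EquilibriumParams(Keq=keq, kex=kex))
        back = rates_to_eq(fwd, rev)
        assert back.Keq == pytest.approx(keq, rel=1e-12)
        assert back.kex == pytest.approx(kex, rel=1e-12)

    def test_invalid_keq(self):
        with pytest.raises(ValueError):
            EquilibriumParams(Keq=0.0, kex=1.0)
        with pytest.raises(ValueError):
            EquilibriumParams(Keq=-2.0, kex=1.0)


class TestMichaelisConstants:
    def test_zero_rates(self):
        p = RateParameters(kcat_E=0.0, k_off=0.0)
        km_e, _ = michaelis_constants(p)
        assert km_e == 0.0

    def test_km_e_value(self):
        p = RateParameters(k1=0.2, kcat_E=0.1, k_off=10.0)
        km_e, _ = michaelis_constants(p)
        assert km_e == pytest.approx(50.5)

    def test_symmetry(self):
        p = RateParameters(k1=0.2, k_off=5.0, kcat_E=0.3, kcat_Estar=0.3,
                           kE_fwd=0.01, kE_rev=0.01, kES_fwd=0.01, kES_rev=0.01)
        km_e, km_estar = michaelis_constants(p)
        assert km_estar == pytest.approx(km_e, rel=1e-12)

    def test_k1_zero_raises(self):
        with pytest.raises(ValueError):
            michaelis_constants(RateParameters(k1=0.0))


class TestApparentPostParams:
    def test_degenerate_two_state(self):
        p = RateParameters(k1=0.2, k_off=5.0, kcat_E=0.3, kcat_Estar=0.3,
                           kE_fwd=0.02, kE_rev=0.01, kES_fwd=0.02, kES_rev=0.01)
        app = apparent_post_params(p)
        km_e, _ = michaelis_constants(p)
        assert app.KM_app == pytest.approx(km_e, rel=1e-12)
        assert app.kcat_app == pytest.approx(p.kcat_E, rel=1e-12)

    def test_dead_estar_limit(self):
        p = RateParameters(k1=0.2, k_off=5.0, kcat_E=0.3, kcat_Estar=0.0,
                           kE_fwd=0.01, kE_rev=0.01,
                           kES_fwd=100.0, kES_rev=1e-4)  # Keq(ES) = 1e6
        app = apparent_post_params(p)
        assert app.kcat_app < 1e-6 * p.kcat_E * 10

    def test_division_safe_with_zero_kcat_e(self):
        p = RateParameters(k1=0.2, k_off=5.0, kcat_E=0.0, kcat_Estar=0.4,
                           kE_fwd=0.01, kE_rev=0.01, kES_fwd=0.02, kES_rev=0.01)
        app = apparent_post_params(p)
        keq_es = 2.0
        assert app.kcat_app == pytest.approx(keq_es * 0.4 / (1 + keq_es), rel=1e-12)

    def test_published_apo_efficiency(self, apo_demethylation_params):
        # APO demethylation row: KM 2.3 uM, kcat 0.032 1/s, efficiency 14 +/- 7
        app = apparent_post_params(apo_demethylation_params)
        assert app.KM_app == pytest.approx(2.3, rel=1e-9)
        assert app.kcat_app == pytest.approx(0.032, rel=1e-9)
        assert app.efficiency == pytest.approx(13.913, abs=1e-3)
        assert abs(app.efficiency - 14.0) < 7.0

    def test_efficiency_unit_conversion(self):
        app = ApparentParams(KM_app=2.0, kcat_app=0.01)
        assert app.efficiency == pytest.approx(5.0)


class TestInitialRateShortTime:
    def test_factorized_form_when_keq_e_zero(self):
        p = RateParameters(k1=0.2, k_off=5.0, kcat_E=0.3, kcat_Estar=0.1,
                           kE_fwd=0.0, kE_rev=1.0, kES_fwd=0.01, kES_rev=0.01)
        km_e, km_estar = michaelis_constants(p)
        for s in (5.0, 50.0, 500.0):
            expected = 0.2 * p.kcat_E / ((1 + km_e / s) * (1 + km_estar / s))
            assert initial_rate_short_time(p, s, 0.2) == \
                pytest.approx(expected, rel=1e-12)

    def test_saturating_limit(self):
        p = RateParameters(k1=0.2, k_off=5.0, kcat_E=0.4, kcat_Estar=0.2,
                           kE_fwd=0.01, kE_rev=0.01, kES_fwd=0.01, kES_rev=0.01)
        v = initial_rate_short_time(p, 1e9, 0.2)
        # population-weighted kcat: 0.2*(0.4 + 0.2*1)/(1+1) = 0.06
        assert v == pytest.approx(0.06, rel=1e-6)

    def test_no_enzyme(self, default_params):
        assert initial_rate_short_time(default_params, 100.0, 0.0) == 0.0

    def test_monotone_in_substrate(self, default_params):
        s = np.logspace(-1, 4, 40)
        v = [initial_rate_short_time(default_params, x, 0.2) for x in s]
        assert np.all(np.diff(v) > 0)

    def test_nonpositive_substrate(self, default_params):
        with pytest.raises(ValueError):
            initial_rate_short_time(default_params, 0.0, 0.2)


class TestSingleSubstrateScheme:
    def test_structure(self, default_params):
        scheme = build_single_substrate_scheme(default_params)
        assert len(scheme.species) == 6
        assert len(scheme.reactions) == 10
        assert len(scheme.conserved_totals) == 2

    def test_conserved_totals_stoichiometric(self, default_params):
        scheme = build_single_substrate_scheme(default_params)
        n = scheme.stoichiometry()
        for _, members in scheme.conserved_totals:
            indicator = np.zeros(len(scheme.species))
            indicator[list(members)] = 1.0
            assert np.allclose(indicator @ n, 0.0)

    def test_rhs_zero_at_brute_force_equilibrium(self, default_params):
        """Root-find the fixed point with substrate clamped, check RHS."""
        from scipy.optimize import fsolve

        p = default_params.replace(kcat_E=0.0, kcat_Estar=0.0)
        scheme = build_single_substrate_scheme(p)
        idx = scheme.index
        s_fixed, e_tot = 30.0, 1.0

        def residual(x):
            # x = (E, Estar, ES); E*S from enzyme conservation
            y = np.zeros(6)
            y[idx["E"]], y[idx["Estar"]], y[idx["ES"]] = x
            y[idx["EstarS"]] = e_tot - x.sum()
            y[idx["S"]] = s_fixed
            dy = scheme.rhs(y)
            return [dy[idx["E"]], dy[idx["Estar"]], dy[idx["ES"]]]

        sol = fsolve(residual, [0.25, 0.25, 0.25], full_output=True)
        x, _, ier, _ = sol
        assert ier == 1
        y = np.zeros(6)
        y[idx["E"]], y[idx["Estar"]], y[idx["ES"]] = x
        y[idx["EstarS"]] = e_tot - x.sum()
        y[idx["S"]] = s_fixed
        dy = scheme.rhs(y)
        # all enzyme-species derivatives vanish at the fixed point
        for sp in ("E", "Estar", "ES", "EstarS"):
            assert abs(dy[idx[sp]]) < 1e-10

    def test_detailed_balance_at_equilibrium(self, default_params):
        """Null eigenvector of the 4-state rate matrix satisfies detailed
        balance on every edge (cycle closure at work)."""
        p = default_params.replace(kcat_E=0.0, kcat_Estar=0.0)
        s = 25.0
        k_on = p.k1 * s
        # states: E, ES, E*S, E*
        q = np.zeros((4, 4))
        pairs = [
            (0, 1, k_on, p.k_off),
            (1, 2, p.kES_fwd, p.kES_rev),
            (2, 3, p.k_off_star, k_on),
            (3, 0, p.kE_rev, p.kE_fwd),
        ]
        for i, j, kf, kr in pairs:
            q[j, i] += kf
            q[i, i] -= kf
            q[i, j] += kr
            q[j, j] -= kr
        w, v = np.linalg.eig(q)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = pi / pi.sum()
        for i, j, kf, kr in pairs:
            assert pi[i] * kf == pytest.approx(pi[j] * kr, rel=1e-10)

    def test_unresolved_rate_reference_rejected(self, default_params):
        from nmrkin.model import Reaction, SchemeSpec

        with pytest.raises(ValueError, match="unresolved"):
            SchemeSpec(species=("A", "B"),
                       reactions=(Reaction(("A",), ("B",), "nope"),),
                       rates={})

    def test_broken_conservation_rejected(self):
        from nmrkin.model import Reaction, SchemeSpec

        with pytest.raises(ValueError, match="conserved"):
            SchemeSpec(species=("A", "B"),
                       reactions=(Reaction(("A",), ("A", "B"), "k"),),
                       rates={"k": 1.0},
                       conserved_totals=(("both", (0, 1)),))


class TestCoupledScheme:
    def _params(self, kcat=0.5):
        return RateParameters(k1=0.2, k_off=10.0, kcat_E=kcat, kcat_Estar=0.1,
                              kE_fwd=0.004, kE_rev=0.002,
                              kES_fwd=0.003, kES_rev=0.001)

    def test_conserved_totals_declared(self):
        scheme = build_coupled_scheme(self._params(), self._params(0.3),
                                      self._params(0.2), self._params(0.4))
        names = [n for n, _ in scheme.conserved_totals]
        assert "enzyme" in names
        assert "peptide" in names
        assert "acetyl" in names

    def test_shared_kinetics_flag_conflicts(self):
        with pytest.raises(ValueError, match="shared_kinetics"):
            build_coupled_scheme(self._params(), self._params(),
                                 self._params(), None, shared_kinetics=True)
        with pytest.raises(ValueError, match="explicit dual"):
            build_coupled_scheme(self._params(), self._params())

    def test_decoupling_limit(self):
        """Independent sites + no dual substrate == two separate single fits."""
        from nmrkin.integrate import integrate_scheme

        p_me, p_ac = self._params(0.5), self._params(0.3)
        coupled = build_coupled_scheme(p_me, p_ac, single_occupancy=False,
                                       shared_kinetics=True)
        t = np.linspace(0.0, 2000.0, 41)
        e0 = 0.3
        pe = 1.0 / (1.0 + p_me.Keq_E)
        init = {"K4meK9": 80.0, "K4K9ac": 50.0,
                "EL": e0 * pe, "ELstar": e0 * (1 - pe),
                "EH": e0 * pe, "EHstar": e0 * (1 - pe)}
        traj_c = integrate_scheme(coupled, init, t, method="lsoda")

        for p_single, sub, s0 in ((p_me, "K4meK9", 80.0), (p_ac, "K4K9ac", 50.0)):
            single = build_single_substrate_scheme(p_single)
            traj_s = integrate_scheme(
                single, {"S": s0, "E": e0 * pe, "Estar": e0 * (1 - pe)}, t,
                method="lsoda")
            np.testing.assert_allclose(traj_c[sub], traj_s["S"], atol=1e-5)

    def test_peptide_conservation_and_acetate_yield(self):
        from nmrkin.integrate import integrate_scheme

        scheme = build_coupled_scheme(self._params(), self._params(0.3),
                                      self._params(0.2), self._params(0.4))
        t = np.linspace(0.0, 200000.0, 30)
        init = {"K4meK9ac": 60.0, "K4meK9": 20.0, "K4K9ac": 10.0,
                "E": 0.5, "Estar": 0.0}
        traj = integrate_scheme(scheme, init, t, method="lsoda")
        drift = traj.conserved_drift()
        assert drift["peptide"] < 1e-6
        assert drift["acetyl"] < 1e-6
        # run to completion: all acetyl marks released as acetate
        assert traj["acetate"][-1] == pytest.approx(70.0, abs=1e-3)
        assert traj["K4K9"][-1] == pytest.approx(90.0, abs=1e-3)

    def test_single_occupancy_shares_one_pool(self):
        scheme = build_coupled_scheme(self._params(), self._params(0.3),
                                      self._params(), self._params())
        assert "E" in scheme.species
        assert "EL" not in scheme.species
        scheme2 = build_coupled_scheme(self._params(), self._params(0.3),
                                       self._params(), self._params(),
                                       single_occupancy=False)
        assert "EL" in scheme2.species and "EH" in scheme2.species
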