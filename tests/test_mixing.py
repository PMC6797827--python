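"""End-member mixing: forward model, inversion, anomalies, ratio diagram."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mofette as m
from mofette.mixing import grid_search_fraction


def soil_gas(site, depth, gas_profiles):
    return next(g for g in gas_profiles if g.site == site and g.depth_cm == depth)


class TestPredictMixture:
    def test_endpoints_reproduce_end_members(self, pair):
        shared = pair.shared_species()
        at0 = m.predict_mixture(0.0, pair)
        at1 = m.predict_mixture(1.0, pair)
        for sp in shared:
            assert at0.conc[sp] == pytest.approx(pair.air.get(sp, "half"))
            assert at1.conc[sp] == pytest.approx(pair.deep.get(sp, "half"))

    def test_linearity_midpoint(self, pair):
        # CO2: deep 983, air 0.41 mmol/mol -> 491.705 mmol/mol at f = 0.5
        mid = m.predict_mixture(0.5, pair)
        assert mid.conc["CO2"] == pytest.approx(491_705, rel=1e-12)

    def test_f_outside_unit_interval_rejected(self, pair):
        with pytest.raises(ValueError):
            m.predict_mixture(1.5, pair)

    @given(f=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_closure_is_linear_in_f(self, f, pair):
        """Σ_s mix(f)_s = f Σ_s deep_s + (1-f) Σ_s air_s."""
        mix = m.predict_mixture(f, pair)
        total = sum(mix.conc.values())
        t_air = sum(pair.air.get(s, "half") for s in pair.shared_species())
        t_deep = sum(pair.deep.get(s, "half") for s in pair.shared_species())
        assert total == pytest.approx(f * t_deep + (1 - f) * t_air, rel=1e-12)


class TestMixingCurve:
    def test_grid_endpoints_and_monotonicity(self, pair):
        curve = m.mixing_curve(pair)
        assert len(curve) == 101
        co2 = [c.conc["CO2"] for _, c in curve]
        assert co2[0] == pytest.approx(410)
        assert co2[-1] == pytest.approx(983_000)
        assert all(a < b for a, b in zip(co2, co2[1:]))

    def test_reversed_grid_gives_reversed_curve(self, pair):
        fwd = m.mixing_curve(pair, [0.0, 0.3, 0.9])
        rev = m.mixing_curve(pair, [0.9, 0.3, 0.0])
        assert [f for f, _ in rev] == [f for f, _ in fwd][::-1]
        assert rev[0][1].conc == fwd[-1][1].conc

    def test_empty_grid_rejected(self, pair):
        with pytest.raises(ValueError):
            m.mixing_curve(pair, [])


class TestInversion:
    def test_site8_argon_fraction(self, gas_profiles, pair):
        # obs Ar 4.6, air 9.34, deep 1.1 mmol/mol -> f = 4.74/8.24
        obs = soil_gas("8", 20, gas_profiles)
        fit = m.infer_deep_fraction(obs, pair, "Ar")
        assert fit.f == pytest.approx(0.5752, abs=1e-4)
        assert not fit.clipped
        assert fit.residuals["Ar"] == pytest.approx(0, abs=1e-9)

    def test_identity_on_end_members(self, pair):
        for tracer in ("Ar", "CO2", "N2"):
            assert m.infer_deep_fraction(pair.deep, pair, tracer).f == pytest.approx(1.0)
            assert m.infer_deep_fraction(pair.air, pair, tracer).f == pytest.approx(0.0)

    def test_closed_form_matches_grid_search_on_field_table(self, gas_profiles, pair):
        """Closed-form inversion equals a brute-force grid minimizer."""
        for obs in gas_profiles:
            if obs.site == "BP":
                continue
            for tracer in ("Ar", "CO2"):
                fit = m.infer_deep_fraction(obs, pair, tracer)
                brute = grid_search_fraction(obs, pair, tracer)
                assert fit.f == pytest.approx(brute, abs=1e-4)

    def test_species_set_least_squares_recovers_pure_mixture(self, pair):
        mix = m.predict_mixture(0.37, pair)
        fit = m.infer_deep_fraction(mix, pair, ("Ar", "CO2", "N2"))
        assert fit.f == pytest.approx(0.37, abs=1e-9)

    def test_out_of_range_fraction_clips_with_flag(self, gas_profiles, pair):
        # site 4 has Ar above the air value -> raw f < 0
        obs = soil_gas("4", 40, gas_profiles)
        fit = m.infer_deep_fraction(obs, pair, "Ar")
        assert fit.f == 0.0 and fit.clipped

    def test_degenerate_tracer_rejected(self, pair):
        # deep differs from air in CO2 only: Ar cannot anchor the inversion
        conc = {sp: pair.air.get(sp, "half") for sp in pair.shared_species()}
        conc["CO2"] = 983_000.0
        degenerate = m.EndMemberPair(
            air=pair.air, deep=m.GasComposition(site="same", depth_cm=None, conc=conc)
        )
        obs = m.predict_mixture(0.5, pair)
        with pytest.raises(ValueError, match="degenerate"):
            m.infer_deep_fraction(obs, degenerate, "Ar")

    def test_identical_end_members_rejected(self, pair):
        same = m.GasComposition(
            site="same", depth_cm=None,
            conc={sp: pair.air.get(sp, "half") for sp in pair.shared_species()},
        )
        with pytest.raises(ValueError, match="identical"):
            m.EndMemberPair(air=pair.air, deep=same)

    def test_fraction_increases_with_depth_at_sites_3_and_5(self, gas_profiles, pair):
        """CO2 rises monotonically downhole, so inferred f must too."""
        for site in ("3", "5"):
            fs = [
                m.infer_deep_fraction(g, pair, "CO2").f
                for g in gas_profiles
                if g.site == site
            ]
            assert all(a < b for a, b in zip(fs, fs[1:]))

    @given(f=st.floats(0.001, 0.999), tracer=st.sampled_from(["Ar", "CO2", "N2"]))
    @settings(max_examples=100, deadline=None)
    def test_noiseless_round_trip(self, f, tracer, pair):
        mix = m.predict_mixture(f, pair)
        assert m.infer_deep_fraction(mix, pair, tracer).f == pytest.approx(f, abs=1e-6)


class TestAnomalies:
    def test_ch4_depletion_at_site8(self, gas_profiles, pair):
        # predicted CH4 at f(Ar)=0.575 is ~72.7 μmol/mol vs observed 41
        obs = soil_gas("8", 20, gas_profiles)
        fit = m.infer_deep_fraction(obs, pair, "Ar")
        pred_ch4 = fit.f * 125 + (1 - fit.f) * 1.9
        assert pred_ch4 == pytest.approx(72.7, abs=0.3)
        flags = m.compute_anomalies(obs, fit, pair)
        assert flags.ch4_depletion is True

    def test_n2_excess_at_site4_40cm_with_co2_anchor(self, gas_profiles, pair):
        obs = soil_gas("4", 40, gas_profiles)
        fit = m.infer_deep_fraction(obs, pair, "CO2")
        assert fit.f == pytest.approx(0.0169, abs=2e-4)
        flags = m.compute_anomalies(obs, fit, pair)
        assert flags.n2_excess is True

    def test_sample_on_mixing_curve_has_no_flags(self, pair):
        mix = m.predict_mixture(0.4, pair)
        fit = m.infer_deep_fraction(mix, pair, "Ar")
        flags = m.compute_anomalies(mix, fit, pair)
        assert not flags.any_process()

    def test_field_pattern_matches_survey(self, gas_profiles, pair):
        """The qualitative process pattern of the survey: N2 excess on the
        rim/back-slope, CO2 excess at sites 5-6, CH4 depletion where the
        deep-gas share is high (methane oxidation)."""
        def flags_for(site, depth):
            return m.classify_sample(soil_gas(site, depth, gas_profiles), pair)

        # N2 excess at sites 3 and 4 and shallow site 5
        assert any(flags_for("3", d).n2_excess for d in (10, 20, 30, 40, 50))
        assert any(flags_for("4", d).n2_excess for d in (10, 20, 30, 40, 50))
        assert any(flags_for("5", d).n2_excess for d in (10, 20, 30, 40))
        # CO2 excess at site 5 and site 6 (10-30 cm)
        assert any(flags_for("5", d).co2_excess for d in (10, 20, 30, 40, 50))
        assert any(flags_for("6", d).co2_excess for d in (10, 20, 30))
        # CH4 depletion at deep site 6 and site 8
        assert any(flags_for("6", d).ch4_depletion for d in (40, 50))
        assert all(flags_for("8", d).ch4_depletion for d in (10, 20))


class TestRatioDiagram:
    def test_pool_coordinates(self, gas_profiles):
        pool = next(g for g in gas_profiles if g.site == "BP")
        ar_ch4, co2_n2 = m.ratio_diagram_coords(pool)
        assert ar_ch4 == pytest.approx(8.8, rel=1e-6)  # 1100/125 μmol/mol
        assert co2_n2 == pytest.approx(983 / 16, rel=1e-6)

    def test_identical_concentrations_give_unit_ratio(self):
        g = m.GasComposition(
            site="x", depth_cm=1,
            conc={"Ar": 5.0, "CH4": 5.0, "CO2": 7.0, "N2": 7.0},
        )
        assert m.ratio_diagram_coords(g) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_censored_denominator_uses_policy(self, gas_profiles):
        g = m.GasComposition(
            site="x", depth_cm=1,
            conc={"Ar": 10.0, "CO2": 7.0, "N2": 7.0}, censored={"CH4": 2.0},
        )
        ar_ch4, _ = m.ratio_diagram_coords(g, policy="limit")
        assert ar_ch4 == pytest.approx(5.0)

    def test_as_printed_unit_convention(self, gas_profiles):
        pool = next(g for g in gas_profiles if g.site == "BP")
        ar_ch4, _ = m.ratio_diagram_coords(pool, same_units=False)
        assert ar_ch4 == pytest.approx(1.1 / 125, rel=1e-6)


class TestSyntheticRecovery:
    def test_noiseless_profiles_lie_on_curve(self, pair):
        profs, truth = m.gen_gas_profiles(
            pair, {10: 0.05, 20: 0.2, 30: 0.5, 40: 0.8, 50: 0.95}, seed=3
        )
        for p in profs:
            true_f = truth.true_f_by_depth[str(p.depth_cm)]
            assert m.infer_deep_fraction(p, pair, "Ar").f == pytest.approx(true_f, abs=1e-6)

    def test_noisy_tracer_median_error_small(self, pair):
        """2% relative noise on the tracer: median |f̂ - f| < 0.02."""
        errs = []
        for s in range(500):
            profs, truth = m.gen_gas_profiles(pair, {10: 0.4}, noise_cv=0.02, seed=s)
            fit = m.infer_deep_fraction(profs[0], pair, "Ar")
            errs.append(abs(fit.f - 0.4))
        assert np.median(errs) < 0.02

    def test_ch4_perturbation_flags_only_methane_oxidation(self, pair):
        profs, _ = m.gen_gas_profiles(
            pair, {30: 0.6}, perturbations={"CH4": 0.5}, seed=0
        )
        flags = m.classify_sample(profs[0], pair)
        assert flags.ch4_depletion is True
        assert not flags.n2_excess and not flags.co2_excess
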