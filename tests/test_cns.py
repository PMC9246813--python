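"""CNS core: clearance assembly, pathway split, steady state, conservation."""

import dataclasses

import numpy as np
import pytest

from btbpk import datasets
from btbpk.cns import (
    CNSModelSpec,
    af_from_kpuu,
    build_clearances,
    simulate_cns,
    steady_state_kpuu,
)
from btbpk.errors import DomainError
from btbpk.physchem import DrugProperties
from btbpk.plasma import DoseEvent, PlasmaPKModel

INFUSION = [DoseEvent("iv_infusion", amount=200000.0, start=0.0, duration=100000.0)]


def _spec(drug_name, plasma_name, rat, **kw):
    return CNSModelSpec(
        drug=datasets.load_drug(drug_name),
        physiology=rat,
        plasma=datasets.load_plasma_model(plasma_name),
        **kw,
    )


class TestClearanceAssembly:
    def test_temozolomide_is_paracellular_dominant(self, tmz_spec):
        cs = build_clearances(tmz_spec)
        assert cs.paracellular_share >= 0.996

    def test_letrozole_is_transcellular_dominant(self, rat):
        cs = build_clearances(_spec("letrozole", "letrozole", rat))
        assert cs.paracellular_share == pytest.approx(0.10, abs=0.03)

    def test_ppa_correction_halves_paracellular_only(self, tmz_spec):
        base = build_clearances(tmz_spec)
        corrected = build_clearances(
            dataclasses.replace(tmz_spec, ppa_correction=2.0)
        )
        assert corrected.cl_para == pytest.approx(base.cl_para / 2.0, rel=1e-12)
        for name in ("cl_tc_in", "cl_tc_out", "cl_ecf_bulk", "q_cbf", "cl_wo",
                     "cl_ow", "cl_lyso", "cl_para_bcsfb"):
            assert getattr(corrected, name) == getattr(base, name)

    def test_af_pattern_for_all_control_kpuu(self, rat):
        """Every measured control-brain Kp_uu < 1 resolves to net efflux."""
        ref = datasets.load_reference_results()["kpuu"]["rat"]
        for model_name, rec in ref.items():
            drug = datasets.plasma_model_drug(model_name)
            spec = CNSModelSpec(
                drug=datasets.load_drug(drug),
                physiology=rat,
                plasma=datasets.load_plasma_model(model_name),
                kpuu_ecf_target=rec["control"],
            )
            cs = build_clearances(spec)
            assert cs.af_in == 1.0
            assert cs.af_out >= 1.0


class TestSteadyState:
    def test_symmetric_passive_is_unity(self):
        from btbpk.cns import ClearanceSet

        cs = ClearanceSet(cl_para=1.0, cl_tc_in=0.5, cl_tc_out=0.5, cl_ecf_bulk=0.0)
        assert steady_state_kpuu(cs) == 1.0

    def test_monotone_vanishing_with_efflux(self):
        from btbpk.cns import ClearanceSet

        values = [
            steady_state_kpuu(
                ClearanceSet(cl_para=1.0, cl_tc_in=0.5, cl_tc_out=0.5, af_out=af)
            )
            for af in (1.0, 10.0, 100.0, 1e4)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 0.01

    def test_scale_invariance(self, mtx_spec):
        cs = build_clearances(mtx_spec)
        scaled = dataclasses.replace(
            cs,
            cl_para=cs.cl_para * 7.0, cl_tc_in=cs.cl_tc_in * 7.0,
            cl_tc_out=cs.cl_tc_out * 7.0, cl_ecf_bulk=cs.cl_ecf_bulk * 7.0,
        )
        assert steady_state_kpuu(scaled) == pytest.approx(
            steady_state_kpuu(cs), rel=1e-12
        )

    @pytest.mark.parametrize("kpuu", np.logspace(-3, 1, 9).tolist())
    def test_af_round_trip(self, kpuu, mtx_spec):
        cs = dataclasses.replace(build_clearances(mtx_spec), af_in=1.0, af_out=1.0)
        af_in, af_out = af_from_kpuu(kpuu, cs)
        back = steady_state_kpuu(
            dataclasses.replace(cs, af_in=af_in, af_out=af_out)
        )
        assert back == pytest.approx(kpuu, rel=1e-6)
        assert (af_in == 1.0) or (af_out == 1.0)

    def test_passive_kpuu_returns_unit_afs(self, tmz_spec):
        cs = build_clearances(tmz_spec)
        assert af_from_kpuu(steady_state_kpuu(cs), cs) == (1.0, 1.0)

    def test_inconsistent_kpuu_rejected(self):
        from btbpk.cns import ClearanceSet

        cs = ClearanceSet(cl_para=1.0, cl_tc_in=0.0, cl_tc_out=0.5)
        with pytest.raises(DomainError):
            af_from_kpuu(5.0, cs)  # needs influx but no influx route

    def test_closed_form_matches_long_time_simulation(self, rat):
        """Constant infusion to steady state: ECF/plasma equals the closed form."""
        for drug_name, plasma_name, kpuu in [
            ("temozolomide", "temozolomide", None),
            ("methotrexate", "methotrexate_sham", 0.114),
            ("letrozole", "letrozole", 0.786),
        ]:
            spec = _spec(drug_name, plasma_name, rat, kpuu_ecf_target=kpuu)
            cs = build_clearances(spec)
            res = simulate_cns(spec, INFUSION, [50000.0, 90000.0])
            ratio = (
                res.profiles["ecf"].values[-1] / res.profiles["plasma"].values[-1]
            )
            assert ratio == pytest.approx(steady_state_kpuu(cs), rel=0.01)


class TestSimulation:
    def test_zero_dose_stays_zero(self, tmz_spec):
        res = simulate_cns(tmz_spec, [], np.linspace(1, 100, 5))
        for prof in res.profiles.values():
            assert np.all(prof.values == 0.0)

    @pytest.mark.parametrize(
        "drug_name,plasma_name",
        [
            ("temozolomide", "temozolomide"),
            ("methotrexate", "methotrexate_sham"),
            ("letrozole", "letrozole"),
            ("ganciclovir", "ganciclovir"),
        ],
    )
    def test_mass_balance_closed(self, drug_name, plasma_name, rat):
        """Dosed = in-system + eliminated within 0.1% at every output time."""
        spec = _spec(drug_name, plasma_name, rat)
        doses = (
            [DoseEvent("depot", 5000.0)]
            if spec.plasma.k_a is not None
            else [DoseEvent("iv_bolus", 5000.0)]
        )
        res = simulate_cns(spec, doses, np.linspace(30.0, 600.0, 20))
        assert res.mass_balance_error().max() < 1e-3

    def test_dose_proportionality(self, tmz_spec, times):
        one = simulate_cns(tmz_spec, [DoseEvent("iv_bolus", 1000.0)], times)
        two = simulate_cns(tmz_spec, [DoseEvent("iv_bolus", 2000.0)], times)
        for name in ("plasma", "ecf", "icf", "csf_sas"):
            assert np.allclose(
                two.profiles[name].values, 2 * one.profiles[name].values, rtol=1e-10
            )

    def test_non_negative_states(self, mtx_spec, times):
        res = simulate_cns(mtx_spec, [DoseEvent("iv_bolus", 12500.0)], times)
        assert np.all(res.states >= -1e-12)

    def test_expm_matches_ode_route(self, mtx_spec):
        t = np.linspace(5.0, 360.0, 20)
        doses = [DoseEvent("iv_bolus", 12500.0)]
        a = simulate_cns(mtx_spec, doses, t, method="expm").profiles["ecf"].values
        b = simulate_cns(mtx_spec, doses, t, method="ode").profiles["ecf"].values
        mask = a > 1e-6 * a.max()
        assert np.max(np.abs(a[mask] - b[mask]) / a[mask]) < 1e-6

    def test_acid_exposure_falls_with_acidic_ecf(self, rat):
        """Acidic ECF raises the unionized fraction on the brain side, boosting
        transcellular efflux: steady-state ECF exposure of an acid falls."""
        acid = DrugProperties("probe_acid", 300.0, "acid", 1.0, pka_acid=4.0)
        plasma = PlasmaPKModel(structure="one_compartment", cl_cen=5.0, v_cen=200.0)
        kp = {}
        for ph in (7.30, 6.80):
            phys = dataclasses.replace(rat, ph_ecf=ph)
            spec = CNSModelSpec(drug=acid, physiology=phys, plasma=plasma)
            kp[ph] = steady_state_kpuu(build_clearances(spec))
        assert kp[6.80] < kp[7.30]
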