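"""Empirical plasma models: closed-form simulation, residual error, fitting."""

import numpy as np
import pytest

from btbpk import datasets
from btbpk.errors import DomainError, EstimationError
from btbpk.plasma import (
    ConcentrationTimeProfile,
    DoseEvent,
    PlasmaPKModel,
    apply_ruv,
    fit_plasma,
    simulate_plasma,
)

ALL_MODELS = [
    ("rat", name) for name in datasets.plasma_model_names("rat")
] + [("human", name) for name in datasets.plasma_model_names("human")]


def _dose_for(model):
    if model.k_a is not None:
        return [DoseEvent("depot", amount=5000.0, start=0.0)]
    return [DoseEvent("iv_bolus", amount=5000.0, start=0.0)]


class TestSimulate:
    def test_bolus_initial_condition(self):
        m = PlasmaPKModel(structure="one_compartment", cl_cen=5.0, v_cen=250.0)
        prof = simulate_plasma(m, [DoseEvent("iv_bolus", 1000.0)], [0.0, 1.0])
        # amount/volume at t=0+: 1000 ug / 250 mL = 4 ug/mL = 4000 ng/mL
        assert prof.values[0] == pytest.approx(1000.0 / 250.0 * 1000.0)

    def test_depot_lag_zero_before_onset(self):
        m = datasets.load_plasma_model("ganciclovir")
        times = [5.0, 10.0, 19.0, 19.29, 25.0, 60.0]
        prof = simulate_plasma(m, [DoseEvent("depot", 5000.0)], times)
        assert np.all(prof.values[np.array(times) < m.lag] == 0.0)
        assert prof.values[-1] > 0.0

    @pytest.mark.parametrize("species,name", ALL_MODELS)
    def test_closed_form_matches_ode(self, species, name):
        """Matrix-exponential and LSODA solutions agree to 1e-6 relative."""
        m = datasets.load_plasma_model(name, species)
        doses = _dose_for(m)
        times = np.linspace(1.0, 480.0, 60)
        a = simulate_plasma(m, doses, times, method="expm").values
        b = simulate_plasma(m, doses, times, method="ode").values
        mask = a > 1e-6 * a.max()
        assert np.max(np.abs(a[mask] - b[mask]) / a[mask]) < 1e-6

    def test_dose_linearity(self):
        m = datasets.load_plasma_model("methotrexate_sham")
        times = np.linspace(1, 300, 30)
        one = simulate_plasma(m, [DoseEvent("iv_bolus", 1000.0)], times).values
        two = simulate_plasma(
            m,
            [DoseEvent("iv_bolus", 1000.0), DoseEvent("iv_infusion", 1000.0, 0.0, 30.0)],
            times,
        ).values
        inf = simulate_plasma(
            m, [DoseEvent("iv_infusion", 1000.0, 0.0, 30.0)], times
        ).values
        assert np.allclose(two, one + inf, rtol=1e-9)
        doubled = simulate_plasma(m, [DoseEvent("iv_bolus", 2000.0)], times).values
        assert np.allclose(doubled, 2 * one, rtol=1e-12)

    def test_zero_eta_equals_population(self):
        m = datasets.load_plasma_model("methotrexate_healthy")
        times = np.linspace(1, 120, 10)
        d = [DoseEvent("iv_bolus", 1000.0)]
        assert np.array_equal(
            simulate_plasma(m, d, times).values,
            simulate_plasma(m, d, times, eta=(0.0, 0.0)).values,
        )

    def test_unsorted_times_rejected(self):
        m = datasets.load_plasma_model("cisplatin")
        with pytest.raises(DomainError):
            simulate_plasma(m, [DoseEvent("iv_bolus", 100.0)], [10.0, 5.0])

    def test_negative_dose_rejected(self):
        with pytest.raises(DomainError):
            DoseEvent("iv_bolus", -1.0)


class TestResidualError:
    def _pred(self):
        return ConcentrationTimeProfile(
            times=np.arange(1.0, 101.0), values=np.full(100, 500.0)
        )

    def test_zero_sigmas_identity(self):
        m = PlasmaPKModel(structure="one_compartment", cl_cen=1.0, v_cen=10.0)
        out, n_floored = apply_ruv(self._pred(), m, np.random.default_rng(1))
        assert np.array_equal(out.values, self._pred().values)
        assert n_floored == 0

    def test_seeded_replay_bit_identical(self):
        m = PlasmaPKModel(
            structure="one_compartment", cl_cen=1.0, v_cen=10.0,
            sigma_prop=0.2, sigma_add=5.0,
        )
        a, _ = apply_ruv(self._pred(), m, np.random.default_rng(42))
        b, _ = apply_ruv(self._pred(), m, np.random.default_rng(42))
        assert np.array_equal(a.values, b.values)

    def test_proportional_sd_law_of_large_numbers(self):
        m = PlasmaPKModel(
            structure="one_compartment", cl_cen=1.0, v_cen=10.0, sigma_prop=0.1
        )
        pred = ConcentrationTimeProfile(
            times=np.arange(1.0, 100001.0), values=np.full(100000, 1000.0)
        )
        out, _ = apply_ruv(pred, m, np.random.default_rng(7))
        assert np.std(out.values) / 1000.0 == pytest.approx(0.1, rel=0.01)


class TestFit:
    TRUE = PlasmaPKModel(structure="one_compartment", cl_cen=5.0, v_cen=250.0)
    DOSES = [DoseEvent("iv_bolus", 5000.0)]

    def test_noise_free_recovery(self):
        times = np.linspace(2.0, 300.0, 25)
        prof = simulate_plasma(self.TRUE, self.DOSES, times)
        fit = fit_plasma([prof], "one_compartment", self.DOSES, seed=1, n_starts=3)
        assert fit.clearance == pytest.approx(5.0, rel=1e-3)
        assert fit.v_cen == pytest.approx(250.0, rel=1e-3)

    def test_monte_carlo_clearance_bias(self):
        """Median CL bias over 20 seeded replicates stays below 2%."""
        times = np.linspace(2.0, 300.0, 100)
        clean = simulate_plasma(self.TRUE, self.DOSES, times)
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = ConcentrationTimeProfile(
                times=times,
                values=np.maximum(clean.values * (1 + rng.normal(0, 0.1, 100)), 1e-9),
            )
            fit = fit_plasma([noisy], "one_compartment", self.DOSES,
                             seed=seed, n_starts=1)
            estimates.append(fit.clearance)
        bias = np.median(np.asarray(estimates) - 5.0) / 5.0
        assert abs(bias) < 0.02

    def test_constant_zero_data_rejected(self):
        prof = ConcentrationTimeProfile(
            times=np.linspace(1, 10, 10), values=np.zeros(10)
        )
        with pytest.raises(EstimationError):
            fit_plasma([prof], "one_compartment", self.DOSES)

    def test_underdetermined_structure_rejected(self):
        prof = ConcentrationTimeProfile(times=[1.0, 2.0], values=[5.0, 4.0])
        with pytest.raises(EstimationError):
            fit_plasma([prof], "two_compartment", self.DOSES)
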