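"""VPC envelopes, the relative-accuracy statistic, sensitivity scans."""

import dataclasses
import math

import numpy as np
import pytest

from btbpk import datasets
from btbpk.cns import CNSModelSpec, simulate_cns
from btbpk.designs import transcellular_probe_design, vpc_design
from btbpk.errors import ConfigurationError, DomainError
from btbpk.evaluation import (
    relative_accuracy,
    sensitivity_scan,
    vpc,
    vpc_coverage,
)
from btbpk.plasma import ConcentrationTimeProfile, DoseEvent
from btbpk.synthetic import generate_study


def _profile(values):
    values = np.asarray(values, dtype=float)
    return ConcentrationTimeProfile(
        times=np.arange(1.0, values.size + 1), values=values
    )


class TestRelativeAccuracy:
    def test_identity_gives_zero(self):
        obs = [_profile([10.0, 20.0, 30.0])]
        rep = relative_accuracy(obs, [obs[0].values.copy()])
        assert rep.ra_drug == 0.0
        assert rep.twofold_fraction == 1.0
        assert rep.m_total == 3

    def test_uniform_twofold_overprediction(self):
        obs = [_profile([10.0, 20.0])]
        rep = relative_accuracy(obs, [2 * obs[0].values])
        assert rep.ra_drug == pytest.approx(math.log10(2.0), abs=1e-9)
        assert rep.twofold_fraction == 1.0

    def test_mixed_two_individual_case(self):
        """Two individuals, m = (2, 1), prediction/observation ratios
        (2, 2, 0.5): RA = (1/3)(log2 + log2 - log2) = 0.10034."""
        obs = [_profile([1.0, 1.0]), _profile([1.0])]
        preds = [np.array([2.0, 2.0]), np.array([0.5])]
        rep = relative_accuracy(obs, preds)
        assert rep.ra_drug == pytest.approx(0.10034, abs=1e-5)
        assert rep.m_per_individual == [2, 1]
        assert rep.m_total == 3
        assert rep.n_individuals == 2

    def test_antisymmetric_under_swap(self):
        obs = [_profile([3.0, 7.0, 11.0])]
        pred = [np.array([4.0, 5.0, 30.0])]
        fwd = relative_accuracy(obs, pred).ra_drug
        swapped = relative_accuracy([_profile(pred[0])], [obs[0].values]).ra_drug
        assert swapped == pytest.approx(-fwd, abs=1e-12)

    def test_twofold_fraction_matches_brute_force(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(3.0, 1.0, 50)
        preds = values * rng.lognormal(0.0, 0.5, 50)
        rep = relative_accuracy([_profile(values)], [preds])
        brute = sum(
            1 for o, p in zip(values, preds) if 0.5 * o <= p <= 2.0 * o
        ) / 50.0
        assert rep.twofold_fraction == pytest.approx(brute, abs=1e-12)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(DomainError):
            relative_accuracy([_profile([1.0, 2.0])], [np.array([1.0])])


class TestVPC:
    def test_degenerate_distribution_collapses_band(self):
        design = dataclasses.replace(
            transcellular_probe_design(seed=2, n_subjects=2, sigma_prop=0.0),
            omega=(0.0, 0.0),
        )
        ds = generate_study(design)
        band = vpc(ds, "plasma", n_sim=5, seed=1)
        assert np.allclose(band.lower_2_5, band.median)
        assert np.allclose(band.upper_97_5, band.median)

    def test_seeded_determinism(self):
        ds = generate_study(vpc_design(seed=3, n_subjects=2))
        a = vpc(ds, "plasma", n_sim=10, seed=4)
        b = vpc(ds, "plasma", n_sim=10, seed=4)
        assert np.array_equal(a.median, b.median)
        assert np.array_equal(a.lower_2_5, b.lower_2_5)
        assert np.array_equal(a.upper_97_5, b.upper_97_5)

    def test_band_width_grows_with_residual_sd(self):
        widths = {}
        for sigma in (0.05, 0.3):
            design = dataclasses.replace(
                vpc_design(seed=5, n_subjects=2),
                omega=(0.0, 0.0),
                sigma=(sigma, 0.0),
            )
            ds = generate_study(design)
            band = vpc(ds, "plasma", n_sim=40, seed=6)
            widths[sigma] = np.mean(band.upper_97_5 - band.lower_2_5)
        assert widths[0.3] > widths[0.05]

    def test_n_sim_floor(self):
        ds = generate_study(vpc_design(seed=3, n_subjects=2))
        with pytest.raises(DomainError):
            vpc(ds, "plasma", n_sim=1, seed=0)

    def test_coverage_requires_observations(self):
        ds = generate_study(vpc_design(seed=3, n_subjects=2))
        band = vpc(ds, "plasma", n_sim=5, seed=0)
        assert 0.0 <= vpc_coverage(band, ds, "plasma") <= 1.0


class TestSensitivityScan:
    def _spec(self, rat):
        return CNSModelSpec(
            drug=datasets.load_drug("methotrexate"),
            physiology=rat,
            plasma=datasets.load_plasma_model("methotrexate_sham"),
            kpuu_ecf_target=0.114,
        )

    def test_single_point_grid_equals_baseline(self, rat, times):
        spec = self._spec(rat)
        doses = [DoseEvent("iv_bolus", 12500.0)]
        sim = lambda s: simulate_cns(s, doses, times)  # noqa: E731
        table = sensitivity_scan(spec, "ppa_correction", [1.0], sim)
        base = sim(spec).profiles["ecf"]
        assert table.loc[0, "cmax"] == pytest.approx(base.values.max())
        assert table.loc[0, "auc"] == pytest.approx(
            np.trapezoid(base.values, times)
        )

    def test_ppa_reduction_lowers_ecf_cmax_monotonically(self, rat, times):
        """Paracellular-dominant acid: increasing the correction factor
        (reducing PPA) lowers ECF Cmax."""
        spec = self._spec(rat)
        doses = [DoseEvent("iv_bolus", 12500.0)]
        table = sensitivity_scan(
            spec, "ppa_correction", [1.0, 5.0, 14.0, 50.0],
            lambda s: simulate_cns(s, doses, times),
        )
        cmax = table["cmax"].to_numpy()
        assert np.all(np.diff(cmax) < 0)

    def test_decoupled_parameter_is_flat(self, rat, times):
        """Lysosomal pH has no handle on a neutral drug (PHF = 1 on both
        sides regardless)."""
        spec = CNSModelSpec(
            drug=datasets.load_drug("temozolomide"),
            physiology=rat,
            plasma=datasets.load_plasma_model("temozolomide"),
        )
        doses = [DoseEvent("iv_bolus", 5000.0)]
        table = sensitivity_scan(
            spec, "physiology.ph_lyso", [4.0, 5.0, 6.0],
            lambda s: simulate_cns(s, doses, times),
        )
        assert table["cmax"].nunique() == 1
        assert table["auc"].nunique() == 1

    def test_unknown_parameter_lists_valid_names(self, rat, times):
        spec = self._spec(rat)
        with pytest.raises(ConfigurationError, match="ppa_correction"):
            sensitivity_scan(
                spec, "no_such_knob", [1.0],
                lambda s: simulate_cns(s, [], times),
            )
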