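"""Tumor extension: BTB construction, fold-change semantics, equivalences."""

import dataclasses

import numpy as np
import pytest

from btbpk import datasets
from btbpk.cns import CNSModelSpec, ClearanceSet, build_clearances
from btbpk.errors import ConfigurationError, DomainError
from btbpk.physiology import TumorPathophysiology, fill_healthy_defaults
from btbpk.plasma import DoseEvent
from btbpk.tumor import (
    FoldChanges,
    TumorModelSpec,
    apply_fold_changes,
    build_btb_clearances,
    resolved_btb,
    simulate_tumor,
)


def _healthy_mirror_tumor(rat, volume=0.1):
    """A 'tumor' whose per-volume properties equal the healthy brain."""
    t = TumorPathophysiology(
        model_name="mirror", species="rat", tumor_volume=volume,
        f_mv=rat.f_mv, f_ecf=rat.f_ecf, ph_ecf=rat.ph_ecf,
        ph_icf=rat.ph_icf, cbf_tumor=rat.cbf,
    )
    return fill_healthy_defaults(t, rat)


def _mtx_tumor_spec(rat, folds, tumor_name="RG-2", **base_kw):
    base = CNSModelSpec(
        drug=datasets.load_drug("methotrexate"),
        physiology=rat,
        plasma=datasets.load_plasma_model("methotrexate_sham"),
        kpuu_ecf_target=0.114,
        ppa_correction=base_kw.pop("ppa_correction", 14.0),
    )
    return TumorModelSpec(
        base=base, tumor=datasets.load_tumor(tumor_name), folds=folds, **base_kw
    )


class TestFoldChangeSemantics:
    BTB = ClearanceSet(cl_para=2.0, cl_tc_in=0.4, cl_tc_out=0.3, cl_ecf_bulk=0.05)

    def test_identity_folds_reproduce_control_barrier(self):
        out = apply_fold_changes(self.BTB, (1.0, 1.3), FoldChanges(1.0, 1.0))
        assert out.cl_para == self.BTB.cl_para
        # active component (1.3-1)*cl_tc_out restored as an explicit term
        assert out.act_out == pytest.approx(0.3 * 0.3)
        assert out.total_out == pytest.approx(2.0 + 1.3 * 0.3)
        assert out.total_in == self.BTB.total_in

    def test_pore_fold_scales_paracellular_linearly(self):
        out = apply_fold_changes(self.BTB, (1.0, 1.0), FoldChanges(2.0, 1.0))
        assert out.cl_para == pytest.approx(4.0)
        assert out.cl_tc_in == self.BTB.cl_tc_in

    def test_quadratic_pore_option(self):
        out = apply_fold_changes(
            self.BTB, (1.0, 1.0), FoldChanges(3.0, 1.0), pore_scaling="quadratic"
        )
        assert out.cl_para == pytest.approx(2.0 * 9.0)

    def test_negative_efflux_fold_reverses_to_influx(self):
        """The printed letrozole case: control AF_out 1.30, fold -1.17 gives a
        net active influx of magnitude 1.17*0.30*CL_tc,out."""
        out = apply_fold_changes(self.BTB, (1.0, 1.30), FoldChanges(1.0, -1.17))
        assert out.act_out == 0.0
        assert out.act_in == pytest.approx(1.17 * 0.30 * 0.3)

    def test_zero_fold_abolishes_active_transport(self):
        out = apply_fold_changes(self.BTB, (1.0, 5.0), FoldChanges(1.0, 0.0))
        assert out.act_in == 0.0 and out.act_out == 0.0

    def test_af_mode_applies_fold_to_af_directly(self):
        out = apply_fold_changes(
            self.BTB, (1.0, 2.0), FoldChanges(1.0, 0.5), efflux_mode="af"
        )
        # f*AF*tc_out = 0.5*2*0.3 = 0.3 -> equals passive, no active term
        assert out.act_out == pytest.approx(0.0)
        assert out.act_in == pytest.approx(0.0)

    def test_non_passive_input_rejected(self):
        btb = dataclasses.replace(self.BTB, af_out=2.0)
        with pytest.raises(DomainError):
            apply_fold_changes(btb, (1.0, 1.0), FoldChanges(1.0, 1.0))

    def test_f_pore_must_be_positive(self):
        with pytest.raises(DomainError):
            FoldChanges(0.0, 1.0)


class TestTumorModel:
    def test_mirror_tumor_tracks_control_brain(self, rat, times):
        """Same per-volume physiology + identity folds => identical ECF courses."""
        base = CNSModelSpec(
            drug=datasets.load_drug("temozolomide"),
            physiology=rat,
            plasma=datasets.load_plasma_model("temozolomide"),
        )
        spec = TumorModelSpec(
            base=base, tumor=_healthy_mirror_tumor(rat), folds=FoldChanges(1.0, 1.0)
        )
        res = simulate_tumor(spec, [DoseEvent("iv_bolus", 5000.0)], times)
        ecf = res.profiles["ecf"].values
        t_ecf = res.profiles["t_ecf"].values
        assert np.allclose(t_ecf, ecf, rtol=1e-9)
        assert np.allclose(
            res.profiles["t_icf"].values, res.profiles["icf"].values, rtol=1e-9
        )

    def test_unresolved_tumor_rejected(self, rat):
        bare = TumorPathophysiology(
            model_name="x", species="rat", tumor_volume=0.1,
            f_mv=3.0, f_ecf=20.0, ph_ecf=7.1, ph_icf=7.2, cbf_tumor=1.0,
        )
        base = CNSModelSpec(
            drug=datasets.load_drug("temozolomide"),
            physiology=rat,
            plasma=datasets.load_plasma_model("temozolomide"),
        )
        with pytest.raises(ConfigurationError):
            TumorModelSpec(base=base, tumor=bare, folds=FoldChanges(1.0, 1.0))

    def test_volume_scaling(self, rat, times):
        """Doubling tumor volume doubles inflow/bulk-flow clearances but leaves
        the concentration courses unchanged (per-volume dynamics)."""
        spec1 = _mtx_tumor_spec(rat, FoldChanges(2.66, 1.0))
        tumor2 = dataclasses.replace(
            spec1.tumor, tumor_volume=2 * spec1.tumor.tumor_volume
        )
        spec2 = dataclasses.replace(spec1, tumor=tumor2)
        btb1, btb2 = build_btb_clearances(spec1), build_btb_clearances(spec2)
        assert btb2.q_cbf == pytest.approx(2 * btb1.q_cbf)
        assert btb2.cl_ecf_bulk == pytest.approx(2 * btb1.cl_ecf_bulk)
        doses = [DoseEvent("iv_bolus", 12500.0)]
        a = simulate_tumor(spec1, doses, times).profiles["t_ecf"].values
        b = simulate_tumor(spec2, doses, times).profiles["t_ecf"].values
        assert np.allclose(a, b, rtol=1e-3)

    def test_exposure_monotone_in_folds(self, rat, times):
        doses = [DoseEvent("iv_bolus", 12500.0)]

        def auc(f_pore, f_efflux):
            spec = _mtx_tumor_spec(rat, FoldChanges(f_pore, f_efflux))
            v = simulate_tumor(spec, doses, times).profiles["t_ecf"].values
            return np.trapezoid(v, times)

        pore_grid = [auc(f, 1.0) for f in (0.5, 1.0, 2.0, 8.0)]
        assert all(a <= b * (1 + 1e-9) for a, b in zip(pore_grid, pore_grid[1:]))
        efflux_grid = [auc(2.0, f) for f in (-0.5, 0.0, 0.5, 2.0)]
        assert all(a >= b * (1 - 1e-9) for a, b in zip(efflux_grid, efflux_grid[1:]))

    def test_matched_ratio_fold_pairs_coincide(self, rat, times):
        """For a paracellular-dominant drug, fold pairs with the same
        pore/efflux ratio give nearly identical tumor ECF profiles."""
        doses = [DoseEvent("iv_bolus", 12500.0)]
        base = simulate_tumor(
            _mtx_tumor_spec(rat, FoldChanges(2.66, 0.392)), doses, times
        ).profiles["t_ecf"].values
        for r in (0.5, 2.0, 4.0):
            alt = simulate_tumor(
                _mtx_tumor_spec(rat, FoldChanges(2.66 * r, 0.392 * r)), doses, times
            ).profiles["t_ecf"].values
            assert np.max(np.abs(alt - base) / base) < 0.05

    def test_effective_pore_size_patient_b(self, human):
        """Patient-B pore fold times the base pore radius: 2210 x 0.7 nm."""
        folds = datasets.load_reference_results()["fold_changes"]["cases"]
        patient_b = next(
            c for c in folds if c["case"] == "methotrexate_human"
        )["patients"]["B"]
        assert patient_b["pore"] * human.pore_radius_base == pytest.approx(1547.0)
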