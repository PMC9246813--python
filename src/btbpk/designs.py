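"""Reference synthetic-study designs.

Three named designs cover the regimes the analysis workflow must handle;
their parameters are the package's fixed study conditions (documented in
docs/methods.md) rather than tuning knobs.

``transcellular_probe_design``
    A neutral probe drug with a meaningful transcellular share (~45% of
    passive barrier transport), moderate control-brain asymmetry and a
    slow-equilibrating tumor: the regime where the two BTB fold changes are
    jointly identifiable from sparse dialysate data.

``paracellular_ridge_design``
    Methotrexate in an RG-2-like glioma: paracellular transport dominates
    and the tumor ECF tracks plasma quasi-instantaneously, so pore-size and
    efflux fold changes trade off along a ridge — the regime where the
    identifiability diagnostic must fire.

``vpc_design``
    A design with inter-individual variability on the plasma parameters,
    used for predictive-check calibration.
"""

from __future__ import annotations

import numpy as np

from . import datasets
from .physchem import DrugProperties
from .plasma import DoseEvent, PlasmaPKModel
from .synthetic import StudyDesign, default_schedule
from .tumor import FoldChanges

__all__ = [
    "transcellular_probe_design",
    "paracellular_ridge_design",
    "vpc_design",
]

#: Neutral probe compound: MW and logP chosen so the corrected BBB carries
#: roughly equal paracellular and transcellular passive clearance.
PROBE_DRUG = DrugProperties(
    name="probe", mw=300.0, charge_class="neutral", logp=-0.3, fup=1.0
)

PROBE_PLASMA = PlasmaPKModel(
    structure="two_compartment",
    cl_cen=5.0, q_cen_per=8.0, v_cen=200.0, v_per=300.0,
    sigma_prop=0.15, sigma_add=0.0,
)


def transcellular_probe_design(
    seed: int,
    n_subjects: int = 6,
    sigma_prop: float = 0.15,
    folds: FoldChanges = FoldChanges(2.5, 0.35),
) -> StudyDesign:
    """Probe drug, BT4C-like tumor, 20-min bins over 0-360 min."""
    return StudyDesign(
        name="transcellular_probe",
        drug=PROBE_DRUG,
        physiology=datasets.load_physiology("rat"),
        tumor=datasets.load_tumor("BT4C"),
        plasma=PROBE_PLASMA,
        dosing=(DoseEvent("iv_bolus", amount=5000.0, start=0.0),),
        control_kpuu=0.9,
        true_ppa_correction=40.0,
        true_folds=folds,
        seed=seed,
        schedule=tuple(default_schedule(360.0, 20.0)),
        bin_width=20.0,
        n_subjects=n_subjects,
        omega=(0.0, 0.0),
        sigma=(sigma_prop, 0.0),
        lloq=0.0,
        sampling_mode="interval_mean",
    )


def paracellular_ridge_design(
    seed: int,
    n_subjects: int = 6,
    sigma_prop: float = 0.15,
    folds: FoldChanges = FoldChanges(2.66, 0.392),
) -> StudyDesign:
    """Methotrexate / RG-2-like study: paracellular-dominant, ridge regime."""
    return StudyDesign(
        name="paracellular_ridge",
        drug=datasets.load_drug("methotrexate"),
        physiology=datasets.load_physiology("rat"),
        tumor=datasets.load_tumor("RG-2"),
        plasma=datasets.load_plasma_model("methotrexate_sham"),
        dosing=(DoseEvent("iv_bolus", amount=12500.0, start=0.0),),
        control_kpuu=0.114,
        true_ppa_correction=14.0,
        true_folds=folds,
        seed=seed,
        schedule=tuple(default_schedule(360.0, 20.0)),
        bin_width=20.0,
        n_subjects=n_subjects,
        omega=(0.0, 0.0),
        sigma=(sigma_prop, 0.0),
        lloq=0.0,
        sampling_mode="interval_mean",
    )


def vpc_design(seed: int, n_subjects: int = 4) -> StudyDesign:
    """Probe design with 30%/20% IIV on plasma CL/V, point sampling."""
    return StudyDesign(
        name="vpc_probe",
        drug=PROBE_DRUG,
        physiology=datasets.load_physiology("rat"),
        tumor=datasets.load_tumor("BT4C"),
        plasma=PROBE_PLASMA,
        dosing=(DoseEvent("iv_bolus", amount=5000.0, start=0.0),),
        control_kpuu=0.9,
        true_ppa_correction=40.0,
        true_folds=FoldChanges(2.5, 0.35),
        seed=seed,
        schedule=tuple(np.arange(15.0, 360.0, 30.0)),
        n_subjects=n_subjects,
        omega=(0.30, 0.20),
        sigma=(0.15, 0.0),
        lloq=0.0,
        sampling_mode="point",
    )
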