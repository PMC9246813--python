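"""Brain-tumor extension of the CNS model.

Five tumor compartments (tumor MV, ECF, ICF, cell membrane, lysosomes) with
the same internal structure as the healthy-brain block are inserted between
plasma and the CSF lateral ventricles.  The blood-tumor barrier (BTB) is
built exactly like the BBB but with the tumor's geometry (surface area
scaled by the microvascular-volume ratio), pH values and volumes, and two
fold changes relative to the control-brain BBB:

``f_pore``
    Paracellular pore-size fold change.  Applied linearly to the
    paracellular clearance through the areal pore fraction (slit-pore
    geometry: areal fraction proportional to pore width at fixed junctional
    length); a quadratic cylindrical-pore option is available via
    ``pore_scaling="quadratic"``.
``f_efflux``
    Active-efflux-clearance fold change.  Pinned reading: the active
    component beyond passive transport is A = (AF - 1) * CL_tc on whichever
    side the control brain is asymmetric; the BTB carries A' = f_efflux * A.
    f_efflux = 1 reproduces the control barrier, 0 abolishes active
    transport, and negative values reverse it into net active influx.  An
    alternative reading applying the fold to AF itself is available via
    ``efflux_mode="af"``.

No transport between tumor ECF and healthy-brain ECF is assumed, and the
tumor ECF bulk flow (per-mL rate times the extravascular tumor volume)
drains to the lateral ventricles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

from .cns import (
    CNS_COMPARTMENTS,
    CNSModelSpec,
    ClearanceSet,
    SimulationResult,
    _run,
    assemble_cns,
    barrier_clearances,
    _cell_exchange,
    build_clearances,
)
from .errors import ConfigurationError, DomainError
from .physchem import ph_factor
from .physiology import TumorPathophysiology, btb_surface_area, is_fully_resolved
from .plasma import DoseEvent

__all__ = [
    "FoldChanges",
    "TumorModelSpec",
    "build_btb_clearances",
    "apply_fold_changes",
    "extend_with_tumor",
    "simulate_tumor",
    "TUMOR_COMPARTMENTS",
]

TUMOR_COMPARTMENTS = ("t_mv", "t_ecf", "t_icf", "t_mem", "t_lyso")


@dataclass(frozen=True)
class FoldChanges:
    """BTB fold changes over the control-brain BBB."""

    f_pore: float
    f_efflux: float

    def __post_init__(self):
        if self.f_pore <= 0:
            raise DomainError("f_pore must be > 0")


@dataclass(frozen=True)
class TumorModelSpec:
    """Control-brain spec + tumor pathophysiology + BTB fold changes."""

    base: CNSModelSpec
    tumor: TumorPathophysiology
    folds: FoldChanges
    pore_scaling: str = "linear"
    efflux_mode: str = "af_minus_one"

    def __post_init__(self):
        if self.pore_scaling not in ("linear", "quadratic"):
            raise ConfigurationError(f"unknown pore_scaling {self.pore_scaling!r}")
        if self.efflux_mode not in ("af_minus_one", "af"):
            raise ConfigurationError(f"unknown efflux_mode {self.efflux_mode!r}")
        if not is_fully_resolved(self.tumor):
            raise ConfigurationError(
                "tumor pathophysiology has unresolved fields; run "
                "fill_healthy_defaults first"
            )


def build_btb_clearances(spec: TumorModelSpec) -> ClearanceSet:
    """Passive BTB clearance set (af = 1), before fold changes.

    Same construction as the BBB — including the control-brain PPA
    correction factor — but with the BTB surface area, tumor pH values and
    tumor volumes.
    """
    base, tumor = spec.base, spec.tumor
    phys = base.physiology
    drug = base.drug
    sa_btb = btb_surface_area(phys.sa_bbb, tumor.v_mv, phys.v_mv)
    cl_para, cl_tc_in, cl_tc_out = barrier_clearances(
        drug, sa_btb, phys.bbb_width, phys.pore_fraction_base,
        tumor.ph_mv, tumor.ph_ecf, base.ppa_correction,
    )
    v_icf_t = tumor.tumor_volume * (
        1.0 - (tumor.f_mv + tumor.f_ecf + tumor.f_mem + tumor.f_lyso) / 100.0
    )
    if v_icf_t <= 0:
        raise ConfigurationError("tumor volume fractions leave no ICF volume")
    v_lyso_t = tumor.tumor_volume * tumor.f_lyso / 100.0
    cl_wo, cl_ow, cl_lyso = _cell_exchange(
        drug, v_icf_t, v_lyso_t, tumor.cell_radius, tumor.lysosome_radius
    )
    return ClearanceSet(
        cl_para=cl_para,
        cl_tc_in=cl_tc_in,
        cl_tc_out=cl_tc_out,
        cl_ecf_bulk=tumor.q_ecf_bulk_per_ml
        * tumor.tumor_volume
        * (1.0 - tumor.f_mv / 100.0),
        q_cbf=tumor.cbf_tumor * tumor.tumor_mass,
        cl_wo=cl_wo,
        cl_ow=cl_ow,
        cl_lyso=cl_lyso,
        phf_ecf=ph_factor(drug, tumor.ph_ecf),
        phf_icf=ph_factor(drug, tumor.ph_icf),
        phf_lyso=ph_factor(drug, tumor.ph_lyso),
    )


def apply_fold_changes(
    btb: ClearanceSet,
    control_afs: Tuple[float, float],
    folds: FoldChanges,
    pore_scaling: str = "linear",
    efflux_mode: str = "af_minus_one",
) -> ClearanceSet:
    """Turn the passive BTB set + control AFs + fold changes into the BTB.

    ``btb`` must be built with af = 1.  With folds (1, 1) the result is the
    control barrier transplanted onto the tumor geometry.

    Raises :class:`DomainError` when the resulting total outward clearance
    would be non-positive (only reachable in ``efflux_mode="af"``).
    """
    if btb.af_in != 1.0 or btb.af_out != 1.0 or btb.act_in or btb.act_out:
        raise DomainError("btb clearances must be passive (af = 1) before folds")
    af_in_c, af_out_c = control_afs
    if af_in_c < 1.0 or af_out_c < 1.0:
        raise DomainError("control asymmetry factors must be >= 1")

    factor = folds.f_pore if pore_scaling == "linear" else folds.f_pore**2
    cl_para = btb.cl_para * factor

    act_in = act_out = 0.0
    if efflux_mode == "af_minus_one":
        active_out = (af_out_c - 1.0) * btb.cl_tc_out
        active_in = (af_in_c - 1.0) * btb.cl_tc_in
        scaled_out = folds.f_efflux * active_out
        scaled_in = folds.f_efflux * active_in
        act_out = max(scaled_out, 0.0) + max(-scaled_in, 0.0)
        act_in = max(-scaled_out, 0.0) + max(scaled_in, 0.0)
    else:  # fold applied to AF directly, only on the asymmetric side(s)
        net_out = (
            (folds.f_efflux * af_out_c - 1.0) * btb.cl_tc_out if af_out_c > 1.0 else 0.0
        )
        net_in = (
            (folds.f_efflux * af_in_c - 1.0) * btb.cl_tc_in if af_in_c > 1.0 else 0.0
        )
        act_out = max(net_out, 0.0) + max(-net_in, 0.0)
        act_in = max(-net_out, 0.0) + max(net_in, 0.0)

    out_total = cl_para + btb.cl_tc_out + act_out
    if out_total <= 0:
        raise DomainError("total outward BTB clearance must be > 0")
    return replace(btb, cl_para=cl_para, act_in=act_in, act_out=act_out)


def resolved_btb(spec: TumorModelSpec) -> ClearanceSet:
    """BTB clearance set with control AFs and fold changes applied."""
    control = build_clearances(spec.base)
    passive = build_btb_clearances(spec)
    return apply_fold_changes(
        passive, (control.af_in, control.af_out), spec.folds,
        spec.pore_scaling, spec.efflux_mode,
    )


def extend_with_tumor(
    spec: TumorModelSpec,
    doses: Sequence[DoseEvent],
    eta: Optional[Sequence[float]] = None,
):
    """Assemble the 14-compartment tumor-extended system (SystemBuilder)."""
    from .cns import _wire_tissue_block

    b, _control = assemble_cns(spec.base, doses, eta)
    tumor = spec.tumor
    btb = resolved_btb(spec)
    v_icf_t = tumor.tumor_volume * (
        1.0 - (tumor.f_mv + tumor.f_ecf + tumor.f_mem + tumor.f_lyso) / 100.0
    )
    volumes = {
        "t_mv": tumor.v_mv,
        "t_ecf": tumor.v_ecf,
        "t_icf": v_icf_t,
        "t_mem": tumor.tumor_volume * tumor.f_mem / 100.0,
        "t_lyso": tumor.tumor_volume * tumor.f_lyso / 100.0,
    }
    _wire_tissue_block(b, "t_", btb, volumes, spec.base.fup_forcing, "csf_lv")
    return b


def simulate_tumor(
    spec: TumorModelSpec,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    eta: Optional[Sequence[float]] = None,
    method: str = "expm",
) -> SimulationResult:
    """Simulate the tumor-extended model.

    Profiles cover plasma, the nine healthy-CNS compartments and the five
    tumor compartments (prefixed ``t_``); all unbound, ng/mL.
    """
    b = extend_with_tumor(spec, doses, eta)
    compartments = ("central",) + CNS_COMPARTMENTS + TUMOR_COMPARTMENTS
    res = _run(b, times, compartments, method, doses, spec.base.plasma.lag or 0.0)
    res.profiles["plasma"] = res.profiles.pop("central")
    res.profiles["plasma"].compartment_label = "plasma"
    return res
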