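"""The nine-compartment CNS PBPK core.

Compartments: brain microvascular plasma (MV), brain ECF, brain ICF, cell
membrane, lysosomes, and four CSF spaces (lateral ventricles LV, third and
fourth ventricles TFV, cisterna magna CM, subarachnoid space SAS).  An
empirical plasma model supplies blood concentrations; exchange across the
BBB combines a PHF-independent paracellular clearance with donor-side
pH-factored passive transcellular clearances, asymmetric active transport
enters as multipliers (AF) or additive active clearances on the
transcellular route, ECF bulk flow drains to the LV, and CSF flows through
LV -> TFV -> CM -> SAS back to plasma.

Clearance construction
----------------------
With D the aqueous diffusivity (cm^2/s), P0 the neutral-species membrane
permeability (cm/s), SA surface areas (cm^2), w the barrier width (cm) and
phi the base pore areal fraction::

    CL_para  = (D / w) * SA_BBB * phi / ppa_correction * 60     [mL/min]
    CL_tc,in = P0 * SA_BBB * PHF(pH_MV)  * 60
    CL_tc,out= P0 * SA_BBB * PHF(pH_ECF) * 60

(The factor 60 converts cm^3/s to mL/min.)  The estimated paracellular
correction factor (a fold-decrease) divides CL_para of the BBB only.

At steady state the unbound ECF-to-plasma ratio has the closed form::

    Kp_uu,ECF = (CL_para + AF_in CL_tc,in + CL_act,in)
              / (CL_para + AF_out CL_tc,out + CL_act,out + CL_ECF,bulk)

which the asymmetry factors are solved from when a measured Kp_uu,ECF is
supplied.  The membrane and lysosome sub-compartments carry no net flux at
steady state and cancel from the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from ._linear import SystemBuilder
from .errors import ConfigurationError, DomainError
from .physchem import (
    DrugProperties,
    aqueous_diffusivity,
    ph_factor,
    transmembrane_permeability,
)
from .physiology import CNSPhysiology
from .plasma import (
    ConcentrationTimeProfile,
    DoseEvent,
    PlasmaPKModel,
    build_plasma_builder,
)

__all__ = [
    "ClearanceSet",
    "CNSModelSpec",
    "build_clearances",
    "simulate_cns",
    "steady_state_kpuu",
    "af_from_kpuu",
    "SimulationResult",
    "CNS_COMPARTMENTS",
]

CNS_COMPARTMENTS = (
    "mv", "ecf", "icf", "mem", "lyso", "csf_lv", "csf_tfv", "csf_cm", "csf_sas",
)

SECONDS_PER_MINUTE = 60.0


@dataclass(frozen=True)
class ClearanceSet:
    """Resolved clearance network of one barrier/tissue block (mL/min).

    ``af_in``/``af_out`` are asymmetry multipliers on the passive
    transcellular clearances (exactly one exceeds 1 when solved from a
    measured Kp_uu); ``act_in``/``act_out`` are additive active clearances
    used when fold changes convert the active component into an explicit
    term (possibly moving it to the influx side).
    """

    cl_para: float
    cl_tc_in: float
    cl_tc_out: float
    af_in: float = 1.0
    af_out: float = 1.0
    act_in: float = 0.0
    act_out: float = 0.0
    cl_ecf_bulk: float = 0.0
    q_cbf: float = 0.0
    cl_csf: float = 0.0
    cl_wo: float = 0.0
    cl_ow: float = 0.0
    cl_lyso: float = 0.0
    phf_ecf: float = 1.0
    phf_icf: float = 1.0
    phf_lyso: float = 1.0
    cl_para_bcsfb: float = 0.0
    cl_tc_in_bcsfb: float = 0.0
    cl_tc_out_bcsfb: float = 0.0

    def __post_init__(self):
        for name in ("cl_para", "cl_tc_in", "cl_tc_out", "act_in", "act_out",
                     "cl_ecf_bulk", "q_cbf", "cl_csf", "cl_wo", "cl_ow",
                     "cl_lyso", "cl_para_bcsfb", "cl_tc_in_bcsfb",
                     "cl_tc_out_bcsfb"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.af_in < 0 or self.af_out < 0:
            raise DomainError("asymmetry factors must be >= 0")

    @property
    def total_in(self) -> float:
        """Total MV -> ECF clearance."""
        return self.cl_para + self.af_in * self.cl_tc_in + self.act_in

    @property
    def total_out(self) -> float:
        """Total ECF -> MV clearance."""
        return self.cl_para + self.af_out * self.cl_tc_out + self.act_out

    @property
    def paracellular_share(self) -> float:
        """Share of passive barrier transport through the paracellular route.

        cl_para / (cl_para + mean passive transcellular clearance); the
        active components and ECF bulk flow do not enter.
        """
        tc = 0.5 * (self.cl_tc_in + self.cl_tc_out)
        return self.cl_para / (self.cl_para + tc)


@dataclass(frozen=True)
class CNSModelSpec:
    """Fully specified control-brain CNS model.

    ``ppa_correction`` is the fitted fold-decrease dividing the BBB
    paracellular clearance.  When ``kpuu_ecf_target`` (a measured control
    Kp_uu,ECF) is given, asymmetry factors are solved from the uncorrected
    clearance set (ppa_correction = 1) once and then held fixed; this keeps
    AF identification and PPA-correction fitting as separate stages.
    """

    drug: DrugProperties
    physiology: CNSPhysiology
    plasma: PlasmaPKModel
    ppa_correction: float = 1.0
    kpuu_ecf_target: Optional[float] = None

    def __post_init__(self):
        if self.ppa_correction <= 0:
            raise ConfigurationError("ppa_correction must be > 0")
        if self.kpuu_ecf_target is not None and self.kpuu_ecf_target <= 0:
            raise ConfigurationError("kpuu_ecf_target must be > 0")

    @property
    def fup_forcing(self) -> float:
        """Unbound fraction applied to the plasma forcing concentration."""
        return self.drug.fup_effective if self.plasma.predicts == "total" else 1.0


# ---------------------------------------------------------------------------
# clearance assembly
# ---------------------------------------------------------------------------

def barrier_clearances(
    drug: DrugProperties,
    sa: float,
    width: float,
    pore_fraction: float,
    ph_donor_in: float,
    ph_donor_out: float,
    ppa_correction: float = 1.0,
) -> Tuple[float, float, float]:
    """(CL_para, CL_tc,in, CL_tc,out) for one endothelial barrier, mL/min."""
    if sa <= 0 or width <= 0 or pore_fraction <= 0:
        raise ConfigurationError("barrier geometry must be positive")
    d_aq = aqueous_diffusivity(drug.mw)
    p0 = transmembrane_permeability(drug.logp)
    cl_para = d_aq / width * sa * pore_fraction / ppa_correction * SECONDS_PER_MINUTE
    cl_tc_in = p0 * sa * ph_factor(drug, ph_donor_in) * SECONDS_PER_MINUTE
    cl_tc_out = p0 * sa * ph_factor(drug, ph_donor_out) * SECONDS_PER_MINUTE
    return cl_para, cl_tc_in, cl_tc_out


def _cell_exchange(drug: DrugProperties, v_icf: float, v_lyso: float,
                   cell_radius: float, lysosome_radius: float) -> Tuple[float, float, float]:
    """(cl_wo, cl_ow, cl_lyso) base membrane-exchange clearances, mL/min.

    Total cell surface area for spheres of radius r filling a volume V is
    3 V / r; the membrane partition of the neutral species is 10**logP, so
    the lipid-to-water release clearance is the uptake clearance divided by
    the partition coefficient.
    """
    p0 = transmembrane_permeability(drug.logp)
    sa_cells = 3.0 * v_icf / cell_radius
    sa_lyso = 3.0 * v_lyso / lysosome_radius
    cl_wo = p0 * sa_cells * SECONDS_PER_MINUTE
    cl_ow = cl_wo / (10.0 ** drug.logp)
    cl_lyso = p0 * sa_lyso * SECONDS_PER_MINUTE
    return cl_wo, cl_ow, cl_lyso


def build_clearances(spec: CNSModelSpec) -> ClearanceSet:
    """Assemble the full control-brain clearance set from drug + physiology.

    Raises :class:`ConfigurationError` naming the offending field when a
    fixture is missing or non-positive.
    """
    drug, phys = spec.drug, spec.physiology
    cl_para, cl_tc_in, cl_tc_out = barrier_clearances(
        drug, phys.sa_bbb, phys.bbb_width, phys.pore_fraction_base,
        phys.ph_mv, phys.ph_ecf, spec.ppa_correction,
    )
    cl_para_b, cl_tc_in_b, cl_tc_out_b = barrier_clearances(
        drug, phys.sa_bcsfb, phys.bbb_width, phys.pore_fraction_base,
        phys.ph_mv, phys.ph_csf, 1.0,
    )
    cl_wo, cl_ow, cl_lyso = _cell_exchange(
        drug, phys.v_icf, phys.v_lyso, phys.cell_radius, phys.lysosome_radius
    )
    cs = ClearanceSet(
        cl_para=cl_para,
        cl_tc_in=cl_tc_in,
        cl_tc_out=cl_tc_out,
        cl_ecf_bulk=phys.q_ecf_bulk_per_ml * phys.brain_volume * (1.0 - phys.f_mv / 100.0),
        q_cbf=phys.cbf * phys.brain_mass,
        cl_csf=phys.q_csf,
        cl_wo=cl_wo,
        cl_ow=cl_ow,
        cl_lyso=cl_lyso,
        phf_ecf=ph_factor(drug, phys.ph_ecf),
        phf_icf=ph_factor(drug, phys.ph_icf),
        phf_lyso=ph_factor(drug, phys.ph_lyso),
        cl_para_bcsfb=cl_para_b,
        cl_tc_in_bcsfb=cl_tc_in_b,
        cl_tc_out_bcsfb=cl_tc_out_b,
    )
    if spec.kpuu_ecf_target is not None:
        # AFs solved from the uncorrected barrier (fold-decrease removed),
        # then carried onto the corrected clearance set unchanged.
        uncorrected = replace(cs, cl_para=cl_para * spec.ppa_correction)
        af_in, af_out = af_from_kpuu(spec.kpuu_ecf_target, uncorrected)
        cs = replace(cs, af_in=af_in, af_out=af_out)
    return cs


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def steady_state_kpuu(clearances: ClearanceSet) -> float:
    """Closed-form steady-state unbound ECF/plasma ratio."""
    denom = clearances.total_out + clearances.cl_ecf_bulk
    if denom <= 0:
        raise DomainError("total outward clearance must be > 0")
    return clearances.total_in / denom


def af_from_kpuu(
    kpuu_measured: float, clearances: ClearanceSet
) -> Tuple[float, float]:
    """Solve the asymmetry factors from a measured Kp_uu,ECF.

    The passive set (af = 1) fixes the purely passive ratio; a measured
    value below it implies net efflux (af_in = 1, af_out > 1 solved in
    closed form) and above it net influx (af_out = 1, af_in > 1).
    """
    if kpuu_measured <= 0:
        raise DomainError("kpuu_measured must be > 0")
    passive = replace(clearances, af_in=1.0, af_out=1.0, act_in=0.0, act_out=0.0)
    kp_passive = steady_state_kpuu(passive)
    clp, tin, tout = passive.cl_para, passive.cl_tc_in, passive.cl_tc_out
    bulk = passive.cl_ecf_bulk
    if math.isclose(kpuu_measured, kp_passive, rel_tol=1e-12):
        return 1.0, 1.0
    if kpuu_measured < kp_passive:
        if tout <= 0:
            raise DomainError(
                "kpuu below the passive ratio needs a transcellular efflux route"
            )
        af_out = ((clp + tin) / kpuu_measured - clp - bulk) / tout
        if af_out < 1.0:
            raise DomainError("inconsistent inputs: solved af_out < 1")
        return 1.0, af_out
    if tin <= 0:
        raise DomainError(
            "kpuu above the passive ratio needs a transcellular influx route"
        )
    af_in = (kpuu_measured * (clp + tout + bulk) - clp) / tin
    if af_in < 1.0:
        raise DomainError("inconsistent inputs: solved af_in < 1")
    return af_in, 1.0


# ---------------------------------------------------------------------------
# system assembly and simulation
# ---------------------------------------------------------------------------

def _wire_tissue_block(
    b: SystemBuilder,
    prefix: str,
    cs: ClearanceSet,
    volumes: Dict[str, float],
    fup_forcing: float,
    csf_lv_state: Optional[str],
) -> None:
    """Add one MV/ECF/ICF/membrane/lysosome block exchanging with plasma.

    ``prefix`` distinguishes the healthy-brain block ("") from the tumor
    block ("t_").  ``csf_lv_state`` receives the ECF bulk outflow.
    """
    mv, ecf, icf = prefix + "mv", prefix + "ecf", prefix + "icf"
    mem, lyso = prefix + "mem", prefix + "lyso"
    for name in (mv, ecf, icf, mem, lyso):
        b.add_state(name, volumes[name])

    b.add_flow("central", mv, cs.q_cbf, donor_scale=fup_forcing)
    b.add_flow(mv, "central", cs.q_cbf)
    b.add_flow(mv, ecf, cs.total_in)
    b.add_flow(ecf, mv, cs.total_out)
    b.add_flow(ecf, mem, cs.cl_wo * cs.phf_ecf)
    b.add_flow(mem, ecf, cs.cl_ow)
    b.add_flow(icf, mem, cs.cl_wo * cs.phf_icf)
    b.add_flow(mem, icf, cs.cl_ow)
    b.add_flow(icf, lyso, cs.cl_lyso * cs.phf_icf)
    b.add_flow(lyso, icf, cs.cl_lyso * cs.phf_lyso)
    if csf_lv_state is not None:
        b.add_flow(ecf, csf_lv_state, cs.cl_ecf_bulk)


def assemble_cns(
    spec: CNSModelSpec,
    doses: Sequence[DoseEvent],
    eta: Optional[Sequence[float]] = None,
    clearances: Optional[ClearanceSet] = None,
) -> Tuple[SystemBuilder, ClearanceSet]:
    """Plasma + 9-compartment CNS system as a SystemBuilder."""
    phys = spec.physiology
    cs = clearances if clearances is not None else build_clearances(spec)
    b = build_plasma_builder(spec.plasma, doses, eta)
    b.set_conc_scale("central", spec.fup_forcing)

    volumes = {
        "mv": phys.v_mv, "ecf": phys.v_ecf, "icf": phys.v_icf,
        "mem": phys.v_mem, "lyso": phys.v_lyso,
    }
    # CSF chain first so the brain block can drain into it
    for name, vol in (("csf_lv", phys.v_lv), ("csf_tfv", phys.v_tfv),
                      ("csf_cm", phys.v_cm), ("csf_sas", phys.v_sas)):
        b.add_state(name, vol)
    _wire_tissue_block(b, "", cs, volumes, spec.fup_forcing, "csf_lv")

    # blood-CSF barrier, split equally between LV and TFV; passive (AF = 1)
    half_in = 0.5 * (cs.cl_para_bcsfb + cs.cl_tc_in_bcsfb)
    half_out = 0.5 * (cs.cl_para_bcsfb + cs.cl_tc_out_bcsfb)
    for csf in ("csf_lv", "csf_tfv"):
        b.add_flow("central", csf, half_in, donor_scale=spec.fup_forcing)
        b.add_flow(csf, "central", half_out)

    # CSF flow; downstream of the LV the bulk-flow contribution adds in
    q = cs.cl_csf + cs.cl_ecf_bulk
    b.add_flow("csf_lv", "csf_tfv", q)
    b.add_flow("csf_tfv", "csf_cm", q)
    b.add_flow("csf_cm", "csf_sas", q)
    b.add_flow("csf_sas", "central", q)
    return b, cs


@dataclass
class SimulationResult:
    """Profiles of every compartment plus the raw state trajectories."""

    times: np.ndarray
    profiles: Dict[str, ConcentrationTimeProfile]
    states: np.ndarray
    state_names: Tuple[str, ...]
    doses: Tuple[DoseEvent, ...] = field(default_factory=tuple)
    lag: float = 0.0

    def total_in_system(self) -> np.ndarray:
        """Total amount across all states (incl. eliminated), ug."""
        return self.states.sum(axis=1)

    def dosed_by(self, t: np.ndarray) -> np.ndarray:
        """Cumulative amount introduced into the system by each time, ug."""
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        for d in self.doses:
            if d.route == "iv_infusion":
                frac = np.clip((t - d.start) / d.duration, 0.0, 1.0)
                total += d.amount * frac
            elif d.route == "depot":
                total += d.amount * (t >= d.start + self.lag)
            else:
                total += d.amount * (t >= d.start)
        return total

    def mass_balance_error(self) -> np.ndarray:
        """Relative mass-balance error at every output time."""
        dosed = self.dosed_by(self.times)
        scale = np.maximum(dosed, 1e-300)
        return np.abs(self.total_in_system() - dosed) / scale


def _run(builder: SystemBuilder, times, compartments, method, doses, lag) -> SimulationResult:
    times = np.asarray(times, dtype=float)
    states = builder.build().solve(times, method=method)
    profiles = {
        name: ConcentrationTimeProfile(
            times=times, values=builder.concentrations(states, name),
            compartment_label=name,
        )
        for name in compartments
    }
    return SimulationResult(
        times=times, profiles=profiles, states=states,
        state_names=tuple(builder.names), doses=tuple(doses), lag=lag,
    )


def simulate_cns(
    spec: CNSModelSpec,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    eta: Optional[Sequence[float]] = None,
    method: str = "expm",
) -> SimulationResult:
    """Simulate the control-brain CNS model; all unbound, ng/mL.

    ``profiles`` holds plasma ("plasma" is the unbound central
    concentration) and every CNS compartment.
    """
    b, _cs = assemble_cns(spec, doses, eta)
    compartments = ("central",) + CNS_COMPARTMENTS
    res = _run(b, times, compartments, method, doses, spec.plasma.lag or 0.0)
    res.profiles["plasma"] = res.profiles.pop("central")
    res.profiles["plasma"].compartment_label = "plasma"
    return res
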