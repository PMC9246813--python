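"""CNS physiology and brain-tumor pathophysiology.

Holds the species-level healthy-brain parameter sets and the tumor rows,
plus the small arithmetic rules used to derive tumor parameters from their
literature sources: arithmetic means over reported values, vascularization
scaling, conversion of tumor/control ratios to absolute values, surface-area
scaling of the blood-tumor barrier by microvascular volume, and inheritance
of healthy-brain defaults for unreported fields.

Derived parameters are rounded to 3 significant figures using decimal
half-up arithmetic. Binary floating point would round a mean like
(7.37 + 7.28)/2 = 7.325 down to 7.32; half-up decimal rounding reproduces
the conventional printed value 7.33.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

from .errors import DomainError

__all__ = [
    "CNSPhysiology",
    "TumorPathophysiology",
    "round_sig",
    "derive_mean_parameter",
    "derive_scaled_parameter",
    "absolute_from_relative_cbf",
    "btb_surface_area",
    "fill_healthy_defaults",
]

#: Tissue density pinned at 1 g/mL: CBF in mL/min/g converts to volumetric
#: flow by multiplying with tissue volume in mL.
TISSUE_DENSITY_G_PER_ML = 1.0


@dataclass(frozen=True)
class CNSPhysiology:
    """Species-level CNS physiology (healthy brain).

    Volumes in mL, flows in mL/min, areas in cm^2, the barrier width in cm,
    CBF in mL/min/g, the base paracellular pore radius in nm. ``f_mv`` and
    ``f_ecf`` are volume fractions in percent of total brain volume.
    ``pore_fraction_base`` is the areal fraction of the barrier occupied by
    paracellular pores at the base pore size.
    """

    species: str
    brain_volume: float
    f_mv: float
    f_ecf: float
    v_icf: float
    v_mem: float
    v_lyso: float
    v_lv: float
    v_tfv: float
    v_cm: float
    v_sas: float
    cbf: float
    q_ecf_bulk_per_ml: float
    q_csf: float
    sa_bbb: float
    sa_bcsfb: float
    bbb_width: float
    pore_fraction_base: float
    pore_radius_base: float
    ph_mv: float
    ph_ecf: float
    ph_icf: float
    ph_lyso: float
    ph_csf: float
    cell_radius: float
    lysosome_radius: float

    def __post_init__(self):
        for name in (
            "brain_volume", "v_icf", "v_mem", "v_lyso", "v_lv", "v_tfv",
            "v_cm", "v_sas", "cbf", "q_ecf_bulk_per_ml", "q_csf", "sa_bbb",
            "sa_bcsfb", "bbb_width", "pore_fraction_base", "pore_radius_base",
            "cell_radius", "lysosome_radius",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("f_mv", "f_ecf"):
            if not (0.0 < getattr(self, name) < 100.0):
                raise DomainError(f"{name} must be in (0, 100) percent")
        for name in ("ph_mv", "ph_ecf", "ph_icf", "ph_lyso", "ph_csf"):
            if not (0.0 <= getattr(self, name) <= 14.0):
                raise DomainError(f"{name} must be in [0, 14]")

    # -- convenience geometry -------------------------------------------------
    @property
    def v_mv(self) -> float:
        """Microvascular plasma volume, mL."""
        return self.brain_volume * self.f_mv / 100.0

    @property
    def v_ecf(self) -> float:
        """Extracellular fluid volume, mL."""
        return self.brain_volume * self.f_ecf / 100.0

    @property
    def brain_mass(self) -> float:
        """Brain mass, g (density pinned at 1 g/mL)."""
        return self.brain_volume * TISSUE_DENSITY_G_PER_ML

    @property
    def f_mem(self) -> float:
        """Cell-membrane volume fraction, percent."""
        return 100.0 * self.v_mem / self.brain_volume

    @property
    def f_lyso(self) -> float:
        """Lysosomal volume fraction, percent."""
        return 100.0 * self.v_lyso / self.brain_volume


@dataclass(frozen=True)
class TumorPathophysiology:
    """Tumor-specific pathophysiology; unreported fields inherit healthy values.

    Mandatory fields are the five literature-derived parameters (tumor
    volume, MV/ECF volume fractions, extracellular/intracellular pH, tumor
    blood flow). Optional fields default to ``None`` and are resolved by
    :func:`fill_healthy_defaults`.
    """

    model_name: str
    species: str
    tumor_volume: float
    f_mv: float
    f_ecf: float
    ph_ecf: float
    ph_icf: float
    cbf_tumor: float
    ph_mv: Optional[float] = None
    ph_lyso: Optional[float] = None
    ph_csf: Optional[float] = None
    f_mem: Optional[float] = None
    f_lyso: Optional[float] = None
    q_ecf_bulk_per_ml: Optional[float] = None
    cell_radius: Optional[float] = None
    lysosome_radius: Optional[float] = None

    def __post_init__(self):
        for name in ("tumor_volume", "cbf_tumor"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("f_mv", "f_ecf"):
            if not (0.0 < getattr(self, name) < 100.0):
                raise DomainError(f"{name} must be in (0, 100) percent")
        for name in ("ph_ecf", "ph_icf"):
            if not (0.0 <= getattr(self, name) <= 14.0):
                raise DomainError(f"{name} must be in [0, 14]")

    @property
    def v_mv(self) -> float:
        return self.tumor_volume * self.f_mv / 100.0

    @property
    def v_ecf(self) -> float:
        return self.tumor_volume * self.f_ecf / 100.0

    @property
    def tumor_mass(self) -> float:
        return self.tumor_volume * TISSUE_DENSITY_G_PER_ML


# ---------------------------------------------------------------------------
# derivation rules
# ---------------------------------------------------------------------------

def round_sig(value: float, sig_figs: int = 3) -> float:
    """Round to ``sig_figs`` significant figures, decimal half-up.

    Uses the shortest decimal representation of the float so that values
    like ``(7.37 + 7.28) / 2`` round to 7.33 rather than 7.32.
    """
    if sig_figs < 1:
        raise DomainError("sig_figs must be >= 1")
    d = Decimal(repr(float(value)))
    if d == 0:
        return 0.0
    quantum = Decimal(1).scaleb(d.adjusted() - sig_figs + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def _decimal_mean(values: Sequence[float]) -> Decimal:
    if len(values) == 0:
        raise DomainError("cannot take the mean of an empty list")
    total = sum((Decimal(repr(float(v))) for v in values), Decimal(0))
    return total / Decimal(len(values))


def derive_mean_parameter(values: Sequence[float], sig_figs: int = 3) -> float:
    """Arithmetic mean of reported values, rounded to significant figures.

    The rule used whenever several literature values exist for the same
    tumor model: the mean, printed to 3 significant figures.
    """
    mean = _decimal_mean(values)
    return round_sig(float(mean), sig_figs)


def derive_scaled_parameter(
    base_values: Sequence[float], scale: float, sig_figs: int = 3
) -> float:
    """``scale x mean(base_values)``, rounded to significant figures.

    Covers cases like a highly vascularized line whose MV fraction is taken
    as a multiple of the mean of related lines.
    """
    if scale <= 0:
        raise DomainError(f"scale must be > 0, got {scale}")
    mean = _decimal_mean(base_values)
    return round_sig(float(Decimal(repr(float(scale))) * mean), sig_figs)


def absolute_from_relative_cbf(relative_cbf: float, healthy_cbf: float) -> float:
    """Convert a tumor/control ratio into an absolute value.

    Used for tumor blood flow and for the MV volume fraction alike: the
    literature ratio is multiplied by the representative healthy-brain
    value. Returns the raw product; printed-table reproduction applies
    :func:`round_sig` on top.
    """
    if relative_cbf <= 0 or healthy_cbf <= 0:
        raise DomainError("relative and healthy values must both be > 0")
    return relative_cbf * healthy_cbf


def btb_surface_area(sa_bbb: float, v_mv_tumor: float, v_mv_brain: float) -> float:
    """Blood-tumor-barrier exchange surface area, cm^2.

    The healthy BBB area scaled by the ratio of microvascular volumes
    between tumor and healthy brain; linear in ``v_mv_tumor``.
    """
    if sa_bbb <= 0 or v_mv_tumor <= 0:
        raise DomainError("surface area and tumor MV volume must be > 0")
    if v_mv_brain <= 0:
        raise DomainError("healthy-brain MV volume must be > 0")
    return sa_bbb * (v_mv_tumor / v_mv_brain)


_INHERITED_FIELDS = (
    "ph_mv",
    "ph_lyso",
    "ph_csf",
    "q_ecf_bulk_per_ml",
    "cell_radius",
    "lysosome_radius",
)


def fill_healthy_defaults(
    tumor: TumorPathophysiology, healthy: CNSPhysiology
) -> TumorPathophysiology:
    """Copy healthy-brain values into every unspecified tumor field.

    Applies the stated assumption for unreported tumor parameters: pH in MV
    and lysosomes, the phospholipid-membrane and lysosome volume fractions,
    the ECF bulk flow per tissue volume, and the tumor-cell radius all take
    the healthy-brain values. Specified fields are left untouched;
    idempotent by construction.
    """
    updates = {}
    for name in _INHERITED_FIELDS:
        if getattr(tumor, name) is None:
            updates[name] = getattr(healthy, name)
    if tumor.f_mem is None:
        updates["f_mem"] = healthy.f_mem
    if tumor.f_lyso is None:
        updates["f_lyso"] = healthy.f_lyso
    return replace(tumor, **updates) if updates else tumor


def is_fully_resolved(tumor: TumorPathophysiology) -> bool:
    """True when no optional field is left unset."""
    return all(getattr(tumor, f.name) is not None for f in fields(TumorPathophysiology))
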