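"""Drug-dependent transport primitives.

Everything the barrier model needs from a compound reduces to four pure
functions of its physicochemical record: the unionized (neutral-species)
fraction at a given pH, the aqueous diffusion coefficient, the intrinsic
transmembrane permeability of the neutral species, and the donor-side pH
factor applied to transcellular clearance.

Ionization follows the monoprotic Henderson-Hasselbalch relation using only
the constant relevant to the drug's assigned charge class: a single acidic
pKa for acids, a single basic pKb for bases, and exactly 1 for neutrals.
Multiprotic speciation and charge/size-restricted paracellular corrections
are deliberately out of scope.

The diffusivity and permeability correlations are pinned, named constants
(overridable per call) rather than fitted quantities:

    D_aq  = 9.9e-5 * MW ** -0.453            [cm^2/s]
    log10 P0 = 0.939 * logP - 6.21           [P0 in cm/s]
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ConfigurationError, DomainError

__all__ = [
    "DrugProperties",
    "unionized_fraction",
    "aqueous_diffusivity",
    "transmembrane_permeability",
    "ph_factor",
    "DIFFUSIVITY_COEFFICIENT",
    "DIFFUSIVITY_EXPONENT",
    "PERMEABILITY_SLOPE",
    "PERMEABILITY_INTERCEPT",
]

#: Aqueous diffusivity correlation D = a * MW**b, D in cm^2/s, MW in g/mol.
DIFFUSIVITY_COEFFICIENT = 9.9e-5
DIFFUSIVITY_EXPONENT = -0.453

#: Neutral-species transmembrane permeability, log10 P0 = slope*logP + intercept.
PERMEABILITY_SLOPE = 0.939
PERMEABILITY_INTERCEPT = -6.21

_CHARGE_CLASSES = ("acid", "base", "neutral")


@dataclass(frozen=True)
class DrugProperties:
    """Physicochemical identity of a compound.

    Parameters
    ----------
    name : str
        Identifier used in bundled records and outputs.
    mw : float
        Molecular weight, g/mol. Must be positive.
    charge_class : {"acid", "base", "neutral"}
        The single dominant ionizable class at physiological pH. Only the
        class-relevant ionization constant participates in pH partitioning.
    pka_acid : float, optional
        Strongest acidic ionization constant (pH units). Required for acids.
    pkb_base : float, optional
        Strongest basic ionization constant (pH units). Required for bases.
    logp : float
        Octanol-water log partition coefficient of the neutral species.
    fup : float, optional
        Fraction unbound in plasma, in (0, 1]. When absent the plasma
        parameters are interpreted as already describing unbound drug
        (equivalent to fup = 1).
    """

    name: str
    mw: float
    charge_class: str
    logp: float
    pka_acid: Optional[float] = None
    pkb_base: Optional[float] = None
    fup: Optional[float] = None

    def __post_init__(self):
        if self.mw <= 0:
            raise ConfigurationError(f"{self.name}: mw must be > 0, got {self.mw}")
        if self.charge_class not in _CHARGE_CLASSES:
            raise ConfigurationError(
                f"{self.name}: charge_class must be one of {_CHARGE_CLASSES}, "
                f"got {self.charge_class!r}"
            )
        if self.charge_class == "acid" and self.pka_acid is None:
            raise ConfigurationError(f"{self.name}: charge_class=acid requires pka_acid")
        if self.charge_class == "base" and self.pkb_base is None:
            raise ConfigurationError(f"{self.name}: charge_class=base requires pkb_base")
        if self.fup is not None and not (0.0 < self.fup <= 1.0):
            raise ConfigurationError(f"{self.name}: fup must be in (0, 1], got {self.fup}")

    @property
    def fup_effective(self) -> float:
        """fup with the missing-value convention (absent -> 1.0)."""
        return 1.0 if self.fup is None else self.fup


def unionized_fraction(drug: DrugProperties, ph: float) -> float:
    """Fraction of drug present as the neutral (membrane-permeant) species.

    Monoprotic Henderson-Hasselbalch per the drug's charge class::

        acid:    1 / (1 + 10**(ph - pka_acid))
        base:    1 / (1 + 10**(pkb_base - ph))
        neutral: 1 exactly

    Parameters
    ----------
    drug : DrugProperties
    ph : float
        Donor-side pH, must lie in [0, 14].
    """
    if not (0.0 <= ph <= 14.0):
        raise DomainError(f"ph must be in [0, 14], got {ph}")
    if drug.charge_class == "neutral":
        return 1.0
    if drug.charge_class == "acid":
        if drug.pka_acid is None:  # pragma: no cover - blocked by __post_init__
            raise ConfigurationError(f"{drug.name}: acid without pka_acid")
        return 1.0 / (1.0 + 10.0 ** (ph - drug.pka_acid))
    if drug.pkb_base is None:  # pragma: no cover - blocked by __post_init__
        raise ConfigurationError(f"{drug.name}: base without pkb_base")
    return 1.0 / (1.0 + 10.0 ** (drug.pkb_base - ph))


def aqueous_diffusivity(
    mw: float,
    coefficient: float = DIFFUSIVITY_COEFFICIENT,
    exponent: float = DIFFUSIVITY_EXPONENT,
) -> float:
    """Aqueous diffusion coefficient, cm^2/s, from molecular weight.

    Power-law correlation ``D = coefficient * mw**exponent``; strictly
    decreasing in MW for the pinned negative exponent.
    """
    if mw <= 0:
        raise DomainError(f"mw must be > 0, got {mw}")
    return coefficient * mw**exponent


def transmembrane_permeability(
    logp: float,
    slope: float = PERMEABILITY_SLOPE,
    intercept: float = PERMEABILITY_INTERCEPT,
) -> float:
    """Intrinsic permeability of the unionized species, cm/s.

    ``log10 P0 = slope*logP + intercept``; monotone increasing in logP.
    """
    return 10.0 ** (slope * logp + intercept)


def ph_factor(drug: DrugProperties, ph_donor: float) -> float:
    """Donor-side pH factor (PHF) multiplying transmembrane clearance.

    Equal to the unionized fraction at the donor pH: only the neutral
    species crosses lipid membranes, so transcellular clearance out of a
    compartment scales with the neutral fraction there. Paracellular
    clearance is PHF-independent.
    """
    return unionized_fraction(drug, ph_donor)
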