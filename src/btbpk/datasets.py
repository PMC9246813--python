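"""Loaders for the bundled parameter documents.

The package ships flat YAML documents with the drug records, healthy CNS
physiology (including the companion-model fixtures), tumor pathophysiology
rows with derivation provenance, empirical plasma PK models and the
reference barrier-estimation results.  Everything here is a thin, validated
constructor from those documents into the domain dataclasses.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache
from typing import Dict, List, Optional

import yaml

from .errors import ConfigurationError
from .physchem import DrugProperties
from .physiology import (
    CNSPhysiology,
    TumorPathophysiology,
    absolute_from_relative_cbf,
    derive_mean_parameter,
    derive_scaled_parameter,
    round_sig,
)
from .plasma import PlasmaPKModel

__all__ = [
    "load_drug",
    "drug_names",
    "load_physiology",
    "load_tumor",
    "tumor_names",
    "load_plasma_model",
    "plasma_model_names",
    "load_reference_results",
    "rederive_tumor_parameters",
    "count_pore_increase_cases",
    "count_efflux_decrease_cases",
    "max_rat_pore_fold",
]


@lru_cache(maxsize=None)
def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("btbpk.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


# -- drugs -------------------------------------------------------------------

def drug_names() -> List[str]:
    return sorted(_load_yaml("drugs.yaml"))


def load_drug(name: str) -> DrugProperties:
    """Bundled physicochemical record by drug name."""
    doc = _load_yaml("drugs.yaml")
    if name not in doc:
        raise ConfigurationError(f"unknown drug {name!r}; known: {sorted(doc)}")
    rec = doc[name]
    return DrugProperties(
        name=name,
        mw=rec["mw"],
        charge_class=rec["charge_class"],
        logp=rec["logp"],
        pka_acid=rec.get("pka_acid"),
        pkb_base=rec.get("pkb_base"),
        fup=rec.get("fup"),
    )


# -- physiology --------------------------------------------------------------

def load_physiology(species: str) -> CNSPhysiology:
    """Healthy-brain physiology for ``species`` ("rat" or "human")."""
    doc = _load_yaml("physiology.yaml")
    if species not in doc or species == "version":
        raise ConfigurationError(f"unknown species {species!r}")
    return CNSPhysiology(**doc[species])


def tumor_names(species: str = "rat") -> List[str]:
    return sorted(_load_yaml("tumors.yaml")[species])


def load_tumor(
    name: str, species: str = "rat", healthy: Optional[CNSPhysiology] = None
) -> TumorPathophysiology:
    """Tumor pathophysiology row, with healthy defaults already filled in.

    Pass ``healthy`` to inherit from a non-bundled physiology; by default
    the bundled physiology of the matching species is used.
    """
    from .physiology import fill_healthy_defaults

    doc = _load_yaml("tumors.yaml")
    if species not in doc or name not in doc[species]:
        raise ConfigurationError(f"unknown tumor {species}/{name!r}")
    rec = doc[species][name]
    tumor = TumorPathophysiology(
        model_name=name,
        species=species,
        tumor_volume=rec["tumor_volume"],
        f_mv=rec["f_mv"],
        f_ecf=rec["f_ecf"],
        ph_ecf=rec["ph_ecf"],
        ph_icf=rec["ph_icf"],
        cbf_tumor=rec["cbf_tumor"],
    )
    return fill_healthy_defaults(tumor, healthy or load_physiology(species))


# -- plasma models -----------------------------------------------------------

def plasma_model_names(species: str = "rat") -> List[str]:
    return sorted(_load_yaml("plasma_models.yaml")[species])


def load_plasma_model(name: str, species: str = "rat") -> PlasmaPKModel:
    doc = _load_yaml("plasma_models.yaml")
    if species not in doc or name not in doc[species]:
        raise ConfigurationError(f"unknown plasma model {species}/{name!r}")
    rec = dict(doc[species][name])
    rec.pop("drug", None)
    return PlasmaPKModel(**rec)


def plasma_model_drug(name: str, species: str = "rat") -> str:
    return _load_yaml("plasma_models.yaml")[species][name]["drug"]


def load_reference_results() -> dict:
    """Reference Kp_uu values, PPA corrections and BTB fold changes."""
    return _load_yaml("btb_results.yaml")


# -- table re-derivation and structure ---------------------------------------

def rederive_tumor_parameters(species: str = "rat") -> Dict[str, Dict[str, float]]:
    """Recompute every derived tumor-table cell from its recorded sources.

    Returns ``{model: {parameter: derived value}}`` covering exactly the
    cells that carry a derivation block; cells loaded verbatim are skipped.
    Used to check that the derivation rules reproduce the printed values.
    """
    doc = _load_yaml("tumors.yaml")[species]
    healthy = load_physiology(species)
    out: Dict[str, Dict[str, float]] = {}
    for model, rec in doc.items():
        derivs = rec.get("derivations")
        if not derivs:
            continue
        out[model] = {}
        for param, spec in derivs.items():
            rule = spec["rule"]
            if rule == "mean":
                value = derive_mean_parameter(spec["sources"])
            elif rule == "scaled_mean":
                value = derive_scaled_parameter(spec["sources"], spec["scale"])
            elif rule == "relative":
                value = round_sig(
                    absolute_from_relative_cbf(spec["relative"], healthy.cbf)
                )
            elif rule == "copy":
                value = derive_mean_parameter(spec["sources"])
            else:
                raise ConfigurationError(f"unknown derivation rule {rule!r}")
            out[model][param] = value
    return out


def _fold_cases() -> List[dict]:
    return load_reference_results()["fold_changes"]["cases"]


def _case_pore_folds(case: dict) -> List[float]:
    if "patients" in case:
        return [p["pore"] for p in case["patients"].values()]
    return [case["pore"]]


def _case_efflux_folds(case: dict) -> List[float]:
    if "patients" in case:
        return [p["efflux"] for p in case["patients"].values()]
    return [case["efflux"]]


def count_pore_increase_cases() -> tuple[int, int]:
    """(cases with pore-size fold > 1, total cases)."""
    cases = _fold_cases()
    n = sum(1 for c in cases if all(v > 1 for v in _case_pore_folds(c)))
    return n, len(cases)


def count_efflux_decrease_cases() -> tuple[int, int]:
    """(cases with decreased active efflux (fold < 1, incl. reversal), total).

    A negative fold means reversal to net active influx and counts as a
    decrease; folds above 1 (increase) do not.
    """
    cases = _fold_cases()
    n = sum(1 for c in cases if all(v < 1 for v in _case_efflux_folds(c)))
    return n, len(cases)


def max_rat_pore_fold() -> float:
    """Largest pore-size fold change among the rat-model cases."""
    return max(
        v
        for c in _fold_cases()
        if c["species"] == "rat"
        for v in _case_pore_folds(c)
    )
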