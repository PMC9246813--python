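"""File formats and run configuration.

All tabular I/O is plain CSV with pinned column names; parameter documents
are YAML/JSON.  Units are fixed package-wide (min, mL, ng/mL, ug, cm/s,
cm^2, nm) — loaders validate structure and reject unknown keys rather than
silently ignoring them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .plasma import ConcentrationTimeProfile, DoseEvent

__all__ = [
    "RunConfig",
    "load_run_config",
    "config_digest",
    "read_profiles_csv",
    "write_profiles_csv",
    "read_doses",
    "write_doses",
]

PROFILE_COLUMNS = ("subject_id", "compartment", "time_min", "conc_ng_per_ml")
OPTIONAL_PROFILE_COLUMNS = ("interval_end_min", "censored")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full two-stage pipeline run.

    Every stochastic stage must carry an explicit seed; the config is
    serialized into each output directory for provenance.
    """

    output_dir: str
    design_name: str = "transcellular_probe"
    seed_generate: Optional[int] = None
    seed_estimate: Optional[int] = None
    seed_vpc: Optional[int] = None
    stages: Tuple[str, ...] = ("generate", "fit-ppa", "handshake", "evaluate")
    n_subjects: int = 6
    n_replicates_vpc: int = 200
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-10
    log_level: str = "INFO"

    _STAGE_SEEDS = {
        "generate": "seed_generate",
        "fit-ppa": "seed_estimate",
        "handshake": "seed_estimate",
        "evaluate": "seed_vpc",
    }

    def __post_init__(self):
        known = set(self._STAGE_SEEDS)
        unknown = set(self.stages) - known
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}; valid: {sorted(known)}")
        for stage in self.stages:
            if getattr(self, self._STAGE_SEEDS[stage]) is None:
                raise ConfigurationError(
                    f"stage {stage!r} is stochastic and needs {self._STAGE_SEEDS[stage]}"
                )


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from YAML/JSON, rejecting unknown keys."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigurationError("run config must be a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig) if not f.name.startswith("_")}
    unknown = set(doc) - valid
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)}; valid: {sorted(valid)}")
    if "stages" in doc:
        doc["stages"] = tuple(doc["stages"])
    return RunConfig(**doc)


def config_digest(config: RunConfig) -> str:
    """Short sha256 digest of the canonical config JSON."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# concentration tables
# ---------------------------------------------------------------------------

def write_profiles_csv(profiles: Sequence[ConcentrationTimeProfile], path) -> None:
    rows = []
    for p in profiles:
        for i, t in enumerate(p.times):
            rows.append({
                "subject_id": p.subject_id,
                "compartment": p.compartment_label,
                "time_min": float(t),
                "conc_ng_per_ml": float(p.values[i]),
                "interval_end_min": (
                    float(p.interval_end[i]) if p.interval_end is not None else np.nan
                ),
                "censored": bool(p.censored[i]) if p.censored is not None else False,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path) -> List[ConcentrationTimeProfile]:
    """Read a tidy concentration table into per-(subject, compartment) profiles."""
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"profile CSV missing columns {sorted(missing)}")
    unknown = set(df.columns) - set(PROFILE_COLUMNS) - set(OPTIONAL_PROFILE_COLUMNS)
    if unknown:
        raise ConfigurationError(f"profile CSV has unknown columns {sorted(unknown)}")
    out = []
    for (sid, comp), grp in df.groupby(["subject_id", "compartment"]):
        grp = grp.sort_values("time_min")
        interval = (
            grp["interval_end_min"].to_numpy()
            if "interval_end_min" in grp
            else np.full(len(grp), np.nan)
        )
        out.append(ConcentrationTimeProfile(
            times=grp["time_min"].to_numpy(),
            values=grp["conc_ng_per_ml"].to_numpy(),
            compartment_label=str(comp),
            subject_id=str(sid),
            interval_end=None if np.isnan(interval).all() else interval,
            censored=grp["censored"].to_numpy() if "censored" in grp else None,
        ))
    return out


# ---------------------------------------------------------------------------
# dosing sidecars
# ---------------------------------------------------------------------------

_DOSE_KEYS = {"route", "amount_ug", "start_min", "duration_min"}


def write_doses(doses: Sequence[DoseEvent], path) -> None:
    doc = [
        {
            "route": d.route,
            "amount_ug": d.amount,
            "start_min": d.start,
            "duration_min": d.duration,
        }
        for d in doses
    ]
    Path(path).write_text(yaml.safe_dump(doc))


def read_doses(path) -> List[DoseEvent]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise ConfigurationError("dose sidecar must be a list of events")
    out = []
    for rec in doc:
        unknown = set(rec) - _DOSE_KEYS
        if unknown:
            raise ConfigurationError(f"unknown dose keys {sorted(unknown)}")
        out.append(DoseEvent(
            route=rec["route"],
            amount=rec["amount_ug"],
            start=rec.get("start_min", 0.0),
            duration=rec.get("duration_min"),
        ))
    return out
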