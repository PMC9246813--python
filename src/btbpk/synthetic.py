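"""Synthetic microdialysis-like study generation.

The source analyses rest on sparse, interval-sampled unbound concentrations
in plasma, control-brain ECF and tumor ECF, with exponential
inter-individual variability on the plasma parameters and
proportional(/additive) residual error.  No such dataset is packaged, so
this module generates studies with exactly that statistical structure from
a fully specified truth (plasma model, physiology, tumor row, PPA
correction, BTB fold changes), making every pipeline stage testable without
any download.

The default schedule emulates a dialysate collection: 20-minute bins over
0-360 min, with each observation the time-average of the simulated unbound
ECF concentration over its bin (trapezoid quadrature).  Probe recovery is
taken as 1: the model states are already unbound ECF concentrations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cns import CNSModelSpec
from .errors import DomainError, EstimationError
from .handshake import (
    estimate_fold_changes,
    estimate_ppa_correction,
    _collapse_to_obs,
    _prediction_grid,
)
from .physchem import DrugProperties
from .physiology import CNSPhysiology, TumorPathophysiology
from .plasma import ConcentrationTimeProfile, DoseEvent, PlasmaPKModel
from .tumor import FoldChanges, TumorModelSpec, simulate_tumor

__all__ = [
    "StudyDesign",
    "StudyDataset",
    "default_schedule",
    "generate_study",
    "recovery_experiment",
]

COMPARTMENT_MAP = {
    "plasma": "plasma",
    "control_ecf": "ecf",
    "tumor_ecf": "t_ecf",
}


def default_schedule(t_end: float = 360.0, bin_width: float = 20.0) -> np.ndarray:
    """Bin start times for dialysate-like sampling (default 20-min bins)."""
    return np.arange(0.0, t_end, bin_width)


@dataclass(frozen=True)
class StudyDesign:
    """Everything needed to generate one synthetic study.

    ``schedule`` holds sampling times (point mode) or bin starts
    (interval_mean mode, bins of ``bin_width`` minutes).  ``true_*`` fields
    are the generating barrier truth retained for recovery tests; ``omega``
    and ``sigma`` are the IIV SDs (log scale, on plasma CL and V) and the
    residual (proportional fraction, additive ng/mL) SDs.
    """

    name: str
    drug: DrugProperties
    physiology: CNSPhysiology
    tumor: TumorPathophysiology
    plasma: PlasmaPKModel
    dosing: Tuple[DoseEvent, ...]
    control_kpuu: float
    true_ppa_correction: float
    true_folds: FoldChanges
    seed: int
    schedule: Tuple[float, ...] = field(
        default_factory=lambda: tuple(default_schedule())
    )
    bin_width: float = 20.0
    n_subjects: int = 6
    omega: Tuple[float, float] = (0.0, 0.0)
    sigma: Tuple[float, float] = (0.15, 0.0)
    lloq: float = 0.0
    sampling_mode: str = "interval_mean"

    def __post_init__(self):
        if self.n_subjects < 1:
            raise DomainError("n_subjects must be >= 1")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0 or np.any(np.diff(sched) <= 0):
            raise DomainError("schedule must be non-empty and increasing")
        if self.sampling_mode not in ("point", "interval_mean"):
            raise DomainError(f"unknown sampling_mode {self.sampling_mode!r}")
        if self.sampling_mode == "interval_mean" and self.bin_width <= 0:
            raise DomainError("interval_mean sampling needs bin_width > 0")
        if self.seed is None:
            raise DomainError("seed is mandatory")

    # -- model resolution ----------------------------------------------------
    def control_spec(self, ppa_correction: Optional[float] = None) -> CNSModelSpec:
        return CNSModelSpec(
            drug=self.drug,
            physiology=self.physiology,
            plasma=self.plasma,
            ppa_correction=(
                self.true_ppa_correction if ppa_correction is None else ppa_correction
            ),
            kpuu_ecf_target=self.control_kpuu,
        )

    def tumor_spec(
        self,
        ppa_correction: Optional[float] = None,
        folds: Optional[FoldChanges] = None,
    ) -> TumorModelSpec:
        return TumorModelSpec(
            base=self.control_spec(ppa_correction),
            tumor=self.tumor,
            folds=self.true_folds if folds is None else folds,
        )

    def observation_template(self) -> ConcentrationTimeProfile:
        """Empty profile carrying the schedule/interval structure."""
        times = np.asarray(self.schedule, dtype=float)
        interval_end = (
            times + self.bin_width if self.sampling_mode == "interval_mean" else None
        )
        return ConcentrationTimeProfile(
            times=times,
            values=np.zeros_like(times),
            interval_end=interval_end,
        )


@dataclass
class StudyDataset:
    """Generated observations + the design and truth that produced them."""

    observations: pd.DataFrame
    design: StudyDesign
    truth: Dict

    def profiles(self, compartment: str) -> List[ConcentrationTimeProfile]:
        """Per-subject observed profiles for one compartment label."""
        out = []
        for sid, grp in self.observations[
            self.observations["compartment"] == compartment
        ].groupby("subject_id"):
            grp = grp.sort_values("time_min")
            interval = grp["interval_end_min"].to_numpy()
            out.append(
                ConcentrationTimeProfile(
                    times=grp["time_min"].to_numpy(),
                    values=grp["conc_ng_per_ml"].to_numpy(),
                    compartment_label=compartment,
                    subject_id=str(sid),
                    interval_end=None if np.isnan(interval).all() else interval,
                    censored=grp["censored"].to_numpy(),
                )
            )
        return out

    # -- serialization -------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(directory / "observations.csv", index=False)
        meta = {
            "truth": self.truth,
            "design": dataclasses.asdict(self.design),
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2, default=list))

    @staticmethod
    def load(directory) -> "StudyDataset":
        directory = Path(directory)
        obs = pd.read_csv(directory / "observations.csv")
        obs["censored"] = obs["censored"].astype(bool)
        meta = json.loads((directory / "meta.json").read_text())
        d = meta["design"]
        design = StudyDesign(
            name=d["name"],
            drug=DrugProperties(**d["drug"]),
            physiology=CNSPhysiology(**d["physiology"]),
            tumor=TumorPathophysiology(**d["tumor"]),
            plasma=PlasmaPKModel(**d["plasma"]),
            dosing=tuple(DoseEvent(**e) for e in d["dosing"]),
            control_kpuu=d["control_kpuu"],
            true_ppa_correction=d["true_ppa_correction"],
            true_folds=FoldChanges(**d["true_folds"]),
            seed=d["seed"],
            schedule=tuple(d["schedule"]),
            bin_width=d["bin_width"],
            n_subjects=d["n_subjects"],
            omega=tuple(d["omega"]),
            sigma=tuple(d["sigma"]),
            lloq=d["lloq"],
            sampling_mode=d["sampling_mode"],
        )
        return StudyDataset(observations=obs, design=design, truth=meta["truth"])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_study(design: StudyDesign) -> StudyDataset:
    """Simulate one study from the design's truth; reproducible from seed.

    Per subject: sample the IIV deviations, simulate the tumor-extended
    model, sample each compartment on the schedule (point values or
    interval means), apply residual error, and censor below the LLOQ
    (censored rows carry the LLOQ as their value).
    """
    rng = np.random.default_rng(design.seed)
    template = design.observation_template()
    grid = _prediction_grid(template)
    spec = design.tumor_spec()
    rows = []
    etas = {}
    for i in range(design.n_subjects):
        sid = f"S{i + 1:02d}"
        eta = (
            rng.normal(0.0, design.omega[0]),
            rng.normal(0.0, design.omega[1]),
        )
        etas[sid] = [float(eta[0]), float(eta[1])]
        res = simulate_tumor(spec, design.dosing, grid, eta=eta)
        for label, state in COMPARTMENT_MAP.items():
            clean = _collapse_to_obs(template, grid, res.profiles[state].values)
            eps_p = rng.normal(0.0, design.sigma[0], size=clean.shape)
            eps_a = rng.normal(0.0, design.sigma[1], size=clean.shape)
            noisy = np.maximum(clean * (1.0 + eps_p) + eps_a, 0.0)
            censored = noisy < design.lloq
            noisy = np.where(censored, design.lloq, noisy)
            for k, t in enumerate(template.times):
                rows.append({
                    "subject_id": sid,
                    "compartment": label,
                    "time_min": float(t),
                    "interval_end_min": (
                        float(template.interval_end[k])
                        if template.interval_end is not None
                        else np.nan
                    ),
                    "conc_ng_per_ml": float(noisy[k]),
                    "censored": bool(censored[k]),
                })
    truth = {
        "ppa_correction": design.true_ppa_correction,
        "f_pore": design.true_folds.f_pore,
        "f_efflux": design.true_folds.f_efflux,
        "control_kpuu": design.control_kpuu,
        "eta": etas,
    }
    return StudyDataset(
        observations=pd.DataFrame(rows), design=design, truth=truth
    )


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------

def estimate_from_dataset(
    dataset: StudyDataset,
    seed: int = 0,
    n_starts_ppa: int = 6,
    n_starts_folds: int = 9,
    fix: Optional[str] = None,
):
    """Run the two-stage workflow on one synthetic study.

    Returns (PPAFitResult, HandshakeResult): stage 1 on the control-brain
    ECF arm with the truth's AFs (from the measured control Kp_uu), stage 2
    on the tumor ECF arm with the stage-1 correction frozen.
    """
    design = dataset.design
    control = design.control_spec(ppa_correction=1.0)
    ppa_fit = estimate_ppa_correction(
        dataset.profiles("control_ecf"),
        control,
        design.dosing,
        n_starts=n_starts_ppa,
        seed=seed,
        lloq=design.lloq or None,
    )
    tumor_spec = design.tumor_spec(
        ppa_correction=ppa_fit.ppa_correction, folds=FoldChanges(1.0, 1.0)
    )
    fold_fit = estimate_fold_changes(
        dataset.profiles("tumor_ecf"),
        tumor_spec,
        design.dosing,
        fix=fix,
        n_starts=n_starts_folds,
        seed=seed + 1,
        lloq=design.lloq or None,
    )
    return ppa_fit, fold_fit


def recovery_experiment(
    design: StudyDesign,
    n_replicates: int,
    seed: int = 0,
    **estimator_kwargs,
) -> pd.DataFrame:
    """Generate -> estimate over seeded replicates; one row per replicate.

    Estimation errors are recorded per replicate (NaN estimates) without
    aborting the batch.  Relative errors are signed, (est - truth)/truth.
    """
    rows = []
    for r in range(max(0, n_replicates)):
        rep_seed = (seed * 1_000_003 + 7919 * r + 1) % 2**31
        ds = generate_study(dataclasses.replace(design, seed=rep_seed))
        row = {
            "replicate": r,
            "seed": rep_seed,
            "true_ppa": design.true_ppa_correction,
            "true_f_pore": design.true_folds.f_pore,
            "true_f_efflux": design.true_folds.f_efflux,
        }
        try:
            ppa_fit, fold_fit = estimate_from_dataset(
                ds, seed=rep_seed + 1, **estimator_kwargs
            )
            row.update({
                "est_ppa": ppa_fit.ppa_correction,
                "est_f_pore": fold_fit.f_pore,
                "est_f_efflux": fold_fit.f_efflux,
                "ridge_flag": fold_fit.ridge_flag,
                "start_dispersion": fold_fit.start_dispersion,
                "error": "",
            })
        except EstimationError as exc:
            row.update({
                "est_ppa": np.nan, "est_f_pore": np.nan, "est_f_efflux": np.nan,
                "ridge_flag": False, "start_dispersion": np.nan,
                "error": str(exc),
            })
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "replicate", "seed", "true_ppa", "true_f_pore", "true_f_efflux",
            "est_ppa", "est_f_pore", "est_f_efflux", "ridge_flag",
            "start_dispersion", "error",
        ],
    )
    for est, true in (
        ("est_ppa", "true_ppa"),
        ("est_f_pore", "true_f_pore"),
        ("est_f_efflux", "true_f_efflux"),
    ):
        df[est.replace("est_", "relerr_")] = (df[est] - df[true]) / df[true]
    return df
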