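"""Model evaluation: VPC envelopes, relative accuracy, sensitivity scans.

The visual predictive check simulates the study design ``n_sim`` times with
inter-individual variability (exponential on plasma CL and V) and residual
error resampled per replicate, then summarises the pointwise median and
2.5/97.5 percentiles (linear interpolation between order statistics) at the
observation grid.

The relative accuracy of a drug in a compartment is the mean log10 ratio of
the time-matched simulated median to each observation,

    RA = (1/M) sum_i sum_j log10(MedP_ij / Obs_ij),   M = sum_i m_i,

with the companion two-fold fraction: the share of observations whose
median prediction lies within a factor of 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, is_dataclass, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .plasma import ConcentrationTimeProfile

__all__ = [
    "VPCResult",
    "AccuracyReport",
    "vpc",
    "vpc_coverage",
    "relative_accuracy",
    "sensitivity_scan",
    "plot_vpc",
]


@dataclass
class VPCResult:
    """Pointwise prediction envelope from stochastic replicates (ng/mL)."""

    times: np.ndarray
    median: np.ndarray
    lower_2_5: np.ndarray
    upper_97_5: np.ndarray
    n_sim: int

    def __post_init__(self):
        if not (np.all(self.lower_2_5 <= self.median + 1e-12)
                and np.all(self.median <= self.upper_97_5 + 1e-12)):
            raise DomainError("percentile bands must be ordered")


@dataclass
class AccuracyReport:
    """RA statistic with its bookkeeping."""

    ra_drug: float
    m_per_individual: List[int]
    m_total: int
    n_individuals: int
    twofold_fraction: float
    n_excluded: int = 0


def vpc(
    dataset,
    compartment: str,
    n_sim: int = 200,
    seed: int = 0,
) -> VPCResult:
    """VPC for one compartment of a synthetic-study design.

    Simulates ``n_sim`` replicate studies from the dataset's design (IIV on
    the plasma parameters, residual error on observations) and returns the
    pointwise median and 95% interval over all replicate values per
    schedule row.
    """
    from .synthetic import generate_study  # local import to avoid a cycle

    if n_sim < 2:
        raise DomainError("n_sim must be >= 2")
    design = dataset.design
    times = np.asarray(design.schedule, dtype=float)
    sims = []
    for r in range(n_sim):
        rep = generate_study(replace(design, seed=(seed * 1_000_003 + r) % 2**31))
        obs = rep.observations
        sub = obs[obs["compartment"] == compartment]
        # schedule rows are shared across subjects: n_subjects x n_times
        vals = sub.pivot_table(
            index="subject_id", columns="time_min", values="conc_ng_per_ml"
        ).to_numpy()
        sims.append(vals)
    stacked = np.concatenate(sims, axis=0)  # (n_sim*n_subjects) x n_times
    return VPCResult(
        times=times,
        median=np.percentile(stacked, 50, axis=0),
        lower_2_5=np.percentile(stacked, 2.5, axis=0),
        upper_97_5=np.percentile(stacked, 97.5, axis=0),
        n_sim=n_sim,
    )


def vpc_coverage(result: VPCResult, dataset, compartment: str) -> float:
    """Fraction of observed values inside the 95% band, schedule-matched."""
    obs = dataset.observations
    sub = obs[(obs["compartment"] == compartment) & (~obs["censored"])]
    lower = dict(zip(result.times, result.lower_2_5))
    upper = dict(zip(result.times, result.upper_97_5))
    inside = [
        lower[t] <= c <= upper[t]
        for t, c in zip(sub["time_min"], sub["conc_ng_per_ml"])
    ]
    if not inside:
        raise DomainError("no uncensored observations to score")
    return float(np.mean(inside))


def relative_accuracy(
    observations: Sequence[ConcentrationTimeProfile],
    median_predictions: Sequence[np.ndarray],
) -> AccuracyReport:
    """RA statistic over matched observation/median-prediction pairs.

    One prediction array per individual profile, aligned element-wise with
    its observations.  Non-positive observations are excluded (counted in
    ``n_excluded``).
    """
    if len(observations) != len(median_predictions):
        raise DomainError("one prediction array per observed profile required")
    logs, m_per = [], []
    excluded = 0
    for p, pred in zip(observations, median_predictions):
        pred = np.asarray(pred, dtype=float)
        if pred.shape != p.values.shape:
            raise DomainError("prediction/observation shape mismatch")
        keep = p.values > 0
        excluded += int(np.sum(~keep))
        lr = np.log10(pred[keep] / p.values[keep])
        logs.append(lr)
        m_per.append(int(keep.sum()))
    all_lr = np.concatenate(logs) if logs else np.array([])
    if all_lr.size == 0:
        raise DomainError("no usable observations")
    return AccuracyReport(
        ra_drug=float(np.mean(all_lr)),
        m_per_individual=m_per,
        m_total=int(all_lr.size),
        n_individuals=len(observations),
        twofold_fraction=float(np.mean(np.abs(all_lr) <= math.log10(2.0))),
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# sensitivity scan
# ---------------------------------------------------------------------------

def _list_paths(obj, prefix="") -> List[str]:
    out = []
    for f in fields(obj):
        val = getattr(obj, f.name)
        path = f"{prefix}{f.name}"
        if is_dataclass(val) and not isinstance(val, type):
            out.extend(_list_paths(val, path + "."))
        elif isinstance(val, (int, float)) or val is None:
            out.append(path)
    return out


def _with_param(spec, dotted: str, value: float):
    head, _, rest = dotted.partition(".")
    if not any(f.name == head for f in fields(spec)):
        raise ConfigurationError(
            f"unknown parameter {dotted!r}; valid: {sorted(_list_paths(spec))}"
        )
    if rest:
        return replace(spec, **{head: _with_param(getattr(spec, head), rest, value)})
    return replace(spec, **{head: value})


def sensitivity_scan(
    spec,
    parameter_name: str,
    grid: Sequence[float],
    simulate: Callable,
    compartment: str = "ecf",
) -> pd.DataFrame:
    """One-at-a-time scan: re-simulate with one parameter swept over a grid.

    ``simulate`` maps a spec to a SimulationResult (e.g.
    ``lambda s: simulate_cns(s, doses, times)``).  Returns a table of the
    parameter value, C_max, time of C_max, and trapezoidal exposure of the
    chosen compartment.
    """
    rows = []
    for value in grid:
        trial = _with_param(spec, parameter_name, float(value))
        res = simulate(trial)
        prof = res.profiles[compartment]
        i = int(np.argmax(prof.values))
        rows.append({
            "parameter": parameter_name,
            "value": float(value),
            "cmax": float(prof.values[i]),
            "tmax": float(prof.times[i]),
            "auc": float(np.trapezoid(prof.values, prof.times)),
        })
    return pd.DataFrame(rows)


def plot_vpc(
    result: VPCResult,
    dataset=None,
    compartment: Optional[str] = None,
    path: Optional[str] = None,
    title: str = "",
):
    """Median + 95% band, with observed mean +/- SD overlaid when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(result.times, result.lower_2_5, result.upper_97_5,
                    alpha=0.3, label="95% prediction interval")
    ax.plot(result.times, result.median, "--", label="simulation median")
    if dataset is not None and compartment is not None:
        obs = dataset.observations
        sub = obs[obs["compartment"] == compartment]
        g = sub.groupby("time_min")["conc_ng_per_ml"]
        ax.errorbar(g.mean().index, g.mean(), yerr=g.std(), fmt="o", ms=4,
                    capsize=2, label="observed mean +/- SD")
    ax.set_yscale("log")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("unbound concentration (ng/mL)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
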