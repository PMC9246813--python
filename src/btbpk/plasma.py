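"""Empirical plasma forcing functions.

One- and two-compartment linear models with optional first-order absorption
(with lag) drive the CNS model from the blood side.  Inter-individual
variability enters exponentially on clearance and central volume
(CL_i = CL e^eta_CL, V_i = V e^eta_V); residual variability is proportional
or combined proportional/additive on observations.

Simulation is the exact solution of the linear system (superposition over
dose events); an LSODA route is retained for cross-checking.  Fitting is a
pooled maximum-likelihood estimate with multi-start over log-transformed
parameters; when at least three subjects are available, per-subject refits
provide the IIV standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from ._linear import SystemBuilder
from .errors import ConfigurationError, DomainError, EstimationError

__all__ = [
    "PlasmaPKModel",
    "DoseEvent",
    "ConcentrationTimeProfile",
    "simulate_plasma",
    "apply_ruv",
    "fit_plasma",
]


@dataclass(frozen=True)
class PlasmaPKModel:
    """Empirical 1/2-compartment plasma model (Table-style parameter set).

    Exactly one of ``cl_cen`` (mL/min) or ``k_el`` (1/min) drives
    elimination. ``predicts`` records whether the model describes unbound or
    total drug; a total-drug model is converted to an unbound forcing by the
    drug's fup at the CNS coupling.
    """

    structure: str
    v_cen: float
    cl_cen: Optional[float] = None
    k_el: Optional[float] = None
    q_cen_per: Optional[float] = None
    v_per: Optional[float] = None
    k_a: Optional[float] = None
    lag: Optional[float] = None
    omega_cl: float = 0.0
    omega_v: float = 0.0
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    predicts: str = "unbound"

    def __post_init__(self):
        if self.structure not in ("one_compartment", "two_compartment"):
            raise ConfigurationError(f"unknown structure {self.structure!r}")
        if (self.cl_cen is None) == (self.k_el is None):
            raise ConfigurationError("exactly one of cl_cen / k_el must be given")
        if self.v_cen <= 0:
            raise ConfigurationError("v_cen must be > 0")
        if self.structure == "two_compartment":
            if self.q_cen_per is None or self.v_per is None:
                raise ConfigurationError("two_compartment needs q_cen_per and v_per")
            if self.q_cen_per < 0 or self.v_per <= 0:
                raise ConfigurationError("q_cen_per >= 0 and v_per > 0 required")
        if self.lag is not None and self.k_a is None:
            raise ConfigurationError("lag requires k_a (first-order absorption)")
        for name in ("omega_cl", "omega_v", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.predicts not in ("unbound", "total"):
            raise ConfigurationError(f"predicts must be unbound/total, got {self.predicts!r}")

    @property
    def clearance(self) -> float:
        """Elimination clearance, mL/min, whichever parameterization."""
        return self.cl_cen if self.cl_cen is not None else self.k_el * self.v_cen

    def individual(self, eta: Optional[Sequence[float]]) -> "PlasmaPKModel":
        """Apply exponential IIV deviations (eta_cl, eta_v)."""
        if eta is None:
            return self
        eta_cl, eta_v = float(eta[0]), float(eta[1])
        updates = {"v_cen": self.v_cen * math.exp(eta_v)}
        if self.cl_cen is not None:
            updates["cl_cen"] = self.cl_cen * math.exp(eta_cl)
        else:
            updates["k_el"] = self.k_el * math.exp(eta_cl)
        return replace(self, **updates)


@dataclass(frozen=True)
class DoseEvent:
    """A dosing event: iv bolus, zero-order iv infusion, or depot dose."""

    route: str
    amount: float          # ug
    start: float = 0.0     # min
    duration: Optional[float] = None  # min, infusion only

    def __post_init__(self):
        if self.route not in ("iv_bolus", "iv_infusion", "depot"):
            raise ConfigurationError(f"unknown route {self.route!r}")
        if self.amount <= 0:
            raise DomainError("dose amount must be > 0")
        if self.start < 0:
            raise DomainError("dose start must be >= 0")
        if self.route == "iv_infusion":
            if self.duration is None or self.duration <= 0:
                raise DomainError("infusions need duration > 0")


@dataclass
class ConcentrationTimeProfile:
    """A sampled concentration-time course for one subject/compartment.

    ``interval_end`` marks interval-averaged (dialysate-like) samples: the
    value at row i is the mean concentration over [times[i], interval_end[i]].
    ``censored`` flags observations reported below the quantification limit.
    """

    times: np.ndarray
    values: np.ndarray
    compartment_label: str = "plasma"
    subject_id: str = "pop"
    interval_end: Optional[np.ndarray] = None
    censored: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DomainError("times and values must have equal shape")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise DomainError("concentrations must be >= 0")
        if self.interval_end is not None:
            self.interval_end = np.asarray(self.interval_end, dtype=float)
        if self.censored is not None:
            self.censored = np.asarray(self.censored, dtype=bool)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def build_plasma_builder(
    model: PlasmaPKModel,
    doses: Iterable[DoseEvent],
    eta: Optional[Sequence[float]] = None,
) -> SystemBuilder:
    """SystemBuilder with the plasma states, doses and elimination wired up.

    Exposed so the CNS assembler can extend the same system.  States:
    optional ``depot``, ``central``, optional ``peripheral``, plus the
    ``eliminated`` accumulator.
    """
    m = model.individual(eta)
    b = SystemBuilder()
    if m.k_a is not None:
        b.add_state("depot", 1.0)
    b.add_state("central", m.v_cen)
    if m.structure == "two_compartment":
        b.add_state("peripheral", m.v_per)
    b.add_accumulator("eliminated")

    if m.k_a is not None:
        # first-order absorption: clearance k_a * V_depot with V_depot = 1
        b.add_flow("depot", "central", m.k_a)
    b.add_flow("central", "eliminated", m.clearance)
    if m.structure == "two_compartment":
        b.add_flow("central", "peripheral", m.q_cen_per)
        b.add_flow("peripheral", "central", m.q_cen_per)

    lag = m.lag or 0.0
    for dose in doses:
        if dose.route == "iv_bolus":
            b.add_impulse(dose.start, "central", dose.amount)
        elif dose.route == "iv_infusion":
            b.add_infusion(
                dose.start, dose.start + dose.duration, "central",
                dose.amount / dose.duration,
            )
        else:
            if m.k_a is None:
                raise ConfigurationError("depot dosing requires k_a in the model")
            b.add_impulse(dose.start + lag, "depot", dose.amount)
    return b


def simulate_plasma(
    model: PlasmaPKModel,
    doses: Sequence[DoseEvent],
    times: Sequence[float],
    eta: Optional[Sequence[float]] = None,
    method: str = "expm",
) -> ConcentrationTimeProfile:
    """Predicted plasma concentration (ng/mL) at ``times``.

    The prediction is on the model's own scale (total drug for a total-drug
    model); before the first dose (plus lag for depot routes) it is 0.
    """
    b = build_plasma_builder(model, doses, eta)
    states = b.build().solve(times, method=method)
    return ConcentrationTimeProfile(
        times=np.asarray(times, dtype=float),
        values=b.concentrations(states, "central"),
        compartment_label="plasma",
    )


def apply_ruv(
    pred: ConcentrationTimeProfile,
    model: PlasmaPKModel,
    rng: np.random.Generator,
) -> Tuple[ConcentrationTimeProfile, int]:
    """Residual-error model: obs = pred*(1+eps_prop) + eps_add.

    Each eps is N(0, sigma^2) with the model's sigmas. Negative results are
    floored at 0; the count of floored values is returned alongside.
    """
    eps_p = rng.normal(0.0, model.sigma_prop, size=pred.values.shape)
    eps_a = rng.normal(0.0, model.sigma_add, size=pred.values.shape)
    obs = pred.values * (1.0 + eps_p) + eps_a
    n_floored = int(np.sum(obs < 0))
    obs = np.maximum(obs, 0.0)
    return (
        ConcentrationTimeProfile(
            times=pred.times.copy(),
            values=obs,
            compartment_label=pred.compartment_label,
            subject_id=pred.subject_id,
            interval_end=None if pred.interval_end is None else pred.interval_end.copy(),
        ),
        n_floored,
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_STRUCT_PARAMS = {
    "one_compartment": ("cl_cen", "v_cen"),
    "two_compartment": ("cl_cen", "v_cen", "q_cen_per", "v_per"),
}


def _model_from_theta(structure: str, theta: np.ndarray, template: PlasmaPKModel) -> PlasmaPKModel:
    names = _STRUCT_PARAMS[structure]
    values = dict(zip(names, np.exp(theta[: len(names)])))
    return replace(
        template,
        structure=structure,
        cl_cen=values["cl_cen"],
        k_el=None,
        v_cen=values["v_cen"],
        q_cen_per=values.get("q_cen_per"),
        v_per=values.get("v_per"),
    )


def _neg2ll(obs, pred, sig_p, sig_a):
    var = (sig_p * pred) ** 2 + sig_a**2
    var = np.maximum(var, 1e-30)
    return float(np.sum((obs - pred) ** 2 / var + np.log(var)))


def fit_plasma(
    data: Sequence[ConcentrationTimeProfile],
    structure: str,
    doses: Sequence[DoseEvent],
    error_model: str = "proportional",
    n_starts: int = 10,
    seed: int = 0,
) -> PlasmaPKModel:
    """Pooled maximum-likelihood fit of an empirical plasma model.

    Point estimates are obtained by minimising the -2 log-likelihood of the
    chosen residual model over all subjects' observations jointly, with
    log-parameter transforms for positivity and seeded multi-start.  With at
    least three subjects, per-subject refits supply exponential-IIV standard
    deviations on clearance and central volume.

    Raises
    ------
    EstimationError
        If the data cannot identify the structure (too few distinct
        timepoints) or all observations are zero.
    """
    if structure not in _STRUCT_PARAMS:
        raise ConfigurationError(f"unknown structure {structure!r}")
    if error_model not in ("proportional", "combined"):
        raise ConfigurationError(f"unknown error model {error_model!r}")
    profiles = list(data)
    if not profiles:
        raise EstimationError("no data")
    all_times = np.unique(np.concatenate([p.times for p in profiles]))
    n_struct = len(_STRUCT_PARAMS[structure])
    if all_times.size < n_struct:
        raise EstimationError(
            f"{structure} needs >= {n_struct} distinct timepoints, got {all_times.size}"
        )
    obs_all = np.concatenate([p.values for p in profiles])
    if np.all(obs_all <= 0):
        raise EstimationError("all observations are zero; refusing to fit")

    template = PlasmaPKModel(
        structure=structure, v_cen=1.0, cl_cen=1.0,
        q_cen_per=1.0 if structure == "two_compartment" else None,
        v_per=1.0 if structure == "two_compartment" else None,
    )

    def objective(x):
        theta, logsig = x[:n_struct], x[n_struct:]
        sig_p = math.exp(logsig[0])
        sig_a = math.exp(logsig[1]) if error_model == "combined" else 0.0
        try:
            m = _model_from_theta(structure, theta, template)
        except ConfigurationError:
            return 1e12
        total = 0.0
        for p in profiles:
            pred = simulate_plasma(m, doses, p.times).values
            total += _neg2ll(p.values, pred, sig_p, sig_a)
        if not np.isfinite(total):
            return 1e12
        return total

    rng = np.random.default_rng(seed)
    # crude data-driven center: V ~ dose/Cmax, CL ~ dose/AUC
    dose_total = sum(d.amount for d in doses)
    cmax = float(np.max(obs_all))
    auc = max(np.trapezoid(profiles[0].values, profiles[0].times), 1e-9) / 1000.0
    v0 = max(dose_total / max(cmax / 1000.0, 1e-9), 1e-3)
    cl0 = max(dose_total / auc, 1e-6)
    center = {"cl_cen": cl0, "v_cen": v0, "q_cen_per": cl0, "v_per": v0}
    theta0 = np.log([center[n] for n in _STRUCT_PARAMS[structure]])

    n_sig = 2 if error_model == "combined" else 1
    best = None
    for start in range(n_starts):
        jitter = rng.normal(0.0, 1.0, size=n_struct) if start else np.zeros(n_struct)
        x0 = np.concatenate([theta0 + jitter, np.full(n_sig, math.log(0.2))])
        res = minimize(objective, x0,
                       method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise EstimationError("all starts failed")

    theta = best.x[:n_struct]
    sig_p = math.exp(best.x[n_struct])
    sig_a = math.exp(best.x[n_struct + 1]) if error_model == "combined" else 0.0
    fitted = replace(
        _model_from_theta(structure, theta, template),
        sigma_prop=sig_p, sigma_add=sig_a,
    )

    # IIV from per-subject refits
    subjects = {p.subject_id for p in profiles}
    if len(subjects) >= 3:
        cls, vols = [], []
        for sid in sorted(subjects):
            sub = [p for p in profiles if p.subject_id == sid]
            try:
                m_i = fit_plasma(sub, structure, doses, error_model,
                                 n_starts=max(2, n_starts // 3), seed=seed + 1)
            except EstimationError:
                continue
            cls.append(math.log(m_i.clearance))
            vols.append(math.log(m_i.v_cen))
        if len(cls) >= 3:
            fitted = replace(
                fitted,
                omega_cl=float(np.std(cls, ddof=1)),
                omega_v=float(np.std(vols, ddof=1)),
            )
    return fitted
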