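"""Piecewise-constant-input linear ODE machinery.

Every model in this package (empirical plasma models, the CNS model, the
tumor-extended model) is a linear mass-action system

    x'(t) = A x(t) + u(t)

with u piecewise constant (zero-order infusions) plus impulses (bolus or
lagged depot doses).  Two solution routes are provided:

``expm``
    Exact propagation segment by segment with the matrix exponential; for
    a segment with constant input the augmented matrix [[A, u], [0, 0]] is
    exponentiated.  This is the closed-form solution of the linear system
    and the package default.
``ode``
    LSODA integration per segment (scipy ``solve_ivp``), kept as an
    independent numerical route for cross-checks.

Impulses at time t are applied before outputs at t are recorded, so a bolus
at t=0 evaluated at t=0 already shows D/V (the 0+ convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .errors import DomainError, SimulationError

__all__ = ["LinearSystem", "SystemBuilder"]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass
class LinearSystem:
    """x' = A x + u(t) with impulses and zero-order infusion windows."""

    a: np.ndarray
    impulses: List[Tuple[float, np.ndarray]] = field(default_factory=list)
    infusions: List[Tuple[float, float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        n = self.a.shape[0]
        if self.a.shape != (n, n):
            raise DomainError("system matrix must be square")
        for t, _v in self.impulses:
            if t < 0:
                raise DomainError("impulse times must be >= 0")
        for t0, t1, _v in self.infusions:
            if t1 <= t0 or t0 < 0:
                raise DomainError("infusion windows must have t1 > t0 >= 0")

    @property
    def n(self) -> int:
        return self.a.shape[0]

    # ------------------------------------------------------------------
    def _segments(self, times: np.ndarray):
        """Breakpoints from 0 to max(times) covering all events/outputs."""
        pts = {0.0, float(times[-1])}
        pts.update(float(t) for t in times)
        pts.update(float(t) for t, _ in self.impulses if t <= times[-1])
        for t0, t1, _ in self.infusions:
            if t0 <= times[-1]:
                pts.add(float(t0))
                pts.add(float(min(t1, times[-1])))
        return np.array(sorted(pts))

    def _rate_at(self, t_mid: float) -> np.ndarray:
        u = np.zeros(self.n)
        for t0, t1, vec in self.infusions:
            if t0 <= t_mid < t1:
                u = u + vec
        return u

    def solve(
        self,
        times: Sequence[float],
        x0: np.ndarray | None = None,
        method: str = "expm",
        rtol: float = DEFAULT_RTOL,
        atol: float = DEFAULT_ATOL,
    ) -> np.ndarray:
        """States at ``times`` (shape n_times x n). ``times`` sorted, >= 0."""
        times = np.asarray(times, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise DomainError("times must be a non-empty 1-D array")
        if np.any(np.diff(times) <= 0):
            raise DomainError("times must be strictly increasing")
        if times[0] < 0:
            raise DomainError("times must be >= 0")

        x = np.zeros(self.n) if x0 is None else np.asarray(x0, dtype=float).copy()
        out = np.empty((times.size, self.n))
        grid = self._segments(times)
        impulse_map: Dict[float, np.ndarray] = {}
        for t, vec in self.impulses:
            if t <= times[-1]:
                key = float(t)
                impulse_map[key] = impulse_map.get(key, 0) + np.asarray(vec, float)
        out_idx = {float(t): i for i, t in enumerate(times)}

        for k, t in enumerate(grid):
            if k > 0:
                dt = t - grid[k - 1]
                u = self._rate_at(0.5 * (t + grid[k - 1]))
                x = self._propagate(x, dt, u, method, rtol, atol)
            if t in impulse_map:
                x = x + impulse_map[t]
            if t in out_idx:
                out[out_idx[t]] = x
        return out

    # ------------------------------------------------------------------
    def _propagate(self, x, dt, u, method, rtol, atol):
        if dt == 0:
            return x
        if method == "expm":
            if np.any(u):
                n = self.n
                m = np.zeros((n + 1, n + 1))
                m[:n, :n] = self.a * dt
                m[:n, n] = u * dt
                ph = expm(m)
                return ph[:n, :n] @ x + ph[:n, n]
            return expm(self.a * dt) @ x
        if method == "ode":
            rhs = lambda _t, y: self.a @ y + u  # noqa: E731
            sol = solve_ivp(
                rhs, (0.0, dt), x, method="LSODA", rtol=rtol, atol=atol,
                t_eval=[dt],
            )
            if not sol.success:
                raise SimulationError(
                    f"integrator failed: {sol.message}",
                    state=x, rtol=rtol, atol=atol,
                )
            return sol.y[:, -1]
        raise DomainError(f"unknown method {method!r}")


class SystemBuilder:
    """Assemble a compartmental clearance network into a LinearSystem.

    States are amounts; a flow ``add_flow(src, dst, cl)`` moves mass at rate
    ``cl * C_src`` where the donor concentration may carry a scale factor
    (e.g. the unbound fraction for a total-drug plasma pool).
    """

    def __init__(self):
        self.names: List[str] = []
        self.volumes: Dict[str, float] = {}
        self._conc_scale: Dict[str, float] = {}
        self._entries: List[Tuple[str, str, float]] = []
        self.impulses: List[Tuple[float, str, float]] = []
        self.infusions: List[Tuple[float, float, str, float]] = []

    def add_state(self, name: str, volume: float, conc_scale: float = 1.0):
        if name in self.volumes:
            raise DomainError(f"duplicate state {name!r}")
        if volume <= 0:
            raise DomainError(f"state {name!r} needs a positive volume")
        self.names.append(name)
        self.volumes[name] = float(volume)
        self._conc_scale[name] = float(conc_scale)

    def add_accumulator(self, name: str):
        """A bookkeeping state (e.g. cumulative elimination); no volume."""
        if name in self.volumes:
            raise DomainError(f"duplicate state {name!r}")
        self.names.append(name)
        self.volumes[name] = float("nan")
        self._conc_scale[name] = 0.0

    def set_conc_scale(self, name: str, scale: float):
        """Scale factor applied when reporting this state's concentration
        (e.g. the unbound fraction for a total-drug plasma pool)."""
        if name not in self.volumes:
            raise DomainError(f"unknown state {name!r}")
        self._conc_scale[name] = float(scale)

    def add_flow(self, src: str, dst: str | None, cl: float, donor_scale: float = 1.0):
        """Clearance-driven transfer src -> dst (dst None discards mass).

        ``donor_scale`` rescales the donor concentration driving the flux,
        e.g. the unbound fraction when the donor pool holds total drug.
        """
        if cl < 0:
            raise DomainError(f"clearance {src}->{dst} must be >= 0, got {cl}")
        self._entries.append((src, dst, float(cl) * float(donor_scale)))

    def add_impulse(self, time: float, state: str, amount: float):
        if amount < 0:
            raise DomainError("dose amounts must be >= 0")
        self.impulses.append((float(time), state, float(amount)))

    def add_infusion(self, t0: float, t1: float, state: str, rate: float):
        if rate < 0:
            raise DomainError("infusion rates must be >= 0")
        self.infusions.append((float(t0), float(t1), state, float(rate)))

    # ------------------------------------------------------------------
    def index(self, name: str) -> int:
        return self.names.index(name)

    def build(self) -> LinearSystem:
        n = len(self.names)
        idx = {name: i for i, name in enumerate(self.names)}
        a = np.zeros((n, n))
        for src, dst, cl in self._entries:
            i = idx[src]
            k = cl / self.volumes[src]
            a[i, i] -= k
            if dst is not None:
                a[idx[dst], i] += k
        impulses = []
        for t, state, amount in self.impulses:
            v = np.zeros(n)
            v[idx[state]] = amount
            impulses.append((t, v))
        infusions = []
        for t0, t1, state, rate in self.infusions:
            v = np.zeros(n)
            v[idx[state]] = rate
            infusions.append((t0, t1, v))
        return LinearSystem(a, impulses, infusions)

    def concentrations(self, states: np.ndarray, name: str) -> np.ndarray:
        """Unbound concentration profile, ng/mL, for a named compartment.

        Amounts are micrograms and volumes mL; 1 ug/mL = 1000 ng/mL.  The
        state's concentration scale (unbound fraction) is applied.
        """
        i = self.index(name)
        return states[:, i] * self._conc_scale[name] / self.volumes[name] * 1000.0
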