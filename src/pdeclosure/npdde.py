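"""Forward solution of neural partial delay differential equations.

The model solved here is a method-of-lines discretization of

    du/dt = L(u, u_x, ...; nu) + F(u, u_x, ...; phi) + y(x, t)
    dy/dt = D(inputs at t; theta) - D(inputs at t - tau; theta)
    y(x, t0) = integral_{t0-tau}^{t0} D(inputs at s; theta) ds

i.e. the distributed-delay (non-Markovian) closure written as an equivalent
coupled system with a single discrete delay.  The delay is handled by the
method of steps: integration proceeds in segments of length tau, so a delayed
lookup always lands in an already-finalized dense-output interpolant (or in
the history function for t < t0).  With no delay kernel the memory state is
dropped and the system is a plain PDE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .closures import DeepClosure, LinearClosure
from .numerics import BCSpec, DerivativeScheme, DiffOp, Grid1D

__all__ = [
    "Term",
    "InputField",
    "ClosureBinding",
    "NPDDESystem",
    "Trajectory",
    "SolverFailure",
    "history_integral",
    "augmented_rhs",
    "solve_forward",
]


class SolverFailure(RuntimeError):
    """Time integration failed; ``last_time`` is the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time t={last_time:.6g})")
        self.last_time = last_time


class Term:
    """One contribution to the low-fidelity right-hand side."""

    def eval(self, u: np.ndarray, t: float) -> np.ndarray:  # (Nx, ns)
        raise NotImplementedError

    def vjp(self, u: np.ndarray, t: float, lam: np.ndarray) -> np.ndarray:
        """J(u)^T lam for the state Jacobian of this term."""
        raise NotImplementedError


@dataclass(frozen=True)
class InputField:
    """Declaration of one closure input.

    kind "state": spatial derivative of order ``deriv`` of state ``index``
    (0 = the state itself); kind "param": a fixed scalar; kind "exog": a
    prescribed field fn(x, t).
    """

    kind: str
    index: int = 0
    deriv: int = 0
    value: float | Callable | None = None


class ClosureBinding:
    """A closure joined to a system's grid, schemes and boundary conditions.

    Responsible for building the node-wise input dictionary from the state
    array (computing the declared spatial derivatives), and for routing the
    adjoint cotangents of the inputs back to state space through the exact
    transposes of the derivative operators.
    """

    def __init__(
        self,
        closure: LinearClosure | DeepClosure,
        input_map: dict[str, InputField],
        grid: Grid1D,
        bcs: Sequence[BCSpec],
        scheme_accuracy: int = 4,
    ):
        self.closure = closure
        self.input_map = dict(input_map)
        self.grid = grid
        self._x = grid.x
        self._ops: dict[tuple[int, int], DiffOp] = {}
        for name, spec in self.input_map.items():
            if spec.kind == "state" and spec.deriv > 0:
                key = (spec.index, spec.deriv)
                if key not in self._ops:
                    self._ops[key] = DiffOp(
                        grid,
                        DerivativeScheme("central", scheme_accuracy, spec.deriv),
                        bcs=bcs[spec.index],
                    )

    @property
    def max_reach(self) -> int:
        return max((op._n_ghost for op in self._ops.values()), default=0)

    def build_inputs(self, u: np.ndarray, t: float) -> dict:
        inp: dict = {}
        for name, spec in self.input_map.items():
            if spec.kind == "state":
                if spec.deriv == 0:
                    inp[name] = u[:, spec.index]
                else:
                    inp[name] = self._ops[(spec.index, spec.deriv)].apply(u[:, spec.index], t=t)
            elif spec.kind == "param":
                inp[name] = spec.value(t) if callable(spec.value) else float(spec.value)
            elif spec.kind == "exog":
                inp[name] = np.asarray(spec.value(self._x, t), dtype=float)
            else:
                raise ValueError(f"unknown input kind {spec.kind!r}")
        return inp

    def eval(self, u: np.ndarray, t: float) -> np.ndarray:
        return self.closure.eval(self.build_inputs(u, t))

    def vjp(self, u: np.ndarray, t: float, lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (J_u^T lam of shape (Nx, ns), parameter-gradient integrand)."""
        cot, grad = self.closure.vjp(self.build_inputs(u, t), lam)
        lam_u = np.zeros_like(u)
        for name, c in cot.items():
            spec = self.input_map[name]
            if spec.kind != "state":
                continue
            if spec.deriv == 0:
                lam_u[:, spec.index] += c
            else:
                lam_u[:, spec.index] += self._ops[(spec.index, spec.deriv)].apply_transpose(c)
        return lam_u, grad


@dataclass
class NPDDESystem:
    """Low-fidelity RHS + closures + delay: the trainable object."""

    grid: Grid1D
    n_states: int
    bcs: Sequence[BCSpec]
    lowfi_terms: Sequence[Term] = ()
    markovian: ClosureBinding | None = None
    nonmarkovian: ClosureBinding | None = None
    tau: float = 0.0
    history: Callable[[float], np.ndarray] | None = None
    state_names: Sequence[str] | None = None
    method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-8
    band_nodes: int = 8  # conservative Jacobian bandwidth in node units

    def __post_init__(self) -> None:
        if len(self.bcs) != self.n_states:
            raise ValueError("one BCSpec per state required")
        if self.state_names is None:
            self.state_names = [f"u{i}" for i in range(self.n_states)]
        # Dirichlet-pinned boundary nodes are not evolved by the PDE: their
        # value is the boundary datum, so the tendency is projected out (and
        # the same projection enters the adjoint as J = P J_full).
        mask = np.ones((self.grid.n_points, self.n_states))
        for s, bc in enumerate(self.bcs):
            if any(c.order == 0 for c in bc.left):
                mask[0, s] = 0.0
            if any(c.order == 0 for c in bc.right):
                mask[-1, s] = 0.0
        self.evolve_mask = mask

    # -- delay bookkeeping ----------------------------------------------------

    @property
    def has_memory(self) -> bool:
        return self.nonmarkovian is not None and self.tau > 0

    @property
    def n_aug(self) -> int:
        return self.n_states * (2 if self.has_memory else 1)

    def pack(self, u: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
        if not self.has_memory:
            return u.ravel()
        return np.concatenate([u, y], axis=1).ravel()

    def unpack(self, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        N = self.grid.n_points
        full = vec.reshape(N, self.n_aug)
        if not self.has_memory:
            return full, None
        return full[:, : self.n_states], full[:, self.n_states :]

    # -- right-hand sides -------------------------------------------------------

    def state_rhs(self, u: np.ndarray, t: float, y: np.ndarray | None) -> np.ndarray:
        du = np.zeros_like(u)
        for term in self.lowfi_terms:
            du += term.eval(u, t)
        if self.markovian is not None:
            du += self.markovian.eval(u, t)
        if y is not None:
            du += y
        return du * self.evolve_mask

    def state_vjp(self, u: np.ndarray, t: float, lam: np.ndarray) -> np.ndarray:
        lam = lam * self.evolve_mask
        out = np.zeros_like(lam)
        for term in self.lowfi_terms:
            out += term.vjp(u, t, lam)
        if self.markovian is not None:
            out += self.markovian.vjp(u, t, lam)[0]
        return out

    def jac_bandwidth(self) -> int:
        reach = self.band_nodes
        for b in (self.markovian, self.nonmarkovian):
            if b is not None:
                reach = max(reach, b.max_reach + 4)
        return (reach + 1) * self.n_aug

    def solver_options(self, method: str) -> dict:
        if method == "LSODA":
            band = min(self.jac_bandwidth(), self.grid.n_points * self.n_aug - 1)
            return {"lband": band, "uband": band}
        return {}


def history_integral(
    system: NPDDESystem,
    prehistory: Callable[[float], np.ndarray] | None = None,
    t0: float = 0.0,
    n_quad: int = 33,
) -> np.ndarray:
    """Memory-state initialization y(t0) by composite-trapezoid quadrature of
    the delay kernel over the history window [t0 - tau, t0]."""
    u_of = prehistory if prehistory is not None else system.history
    if system.nonmarkovian is None or system.tau <= 0:
        if system.nonmarkovian is not None:
            import warnings

            warnings.warn("delay kernel present but tau <= 0; memory state is zero")
        return np.zeros((system.grid.n_points, system.n_states))
    if u_of is None:
        raise ValueError("history function required for tau > 0")
    ss = np.linspace(t0 - system.tau, t0, n_quad)
    w = np.full(n_quad, ss[1] - ss[0])
    w[0] = w[-1] = 0.5 * (ss[1] - ss[0])
    y0 = np.zeros((system.grid.n_points, system.n_states))
    for s, ws in zip(ss, w):
        y0 += ws * system.nonmarkovian.eval(u_of(s), s)
    return y0


def augmented_rhs(
    t: float,
    u: np.ndarray,
    y: np.ndarray | None,
    system: NPDDESystem,
    delayed_lookup: Callable[[float], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Tendencies of the coupled (state, memory) system."""
    du = system.state_rhs(u, t, y)
    if not system.has_memory:
        return du, None
    if delayed_lookup is None:
        raise ValueError("delayed_lookup required for a system with memory")
    u_del = delayed_lookup(t - system.tau)
    dy = system.nonmarkovian.eval(u, t) - system.nonmarkovian.eval(u_del, t - system.tau)
    return du, dy


class Trajectory:
    """Time-stamped forward solution with a continuous-in-time interpolant."""

    def __init__(
        self,
        system: NPDDESystem,
        segments: list,
        t0: float,
        t_end: float,
        save_times: np.ndarray,
        prehistory: Callable[[float], np.ndarray] | None,
    ):
        self.system = system
        self.segments = segments  # list of scipy OdeSolution
        self.t0 = float(t0)
        self.t_end = float(t_end)
        self.times = np.asarray(save_times, dtype=float)
        self.prehistory = prehistory
        self.states = np.stack([self.u(t) for t in self.times], axis=0)  # (M, Nx, ns)

    def _vec(self, t: float) -> np.ndarray:
        for seg in self.segments:
            lo, hi = min(seg.t_min, seg.t_max), max(seg.t_min, seg.t_max)
            if lo - 1e-12 <= t <= hi + 1e-12:
                return seg(np.clip(t, lo, hi))
        raise ValueError(f"time {t} outside solved span [{self.t0}, {self.t_end}]")

    def u(self, t: float) -> np.ndarray:
        if t < self.t0:
            if self.prehistory is None:
                raise ValueError(f"time {t} precedes the solved span and no history is set")
            return self.prehistory(t)
        return self.system.unpack(self._vec(t))[0]

    def y(self, t: float) -> np.ndarray | None:
        return self.system.unpack(self._vec(max(t, self.t0)))[1]

    def lookup(self, t: float) -> np.ndarray:
        return self.u(t)


def solve_forward(
    system: NPDDESystem,
    u0: np.ndarray,
    save_times: Sequence[float],
    t0: float = 0.0,
    prehistory: Callable[[float], np.ndarray] | None = None,
    method: str | None = None,
    rtol: float | None = None,
    atol: float | None = None,
    max_step: float | None = None,
) -> Trajectory:
    """Adaptive method-of-lines integration of the (possibly delayed) system.

    ``prehistory`` overrides the system history function; for delay systems it
    supplies u(t) on [t0 - tau, t0] for delayed lookups and the memory-state
    initialization.
    """
    save_times = np.asarray(save_times, dtype=float)
    if np.any(np.diff(save_times) <= 0):
        raise ValueError("save_times must be strictly increasing")
    if save_times[0] < t0 - 1e-12:
        raise ValueError("save_times must lie within the solved span")
    method = method or system.method
    rtol = system.rtol if rtol is None else rtol
    atol = system.atol if atol is None else atol
    t_end = float(save_times[-1])
    u0 = np.asarray(u0, dtype=float).reshape(system.grid.n_points, system.n_states)
    opts = system.solver_options(method)
    if max_step is not None:
        opts["max_step"] = max_step

    pre = prehistory if prehistory is not None else system.history
    segments: list = []

    if not system.has_memory:
        vec0 = system.pack(u0)

        def f(t, vec):
            u, _ = system.unpack(vec)
            return system.state_rhs(u, t, None).ravel()

        sol = solve_ivp(f, (t0, t_end), vec0, method=method, dense_output=True,
                        rtol=rtol, atol=atol, **opts)
        if not sol.success:
            raise SolverFailure(f"forward solve failed: {sol.message}", sol.t[-1] if len(sol.t) else t0)
        if not np.all(np.isfinite(sol.y[:, -1])) or np.max(np.abs(sol.y[:, -1])) > 1e6:
            raise SolverFailure("forward solution blew up", sol.t[-1])
        segments.append(sol.sol)
        return Trajectory(system, segments, t0, t_end, save_times, pre)

    if pre is None:
        raise ValueError("delay system requires a history function")
    y0 = history_integral(system, prehistory=pre, t0=t0)
    vec = system.pack(u0, y0)

    def lookup(t: float) -> np.ndarray:
        if t <= t0 + 1e-14:
            return pre(min(t, t0))
        for seg in segments:
            if seg.t_min - 1e-12 <= t <= seg.t_max + 1e-12:
                return system.unpack(seg(np.clip(t, seg.t_min, seg.t_max)))[0]
        raise ValueError(f"delayed lookup at t={t} not covered (interpolant bug)")

    def f(t, v):
        u, y = system.unpack(v)
        du, dy = augmented_rhs(t, u, y, system, delayed_lookup=lookup)
        return np.concatenate([du, dy], axis=1).ravel()

    t = t0
    while t < t_end - 1e-12:
        t_next = min(t + system.tau, t_end)
        sol = solve_ivp(f, (t, t_next), vec, method=method, dense_output=True,
                        rtol=rtol, atol=atol, **opts)
        if not sol.success:
            raise SolverFailure(f"forward solve failed: {sol.message}", sol.t[-1])
        if not np.all(np.isfinite(sol.y[:, -1])) or np.max(np.abs(sol.y[:, -1])) > 1e6:
            raise SolverFailure("forward solution blew up", sol.t[-1])
        segments.append(sol.sol)
        vec = sol.y[:, -1]
        t = t_next
    return Trajectory(system, segments, t0, t_end, save_times, pre)
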