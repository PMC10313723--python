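"""Nonlinear-wave testbeds: KdV–Burgers two-soliton and Burgers shock.

The KdV–Burgers truth is  u_t = -6 u u_x - u_xxx  with an exact two-soliton
solution; the low-fidelity model keeps only  u_t = -u u_x  and the missing
dispersion/advection must be discovered by a library closure.

The Burgers truth is  u_t = -u u_x + (1/Re) u_xx  with an exact shock
solution; the "low-fidelity" error is the truncation error of a 1st-order
upwind discretization, whose leading term  -(dx/2) u u_xx  the closure should
discover.  A Smagorinsky eddy-viscosity model and the raw truncation term are
the comparison baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .closures import DeepClosure, Feature, FunctionLibrary, LinearClosure
from .numerics import BCSpec, BoundaryCondition, DerivativeScheme, DiffOp, Grid1D
from .npdde import ClosureBinding, InputField, NPDDESystem, SolverFailure, Term, solve_forward

__all__ = [
    "SolitonParams",
    "BurgersParams",
    "kdv_two_soliton",
    "burgers_analytical",
    "AdvectionTerm",
    "LinearDerivativeTerm",
    "TruncationClosureTerm",
    "SmagorinskyTerm",
    "wave_model_rhs",
    "make_kdv_system",
    "make_burgers_system",
    "kdv_library",
    "burgers_library",
    "burgers_deep_kernel",
    "error_metrics",
    "generalization_sweep",
]


@dataclass(frozen=True)
class SolitonParams:
    eta1: float = 1.2
    eta2: float = 0.8
    x1: float = -6.0
    x2: float = -2.0
    L: float = 10.0
    T: float = 1.5

    def __post_init__(self) -> None:
        if not self.eta1 >= self.eta2 > 0:
            raise ValueError("need eta1 >= eta2 > 0")


@dataclass(frozen=True)
class BurgersParams:
    Re: float = 1000.0
    L: float = 1.25
    T: float = 8.0
    Nx: int = 50
    Cs: float = 1.0

    @property
    def nu(self) -> float:
        return 1.0 / self.Re

    @property
    def t0(self) -> float:
        return float(np.exp(self.Re / 8.0))


def kdv_two_soliton(x, t, p: SolitonParams = SolitonParams()) -> np.ndarray:
    """Exact elastic-collision two-soliton solution of u_t = -6uu_x - u_xxx.

    Soliton i has amplitude 2*eta_i^2, width 1/eta_i, speed 4*eta_i^2.
    """
    x = np.asarray(x, dtype=float)
    th1 = p.eta1 * (x - p.x1 - 4.0 * p.eta1**2 * t)
    th2 = p.eta2 * (x - p.x2 - 4.0 * p.eta2**2 * t)
    num = 8.0 * (p.eta1**2 - p.eta2**2) * (
        p.eta1**2 * np.cosh(th2) ** 2 + p.eta2**2 * np.sinh(th1) ** 2
    )
    den = (p.eta1 - p.eta2) * np.cosh(th1 + th2) + (p.eta1 + p.eta2) * np.cosh(th1 - th2)
    return num / den**2


def burgers_analytical(x, t, p: BurgersParams) -> np.ndarray:
    """Exact advecting-shock solution of u_t = -uu_x + (1/Re) u_xx."""
    x = np.asarray(x, dtype=float)
    return (x / (t + 1.0)) / (
        1.0 + np.sqrt((t + 1.0) / p.t0) * np.exp(p.Re * x**2 / (4.0 * t + 4.0))
    )


# ---------------------------------------------------------------------------
# low-fidelity / truth right-hand-side terms


class AdvectionTerm(Term):
    """-factor * u * u_x with an upwind discretization (wind = u)."""

    def __init__(self, grid: Grid1D, bcs: BCSpec, factor: float = 1.0, accuracy: int = 2):
        self.factor = factor
        self.op = DiffOp(grid, DerivativeScheme("upwind", accuracy, 1), bcs=bcs)

    def eval(self, u, t):
        v = u[:, 0]
        ux = self.op.apply(v, wind=v, t=t)
        return (-self.factor * v * ux)[:, None]

    def vjp(self, u, t, lam):
        v = u[:, 0]
        l = lam[:, 0]
        ux = self.op.apply(v, wind=v, t=t)
        out = -self.factor * (ux * l + self.op.apply_transpose(v * l, wind=v))
        return out[:, None]


class LinearDerivativeTerm(Term):
    """coef * d^d u / dx^d with a central discretization."""

    def __init__(self, grid: Grid1D, bcs: BCSpec, coef: float, deriv: int, accuracy: int = 4):
        self.coef = coef
        self.op = DiffOp(grid, DerivativeScheme("central", accuracy, deriv), bcs=bcs)

    def eval(self, u, t):
        return (self.coef * self.op.apply(u[:, 0], t=t))[:, None]

    def vjp(self, u, t, lam):
        return (self.coef * self.op.apply_transpose(lam[:, 0]))[:, None]


class TruncationClosureTerm(Term):
    """The leading upwind truncation error, -(dx/2) u u_xx, used as a fixed
    (untrained) closure baseline."""

    def __init__(self, grid: Grid1D, bcs: BCSpec, accuracy: int = 4):
        self.dx = grid.dx
        self.op = DiffOp(grid, DerivativeScheme("central", accuracy, 2), bcs=bcs)

    def eval(self, u, t):
        v = u[:, 0]
        return (-0.5 * self.dx * v * self.op.apply(v, t=t))[:, None]

    def vjp(self, u, t, lam):
        v = u[:, 0]
        l = lam[:, 0]
        uxx = self.op.apply(v, t=t)
        return (-0.5 * self.dx * (uxx * l + self.op.apply_transpose(v * l)))[:, None]


class SmagorinskyTerm(Term):
    """LES eddy-viscosity closure  d/dx( nu_e u_x ),  nu_e = (Cs dx)^2 |u_x|."""

    def __init__(self, grid: Grid1D, bcs: BCSpec, Cs: float = 1.0):
        self.c2 = (Cs * grid.dx) ** 2
        self.op_in = DiffOp(grid, DerivativeScheme("central", 2, 1), bcs=bcs)
        self.op_out = DiffOp(grid, DerivativeScheme("central", 2, 1))  # flux field

    def eval(self, u, t):
        ux = self.op_in.apply(u[:, 0], t=t)
        flux = self.c2 * np.abs(ux) * ux
        return self.op_out.apply(flux)[:, None]

    def vjp(self, u, t, lam):
        ux = self.op_in.apply(u[:, 0], t=t)
        w = self.op_out.apply_transpose(lam[:, 0])
        return self.op_in.apply_transpose(2.0 * self.c2 * np.abs(ux) * w)[:, None]


# ---------------------------------------------------------------------------
# systems and libraries

KDV_BCS = BCSpec(
    left=(BoundaryCondition(0, 0.0),),
    right=(BoundaryCondition(1, 0.0), BoundaryCondition(2, 0.0)),
)


def kdv_library() -> FunctionLibrary:
    return FunctionLibrary(
        [
            Feature("u_xx", "u_xx", ["u_xx"]),
            Feature("u_xxx", "u_xxx", ["u_xxx"]),
            Feature("u*u_x", "u*u_x", ["u", "u_x"]),
            Feature("u^2*u_x", "u**2*u_x", ["u", "u_x"]),
        ]
    )


def burgers_library() -> FunctionLibrary:
    """Second-degree combinations of u, u_x, u_xx made dimensionally
    consistent with powers of the grid spacing."""
    return FunctionLibrary(
        [
            Feature("dx*(u_x)^2", "dx*u_x**2", ["u_x", "dx"]),
            Feature("dx^3*(u_xx)^2", "dx**3*u_xx**2", ["u_xx", "dx"]),
            Feature("dx^2*(u_x*u_xx)", "dx**2*u_x*u_xx", ["u_x", "u_xx", "dx"]),
            Feature("dx*(u*u_xx)", "dx*u*u_xx", ["u", "u_xx", "dx"]),
        ]
    )


def _wave_input_map(grid: Grid1D, max_deriv: int, nu: float | None = None) -> dict[str, InputField]:
    m = {
        "u": InputField("state", 0, 0),
        "u_x": InputField("state", 0, 1),
        "u_xx": InputField("state", 0, 2),
        "dx": InputField("param", value=grid.dx),
    }
    if max_deriv >= 3:
        m["u_xxx"] = InputField("state", 0, 3)
    if nu is not None:
        m["nu"] = InputField("param", value=nu)
    return m


def burgers_deep_kernel(hidden=(32, 32, 32, 32)) -> DeepClosure:
    """Delay kernel for the Burgers experiments: inputs (u, u_x, u_xx, nu, dx),
    swish MLP, output gated by |u| so the closure vanishes ahead of the shock."""
    return DeepClosure(["u", "u_x", "u_xx", "nu", "dx"], hidden, n_out=1, gate="u")


def make_kdv_system(
    model_kind: str = "lowfi",
    Nx: int = 200,
    p: SolitonParams = SolitonParams(),
    closure: LinearClosure | None = None,
) -> NPDDESystem:
    """KdV testbed systems.

    kinds: "true" (full KdV), "lowfi" (advection only), "closure" (lowfi +
    trainable library closure).  Advection is 2nd-order upwind, all other
    derivatives 4th-order central; adaptive stiff time stepping.
    """
    grid = Grid1D(-p.L, p.L, Nx)
    bcs = [KDV_BCS]
    terms: list[Term] = []
    markovian = None
    if model_kind == "true":
        terms = [AdvectionTerm(grid, KDV_BCS, factor=6.0, accuracy=2),
                 LinearDerivativeTerm(grid, KDV_BCS, -1.0, 3, accuracy=4)]
    elif model_kind == "lowfi":
        terms = [AdvectionTerm(grid, KDV_BCS, factor=1.0, accuracy=2)]
    elif model_kind == "closure":
        terms = [AdvectionTerm(grid, KDV_BCS, factor=1.0, accuracy=2)]
        if closure is None:
            closure = LinearClosure(kdv_library())
        markovian = ClosureBinding(closure, _wave_input_map(grid, 3), grid, bcs, scheme_accuracy=4)
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    return NPDDESystem(grid, 1, bcs, lowfi_terms=terms, markovian=markovian,
                       state_names=["u"], method="LSODA")


def make_burgers_system(
    p: BurgersParams,
    closure_kind: str = "none",
    markovian_closure: LinearClosure | None = None,
    delay_kernel: DeepClosure | None = None,
    tau: float = 0.075,
    right_bc: str = "neumann",
    Nx: int | None = None,
) -> NPDDESystem:
    """Burgers testbed: 1st-order upwind advection + 2nd-order central
    diffusion, optional closure terms.

    closure_kind in {"none", "truncation", "smagorinsky", "markovian",
    "full"}; "full" adds the non-Markovian delay kernel on top of the
    Markovian library term.
    """
    Nx = Nx if Nx is not None else p.Nx
    grid = Grid1D(0.0, p.L, Nx)
    right = (BoundaryCondition(0, 0.0),) if right_bc == "dirichlet" else (BoundaryCondition(1, 0.0),)
    bc = BCSpec(left=(BoundaryCondition(0, 0.0),), right=right)
    bcs = [bc]
    terms: list[Term] = [
        AdvectionTerm(grid, bc, factor=1.0, accuracy=1),
        LinearDerivativeTerm(grid, bc, p.nu, 2, accuracy=2),
    ]
    markovian = None
    nonmark = None
    if closure_kind == "truncation":
        terms.append(TruncationClosureTerm(grid, bc, accuracy=4))
    elif closure_kind == "smagorinsky":
        terms.append(SmagorinskyTerm(grid, bc, Cs=p.Cs))
    elif closure_kind in ("markovian", "full"):
        if markovian_closure is None:
            markovian_closure = LinearClosure(burgers_library())
        markovian = ClosureBinding(markovian_closure, _wave_input_map(grid, 2, nu=p.nu),
                                   grid, bcs, scheme_accuracy=4)
        if closure_kind == "full":
            if delay_kernel is None:
                delay_kernel = burgers_deep_kernel()
            nonmark = ClosureBinding(delay_kernel, _wave_input_map(grid, 2, nu=p.nu),
                                     grid, bcs, scheme_accuracy=4)
    elif closure_kind != "none":
        raise ValueError(f"unknown closure_kind {closure_kind!r}")
    return NPDDESystem(grid, 1, bcs, lowfi_terms=terms, markovian=markovian,
                       nonmarkovian=nonmark, tau=tau if nonmark is not None else 0.0,
                       state_names=["u"], method="LSODA")


def wave_model_rhs(u: np.ndarray, grid: Grid1D, model_kind: str, params=None) -> np.ndarray:
    """One-off tendency evaluation for the wave models (diagnostic surface)."""
    u = np.asarray(u, dtype=float).reshape(grid.n_points, 1)
    if model_kind in ("kdv_true", "kdv_lowfi"):
        p = params or SolitonParams()
        sysm = make_kdv_system("true" if model_kind == "kdv_true" else "lowfi",
                               Nx=grid.n_points, p=p)
        return sysm.state_rhs(u, 0.0, None)[:, 0]
    p = params or BurgersParams()
    kind = {"burgers": "none", "burgers_truncation": "truncation",
            "burgers_smagorinsky": "smagorinsky"}.get(model_kind)
    if kind is None:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    sysm = make_burgers_system(replace(p, Nx=grid.n_points), closure_kind=kind)
    return sysm.state_rhs(u, 0.0, None)[:, 0]


# ---------------------------------------------------------------------------
# metrics and sweep


def error_metrics(pred: np.ndarray, true: np.ndarray, rel_threshold: float = 0.02):
    """Snapshot-averaged spatial errors.

    RMSE = (1/M) sum_i sqrt( (1/Nx) sum_j delta_ij^2 ).  RMSE(>2%) repeats the
    computation keeping only grid points where |delta| >= rel_threshold *
    max|u_true| (global max); a snapshot with an empty mask contributes zero.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth shape mismatch")
    d = pred - true
    rmse = float(np.mean(np.sqrt(np.mean(d**2, axis=1))))
    thr = rel_threshold * np.max(np.abs(true))
    mask = np.abs(d) >= thr
    per_t = np.zeros(d.shape[0])
    for i in range(d.shape[0]):
        if mask[i].any():
            per_t[i] = np.sqrt(np.mean(d[i, mask[i]] ** 2))
    return rmse, float(np.mean(per_t))


def _burgers_truth_prehistory(p: BurgersParams, grid: Grid1D):
    u0 = burgers_analytical(grid.x, 0.0, p)[:, None]
    return lambda t: u0  # initial state held constant over the history window


def generalization_sweep(
    closure_kind: str,
    Nx_list=(50, 88, 125, 162, 200),
    Re_list=(50, 292, 533, 775, 1017, 1258, 1500),
    markovian_closure: LinearClosure | None = None,
    delay_kernel: DeepClosure | None = None,
    T: float = 8.0,
    n_eval: int = 81,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> pd.DataFrame:
    """Evaluate a closure over the (Nx, Re) lattice against the exact shock
    solution; solver failures and blow-ups are recorded, not raised."""
    rows = []
    times = np.linspace(0.0, T, n_eval)[1:]
    for Nx in Nx_list:
        for Re in Re_list:
            p = BurgersParams(Re=float(Re), Nx=int(Nx), T=T)
            sysm = make_burgers_system(p, closure_kind=closure_kind,
                                       markovian_closure=markovian_closure,
                                       delay_kernel=delay_kernel)
            grid = sysm.grid
            u0 = burgers_analytical(grid.x, 0.0, p)
            truth = np.stack([burgers_analytical(grid.x, t, p) for t in times])
            try:
                traj = solve_forward(sysm, u0[:, None], times, rtol=rtol, atol=atol,
                                     prehistory=_burgers_truth_prehistory(p, grid))
                pred = traj.states[:, :, 0]
                converged = bool(np.all(np.isfinite(pred)) and np.max(np.abs(pred)) < 1e3)
            except (SolverFailure, FloatingPointError):
                pred = None
                converged = False
            if converged:
                rmse, rmse2 = error_metrics(pred, truth)
            else:
                rmse = rmse2 = np.nan
            rows.append({"Nx": Nx, "Re": Re, "rmse": rmse, "rmse_gt2pct": rmse2,
                         "converged": converged})
    return pd.DataFrame(rows)
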