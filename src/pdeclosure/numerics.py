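"""Uniform 1-D grids, finite-difference operators, and ghost-cell boundary
conditions.

Derivative operators are materialized as dense matrices acting on the raw
nodal values (ghost construction folded in), because the backward adjoint
solve needs their exact transposes.  All grids in this package are small
(N <= 1000), so dense algebra is both simpler and faster than sparse here.

Boundary conditions are imposed with ghost layers: on each side a single
polynomial is fit to the boundary conditions (derivative order k, value g)
plus the nearest interior nodal values, and evaluated at the ghost nodes.
This makes mixed high-order conditions (e.g. u_x = u_xx = 0 on the right
edge of the KdV domain) one-liners, and the whole extension is affine in
the interior values: ``u_ext = E u + b(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Grid1D",
    "BoundaryCondition",
    "BCSpec",
    "DerivativeScheme",
    "GhostExtension",
    "DiffOp",
    "fornberg_weights",
    "fd_derivative",
    "apply_boundary_conditions",
]


@dataclass(frozen=True)
class Grid1D:
    """Node-centered uniform grid, inclusive of both endpoints."""

    x_left: float
    x_right: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if not self.x_right > self.x_left:
            raise ValueError("x_right must exceed x_left")

    @property
    def dx(self) -> float:
        return (self.x_right - self.x_left) / (self.n_points - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.x_left, self.x_right, self.n_points)

    @property
    def quad_weights(self) -> np.ndarray:
        """Trapezoid quadrature weights for integrals over the domain."""
        w = np.full(self.n_points, self.dx)
        w[0] = w[-1] = 0.5 * self.dx
        return w

    @property
    def length(self) -> float:
        return self.x_right - self.x_left


@dataclass(frozen=True)
class BoundaryCondition:
    """One condition d^k u / dx^k = value at a boundary.

    ``value`` may be a constant or a callable of time.
    """

    order: int
    value: float | Callable[[float], float] = 0.0

    def __call__(self, t: float) -> float:
        if callable(self.value):
            return float(self.value(t))
        return float(self.value)


@dataclass(frozen=True)
class BCSpec:
    """Per-side condition lists for one state variable."""

    left: tuple[BoundaryCondition, ...] = ()
    right: tuple[BoundaryCondition, ...] = ()

    @staticmethod
    def dirichlet(left: float | None = 0.0, right: float | None = 0.0) -> "BCSpec":
        l = (BoundaryCondition(0, left),) if left is not None else ()
        r = (BoundaryCondition(0, right),) if right is not None else ()
        return BCSpec(left=l, right=r)

    @staticmethod
    def noflux() -> "BCSpec":
        return BCSpec(left=(BoundaryCondition(1, 0.0),), right=(BoundaryCondition(1, 0.0),))


@dataclass(frozen=True)
class DerivativeScheme:
    kind: str = "central"  # {"central", "upwind"}
    accuracy: int = 2
    order: int = 1  # derivative order d

    def __post_init__(self) -> None:
        if self.kind not in ("central", "upwind"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.order not in (1, 2, 3):
            raise ValueError("derivative order must be 1, 2 or 3")
        if self.accuracy not in (1, 2, 4):
            raise ValueError("accuracy must be 1, 2 or 4")
        if self.kind == "upwind" and self.order != 1:
            raise ValueError("upwind schemes are for first derivatives")
        if self.kind == "central" and self.accuracy % 2:
            raise ValueError("central schemes have even accuracy")

    @property
    def half_width(self) -> int:
        d, a = self.order, self.accuracy
        if self.kind == "upwind":
            return a  # points {j-a, ..., j} for positive wind
        return (a + d - 1) // 2 if d % 2 else (a + d - 2) // 2


def fornberg_weights(x: np.ndarray, x0: float, d: int) -> np.ndarray:
    """Finite-difference weights of B. Fornberg (1988) for the d-th
    derivative at ``x0`` on arbitrary nodes ``x``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= d:
        raise ValueError("need more than d nodes")
    c = np.zeros((n, d + 1))
    c[0, 0] = 1.0
    c1, c4 = 1.0, x[0] - x0
    for i in range(1, n):
        mn = min(i, d)
        c2, c5, c4 = 1.0, c4, x[i] - x0
        for j in range(i):
            c3 = x[i] - x[j]
            c2 *= c3
            if j == i - 1:
                for k in range(mn, 0, -1):
                    c[i, k] = c1 * (k * c[i - 1, k - 1] - c5 * c[i - 1, k]) / c2
                c[i, 0] = -c1 * c5 * c[i - 1, 0] / c2
            for k in range(mn, 0, -1):
                c[j, k] = (c4 * c[j, k] - k * c[j, k - 1]) / c3
            c[j, 0] = c4 * c[j, 0] / c3
        c1 = c2
    return c[:, d]


class GhostExtension:
    """Affine ghost-layer construction ``u_ext = E u + b(t)`` for one state.

    On each side, a polynomial of degree ``fit_points - 1`` is determined by
    the boundary conditions plus the nearest interior values and evaluated at
    the ghost nodes.  With ``fit_points = m`` the ghost values are accurate to
    O(dx^m), so a d-th derivative through ghosts keeps its formal order as
    long as m >= accuracy + d.
    """

    def __init__(self, grid: Grid1D, bcs: BCSpec, n_ghost: int, fit_points: int | None = None):
        self.grid = grid
        self.bcs = bcs
        self.n_ghost = int(n_ghost)
        nbc = max(len(bcs.left), len(bcs.right))
        m = fit_points if fit_points is not None else max(self.n_ghost + 4, nbc + 2)
        for conds in (bcs.left, bcs.right):
            if len(conds) >= m:
                raise ValueError("over-determined boundary condition set")
            if len({c.order for c in conds}) != len(conds):
                raise ValueError("duplicate boundary condition orders on one side")
        if m > grid.n_points + min(len(bcs.left), len(bcs.right)):
            raise ValueError("grid too small for ghost extrapolation")
        self.fit_points = m
        N, g = grid.n_points, self.n_ghost
        E = np.zeros((N + 2 * g, N))
        E[g : g + N, :] = np.eye(N)
        # per-side: rows of the ghost values as linear maps on (interior values,
        # condition values)
        self._bc_maps: list[tuple[np.ndarray, tuple[BoundaryCondition, ...], np.ndarray]] = []
        dx = grid.dx
        for side in ("left", "right"):
            conds = bcs.left if side == "left" else bcs.right
            nbc = len(conds)
            q = m - nbc  # interior points used in the fit
            # condition rows: p^(k)(0) in scaled coordinate xi = (x - xb)/dx
            A = np.zeros((m, m))
            for i, c in enumerate(conds):
                A[i, c.order] = math.factorial(c.order) / dx**c.order
            # interior collocation rows at xi = 0, s, 2s, ... (s = +1 left, -1 right);
            # the boundary node is skipped when a Dirichlet condition already
            # pins the value there
            s = 1.0 if side == "left" else -1.0
            skip = 1 if any(c.order == 0 for c in conds) else 0
            for l in range(q):
                A[nbc + l, :] = (s * (l + skip)) ** np.arange(m)
            Ainv = np.linalg.inv(A)
            # ghost nodes at xi = -1..-g (left) or +1..+g in local coords -> -s*i
            V = np.array([[(-s * i) ** j for j in range(m)] for i in range(1, g + 1)])
            G = V @ Ainv  # (g, m): ghost values from [cond values; interior values]
            Gc, Gu = G[:, :nbc], G[:, nbc:]
            if side == "left":
                rows = np.arange(g - 1, -1, -1)  # ghost i=1 is row g-1
                cols = np.arange(skip, q + skip)
            else:
                rows = np.arange(N + g, N + 2 * g)
                cols = np.arange(N - 1 - skip, N - 1 - skip - q, -1)
            for gi, r in enumerate(rows):
                E[r, cols] = Gu[gi, :]
            bc_rows = np.zeros((g, N + 2 * g))  # placeholder; offsets built on demand
            self._bc_maps.append((Gc, conds, rows))
        self.E = E

    @property
    def time_dependent(self) -> bool:
        return any(callable(c.value) for _, conds, _ in self._bc_maps for c in conds)

    def offset(self, t: float) -> np.ndarray:
        if not self.time_dependent:
            if not hasattr(self, "_b_cache"):
                self._b_cache = self._offset(0.0)
            return self._b_cache
        return self._offset(t)

    def _offset(self, t: float) -> np.ndarray:
        b = np.zeros(self.grid.n_points + 2 * self.n_ghost)
        for Gc, conds, rows in self._bc_maps:
            if len(conds) == 0:
                continue
            gvals = np.array([c(t) for c in conds])
            b[rows] += Gc @ gvals
        return b

    def extend(self, values: np.ndarray, t: float = 0.0) -> np.ndarray:
        return self.E @ values + self.offset(t)


def apply_boundary_conditions(
    values: np.ndarray,
    grid: Grid1D,
    bcs: BCSpec,
    t: float = 0.0,
    n_ghost: int = 2,
    fit_points: int | None = None,
) -> np.ndarray:
    """Return the field extended with ``n_ghost`` ghost layers per side."""
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_points,):
        raise ValueError("field length must equal n_points")
    ext = GhostExtension(grid, bcs, n_ghost, fit_points)
    return ext.extend(values, t)


class DiffOp:
    """A derivative operator on a grid, materialized as dense matrices.

    Without boundary conditions, boundary-adjacent rows use shifted
    (one-sided) stencils of matching formal order.  With boundary
    conditions, every row differences the ghost-extended field.

    For upwind schemes the operator holds the positive-wind, negative-wind
    and central variants; ``apply`` selects per node by the sign of the
    advecting velocity (ties use the central stencil).
    """

    def __init__(
        self,
        grid: Grid1D,
        scheme: DerivativeScheme,
        bcs: BCSpec | None = None,
    ):
        self.grid = grid
        self.scheme = scheme
        self.bcs = bcs
        N, dx, d = grid.n_points, grid.dx, scheme.order
        hw = scheme.half_width
        if 2 * hw + 1 > N:
            raise ValueError("grid too small")

        def interior_matrix(offsets: np.ndarray) -> np.ndarray:
            """Rows differencing an extended field (N + 2*ghost columns)."""
            g = self._n_ghost
            w = fornberg_weights(offsets * dx, 0.0, d)
            M = np.zeros((N, N + 2 * g))
            for j in range(N):
                M[j, g + j + offsets] = w
            return M

        if bcs is not None:
            self._n_ghost = hw
            fit = scheme.accuracy + d  # ghost accuracy preserves formal order
            fit = max(fit, len(bcs.left) + 2, len(bcs.right) + 2, hw + 2)
            self.ext = GhostExtension(grid, bcs, hw, fit_points=fit)
            build = lambda offs: interior_matrix(offs) @ self.ext.E
            self._Dext = {}
            if scheme.kind == "central":
                offs = np.arange(-hw, hw + 1)
                self.A = build(offs)
                self._Dext["c"] = interior_matrix(offs)
            else:
                self.A_plus = build(np.arange(-hw, 1))
                self.A_minus = build(np.arange(0, hw + 1))
                coffs = np.arange(-((hw + 1) // 2), (hw + 1) // 2 + 1)
                self.A_central = build(coffs)
                self._Dext["+"] = interior_matrix(np.arange(-hw, 1))
                self._Dext["-"] = interior_matrix(np.arange(0, hw + 1))
                self._Dext["c"] = interior_matrix(coffs)
        else:
            self._n_ghost = 0
            self.ext = None

            def onesided(npts_interior: int) -> np.ndarray:
                # stencils clamped into the grid, widened near the boundary to
                # keep the formal order of accuracy
                npts_b = max(2 * hw + 1, d + scheme.accuracy)
                M = np.zeros((N, N))
                for j in range(N):
                    npts = 2 * hw + 1
                    lo = j - hw
                    if lo < 0 or lo + npts > N:
                        npts = min(npts_b, N)
                        lo = min(max(j - npts // 2, 0), N - npts)
                    idx = np.arange(lo, lo + npts)
                    M[j, idx] = fornberg_weights((idx - j) * dx, 0.0, d)
                return M

            if scheme.kind == "central":
                self.A = onesided(2 * hw + 1)
            else:

                def biased(direction: int) -> np.ndarray:
                    M = np.zeros((N, N))
                    for j in range(N):
                        offs = np.arange(-hw, 1) if direction > 0 else np.arange(0, hw + 1)
                        idx = j + offs
                        if idx[0] < 0 or idx[-1] >= N:
                            lo = min(max(j - hw // 2, 0), N - (hw + 1))
                            idx = np.arange(lo, lo + hw + 1)
                        M[j, idx] = fornberg_weights((idx - j) * dx, 0.0, d)
                    return M

                self.A_plus = biased(+1)
                self.A_minus = biased(-1)
                # ties (wind == 0) fall back to a 2nd-order central stencil
                self.A_central = DiffOp(grid, DerivativeScheme("central", 2, d)).A

    # -- application -------------------------------------------------------

    def masks(self, wind: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.scheme.kind != "upwind":
            raise ValueError("masks only apply to upwind schemes")
        if wind is None:
            raise ValueError("missing advecting velocity for upwind scheme")
        w = np.asarray(wind, dtype=float)
        mp = w > 0
        mm = w < 0
        mc = ~(mp | mm)
        return mp, mm, mc

    def _dboffset(self, key: str, t: float) -> np.ndarray | None:
        """Cached derivative-of-offset vector; None when identically zero."""
        if self.ext is None:
            return None
        if not self.ext.time_dependent:
            cache = getattr(self, "_db_cache", None)
            if cache is None:
                cache = self._db_cache = {}
            if key not in cache:
                v = self._Dext[key] @ self.ext.offset(0.0)
                cache[key] = v if np.any(v) else None
            return cache[key]
        return self._Dext[key] @ self.ext.offset(t)

    def apply(self, values: np.ndarray, wind: np.ndarray | None = None, t: float = 0.0) -> np.ndarray:
        if self.scheme.kind == "central":
            out = self.A @ values
            b = self._dboffset("c", t)
            if b is not None:
                out = out + b
            return out
        mp, mm, mc = self.masks(wind)
        out = mp * (self.A_plus @ values) + mm * (self.A_minus @ values) + mc * (self.A_central @ values)
        if self.ext is not None:
            for key, m in (("+", mp), ("-", mm), ("c", mc)):
                b = self._dboffset(key, t)
                if b is not None:
                    out = out + m * b
        return out

    def apply_transpose(self, lam: np.ndarray, wind: np.ndarray | None = None) -> np.ndarray:
        """Apply the transpose of the (wind-frozen) linear part."""
        if self.scheme.kind == "central":
            return self.A.T @ lam
        mp, mm, mc = self.masks(wind)
        return (
            self.A_plus.T @ (mp * lam)
            + self.A_minus.T @ (mm * lam)
            + self.A_central.T @ (mc * lam)
        )

    def matrix(self, wind: np.ndarray | None = None) -> np.ndarray:
        if self.scheme.kind == "central":
            return self.A
        mp, mm, mc = self.masks(wind)
        return mp[:, None] * self.A_plus + mm[:, None] * self.A_minus + mc[:, None] * self.A_central


def fd_derivative(
    values: np.ndarray,
    grid: Grid1D,
    scheme: DerivativeScheme,
    wind: np.ndarray | None = None,
    bcs: BCSpec | None = None,
    t: float = 0.0,
) -> np.ndarray:
    """d-th spatial derivative of a nodal field.

    With ``bcs`` the stencil reaches into ghost layers built from the
    conditions; otherwise boundary-adjacent nodes fall back to one-sided
    stencils of matching order.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_points,):
        raise ValueError("field length must equal n_points")
    op = DiffOp(grid, scheme, bcs=bcs)
    return op.apply(values, wind=wind, t=t)
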