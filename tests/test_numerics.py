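"""Finite-difference operators, grids and ghost-cell boundary conditions."""

import numpy as np
import pytest

from pdeclosure.numerics import (BCSpec, BoundaryCondition, DerivativeScheme,
                                 DiffOp, Grid1D, apply_boundary_conditions,
                                 fd_derivative, fornberg_weights)

GRID = Grid1D(-10.0, 10.0, 201)


class TestGrid:
    def test_spacing_and_nodes(self):
        g = Grid1D(0.0, 1.0, 11)
        assert g.dx == pytest.approx(0.1)
        assert g.x[0] == 0.0 and g.x[-1] == 1.0
        assert np.allclose(np.diff(g.x), g.dx)

    def test_quadrature_integrates_exactly(self):
        g = Grid1D(0.0, 2.0, 21)
        assert g.quad_weights @ (3 * g.x + 1) == pytest.approx(8.0)

    def test_invalid_grids(self):
        with pytest.raises(ValueError):
            Grid1D(0.0, 0.0, 10)
        with pytest.raises(ValueError):
            Grid1D(0.0, 1.0, 1)


class TestFornberg:
    def test_classic_central_weights(self):
        w = fornberg_weights(np.array([-1.0, 0.0, 1.0]), 0.0, 2)
        assert np.allclose(w, [1.0, -2.0, 1.0])
        w = fornberg_weights(np.array([-2.0, -1.0, 0.0]), 0.0, 1)
        assert np.allclose(w, [0.5, -2.0, 1.5])  # 2nd-order upwind


@pytest.mark.parametrize("scheme,degree", [
    (DerivativeScheme("central", 2, 1), 2),
    (DerivativeScheme("central", 4, 1), 4),
    (DerivativeScheme("central", 4, 2), 5),
    (DerivativeScheme("central", 4, 3), 6),
])
def test_polynomial_exactness(scheme, degree):
    """A p-th order scheme differentiates degree <= p + d - 1 polynomials
    exactly (interior and one-sided boundary stencils alike)."""
    coeffs = np.arange(1, degree + 2, dtype=float)
    poly = np.polynomial.Polynomial(coeffs)
    exact = poly.deriv(scheme.order)(GRID.x)
    num = fd_derivative(poly(GRID.x), GRID, scheme)
    assert np.allclose(num, exact, rtol=1e-6, atol=1e-6 * np.abs(exact).max())


@pytest.mark.parametrize("d", [1, 2, 3])
def test_constant_field_has_zero_derivative(d):
    u = np.full(GRID.n_points, 7.3)
    out = fd_derivative(u, GRID, DerivativeScheme("central", 4, d))
    assert np.allclose(out, 0.0, atol=1e-9)


def test_measured_convergence_order_matches_nominal():
    """Richardson test on sin(x): halving dx divides the 4th-order error by
    about 16 (measured order >= nominal - 0.2)."""
    errs = []
    for n in (401, 801):
        g = Grid1D(-10.0, 10.0, n)
        num = fd_derivative(np.sin(g.x), g, DerivativeScheme("central", 4, 1))
        errs.append(np.abs(num - np.cos(g.x)).max())
    order = np.log2(errs[0] / errs[1])
    assert order >= 4.0 - 0.2


class TestUpwind:
    def test_requires_wind(self):
        with pytest.raises(ValueError, match="advecting velocity"):
            fd_derivative(np.sin(GRID.x), GRID, DerivativeScheme("upwind", 2, 1))

    def test_direction_selects_stencil(self):
        """With wind > 0 the stencil is fully left-biased, so a field that is
        polynomial on the left side is differentiated exactly even if it is
        wild on the right of the node."""
        g = Grid1D(0.0, 1.0, 11)
        u = g.x.copy()
        u[6:] = 100.0  # garbage downstream of node 5
        op = DiffOp(g, DerivativeScheme("upwind", 2, 1))
        d = op.apply(u, wind=np.ones(11))
        assert d[5] == pytest.approx(1.0)

    def test_tie_uses_central(self):
        g = Grid1D(0.0, 1.0, 11)
        op = DiffOp(g, DerivativeScheme("upwind", 2, 1))
        d = op.apply(g.x**2, wind=np.zeros(11))
        assert np.allclose(d[1:-1], 2 * g.x[1:-1])


class TestBoundaryConditions:
    def test_zero_dirichlet_reconstruction(self):
        bcs = BCSpec(left=(BoundaryCondition(0, 0.0),))
        u = np.sin(GRID.x + 10.0)  # satisfies u(x_left) = 0
        ext = apply_boundary_conditions(u, GRID, bcs, n_ghost=2)
        # interior untouched; ghost-filled field keeps u(x_left) = 0 under a
        # symmetric interpolation through the boundary
        assert np.array_equal(ext[2:-2], u)
        p = np.polyfit(np.arange(5), ext[:5], 4)
        assert np.polyval(p, 2.0) == pytest.approx(0.0, abs=1e-10)

    def test_neumann_on_constant_is_exact(self):
        bcs = BCSpec.noflux()
        ext = apply_boundary_conditions(np.full(201, 4.2), GRID, bcs, n_ghost=2)
        assert np.allclose(ext, 4.2, atol=1e-12)

    def test_kdv_right_edge_conditions_enforced(self):
        """u_x = u_xx = 0 at x = L imposed on cos(x - L): one-sided values
        recovered from the ghost-filled field are forced toward zero with
        O(dx^accuracy) residual."""
        bcs = BCSpec(left=(BoundaryCondition(0, np.cos(-20.0)),),
                     right=(BoundaryCondition(1, 0.0), BoundaryCondition(2, 0.0)))
        g = Grid1D(-10.0, 10.0, 201)
        u = np.cos(g.x - 10.0)
        d1 = DiffOp(g, DerivativeScheme("central", 4, 1), bcs=bcs).apply(u)
        d2 = DiffOp(g, DerivativeScheme("central", 4, 2), bcs=bcs).apply(u)
        # the ghost fit collocates the imposed conditions, so the recovered
        # boundary derivatives match them to round-off even though the field
        # itself has u_xx(L) = -1
        assert abs(d1[-1]) < 1e-8 and abs(d2[-1]) < 1e-8
        # away from the ghost-dominated edge the derivative is still accurate
        assert np.allclose(d1[:-6], -np.sin(g.x - 10.0)[:-6], atol=1e-4)

    def test_idempotent_on_satisfying_field(self):
        bcs = BCSpec.dirichlet(0.0, None)
        u = np.sin(np.pi * (GRID.x + 10) / 20)
        e1 = apply_boundary_conditions(u, GRID, bcs, n_ghost=2)
        e2 = apply_boundary_conditions(e1[2:-2], GRID, bcs, n_ghost=2)
        assert np.array_equal(e1, e2)

    def test_overdetermined_raises(self):
        bcs = BCSpec(left=tuple(BoundaryCondition(k, 0.0) for k in range(6)))
        with pytest.raises(ValueError, match="over-determined"):
            apply_boundary_conditions(np.zeros(201), GRID, bcs, n_ghost=2, fit_points=6)

    def test_time_dependent_value(self):
        bcs = BCSpec(left=(BoundaryCondition(0, lambda t: 2.0 * t),))
        ext_t1 = apply_boundary_conditions(np.zeros(201), GRID, bcs, t=1.0,
                                           n_ghost=1, fit_points=5)
        # degree-4 fit through (ghost at -1) and interior nodes 1..4 (zeros)
        # must pass through the boundary value 2t at node 0
        p = np.polyfit([-1, 1, 2, 3, 4], [ext_t1[0], 0, 0, 0, 0], 4)
        assert np.polyval(p, 0.0) == pytest.approx(2.0, abs=1e-9)


def test_grid_too_small_raises():
    with pytest.raises(ValueError, match="too small"):
        fd_derivative(np.zeros(3), Grid1D(0, 1, 3), DerivativeScheme("central", 4, 3))


def test_transpose_is_exact_adjoint_of_linear_part():
    rng = np.random.default_rng(0)
    bcs = BCSpec(left=(BoundaryCondition(0, 0.0),),
                 right=(BoundaryCondition(1, 0.0), BoundaryCondition(2, 0.0)))
    op = DiffOp(GRID, DerivativeScheme("central", 4, 3), bcs=bcs)
    u, lam = rng.normal(size=201), rng.normal(size=201)
    assert lam @ (op.A @ u) == pytest.approx(op.apply_transpose(lam) @ u)
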