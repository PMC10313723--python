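"""Closure parameterizations: interpretable linear-library terms and small
fully-connected networks.

Two families are provided:

``LinearClosure``
    A linear combination of a named :class:`FunctionLibrary` of node-wise
    nonlinear features (a no-hidden-layer, linear-activation network).  Hard
    linear constraints between output channels (e.g. biomass conservation in
    a plankton model, or carbonate coupling through fixed C:N ratios) are
    imposed exactly by a channel map applied after the free weights.

``DeepClosure``
    A fully-connected multilayer perceptron with the smooth *swish*
    activation, applied independently at every grid node, with optional
    output gating (multiply by |gate field|) and the same channel-map
    constraint mechanism.  Forward and reverse passes are hand-written in
    numpy; the reverse pass supplies both the input-space cotangents needed
    by the adjoint PDE and the parameter gradients.

Sparsity of library closures is induced by L1 regularization plus hard
pruning: once a weight magnitude falls below the threshold it is set to
exactly zero and frozen for the rest of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "Feature",
    "FunctionLibrary",
    "LinearClosure",
    "DeepClosure",
    "build_features",
    "closure_eval",
    "prune_and_penalty",
]


class Feature:
    """One named node-wise feature, defined by a sympy expression.

    Partial derivatives with respect to every input are generated
    symbolically at construction; they drive the adjoint solve.
    """

    def __init__(self, name: str, expr: str | sp.Expr, inputs: Sequence[str]):
        self.name = name
        self.inputs = tuple(inputs)
        syms = sp.symbols(self.inputs)
        if isinstance(expr, str):
            expr = sp.sympify(expr, locals=dict(zip(self.inputs, syms)))
        self.expr = expr
        self._value = sp.lambdify(syms, expr, modules="numpy")
        self._partials = {
            name: sp.lambdify(syms, sp.diff(expr, s), modules="numpy")
            for name, s in zip(self.inputs, syms)
        }

    def _args(self, inp: dict) -> list:
        try:
            return [inp[k] for k in self.inputs]
        except KeyError as exc:
            raise KeyError(
                f"feature {self.name!r} requires input {exc.args[0]!r}, not provided"
            ) from None

    def value(self, inp: dict) -> np.ndarray:
        return np.asarray(self._value(*self._args(inp)), dtype=float)

    def partials(self, inp: dict) -> dict[str, np.ndarray]:
        args = self._args(inp)
        return {k: np.asarray(f(*args), dtype=float) for k, f in self._partials.items()}

    def __repr__(self) -> str:  # pragma: no cover
        return f"Feature({self.name!r})"


class FunctionLibrary:
    """Ordered collection of uniquely named features."""

    def __init__(self, features: Sequence[Feature]):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self.features = list(features)
        self.names = names
        self.inputs = tuple(dict.fromkeys(k for f in features for k in f.inputs))

    def __len__(self) -> int:
        return len(self.features)

    def evaluate(self, inp: dict) -> np.ndarray:
        """Feature matrix of shape (n_features, n_nodes)."""
        cols = [np.broadcast_to(f.value(inp), _field_shape(inp)).astype(float) for f in self.features]
        return np.stack(cols, axis=0)


def _field_shape(inp: dict) -> tuple:
    for v in inp.values():
        if isinstance(v, np.ndarray) and v.ndim:
            return v.shape
    return ()


def build_features(inp: dict, library: FunctionLibrary) -> np.ndarray:
    """Evaluate a library node-wise; rows follow the library order."""
    return library.evaluate(inp)


def _as_mask_array(x, shape):
    return np.broadcast_to(np.asarray(x, dtype=float), shape)


class LinearClosure:
    """phi^T f closure: one trainable coefficient per feature per free channel.

    ``channel_map`` (n_states x n_free) linearly maps the free channel
    contributions to per-state tendencies; constraints such as "biomass
    channels sum to zero" are exact by construction.  Pruned weights are
    exactly zero and frozen.
    """

    def __init__(
        self,
        library: FunctionLibrary,
        n_free: int = 1,
        channel_map: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ):
        self.library = library
        self.n_free = int(n_free)
        if channel_map is None:
            channel_map = np.eye(self.n_free)
        self.channel_map = np.asarray(channel_map, dtype=float)
        if self.channel_map.shape[1] != self.n_free:
            raise ValueError("channel map inconsistent with number of free channels")
        self.n_states = self.channel_map.shape[0]
        if weights is None:
            # zero start: training begins from the unclosed low-fidelity model
            weights = np.zeros((self.n_free, len(library)))
        self.weights = np.asarray(weights, dtype=float).reshape(self.n_free, len(library))
        self.active = np.ones_like(self.weights, dtype=bool)

    # -- parameter vector interface -----------------------------------------

    @property
    def n_params(self) -> int:
        return self.weights.size

    def get_params(self) -> np.ndarray:
        return self.weights.ravel().copy()

    def set_params(self, p: np.ndarray) -> None:
        self.weights = np.asarray(p, dtype=float).reshape(self.weights.shape)
        self.weights[~self.active] = 0.0

    def init_params(self, rng: np.random.Generator) -> None:
        self.weights = np.zeros_like(self.weights)
        self.active[:] = True

    def coefficients(self) -> dict[str, np.ndarray]:
        """Named coefficients per free channel."""
        return {name: self.weights[:, k].copy() for k, name in enumerate(self.library.names)}

    # -- evaluation -----------------------------------------------------------

    def eval(self, inp: dict) -> np.ndarray:
        """Contribution field of shape (n_nodes, n_states)."""
        feats = self.library.evaluate(inp)  # (n_feat, n_nodes)
        free = self.weights @ feats  # (n_free, n_nodes)
        return (self.channel_map @ free).T

    def vjp(self, inp: dict, lam: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Reverse pass.

        ``lam`` has shape (n_nodes, n_states).  Returns the cotangents with
        respect to every library input field and the parameter-gradient
        integrand  sum_nodes lam^T d(out)/d(weights).
        """
        lam_free = self.channel_map.T @ lam.T  # (n_free, n_nodes)
        feats = self.library.evaluate(inp)
        grad_w = lam_free @ feats.T  # (n_free, n_feat)
        grad_w[~self.active] = 0.0
        # cotangent per feature: sum_c W[c,k] lam_free[c]
        cof = self.weights.T @ lam_free  # (n_feat, n_nodes)
        shape = _field_shape(inp)
        cotangents: dict[str, np.ndarray] = {}
        for k, f in enumerate(self.library.features):
            for key, dfk in f.partials(inp).items():
                c = _as_mask_array(dfk, shape) * cof[k]
                if key in cotangents:
                    cotangents[key] = cotangents[key] + c
                else:
                    cotangents[key] = c.copy()
        return cotangents, grad_w.ravel()

    def prune(self, threshold: float) -> int:
        """Freeze weights whose magnitude fell below ``threshold``."""
        newly = self.active & (np.abs(self.weights) < threshold)
        self.active &= ~newly
        self.weights[~self.active] = 0.0
        return int(newly.sum())


def _swish(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s, s * (1.0 + x * (1.0 - s))


class DeepClosure:
    """Node-wise MLP with swish hidden activations and a linear output layer.

    With all weights zero the output is identically zero (biases included in
    the parameter vector start at zero).  Optional ``gate`` multiplies the
    raw output by |gate input| so that the contribution vanishes wherever the
    gating field vanishes.  ``channel_map`` distributes the raw output
    channels to state tendencies under exact linear constraints.
    """

    def __init__(
        self,
        inputs: Sequence[str],
        hidden: Sequence[int],
        n_out: int = 1,
        channel_map: np.ndarray | None = None,
        gate: str | None = None,
    ):
        self.inputs = tuple(inputs)
        self.sizes = [len(self.inputs), *hidden, int(n_out)]
        if channel_map is None:
            channel_map = np.eye(n_out)
        self.channel_map = np.asarray(channel_map, dtype=float)
        if self.channel_map.shape[1] != n_out:
            raise ValueError("channel map inconsistent with output channel count")
        self.n_states = self.channel_map.shape[0]
        self.gate = gate
        if gate is not None and gate not in self.inputs:
            raise ValueError("gate field must be one of the inputs")
        self.W = [np.zeros((m, n)) for n, m in zip(self.sizes[:-1], self.sizes[1:])]
        self.b = [np.zeros(m) for m in self.sizes[1:]]
        # fixed input standardization (set once from training data)
        self.in_shift = np.zeros(len(self.inputs))
        self.in_scale = np.ones(len(self.inputs))

    # -- parameters -----------------------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.W) + sum(b.size for b in self.b)

    def get_params(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.W] + [b for b in self.b])

    def set_params(self, p: np.ndarray) -> None:
        i = 0
        for w in self.W:
            w[...] = p[i : i + w.size].reshape(w.shape)
            i += w.size
        for b in self.b:
            b[...] = p[i : i + b.size]
            i += b.size

    def init_params(self, rng: np.random.Generator, scale: float = 1.0) -> None:
        for w in self.W:
            w[...] = rng.normal(0.0, scale / np.sqrt(w.shape[1]), size=w.shape)
        # keep last layer small so training starts near the unclosed model
        self.W[-1] *= 0.1
        for b in self.b:
            b[...] = 0.0

    def set_input_scales(self, shift: np.ndarray, scale: np.ndarray) -> None:
        self.in_shift = np.asarray(shift, dtype=float)
        self.in_scale = np.where(np.asarray(scale, dtype=float) > 0, scale, 1.0)

    # -- evaluation -----------------------------------------------------------

    def _stack_inputs(self, inp: dict) -> np.ndarray:
        shape = _field_shape(inp)
        cols = []
        for k in self.inputs:
            if k not in inp:
                raise KeyError(f"closure input {k!r} not provided")
            cols.append(np.broadcast_to(np.asarray(inp[k], dtype=float), shape))
        return np.stack(cols, axis=-1)  # (n_nodes, n_in)

    def _forward(self, X: np.ndarray):
        Z = (X - self.in_shift) / self.in_scale
        cache = [Z]
        acts = []
        a = Z
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = a @ w.T + b
            if i < len(self.W) - 1:
                a, da = _swish(z)
                acts.append(da)
            else:
                a = z
            cache.append(a)
        return a, cache, acts

    def eval(self, inp: dict) -> np.ndarray:
        X = self._stack_inputs(inp)
        out, _, _ = self._forward(X)  # (n_nodes, n_out)
        if self.gate is not None:
            g = np.abs(X[:, self.inputs.index(self.gate)])
            out = out * g[:, None]
        return out @ self.channel_map.T

    def vjp(self, inp: dict, lam: np.ndarray) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Cotangents w.r.t. input fields and the parameter-gradient integrand."""
        X = self._stack_inputs(inp)
        out, cache, acts = self._forward(X)
        lam_out = lam @ self.channel_map  # (n_nodes, n_out)
        gidx = None
        if self.gate is not None:
            gidx = self.inputs.index(self.gate)
            graw = X[:, gidx]
            g = np.abs(graw)
            d_out = lam_out * g[:, None]
            gate_cot = np.sign(graw) * np.sum(lam_out * out, axis=1)
        else:
            d_out = lam_out
            gate_cot = None
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = d_out
        for i in range(len(self.W) - 1, -1, -1):
            a_prev = cache[i]
            gW[i] = delta.T @ a_prev
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i]) * acts[i - 1]
        dX = (delta @ self.W[0]) / self.in_scale  # (n_nodes, n_in)
        cot = {k: dX[:, j].copy() for j, k in enumerate(self.inputs)}
        if gate_cot is not None:
            cot[self.gate] = cot[self.gate] + gate_cot
        grad = np.concatenate([g.ravel() for g in gW] + [g for g in gb])
        return cot, grad

    def prune(self, threshold: float) -> int:
        return 0  # pruning applies to library closures only

    @property
    def active(self) -> np.ndarray:
        return np.ones(self.n_params, dtype=bool)

    def input_layer_importance(self) -> np.ndarray:
        """RMS of first-layer weights per input feature (interpretation aid)."""
        return np.sqrt(np.mean(self.W[0] ** 2, axis=0))


def closure_eval(closure: LinearClosure | DeepClosure, inp: dict) -> np.ndarray:
    """Per-node, per-state tendency contribution of a closure."""
    return closure.eval(inp)


def prune_and_penalty(
    closure: LinearClosure | DeepClosure,
    l1: float,
    l2: float,
    threshold: float,
) -> tuple[float, LinearClosure | DeepClosure]:
    """Regularization penalty and in-place pruning.

    Pruning only happens when the L1 weight is strictly positive; it zeroes
    and permanently freezes any trainable weight below ``threshold``.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if l1 > 0 and isinstance(closure, LinearClosure):
        closure.prune(threshold)
    p = closure.get_params()
    if isinstance(closure, LinearClosure):
        p = p[closure.active.ravel()]
    penalty = l1 * np.sum(np.abs(p)) + l2 * np.sum(p**2)
    return float(penalty), closure


def penalty_gradient(closure: LinearClosure | DeepClosure, l1: float, l2: float) -> np.ndarray:
    """d(penalty)/d(params) for the full (unmasked) parameter vector.

    The L1 (sparsity) term targets interpretable library closures only; deep
    closures receive just the L2 weight decay.
    """
    p = closure.get_params()
    if isinstance(closure, LinearClosure):
        g = l1 * np.sign(p) + 2.0 * l2 * p
        g[~closure.active.ravel()] = 0.0
        return g
    return 2.0 * l2 * p
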