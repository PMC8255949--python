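"""Convex-function calculus: values, gradients, proximal mappings, conjugates.

All functions map a data container (or block container) to a real number.
Smooth functions expose ``gradient`` and a Lipschitz constant ``L``;
proximable functions expose ``proximal(x, tau)``, the minimizer of
``tau*g(v) + 0.5*||v - x||^2``.  ``proximal_conjugate`` defaults to the
Moreau identity ``prox_{s f*}(y) = y - s*prox_{f/s}(y/s)`` and is overridden
with closed forms where those are simpler or sturdier.

Conventions worth noting:

* ``L2NormSquared`` and ``LeastSquares`` carry *no* 1/2 factor: they are
  ``||x-b||^2`` and ``||Ax-b||^2``.
* The Kullback-Leibler fidelity is the count-data divergence
  ``sum((v+eta) - b + b*log(b/(v+eta)))`` with ``0*log 0 = 0`` and an
  optional background ``eta`` (default 0).
* ``TotalVariation`` is isotropic, with Neumann forward differences, and its
  proximal map is computed by an accelerated dual projected-gradient scheme
  (FGP) with dual step ``1/(4d)`` and optional warm-started dual variables.
"""

from __future__ import annotations

import math
import numbers

import numpy as np

from .datamodel import BlockDataContainer, DataContainer
from .operators.finite_difference import forward_difference, forward_difference_adjoint

__all__ = [
    "Function",
    "ConstantFunction",
    "ZeroFunction",
    "L2NormSquared",
    "WeightedL2NormSquared",
    "LeastSquares",
    "L1Norm",
    "MixedL21Norm",
    "SmoothMixedL21Norm",
    "KullbackLeibler",
    "IndicatorBox",
    "TotalVariation",
    "BlockFunction",
    "SumFunction",
    "ScaledFunction",
    "OperatorCompositionFunction",
    "soft_threshold",
]


def soft_threshold(x: np.ndarray, threshold: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - threshold, 0.0)


class Function:
    """Base class; subclasses override what they support."""

    L: float | None = None  # Lipschitz constant of the gradient, if smooth

    def __call__(self, x) -> float:
        raise NotImplementedError

    def gradient(self, x):
        raise NotImplementedError(f"{type(self).__name__} is not smooth")

    def proximal(self, x, tau):
        raise NotImplementedError(f"{type(self).__name__} has no proximal mapping")

    def convex_conjugate(self, y) -> float:
        raise NotImplementedError

    def proximal_conjugate(self, y, sigma):
        # Moreau identity
        return y - sigma * self.proximal(y * (1.0 / sigma), 1.0 / sigma)

    # -- algebra -------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Function):
            return SumFunction(self, other)
        return NotImplemented

    def __rmul__(self, scalar):
        if isinstance(scalar, numbers.Real):
            return ScaledFunction(scalar, self)
        return NotImplemented

    __mul__ = __rmul__


class ConstantFunction(Function):
    L = 0.0

    def __init__(self, constant: float = 0.0):
        self.constant = float(constant)

    def __call__(self, x):
        return self.constant

    def gradient(self, x):
        return x * 0.0

    def proximal(self, x, tau):
        return x.copy()

    def convex_conjugate(self, y):
        # true conjugate is an indicator of {0} shifted by -constant; the
        # finite surrogate -constant is reported (used by PDHG monitoring)
        return -self.constant


class ZeroFunction(ConstantFunction):
    def __init__(self):
        super().__init__(0.0)


class L2NormSquared(Function):
    """f(x) = ||x - b||^2  (no 1/2 factor)."""

    L = 2.0

    def __init__(self, b=None):
        self.b = b

    def _shift(self, x):
        return x if self.b is None else x - self.b

    def __call__(self, x):
        return self._shift(x).squared_norm()

    def gradient(self, x):
        return 2.0 * self._shift(x)

    def proximal(self, x, tau):
        if self.b is None:
            return x * (1.0 / (1.0 + 2.0 * tau))
        return (x + (2.0 * tau) * self.b) * (1.0 / (1.0 + 2.0 * tau))

    def convex_conjugate(self, y):
        val = 0.25 * y.squared_norm()
        if self.b is not None:
            val += y.dot(self.b)
        return val

    def proximal_conjugate(self, y, sigma):
        # prox of f*(y) = ||y||^2/4 + <y, b>
        if self.b is None:
            return y * (2.0 / (2.0 + sigma))
        return (y - sigma * self.b) * (2.0 / (2.0 + sigma))


class WeightedL2NormSquared(Function):
    """f(x) = sum_i w_i (x_i - b_i)^2, with w >= 0."""

    def __init__(self, weight, b=None):
        if weight.min() < 0:
            raise ValueError("weights must be non-negative")
        self.weight = weight
        self.b = b
        self.L = 2.0 * weight.max()

    def _shift(self, x):
        return x if self.b is None else x - self.b

    def __call__(self, x):
        d = self._shift(x)
        return (d * d * self.weight).sum()

    def gradient(self, x):
        return 2.0 * (self.weight * self._shift(x))

    def proximal(self, x, tau):
        denom = 1.0 + 2.0 * tau * self.weight
        num = x if self.b is None else x + (2.0 * tau) * (self.weight * self.b)
        return num / denom


class LeastSquares(Function):
    """f(u) = ||A u - b||^2 with gradient 2 A*(Au - b) and L = 2||A||^2."""

    def __init__(self, operator, b):
        self.operator = operator
        self.b = b
        self._L = None

    @property
    def L(self):
        if self._L is None:
            self._L = 2.0 * self.operator.norm() ** 2
        return self._L

    def residual(self, u):
        return self.operator.direct(u) - self.b

    def __call__(self, u):
        return self.residual(u).squared_norm()

    def gradient(self, u):
        return 2.0 * self.operator.adjoint(self.residual(u))


class L1Norm(Function):
    """f(x) = sum_i |x_i|; proximal mapping is soft-thresholding."""

    def __call__(self, x):
        return x.abs().sum()

    def proximal(self, x, tau):
        return x.clone_with(soft_threshold(x.as_array(), tau))

    def convex_conjugate(self, y):
        if float(np.max(np.abs(y.as_array()))) <= 1.0 + 1e-9:
            return 0.0
        return math.inf

    def proximal_conjugate(self, y, sigma):
        return y.clone_with(np.clip(y.as_array(), -1.0, 1.0))


def _voxel_norms(block: BlockDataContainer) -> np.ndarray:
    acc = None
    for b in block:
        sq = b.as_array().astype(np.float64, copy=False) ** 2
        acc = sq if acc is None else acc + sq
    return np.sqrt(acc)


class MixedL21Norm(Function):
    """f(X) = sum_voxels sqrt(sum_blocks X_k^2)  (isotropic coupling)."""

    def __call__(self, X):
        return float(np.sum(_voxel_norms(X)))

    def proximal(self, X, tau):
        norms = _voxel_norms(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            shrink = np.where(norms > 0, np.maximum(1.0 - tau / np.maximum(norms, 1e-300), 0.0), 0.0)
        return BlockDataContainer(*[b.clone_with(b.as_array() * shrink) for b in X])

    def convex_conjugate(self, Y):
        if float(np.max(_voxel_norms(Y))) <= 1.0 + 1e-9:
            return 0.0
        return math.inf

    def proximal_conjugate(self, Y, sigma):
        # projection onto the per-voxel unit 2-ball
        norms = _voxel_norms(Y)
        scale = 1.0 / np.maximum(norms, 1.0)
        return BlockDataContainer(*[b.clone_with(b.as_array() * scale) for b in Y])


class SmoothMixedL21Norm(Function):
    """f(X) = sum_voxels sqrt(sum_blocks X_k^2 + beta^2); L = 1/beta."""

    def __init__(self, beta: float):
        if beta <= 0:
            raise ValueError("beta must be > 0")
        self.beta = float(beta)
        self.L = 1.0 / self.beta

    def _root(self, X):
        acc = self.beta ** 2
        for b in X:
            acc = acc + b.as_array().astype(np.float64, copy=False) ** 2
        return np.sqrt(acc)

    def __call__(self, X):
        return float(np.sum(self._root(X)))

    def gradient(self, X):
        root = self._root(X)
        return BlockDataContainer(*[b.clone_with(b.as_array() / root) for b in X])


class KullbackLeibler(Function):
    """Count-data divergence sum((v+eta) - b + b log(b/(v+eta))), 0 log 0 = 0."""

    def __init__(self, b, eta=0.0):
        if b.min() < 0:
            raise ValueError("counts b must be non-negative")
        self.b = b
        self.eta = eta

    def _eta_arr(self, like):
        if isinstance(self.eta, DataContainer):
            return self.eta.as_array().astype(np.float64, copy=False)
        return np.full(like.shape, float(self.eta))

    def __call__(self, v):
        barr = self.b.as_array().astype(np.float64, copy=False)
        varr = v.as_array().astype(np.float64, copy=False) + self._eta_arr(v)
        pos = barr > 0
        if np.any(varr[pos] <= 0):
            raise ValueError("v + eta must be > 0 wherever b > 0")
        val = np.sum(varr - barr)
        val += np.sum(barr[pos] * np.log(barr[pos] / varr[pos]))
        return float(val)

    def gradient(self, v):
        barr = self.b.as_array().astype(np.float64, copy=False)
        varr = v.as_array().astype(np.float64, copy=False) + self._eta_arr(v)
        if np.any(varr[barr > 0] <= 0):
            raise ValueError("v + eta must be > 0 wherever b > 0")
        with np.errstate(divide="ignore", invalid="ignore"):
            g = 1.0 - np.where(barr > 0, barr / varr, 0.0)
        return v.clone_with(g)

    def proximal(self, v, tau):
        # root of (z - v) + tau*(1 - b/(z+eta)) = 0 with z + eta > 0
        barr = self.b.as_array().astype(np.float64, copy=False)
        varr = v.as_array().astype(np.float64, copy=False)
        eta = self._eta_arr(v)
        half_b = eta - varr + tau
        disc = half_b ** 2 + 4.0 * (eta * (varr - tau) + tau * barr)
        z = 0.5 * (-half_b + np.sqrt(np.maximum(disc, 0.0)))
        return v.clone_with(z)

    def convex_conjugate(self, y):
        barr = self.b.as_array().astype(np.float64, copy=False)
        yarr = y.as_array().astype(np.float64, copy=False)
        if np.any(yarr >= 1.0):
            return math.inf
        pos = barr > 0
        val = -np.sum(barr[pos] * np.log(1.0 - yarr[pos]))
        val -= np.sum(self._eta_arr(y) * yarr)
        return float(val)

    def proximal_conjugate(self, y, sigma):
        barr = self.b.as_array().astype(np.float64, copy=False)
        w = y.as_array().astype(np.float64, copy=False) + sigma * self._eta_arr(y)
        z = 0.5 * ((1.0 + w) - np.sqrt((1.0 - w) ** 2 + 4.0 * sigma * barr))
        return y.clone_with(z)


class IndicatorBox(Function):
    """Indicator of the box {lower <= u <= upper}; proximal map is clipping."""

    def __init__(self, lower=-math.inf, upper=math.inf):
        l = lower.as_array() if isinstance(lower, DataContainer) else lower
        u = upper.as_array() if isinstance(upper, DataContainer) else upper
        if np.any(np.asarray(l) > np.asarray(u)):
            raise ValueError("lower bound exceeds upper bound")
        self.lower = l
        self.upper = u

    def __call__(self, x, tol=1e-6):
        arr = x.as_array()
        if np.all(arr >= self.lower - tol) and np.all(arr <= self.upper + tol):
            return 0.0
        return math.inf

    def proximal(self, x, tau):
        return x.clone_with(np.clip(x.as_array(), self.lower, self.upper))

    def convex_conjugate(self, y):
        arr = y.as_array().astype(np.float64, copy=False)
        val = np.sum(self.upper * np.maximum(arr, 0.0)) + np.sum(self.lower * np.minimum(arr, 0.0))
        return float(val) if np.isfinite(val) else math.inf


class TotalVariation(Function):
    """Isotropic TV, g(u) = || grad u ||_{2,1}, with an FGP proximal solver.

    Parameters
    ----------
    max_iterations, tolerance:
        Inner (dual) iteration budget and relative-change stopping rule.
    nonneg:
        Project the primal variable onto [0, inf) inside the solver.
    warm_start:
        Reuse the dual variables of the previous proximal call (shape
        permitting) — effective inside FISTA outer loops.
    """

    def __init__(self, max_iterations: int = 100, tolerance: float = 1e-5,
                 nonneg: bool = False, warm_start: bool = True):
        self.max_iterations = int(max_iterations)
        self.tolerance = float(tolerance)
        self.nonneg = nonneg
        self.warm_start = warm_start
        self._dual = None

    @staticmethod
    def _grad(arr):
        return [forward_difference(arr, ax) for ax in range(arr.ndim)]

    @staticmethod
    def _grad_adjoint(ps):
        out = None
        for ax, p in enumerate(ps):
            term = forward_difference_adjoint(p, ax)
            out = term if out is None else out + term
        return out

    def __call__(self, u):
        gs = self._grad(u.as_array().astype(np.float64, copy=False))
        return float(np.sum(np.sqrt(sum(g ** 2 for g in gs))))

    def reset(self):
        self._dual = None

    def _primal(self, uarr, ps):
        v = uarr - self._grad_adjoint(ps)
        if self.nonneg:
            v = np.maximum(v, 0.0)
        return v

    def proximal(self, u, tau):
        uarr = u.as_array().astype(np.float64, copy=False)
        d = uarr.ndim
        step = 1.0 / (4.0 * d)
        if self.warm_start and self._dual is not None and self._dual[0].shape == uarr.shape:
            p = [q.copy() for q in self._dual]
        else:
            p = [np.zeros_like(uarr) for _ in range(d)]
        q = [a.copy() for a in p]
        t = 1.0
        for _ in range(self.max_iterations):
            v = self._primal(uarr, q)
            gs = self._grad(v)
            cand = [qk + step * gk for qk, gk in zip(q, gs)]
            norms = np.sqrt(sum(c ** 2 for c in cand))
            scale = tau / np.maximum(norms, tau)
            p_new = [c * scale for c in cand]
            t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
            q = [pn + ((t - 1.0) / t_new) * (pn - po) for pn, po in zip(p_new, p)]
            change = math.sqrt(sum(float(np.sum((pn - po) ** 2)) for pn, po in zip(p_new, p)))
            size = math.sqrt(sum(float(np.sum(pn ** 2)) for pn in p_new))
            p = p_new
            t = t_new
            if size > 0 and change <= self.tolerance * size:
                break
        if self.warm_start:
            self._dual = [pk.copy() for pk in p]
        return u.clone_with(self._primal(uarr, p))

    def convex_conjugate(self, y):
        raise NotImplementedError("use the (MixedL21Norm o Gradient) splitting for duals")


class BlockFunction(Function):
    """Separable sum f(x) = sum_i f_i(x_i) over a block container."""

    def __init__(self, *functions):
        if not functions:
            raise ValueError("BlockFunction needs at least one function")
        self.functions = functions

    def _check(self, x):
        if not isinstance(x, BlockDataContainer) or len(x) != len(self.functions):
            raise ValueError("block structure does not match the function list")

    def __call__(self, x):
        self._check(x)
        return float(sum(f(b) for f, b in zip(self.functions, x)))

    def gradient(self, x):
        self._check(x)
        return BlockDataContainer(*[f.gradient(b) for f, b in zip(self.functions, x)])

    @property
    def L(self):
        Ls = [f.L for f in self.functions]
        if any(l is None for l in Ls):
            return None
        return max(Ls)

    def proximal(self, x, tau):
        self._check(x)
        return BlockDataContainer(*[f.proximal(b, tau) for f, b in zip(self.functions, x)])

    def convex_conjugate(self, y):
        self._check(y)
        return float(sum(f.convex_conjugate(b) for f, b in zip(self.functions, y)))

    def proximal_conjugate(self, y, sigma):
        self._check(y)
        return BlockDataContainer(
            *[f.proximal_conjugate(b, sigma) for f, b in zip(self.functions, y)]
        )


class SumFunction(Function):
    def __init__(self, f, g):
        self.f = f
        self.g = g

    def __call__(self, x):
        return self.f(x) + self.g(x)

    def gradient(self, x):
        return self.f.gradient(x) + self.g.gradient(x)

    @property
    def L(self):
        if self.f.L is None or self.g.L is None:
            return None
        return self.f.L + self.g.L

    def proximal(self, x, tau):
        raise NotImplementedError("the proximal mapping of a sum is not separable")


class ScaledFunction(Function):
    """(alpha f)(x) = alpha * f(x), alpha > 0."""

    def __init__(self, scalar, function):
        if scalar <= 0:
            raise ValueError("scale must be positive")
        self.scalar = float(scalar)
        self.function = function

    def __call__(self, x):
        return self.scalar * self.function(x)

    def gradient(self, x):
        return self.scalar * self.function.gradient(x)

    @property
    def L(self):
        base = self.function.L
        return None if base is None else self.scalar * base

    def proximal(self, x, tau):
        return self.function.proximal(x, self.scalar * tau)

    def convex_conjugate(self, y):
        # (a f)*(y) = a f*(y / a)
        return self.scalar * self.function.convex_conjugate(y * (1.0 / self.scalar))

    def proximal_conjugate(self, y, sigma):
        if isinstance(self.function, (MixedL21Norm,)):
            # projection onto the per-voxel ball of radius alpha
            norms = _voxel_norms(y)
            scale = self.scalar / np.maximum(norms, self.scalar)
            return BlockDataContainer(*[b.clone_with(b.as_array() * scale) for b in y])
        if isinstance(self.function, L1Norm):
            return y.clone_with(np.clip(y.as_array(), -self.scalar, self.scalar))
        return super().proximal_conjugate(y, sigma)


class OperatorCompositionFunction(Function):
    """f(A x) for a smooth f and linear A; gradient A* grad f(Ax)."""

    def __init__(self, function, operator):
        self.function = function
        self.operator = operator
        self._L = None

    def __call__(self, x):
        return self.function(self.operator.direct(x))

    def gradient(self, x):
        return self.operator.adjoint(self.function.gradient(self.operator.direct(x)))

    @property
    def L(self):
        if self._L is None:
            base = self.function.L
            if base is None:
                return None
            self._L = base * self.operator.norm() ** 2
        return self._L
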