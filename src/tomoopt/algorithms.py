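"""Iterative solvers with resumable state and objective histories.

Every solver derives from :class:`Algorithm`: ``run(n)`` advances ``n``
iterations and may be called repeatedly — ``run(a)`` followed by ``run(b)``
reproduces ``run(a+b)`` bit-exactly because all state lives on the instance
and no randomness enters the updates.  Objective (and, for PDHG, dual and
gap) values are recorded as ``(iteration, value)`` pairs at a configurable
interval and can be exported to CSV for convergence plots.
"""

from __future__ import annotations

import csv
import math
import warnings

import numpy as np

from .functions import ConstantFunction

__all__ = ["Algorithm", "CGLS", "SIRT", "GD", "FISTA", "PDHG", "save_history_csv"]


def _as_float64(container):
    """Promote iterate storage to float64 so updates accumulate accurately."""
    from .datamodel import BlockDataContainer

    if isinstance(container, BlockDataContainer):
        return BlockDataContainer(*[_as_float64(b) for b in container])
    return container.clone_with(container.as_array().astype(np.float64))


class Algorithm:
    def __init__(self, update_objective_interval: int = 1):
        self.iteration = 0
        self.objective: list[tuple[int, float]] = []
        self.update_objective_interval = int(update_objective_interval)
        self.configuration: dict = {}
        self._converged = False

    # subclass API -----------------------------------------------------
    def update(self):
        raise NotImplementedError

    def update_objective(self) -> float:
        raise NotImplementedError

    @property
    def solution(self):
        return self.x

    # ------------------------------------------------------------------
    def should_record(self) -> bool:
        return (
            self.update_objective_interval > 0
            and self.iteration % self.update_objective_interval == 0
        )

    def run(self, iterations: int, verbose: bool = False):
        if self.iteration == 0 and self.should_record():
            self._record()
        for _ in range(int(iterations)):
            if self._converged:
                break
            self.update()
            self.iteration += 1
            if self.should_record():
                self._record()
                if verbose:
                    print(f"iter {self.iteration:6d}  objective {self.objective[-1][1]:.8e}")
        return self

    def _record(self):
        self.objective.append((self.iteration, self.update_objective()))


def save_history_csv(path, history, header=("iteration", "value")):
    """Write a list of (iteration, value) pairs to CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in history:
            writer.writerow(row)


class CGLS(Algorithm):
    """Conjugate gradient on the normal equations, without forming A*A.

    Stops after ``max_iterations`` via :meth:`run`, or earlier when
    ``||A*(Au-b)|| / ||A*b|| < tolerance`` (tolerance 0 disables the test).
    """

    def __init__(self, initial, operator, data, tolerance: float = 0.0,
                 update_objective_interval: int = 1):
        super().__init__(update_objective_interval)
        self.operator = operator
        self.data = data
        self.tolerance = float(tolerance)
        self.x = _as_float64(initial)
        self.r = data - operator.direct(self.x)
        self.s = operator.adjoint(self.r)
        self.p = self.s.copy()
        self.gamma = self.s.squared_norm()
        self._norm_Atb = operator.adjoint(data).norm()

    def update(self):
        q = self.operator.direct(self.p)
        delta = q.squared_norm()
        if delta == 0.0:
            self._converged = True
            return
        alpha = self.gamma / delta
        self.x += alpha * self.p
        self.r -= alpha * q
        self.s = self.operator.adjoint(self.r)
        gamma_new = self.s.squared_norm()
        beta = gamma_new / self.gamma
        self.gamma = gamma_new
        self.p = self.s + beta * self.p
        if self.tolerance > 0 and self._norm_Atb > 0:
            if math.sqrt(self.gamma) / self._norm_Atb < self.tolerance:
                self._converged = True

    def update_objective(self):
        return self.r.squared_norm()


class SIRT(Algorithm):
    """Simultaneous iterative reconstruction technique with box constraints.

    Update: x <- P_box(x + D A^T (M (b - A x))) with M, D the inverse row
    and column sums of |A| (estimated by applying A and A* to all-ones;
    valid for projectors, whose entries are non-negative).  Zero sums yield
    zero weights, with a warning.
    """

    def __init__(self, initial, operator, data, lower=None, upper=None,
                 update_objective_interval: int = 1):
        super().__init__(update_objective_interval)
        self.operator = operator
        self.data = data
        self.lower = lower
        self.upper = upper
        self.x = _as_float64(initial)

        ones_dom = operator.domain.allocate(1.0, dtype=np.float64)
        ones_ran = operator.range.allocate(1.0, dtype=np.float64)
        row_sums = operator.direct(ones_dom)
        col_sums = operator.adjoint(ones_ran)
        self.M = _safe_reciprocal(row_sums, "row")
        self.D = _safe_reciprocal(col_sums, "column")
        self._project()

    def _project(self):
        if self.lower is not None or self.upper is not None:
            lo = -np.inf if self.lower is None else self.lower
            hi = np.inf if self.upper is None else self.upper
            self.x = self.x.clip(lo, hi)

    def update(self):
        residual = self.data - self.operator.direct(self.x)
        self.x += self.D * self.operator.adjoint(self.M * residual)
        self._project()

    def update_objective(self):
        # weighted least-squares objective || b - Ax ||^2_M
        residual = self.data - self.operator.direct(self.x)
        return (residual * residual * self.M).sum()


def _safe_reciprocal(container, which):
    arr = container.as_array().astype(np.float64)
    zero = arr == 0
    if np.any(zero):
        warnings.warn(f"SIRT: {int(zero.sum())} zero {which} sums; weights set to 0")
    out = np.zeros_like(arr)
    np.divide(1.0, arr, out=out, where=~zero)
    return container.clone_with(out)


class GD(Algorithm):
    """Gradient descent with a constant step or Armijo backtracking.

    ``step_size``: a positive float, ``None`` (use 1/L from the function),
    or ``"backtracking"`` (Armijo with shrink 0.5, slope factor 1e-4,
    initial trial step 1).
    """

    def __init__(self, initial, f, step_size=None, update_objective_interval: int = 1):
        super().__init__(update_objective_interval)
        self.f = f
        self.x = _as_float64(initial)
        if step_size is None:
            if f.L is None:
                raise ValueError("constant-step GD needs a Lipschitz constant; "
                                 "pass step_size explicitly or use 'backtracking'")
            self.step_size = 1.0 / f.L
            self.backtracking = False
        elif step_size == "backtracking":
            self.step_size = 1.0
            self.backtracking = True
        else:
            self.step_size = float(step_size)
            self.backtracking = False

    def update(self):
        g = self.f.gradient(self.x)
        if self.backtracking:
            f0 = self.f(self.x)
            gnorm2 = g.squared_norm()
            step = 1.0
            for _ in range(50):
                trial = self.x - step * g
                if self.f(trial) <= f0 - 1e-4 * step * gnorm2:
                    break
                step *= 0.5
            self.x = trial
        else:
            self.x -= self.step_size * g

    def update_objective(self):
        return self.f(self.x)


class FISTA(Algorithm):
    """Accelerated proximal gradient for min f(x) + g(x).

    f must be L-smooth (or ``step_size`` given); g proximable.  Momentum
    t_{k+1} = (1 + sqrt(1 + 4 t_k^2)) / 2, step 1/L.
    """

    def __init__(self, initial, f, g, step_size=None, update_objective_interval: int = 1):
        super().__init__(update_objective_interval)
        self.f = f
        self.g = g
        if step_size is None:
            if f.L is None:
                raise ValueError("FISTA needs f.L or an explicit step_size")
            step_size = 1.0 / f.L
        self.step_size = float(step_size)
        self.x = _as_float64(initial)
        self.y = _as_float64(initial)
        self.t = 1.0

    def update(self):
        x_new = self.g.proximal(self.y - self.step_size * self.f.gradient(self.y),
                                self.step_size)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * self.t * self.t))
        self.y = x_new + ((self.t - 1.0) / t_new) * (x_new - self.x)
        self.x = x_new
        self.t = t_new

    def update_objective(self):
        return self.f(self.x) + self.g(self.x)


class PDHG(Algorithm):
    """Primal-dual hybrid gradient (Chambolle-Pock) with theta = 1.

    Solves min_x f(Kx) + g(x) where f is a (block) function whose conjugate
    is proximable.  Defaults sigma = tau = 1/||K||; the pair must satisfy
    sigma * tau * ||K||^2 <= 1.

    Records primal objective, dual objective and the primal-dual gap.  When
    g is zero the dual value is the unconstrained surrogate -sum_i f_i*(y_i)
    (the K*y = 0 feasibility term is relaxed).
    """

    def __init__(self, f, operator, g, initial=None, sigma=None, tau=None,
                 update_objective_interval: int = 1):
        super().__init__(update_objective_interval)
        self.f = f
        self.g = g
        self.operator = operator
        norm_K = operator.norm()
        if sigma is None and tau is None:
            sigma = tau = 1.0 / norm_K
        elif sigma is None or tau is None:
            raise ValueError("provide both sigma and tau, or neither")
        if sigma * tau * norm_K ** 2 > 1.0 + 1e-6:
            raise ValueError(
                f"step sizes violate sigma*tau*||K||^2 <= 1 "
                f"(got {sigma * tau * norm_K ** 2:.3g}); try sigma = tau = 1/||K|| "
                f"= {1.0 / norm_K:.3g}")
        self.sigma = float(sigma)
        self.tau = float(tau)
        if initial is None:
            initial = operator.domain.allocate(0.0, dtype=np.float64)
        self.x = _as_float64(initial)
        self.x_bar = _as_float64(initial)
        self.y = operator.direct(self.x) * 0.0
        self.dual: list[tuple[int, float]] = []
        self.gap: list[tuple[int, float]] = []

    def update(self):
        self.y = self.f.proximal_conjugate(self.y + self.sigma * self.operator.direct(self.x_bar),
                                           self.sigma)
        x_new = self.g.proximal(self.x - self.tau * self.operator.adjoint(self.y), self.tau)
        self.x_bar = 2.0 * x_new - self.x
        self.x = x_new

    def primal_objective(self):
        return self.f(self.operator.direct(self.x)) + self.g(self.x)

    def dual_objective(self):
        val = -self.f.convex_conjugate(self.y)
        if not isinstance(self.g, ConstantFunction):
            val -= self.g.convex_conjugate(-self.operator.adjoint(self.y))
        return val

    def update_objective(self):
        primal = self.primal_objective()
        dual = self.dual_objective()
        self.dual.append((self.iteration, dual))
        self.gap.append((self.iteration, primal - dual))
        return primal
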