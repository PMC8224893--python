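"""Steady-state perturbation propagation.

Given an imposed expression-change vector dE, the perturbation of every
node is the fixed point of

    P(i) = dE(i) + sum_{u in U(i)} w(u, i) / W(u) * P(u),

where U(i) are the upstream neighbours of i, w(u, i) in {+1, -1} is the
interaction sign and W(u) = sum_{d in D(u)} |w(u, d)| is the total
absolute outgoing weight of u (its out-degree for unit weights).  Each
node thus splits its perturbation evenly over its outgoing interactions,
signed by the interaction type.

Two solvers are provided: a Jacobi iteration (:func:`propagate`), which
on acyclic graphs converges in at most longest-path sweeps, and a direct
linear solve of (I - M) P = dE (:func:`propagate_exact`) that serves as
an exact oracle and as the fallback when the iteration does not
converge (cyclic graphs can place the spectral radius of M at or above
1, where no iterative steady state exists; the minimum-norm
least-squares solution is then returned and flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp

from .logfc import ExpressionChangeVector
from .metapathway import MetaPathwayGraph

__all__ = ["PerturbationVector", "PropagationEngine", "propagate", "propagate_exact"]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 2000


@dataclass(frozen=True)
class PerturbationVector:
    """Per-node steady-state perturbation.

    ``converged`` is False when the iterative solver hit its sweep cap
    (values then come from the least-squares fallback) or the linear
    system was singular.
    """

    values: Mapping[str, float]
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, node_id: str) -> float:
        return self.values[node_id]


class PropagationEngine:
    """Reusable propagation operator for a fixed graph.

    Building the sparse operator matrix once and reusing it across the
    thousands of Monte-Carlo steps of a simulation dominates the cost
    profile, so the engine is the workhorse behind both public solvers.
    Rows/columns follow ``graph.node_ids`` (sorted) order.
    """

    def __init__(self, graph: MetaPathwayGraph) -> None:
        self.node_ids = graph.node_ids
        self.index = {n: i for i, n in enumerate(self.node_ids)}
        m = len(self.node_ids)
        rows, cols, vals = [], [], []
        for edge in graph.edges():
            u, i = self.index[edge.source], self.index[edge.target]
            rows.append(i)
            cols.append(u)
            vals.append(edge.weight / graph.out_weight_total(edge.source))
        self.matrix = sp.csr_matrix((vals, (rows, cols)), shape=(m, m))
        self._dense_system: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.node_ids)

    def as_array(self, delta_e: ExpressionChangeVector) -> np.ndarray:
        missing = [n for n in self.node_ids if n not in delta_e.values]
        if missing:
            raise KeyError(f"expression-change vector misses node(s): {missing}")
        arr = np.array([delta_e.values[n] for n in self.node_ids], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression-change vector contains non-finite entries")
        return arr

    def iterate(
        self,
        delta: np.ndarray,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ) -> tuple[np.ndarray, bool, int]:
        """Jacobi iteration from P = dE; returns (P, converged, sweeps)."""
        if tol <= 0:
            raise ValueError("tol must be positive")
        if max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        p = delta.copy()
        for it in range(1, max_iter + 1):
            nxt = delta + self.matrix @ p
            if np.max(np.abs(nxt - p), initial=0.0) < tol:
                return nxt, True, it
            p = nxt
        return p, False, max_iter

    def solve_exact(self, delta: np.ndarray) -> tuple[np.ndarray, bool]:
        """Direct solve of (I - M) P = dE; returns (P, full_rank)."""
        if self._dense_system is None:
            self._dense_system = np.eye(self.m) - self.matrix.toarray()
        a = self._dense_system
        solution, _, rank, _ = np.linalg.lstsq(a, delta, rcond=None)
        return solution, rank == self.m

    def to_vector(
        self, values: np.ndarray, converged: bool, iterations: int
    ) -> PerturbationVector:
        return PerturbationVector(
            dict(zip(self.node_ids, values.tolist())), converged, iterations
        )


def propagate(
    graph: MetaPathwayGraph,
    delta_e: ExpressionChangeVector,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PerturbationVector:
    """Iteratively compute the steady-state perturbation of every node.

    Jacobi (simultaneous-update) sweeps run from P = dE until the
    max-norm change drops below ``tol``.  On non-convergence the direct
    least-squares solution is returned with ``converged=False``.
    """
    engine = PropagationEngine(graph)
    delta = engine.as_array(delta_e)
    values, converged, iters = engine.iterate(delta, tol, max_iter)
    if not converged:
        values, _ = engine.solve_exact(delta)
    return engine.to_vector(values, converged, iters)


def propagate_exact(
    graph: MetaPathwayGraph, delta_e: ExpressionChangeVector
) -> PerturbationVector:
    """Solve the propagation linear system (I - M) P = dE directly.

    A singular system (e.g. a feedback cycle that conserves
    perturbation) yields the minimum-norm least-squares solution with
    ``converged=False``.
    """
    engine = PropagationEngine(graph)
    delta = engine.as_array(delta_e)
    values, full_rank = engine.solve_exact(delta)
    return engine.to_vector(values, full_rank, 0)
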