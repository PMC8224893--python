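"""Empirical significance of activity scores by input randomization.

A node's alteration is biologically specific to the input if comparable
alterations rarely arise when *arbitrary* nodes are deregulated the same
way.  The null is built by drawing R random input sets — same number of
deregulated nodes, same multiset of directions, node identities uniform
over the (non-virtual) network — running a reduced simulation on each,
and counting how often the random Activity Score exceeds the observed
one:

    p_i = #{r : |A(IR_r)_i| > |A(I)_i|} / R.

The default comparison is on magnitudes, giving two-sided semantics so
that strong inhibition (large negative score) is as significant as
strong activation; ``mode="raw"`` recovers the literal one-sided
comparison A(IR_r)_i > A(I)_i.

p-values are corrected for multiple testing with Storey q-values
(pi0 estimated at a single lambda, default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .logfc import LogFCParams, PolarGaussian
from .metapathway import InputSpec, MetaPathwayGraph
from .propagation import DEFAULT_MAX_ITER, DEFAULT_TOL, PropagationEngine
from .simulation import SimulationResult, run_simulation

__all__ = [
    "RandomizationEnsemble",
    "SignificanceResult",
    "randomize_input",
    "empirical_pvalues",
    "qvalues",
    "run_significance",
]

DEFAULT_R = 1000
DEFAULT_T_INNER = 100
DEFAULT_LAMBDA = 0.5


@dataclass(frozen=True)
class RandomizationEnsemble:
    """Random activity scores: one row per randomization, one column per
    scored entity (keyed by (level, id))."""

    keys: tuple[tuple[str, str], ...]
    scores: np.ndarray  # shape (R, n_entities)

    @property
    def R(self) -> int:
        return self.scores.shape[0]

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != len(self.keys):
            raise ValueError("ensemble score matrix does not match keys")
        if self.R < 1:
            raise ValueError("ensemble needs at least one randomization")


@dataclass(frozen=True)
class SignificanceResult:
    """Empirical p-values and Storey q-values, keyed by (level, id)."""

    p_values: Mapping[tuple[str, str], float]
    q_values: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "p_values", dict(self.p_values))
        object.__setattr__(self, "q_values", dict(self.q_values))


def randomize_input(
    graph: MetaPathwayGraph, input_spec: InputSpec, rng: np.random.Generator
) -> InputSpec:
    """Draw a null input: same direction multiset on random nodes.

    Node identities are sampled uniformly without replacement from the
    graph's non-virtual nodes; the original direction values are
    assigned in (sorted-id) order.  The non-expressed list carries over
    unchanged, so the null shares every constraint of the observed run
    except node identity.
    """
    candidates = [
        nid for nid in graph.node_ids if graph.node(nid).category != "virtual"
    ]
    n = len(input_spec.active_nodes)
    if len(candidates) < n:
        raise ValueError(
            f"graph has {len(candidates)} candidate nodes; cannot draw {n}"
        )
    chosen = rng.choice(len(candidates), size=n, replace=False)
    directions = {
        candidates[j]: v for j, v in zip(chosen, input_spec.direction_values)
    }
    return InputSpec(directions=directions, nonexpressed=input_spec.nonexpressed)


def empirical_pvalues(
    observed: Mapping[tuple[str, str], float],
    ensemble: RandomizationEnsemble,
    mode: str = "abs",
) -> dict[tuple[str, str], float]:
    """Exceedance p-values of observed scores against the random ensemble.

    ``mode="abs"`` (default) counts |random| > |observed|;
    ``mode="raw"`` counts random > observed.  No smoothing is applied,
    so p = 0 is attainable.
    """
    if mode not in ("abs", "raw"):
        raise ValueError(f"unknown p-value mode {mode!r}")
    col = {k: j for j, k in enumerate(ensemble.keys)}
    missing = [k for k in observed if k not in col]
    if missing:
        raise KeyError(f"ensemble does not cover: {sorted(missing)}")
    out: dict[tuple[str, str], float] = {}
    scores = np.abs(ensemble.scores) if mode == "abs" else ensemble.scores
    for key, a in observed.items():
        ref = abs(a) if mode == "abs" else a
        out[key] = float(np.count_nonzero(scores[:, col[key]] > ref)) / ensemble.R
    return out


def qvalues(
    p: Sequence[float],
    lam: float = DEFAULT_LAMBDA,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with single-lambda pi0 estimation.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) * m)); then on sorted p,
    q_(i) = min_{j >= i} pi0 * m * p_(j) / j.  ``pi0`` may be forced
    (e.g. to 1, recovering Benjamini–Hochberg).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if not 0 < lam < 1:
            raise ValueError("lambda must be in (0, 1)")
        pi0 = min(1.0, np.count_nonzero(p > lam) / ((1.0 - lam) * m))
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def run_significance(
    graph: MetaPathwayGraph,
    input_spec: InputSpec,
    observed: SimulationResult,
    R: int,
    T_inner: int,
    rng: np.random.Generator,
    *,
    params: LogFCParams = LogFCParams(),
    mode: str = "abs",
    lam: float = DEFAULT_LAMBDA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    pathway_aggregation: str = "sum",
) -> SignificanceResult:
    """Full randomization pass: R null inputs, T_inner steps each.

    Returns per-node and per-pathway p-values (exceedance against the
    null score ensemble) and q-values corrected jointly across all
    scored entities.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if T_inner < 1:
        raise ValueError("T_inner must be >= 1")
    keys = tuple(
        [("node", k) for k in sorted(observed.nodes)]
        + [("pathway", k) for k in sorted(observed.pathways)]
    )
    engine = PropagationEngine(graph)
    scores = np.empty((R, len(keys)))
    for r in range(R):
        null_input = randomize_input(graph, input_spec, rng)
        sim = run_simulation(
            graph,
            null_input,
            T_inner,
            PolarGaussian(rng),
            params=params,
            tol=tol,
            max_iter=max_iter,
            pathway_aggregation=pathway_aggregation,
            engine=engine,
        )
        lookup = {"node": sim.nodes, "pathway": sim.pathways}
        scores[r] = [lookup[level][eid].activity_score for level, eid in keys]
    ensemble = RandomizationEnsemble(keys, scores)
    observed_scores = {
        key: (
            observed.nodes[key[1]] if key[0] == "node" else observed.pathways[key[1]]
        ).activity_score
        for key in keys
    }
    p_map = empirical_pvalues(observed_scores, ensemble, mode)
    q_arr = qvalues([p_map[k] for k in keys], lam=lam)
    q_map = dict(zip(keys, q_arr.tolist()))
    return SignificanceResult(p_map, q_map)
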