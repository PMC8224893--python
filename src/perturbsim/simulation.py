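"""Monte-Carlo simulation loop and activity scoring.

The simulator treats each node as a three-state random variable —
activated (+1), inhibited (-1), unchanged (0) — whose distribution under
a given input is unknown.  It is estimated empirically: T times, fresh
synthetic LogFCs are drawn for the input nodes, propagated to steady
state, and each node's state at that step is the sign of its
perturbation.  From the tallies:

* state probabilities  Pr(V_i = v | I) = #{steps with sign v} / T;
* the Activity Score, a signed log2-odds of the majority state —
  positive for predicted activation, negative for inhibition, 0 when
  "unchanged" is the majority (or no state reaches a majority);
* the Average Perturbation, the mean propagated value over the T steps.

Pathway-level records run the same tally machinery on a per-step
pathway perturbation (by default the sum of member-node perturbations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np

from .logfc import LogFCParams, PolarGaussian, sample_logfc
from .metapathway import InputSpec, MetaPathwayGraph
from .propagation import DEFAULT_MAX_ITER, DEFAULT_TOL, PerturbationVector, PropagationEngine

__all__ = [
    "StateCounts",
    "EntityResult",
    "SimulationResult",
    "SimulationError",
    "run_simulation",
    "state_probabilities",
    "activity_score",
    "pathway_perturbation",
    "write_results",
]


class SimulationError(RuntimeError):
    """The Monte-Carlo run could not produce a trustworthy result."""


@dataclass(frozen=True)
class StateCounts:
    """Tally of node states over T simulation steps."""

    n_up: int
    n_down: int
    n_zero: int

    @property
    def T(self) -> int:
        return self.n_up + self.n_down + self.n_zero

    def __post_init__(self) -> None:
        if min(self.n_up, self.n_down, self.n_zero) < 0:
            raise ValueError("state counts must be non-negative")


def state_probabilities(counts: StateCounts) -> tuple[float, float, float]:
    """Empirical (Pr(+1), Pr(-1), Pr(0)) from a state tally."""
    if counts.T == 0:
        raise ValueError("cannot form probabilities from an empty tally (T=0)")
    t = counts.T
    return counts.n_up / t, counts.n_down / t, counts.n_zero / t


def activity_score(
    probs: tuple[float, float, float], T: int | None = None
) -> float:
    """Signed log2-odds of the majority state.

    ``probs`` is (Pr(+1), Pr(-1), Pr(0)).  If Pr(+1) > 1/2 the score is
    log2(Pr/(1-Pr)); if Pr(-1) > 1/2 it is the negation of that
    expression on Pr(-1); if Pr(0) > 1/2, or no state exceeds 1/2, the
    score is 0.  A majority probability of exactly 1 has infinite odds;
    when ``T`` is supplied the count is continuity-corrected from T to
    T - 1/2, capping |score| at log2((T - 1/2) / (1/2)) while keeping
    the T-dependence of the confidence.
    """
    p_up, p_down, p_zero = probs
    if min(probs) < 0 or not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
        raise ValueError(f"invalid probability triple {probs!r}")
    if p_up > 0.5:
        p, sign = p_up, 1.0
    elif p_down > 0.5:
        p, sign = p_down, -1.0
    else:
        return 0.0
    if p == 1.0:
        if T is None:
            raise ValueError(
                "majority probability is exactly 1; supply T for the "
                "continuity-corrected odds"
            )
        return sign * math.log2((T - 0.5) / 0.5)
    return sign * math.log2(p / (1.0 - p))


def pathway_perturbation(
    perturbations: PerturbationVector | Mapping[str, float],
    membership: Mapping[str, Iterable[str]],
    aggregation: str = "sum",
) -> dict[str, float]:
    """Aggregate one step's node perturbations to pathway level.

    ``aggregation`` is ``"sum"`` (default; linear, respects
    superposition) or ``"mean"``.  An empty pathway maps to 0 with a
    warning.
    """
    import warnings

    values = perturbations.values if isinstance(perturbations, PerturbationVector) else perturbations
    if aggregation not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    out: dict[str, float] = {}
    for pid, members in membership.items():
        members = list(members)
        missing = [n for n in members if n not in values]
        if missing:
            raise KeyError(f"pathway {pid!r} references unscored node(s): {missing}")
        if not members:
            warnings.warn(f"pathway {pid!r} has no member nodes", stacklevel=2)
            out[pid] = 0.0
            continue
        total = sum(values[n] for n in members)
        out[pid] = total / len(members) if aggregation == "mean" else total
    return out


@dataclass(frozen=True)
class EntityResult:
    """Simulation summary for one node or pathway."""

    id: str
    name: str
    level: str  # "node" | "pathway"
    counts: StateCounts
    avg_perturbation: float
    activity_score: float
    p_value: float | None = None
    q_value: float | None = None

    @property
    def probabilities(self) -> tuple[float, float, float]:
        return state_probabilities(self.counts)


@dataclass(frozen=True)
class SimulationResult:
    """Per-node and per-pathway outcome of a T-repetition run."""

    nodes: dict[str, EntityResult]
    pathways: dict[str, EntityResult]
    T: int
    n_diverged: int = 0

    def all_entities(self) -> list[EntityResult]:
        """Nodes (sorted by id) followed by pathways (sorted by id)."""
        return [self.nodes[k] for k in sorted(self.nodes)] + [
            self.pathways[k] for k in sorted(self.pathways)
        ]

    def with_significance(
        self, p_values: Mapping[tuple[str, str], float], q_values: Mapping[tuple[str, str], float]
    ) -> "SimulationResult":
        """A copy with p/q-values attached (keys are (level, id))."""

        def upd(rec: EntityResult) -> EntityResult:
            key = (rec.level, rec.id)
            return replace(
                rec, p_value=p_values.get(key), q_value=q_values.get(key)
            )

        return SimulationResult(
            {k: upd(v) for k, v in self.nodes.items()},
            {k: upd(v) for k, v in self.pathways.items()},
            self.T,
            self.n_diverged,
        )


def run_simulation(
    graph: MetaPathwayGraph,
    input_spec: InputSpec,
    T: int,
    gaussian: PolarGaussian,
    *,
    params: LogFCParams = LogFCParams(),
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    pathway_aggregation: str = "sum",
    max_diverged_fraction: float = 0.1,
    engine: PropagationEngine | None = None,
) -> SimulationResult:
    """Run the T-repetition Monte-Carlo simulation.

    Dependency groups must already be resolved (``add_dependency_node``)
    and non-expressed nodes removed (``apply_nonexpressed``).  Each step
    draws fresh LogFCs for the input nodes (sorted id order), propagates
    them, and tallies the sign of every node's perturbation; sign uses
    exact zero — no epsilon — so only nodes receiving no signal (or
    rectified-to-zero draws) count as unchanged.

    Steps whose propagation does not converge are flagged; if more than
    ``max_diverged_fraction`` of steps diverge the run aborts.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    missing = [n for n in input_spec.directions if n not in graph]
    if missing:
        raise KeyError(f"input node(s) absent from graph: {sorted(missing)}")
    if input_spec.dependency_groups:
        raise ValueError(
            "unresolved dependency groups: call add_dependency_node first"
        )
    if engine is None:
        engine = PropagationEngine(graph)
    m = engine.m
    idx = [engine.index[n] for n in input_spec.active_nodes]
    dirs = list(input_spec.direction_values)

    pathway_ids = sorted(graph.membership)
    membership = graph.membership
    # pathway aggregation as a sparse-free matmul: small count of pathways
    agg = np.zeros((len(pathway_ids), m))
    for pi, pid in enumerate(pathway_ids):
        members = membership[pid]
        if not members:
            import warnings

            warnings.warn(f"pathway {pid!r} has no member nodes", stacklevel=2)
            continue
        for n in members:
            agg[pi, engine.index[n]] = 1.0
        if pathway_aggregation == "mean":
            agg[pi] /= len(members)
        elif pathway_aggregation != "sum":
            raise ValueError(f"unknown aggregation {pathway_aggregation!r}")

    counts = np.zeros((3, m), dtype=np.int64)  # rows: up, down, zero
    pcounts = np.zeros((3, len(pathway_ids)), dtype=np.int64)
    total = np.zeros(m)
    ptotal = np.zeros(len(pathway_ids))
    n_diverged = 0
    delta = np.zeros(m)
    for _ in range(T):
        delta[:] = 0.0
        for j, v in zip(idx, dirs):
            delta[j] = sample_logfc(v, gaussian, params)
        values, converged, _ = engine.iterate(delta, tol, max_iter)
        if not converged:
            n_diverged += 1
            values, _ = engine.solve_exact(delta)
        counts[0] += values > 0
        counts[1] += values < 0
        counts[2] += values == 0
        total += values
        if pathway_ids:
            pvals = agg @ values
            pcounts[0] += pvals > 0
            pcounts[1] += pvals < 0
            pcounts[2] += pvals == 0
            ptotal += pvals
    if n_diverged > max_diverged_fraction * T:
        raise SimulationError(
            f"{n_diverged}/{T} simulation steps failed to converge "
            f"(> {max_diverged_fraction:.0%}); the network's feedback structure "
            "admits no iterative steady state for this input"
        )

    def summarize(eid: str, name: str, level: str, col_counts, avg: float) -> EntityResult:
        sc = StateCounts(int(col_counts[0]), int(col_counts[1]), int(col_counts[2]))
        return EntityResult(
            id=eid,
            name=name,
            level=level,
            counts=sc,
            avg_perturbation=avg,
            activity_score=activity_score(state_probabilities(sc), T),
        )

    nodes = {
        nid: summarize(nid, graph.node(nid).name, "node", counts[:, i], total[i] / T)
        for i, nid in enumerate(engine.node_ids)
    }
    names = graph.pathway_names
    pathways = {
        pid: summarize(
            pid, names.get(pid, pid), "pathway", pcounts[:, pi], ptotal[pi] / T
        )
        for pi, pid in enumerate(pathway_ids)
    }
    return SimulationResult(nodes, pathways, T, n_diverged)


def _fmt(x: float | None) -> str:
    if x is None:
        return "NA"
    return f"{x:.6g}"


def write_results(
    result: SimulationResult,
    path: str | Path | IO[str],
    header_lines: Iterable[str] = (),
) -> None:
    """Write the result TSV: one row per node, then per pathway.

    Columns: id, name, level, avg_perturbation, activity_score, prob_up,
    prob_down, prob_zero, p_value, q_value (floats with 6 significant
    digits; missing significance as NA).  ``header_lines`` are emitted
    first as ``#`` comments.
    """
    own = isinstance(path, (str, Path))
    fh = open(path, "w", encoding="utf-8") if own else path
    try:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "id\tname\tlevel\tavg_perturbation\tactivity_score\t"
            "prob_up\tprob_down\tprob_zero\tp_value\tq_value\n"
        )
        for rec in result.all_entities():
            pu, pd, pz = rec.probabilities
            fh.write(
                "\t".join(
                    [
                        rec.id,
                        rec.name,
                        rec.level,
                        _fmt(rec.avg_perturbation),
                        _fmt(rec.activity_score),
                        _fmt(pu),
                        _fmt(pd),
                        _fmt(pz),
                        _fmt(rec.p_value),
                        _fmt(rec.q_value),
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()
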