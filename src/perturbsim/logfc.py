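"""Synthetic log-fold-change generation.

Each simulation step imposes a random magnitude on every deregulated
input node.  Magnitudes are drawn from a *rectified* Gaussian: a normal
with mean +5 (up-regulation) or -5 (down-regulation) and standard
deviation 2 — parameters fitted elsewhere to tumour-vs-normal LogFC
distributions and taken as given here — whose wrong-signed tail is
clamped to 0::

    LFC(v) = max(0, sd*rN + mean)   if v = +1
           = min(0, sd*rN - mean)   if v = -1
           = 0                      if v =  0

where ``rN`` is a standard Gaussian variate produced by the Marsaglia
polar method.  All other nodes receive an expression change of exactly 0.

The rectified distribution has closed-form moments
(:func:`rectified_normal_moments`) used by the tests as an independent
oracle: for X = max(0, N(mu, sd)), E[X] = mu*Phi(mu/sd) + sd*phi(mu/sd).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .metapathway import InputSpec, MetaPathwayGraph

__all__ = [
    "LogFCParams",
    "PolarGaussian",
    "sample_logfc",
    "sample_logfc_many",
    "build_delta_e",
    "ExpressionChangeVector",
    "rectified_normal_moments",
]

DEFAULT_MEAN = 5.0
DEFAULT_SD = 2.0


@dataclass(frozen=True)
class LogFCParams:
    """Parameters of the LogFC magnitude distribution.

    ``mean`` is the centre of the up-regulation normal (down-regulation
    uses its negation); ``sd`` its standard deviation.  Units are log2
    fold change.
    """

    mean: float = DEFAULT_MEAN
    sd: float = DEFAULT_SD

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("logfc.sd must be positive")


class PolarGaussian:
    """Standard-normal stream via the Marsaglia polar method.

    Pairs (u, v) are drawn uniformly on (-1, 1)^2; pairs whose squared
    radius s = u^2 + v^2 is >= 1 or = 0 are rejected; each accepted pair
    yields two variates u*sqrt(-2 ln s / s) and v*sqrt(-2 ln s / s).
    Variates are handed out in generation order, so a stream seeded the
    same way always produces the same sequence regardless of whether it
    is consumed one at a time or in vectorised blocks.
    """

    def __init__(self, rng: np.random.Generator, batch_pairs: int = 512) -> None:
        self._rng = rng
        self._batch = int(batch_pairs)
        self._buffer = np.empty(0)
        self._pos = 0

    def _refill(self) -> None:
        u = self._rng.uniform(-1.0, 1.0, size=self._batch)
        v = self._rng.uniform(-1.0, 1.0, size=self._batch)
        s = u * u + v * v
        ok = (s < 1.0) & (s > 0.0)
        u, v, s = u[ok], v[ok], s[ok]
        factor = np.sqrt(-2.0 * np.log(s) / s)
        out = np.empty(2 * u.size)
        out[0::2] = u * factor
        out[1::2] = v * factor
        self._buffer = out
        self._pos = 0

    def normal(self) -> float:
        """One standard-normal variate."""
        return float(self.normals(1)[0])

    def normals(self, n: int) -> np.ndarray:
        """The next ``n`` variates of the stream."""
        chunks = []
        need = int(n)
        while need > 0:
            avail = self._buffer.size - self._pos
            if avail == 0:
                self._refill()
                continue
            take = min(avail, need)
            chunks.append(self._buffer[self._pos : self._pos + take])
            self._pos += take
            need -= take
        return np.concatenate(chunks) if len(chunks) != 1 else chunks[0].copy()


def sample_logfc(
    v: int, gaussian: PolarGaussian, params: LogFCParams = LogFCParams()
) -> float:
    """Draw one synthetic LogFC for deregulation direction ``v``.

    Returns exactly 0 for v=0; a value >= 0 for v=+1; a value <= 0 for
    v=-1.  The clamp means an up-regulated node can occasionally draw a
    LogFC of exactly 0 (probability Phi(-mean/sd), about 0.6% at the
    defaults) and tally as unchanged downstream.
    """
    if v == 0:
        return 0.0
    if v == 1:
        return max(0.0, params.sd * gaussian.normal() + params.mean)
    if v == -1:
        return min(0.0, params.sd * gaussian.normal() - params.mean)
    raise ValueError(f"direction must be -1, 0 or +1, got {v!r}")


def sample_logfc_many(
    v: int, n: int, gaussian: PolarGaussian, params: LogFCParams = LogFCParams()
) -> np.ndarray:
    """Vectorised :func:`sample_logfc`: ``n`` independent draws."""
    if v == 0:
        return np.zeros(int(n))
    if v == 1:
        return np.maximum(0.0, params.sd * gaussian.normals(n) + params.mean)
    if v == -1:
        return np.minimum(0.0, params.sd * gaussian.normals(n) - params.mean)
    raise ValueError(f"direction must be -1, 0 or +1, got {v!r}")


@dataclass(frozen=True)
class ExpressionChangeVector:
    """Per-node imposed expression change for one simulation step.

    Nodes outside the input carry exactly 0.
    """

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, node_id: str) -> float:
        return self.values[node_id]


def build_delta_e(
    graph: MetaPathwayGraph,
    input_spec: InputSpec,
    gaussian: PolarGaussian,
    params: LogFCParams = LogFCParams(),
) -> ExpressionChangeVector:
    """Assemble the expression-change vector for one simulation step.

    One fresh LogFC is drawn per deregulated input node, in sorted node-id
    order (the documented stream-consumption order); every other node
    gets 0.
    """
    missing = [n for n in input_spec.directions if n not in graph]
    if missing:
        raise KeyError(f"input node(s) absent from graph: {sorted(missing)}")
    values = dict.fromkeys(graph.node_ids, 0.0)
    for node in input_spec.active_nodes:
        values[node] = sample_logfc(input_spec.directions[node], gaussian, params)
    return ExpressionChangeVector(values)


def rectified_normal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Exact (mean, sd) of max(0, N(mean, sd)).

    E[X]   = mu*Phi(mu/sd) + sd*phi(mu/sd)
    E[X^2] = (mu^2 + sd^2)*Phi(mu/sd) + mu*sd*phi(mu/sd)
    """
    from scipy.stats import norm

    a = mean / sd
    m1 = mean * norm.cdf(a) + sd * norm.pdf(a)
    m2 = (mean**2 + sd**2) * norm.cdf(a) + mean * sd * norm.pdf(a)
    return m1, float(np.sqrt(m2 - m1 * m1))
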