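"""Benchmarking arithmetic against observed expression changes.

Predictions (up / down / unaltered, from the sign of the Activity
Score) are compared with observed log-fold-changes thresholded at
|LogFC| = 0.6 (boundary counts as altered).  Two bespoke tables are
built, following the benchmark's class-conditional scheme rather than a
standard multi-class confusion matrix:

* altered class (observed up or down):
  TP = predicted up & observed up, TN = predicted down & observed down,
  FP = predicted up & observed down, FN = predicted down & observed up;
  a node predicted unaltered but observed altered fits none of these
  four sign cells and is reported separately as ``missed_altered``.
* non-altered class (observed unaltered):
  TP = predicted unaltered, FN = predicted altered.

Rates: PPV = TP/(TP+FP), Sensitivity = TP/(TP+FN), Specificity =
TN/(TN+FP) on the altered table; PPV and FNR = FN/(FN+TP) on the
non-altered table.  A zero denominator yields ``None`` (NA), never 0,
so averaging reports across datasets is not biased by degenerate
tables.  Accuracy is the fraction of all scored nodes whose predicted
state equals the observed one.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "EvaluationReport",
    "classify_logfc",
    "predictions_from_scores",
    "evaluate",
    "detect_nonexpressed",
    "DEFAULT_LOGFC_THRESHOLD",
]

DEFAULT_LOGFC_THRESHOLD = 0.6

STATES = ("up", "down", "unaltered")


def classify_logfc(logfc: float, threshold: float = DEFAULT_LOGFC_THRESHOLD) -> str:
    """Ternary state of an observed log-fold-change.

    |logfc| strictly below ``threshold`` is ``unaltered``; otherwise the
    sign decides (|logfc| equal to the threshold counts as altered).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not math.isfinite(logfc):
        raise ValueError(f"non-finite LogFC {logfc!r}")
    if abs(logfc) < threshold:
        return "unaltered"
    return "up" if logfc > 0 else "down"


def predictions_from_scores(scores: Mapping[str, float]) -> dict[str, str]:
    """Map activity scores to predicted states by sign (0 -> unaltered)."""
    out = {}
    for node, a in scores.items():
        if a > 0:
            out[node] = "up"
        elif a < 0:
            out[node] = "down"
        else:
            out[node] = "unaltered"
    return out


@dataclass(frozen=True)
class EvaluationReport:
    """Counts and rates of the two class-conditional benchmark tables."""

    tp_altered: int
    tn_altered: int
    fp_altered: int
    fn_altered: int
    missed_altered: int  # predicted unaltered, observed altered
    tp_unaltered: int
    fn_unaltered: int
    accuracy: float
    ppv_altered: float | None
    sensitivity: float | None
    specificity: float | None
    ppv_unaltered: float | None
    fnr_unaltered: float | None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv(self) -> str:
        lines = []
        for key, value in asdict(self).items():
            if value is None:
                value = "NA"
            elif isinstance(value, float):
                value = f"{value:.6g}"
            lines.append(f"{key}\t{value}")
        return "\n".join(lines) + "\n"


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def evaluate(
    predicted: Mapping[str, str], observed: Mapping[str, str]
) -> EvaluationReport:
    """Build the benchmark report from per-node ternary states."""
    missing = sorted(set(predicted) ^ set(observed))
    if missing:
        raise KeyError(f"predicted/observed key mismatch: {missing}")
    if not predicted:
        raise ValueError("no nodes to evaluate")
    for mapping, label in ((predicted, "predicted"), (observed, "observed")):
        bad = sorted({v for v in mapping.values()} - set(STATES))
        if bad:
            raise ValueError(f"unknown {label} state(s): {bad}")
    tp = tn = fp = fn = missed = 0
    tpu = fnu = correct = 0
    for node, obs in observed.items():
        pred = predicted[node]
        if pred == obs:
            correct += 1
        if obs == "up":
            if pred == "up":
                tp += 1
            elif pred == "down":
                fn += 1
            else:
                missed += 1
        elif obs == "down":
            if pred == "down":
                tn += 1
            elif pred == "up":
                fp += 1
            else:
                missed += 1
        else:  # observed unaltered
            if pred == "unaltered":
                tpu += 1
            else:
                fnu += 1
    return EvaluationReport(
        tp_altered=tp,
        tn_altered=tn,
        fp_altered=fp,
        fn_altered=fn,
        missed_altered=missed,
        tp_unaltered=tpu,
        fn_unaltered=fnu,
        accuracy=correct / len(observed),
        ppv_altered=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv_unaltered=_ratio(tpu, tpu + fnu),
        fnr_unaltered=_ratio(fnu, fnu + tpu),
    )


def detect_nonexpressed(
    expression: Mapping[str, Iterable[float]], platform: str
) -> set[str]:
    """Flag silent genes from raw expression measurements.

    ``platform="sequencing"``: mean count below 10.
    ``platform="microarray"``: mean expression below the 10th percentile
    of all gene means (linear-interpolation percentile).
    """
    if platform not in ("sequencing", "microarray"):
        raise ValueError(f"unknown platform {platform!r}")
    if not expression:
        raise ValueError("empty expression table")
    means = {}
    for node, vals in expression.items():
        vals = np.asarray(list(vals), dtype=float)
        if vals.size == 0:
            raise ValueError(f"node {node!r} has no measurements")
        means[node] = float(vals.mean())
    if platform == "sequencing":
        return {n for n, mu in means.items() if mu < 10.0}
    cutoff = float(np.percentile(list(means.values()), 10))
    return {n for n, mu in means.items() if mu < cutoff}
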