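"""Error metrics, model comparison and descriptive trend classification.

The comparison criterion throughout is the mean absolute percentage error
(MAPE) of signed per-epoch errors (actual − fitted)/actual × 100.  Because
the base epoch's fitted value is pinned to the actual value (zero error by
construction), two averaging conventions exist: ``exclude_base`` (epochs
2..n, the default) and ``include_base`` (all n epochs, which dilutes the
mean by one zero term).  Both are computed and reported side by side so the
choice is never silent.

Trend classification is purely descriptive: the sign pattern of first
differences, with a relative flatness tolerance, maps a fitted curve to one
of {increasing, decreasing, U_shaped, inverted_U, mixed}.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError

__all__ = [
    "ErrorReport",
    "percentage_errors",
    "mape",
    "evaluate",
    "compare_models",
    "classify_trend",
    "TREND_CLASSES",
]

TREND_CLASSES = ("increasing", "decreasing", "U_shaped", "inverted_U", "mixed")


def percentage_errors(
    actual: Sequence[float],
    fitted: Sequence[float],
    epochs: Sequence[int] | None = None,
) -> np.ndarray:
    """Signed percentage errors (actual − fitted)/actual × 100.

    Positive where the model under-predicts.  A zero actual value is a
    division error naming the offending epoch.
    """
    a = np.asarray(actual, float)
    f = np.asarray(fitted, float)
    if a.shape != f.shape:
        raise AlignmentError(f"actual {a.shape} vs fitted {f.shape}")
    if (a == 0).any():
        k = int(np.argmax(a == 0))
        label = epochs[k] if epochs is not None else f"position {k + 1}"
        raise ZeroDivisionError(f"actual value is zero at {label}")
    return (a - f) / a * 100.0


def mape(errors: Sequence[float], convention: str = "exclude_base") -> float:
    """Mean absolute percentage error over the convention's epoch set.

    ``errors`` is the full signed error sequence including the base epoch at
    position 1; ``exclude_base`` averages positions 2..n, ``include_base``
    averages all of them.
    """
    e = np.abs(np.asarray(errors, float))
    if len(e) == 0:
        raise ValueError("empty error sequence")
    if convention == "exclude_base":
        if len(e) < 2:
            raise ValueError("exclude_base needs at least 2 epochs")
        return float(e[1:].mean())
    if convention == "include_base":
        return float(e.mean())
    raise ValueError(f"unknown MAPE convention {convention!r}")


@dataclass(frozen=True)
class ErrorReport:
    """Per-epoch signed percentage errors with their MAPE and convention."""

    errors_pct: np.ndarray
    mape: float
    mape_convention: str
    n_terms: int


def evaluate(
    actual: Sequence[float],
    fitted: Sequence[float],
    convention: str = "exclude_base",
    epochs: Sequence[int] | None = None,
) -> ErrorReport:
    errors = percentage_errors(actual, fitted, epochs=epochs)
    n_terms = len(errors) if convention == "include_base" else len(errors) - 1
    return ErrorReport(
        errors_pct=errors,
        mape=mape(errors, convention),
        mape_convention=convention,
        n_terms=n_terms,
    )


def compare_models(results: Sequence) -> tuple[pd.DataFrame, dict]:
    """Side-by-side fitted/error table for fits of the same series.

    Returns ``(table, summary)``; the table mirrors the conventional report
    layout (Actual Value, then Model Value / Error per model), and the
    summary holds each model's MAPE under both conventions plus the winner
    (lowest exclude-base MAPE; a tie is reported as such).  More than one
    result requires identical epochs and actual values.
    """
    if not results:
        raise ValueError("no results to compare")
    first = results[0]
    for r in results[1:]:
        if not np.array_equal(r.epochs, first.epochs):
            raise AlignmentError("results do not share epochs")
        if not np.allclose(r.actual, first.actual, rtol=0, atol=1e-12):
            raise AlignmentError("results do not share actual values")
    table = pd.DataFrame({"Year": first.epochs, "Actual Value": first.actual})
    summary: dict = {"models": {}}
    for r in results:
        table[f"Model Value ({r.model})"] = r.fitted
        table[f"Error ({r.model})"] = r.errors_pct
        summary["models"][r.model] = {
            "mape_exclude_base": float(r.mape),
            "mape_include_base": float(r.mape_include_base),
        }
    if len(results) > 1:
        mapes = {r.model: r.mape for r in results}
        lowest = min(mapes.values())
        winners = sorted(m for m, v in mapes.items() if np.isclose(v, lowest))
        summary["winner"] = winners[0] if len(winners) == 1 else "tie"
    return table, summary


def classify_trend(fitted: Sequence[float], flat_tol: float = 1e-6) -> str:
    """Classify a curve's shape from the sign pattern of first differences.

    Differences smaller than ``flat_tol`` times the series scale count as
    flat.  At most one sign change yields one of the four named shapes;
    anything else is ``mixed``.
    """
    y = np.asarray(fitted, float)
    if len(y) < 3:
        raise ValueError("need at least 3 points to classify a trend")
    d = np.diff(y)
    scale = np.max(np.abs(y)) or 1.0
    signs = np.sign(np.where(np.abs(d) <= flat_tol * scale, 0.0, d))
    signs = signs[signs != 0]
    if len(signs) == 0:
        return "mixed"  # flat everywhere: no named monotone/U shape applies
    # compress runs: [1,1,-1,-1] -> [1,-1]
    compressed = [signs[0]]
    for s in signs[1:]:
        if s != compressed[-1]:
            compressed.append(s)
    if compressed == [1.0]:
        return "increasing"
    if compressed == [-1.0]:
        return "decreasing"
    if compressed == [-1.0, 1.0]:
        return "U_shaped"
    if compressed == [1.0, -1.0]:
        return "inverted_U"
    return "mixed"
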