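"""Rank-agreement statistics between inferred pseudo-time and ground truth.

Two statistics are used:

* an absolute-numerator, tie-corrected Kendall coefficient

      τ_b = |C − D| / √((C + D + T_pred)(C + D + T_true)) ∈ [0, 1],

  where C/D count concordant/discordant pairs and T_pred/T_true count pairs
  tied in exactly that ordering — taking the absolute value makes the score
  direction-blind, which suits pseudo-time (a path traversed backwards is
  still the right ordering);
* Spearman's ρ ∈ [−1, 1], the Pearson correlation of the two rank vectors
  (average ranks on ties).

With several trajectories, each path is scored on its own cells against the
truth restricted to those cells and the unweighted mean across paths is
reported.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import MetricError


def _validate(pred, true) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1:
        raise MetricError("pred and true must be 1-D vectors of equal length")
    if pred.size < 2:
        raise MetricError("need at least 2 observations")
    return pred, true


def kendall_tau_b_abs(pred, true) -> float:
    """Absolute-numerator tie-corrected Kendall coefficient in [0, 1]."""
    pred, true = _validate(pred, true)
    if np.all(pred == pred[0]) or np.all(true == true[0]):
        raise MetricError("tau_b undefined when all values are tied in a vector")
    tau = stats.kendalltau(pred, true, variant="b").statistic
    return float(abs(tau))


def spearman_rho(pred, true) -> float:
    """Spearman rank correlation in [−1, 1] (average ranks on ties)."""
    pred, true = _validate(pred, true)
    if np.all(pred == pred[0]) or np.all(true == true[0]):
        raise MetricError("spearman undefined for a constant vector")
    return float(stats.spearmanr(pred, true).statistic)


def evaluate_paths(
    pseudotime: dict[int, dict[int, float]] | list[dict[int, float]],
    truth_time: np.ndarray,
) -> dict:
    """Per-path and mean rank agreement against ground-truth time.

    ``pseudotime`` maps path_id -> {cell index -> normalized pseudo-time}
    (or is a list of such dicts). Paths with fewer than 2 cells, or with a
    degenerate (all-tied) ordering, are skipped with a null score.
    """
    if isinstance(pseudotime, list):
        pseudotime = {i: d for i, d in enumerate(pseudotime)}
    per_path = {}
    taus, rhos = [], []
    for path_id, times in sorted(pseudotime.items()):
        cells = sorted(times)
        pred = np.array([times[i] for i in cells])
        true = truth_time[cells]
        try:
            tau = kendall_tau_b_abs(pred, true)
            rho = spearman_rho(pred, true)
        except MetricError:
            per_path[path_id] = {"kendall": None, "spearman": None, "n_cells": len(cells)}
            continue
        per_path[path_id] = {"kendall": tau, "spearman": rho, "n_cells": len(cells)}
        taus.append(tau)
        rhos.append(rho)
    if not taus:
        raise MetricError("no path had enough cells for evaluation")
    return {
        "per_path": per_path,
        "kendall": float(np.mean(taus)),
        "spearman": float(np.mean(rhos)),
        "n_paths": len(taus),
    }
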