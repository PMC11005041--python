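"""Exhaustive consensus-combination scanning and selection.

A consensus combination is a subset of k >= 2 trained models; its consensus
score CS for a compound is the arithmetic mean of the member probability
scores, and the compound is labeled toxic when CS >= 0.5 (the same inclusive
threshold used for single-model PS).  For n models the number of
combinations with k in [2, n] is

    Nc = sum_{k=2}^{n} C(n, k) = 2^n - n - 1

which gives 4083 for the 12-model ensemble and 1,048,555 for 20 models.  The
scan computes each model's PS vector once and reuses it across all
combinations; combinations are ranked by test MCC, ties broken by fewer
members, then lexicographic member order.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .curation import LabeledCompound
from .metrics import MetricsReport, evaluate
from .training import TrainedClassifier, classify_ps, predict_ps


def count_combinations(n: int, k_min: int = 2, k_max: int | None = None) -> int:
    """Number of model subsets with size in [k_min, k_max]."""
    if k_max is None:
        k_max = n
    if not 0 <= k_min <= k_max <= n:
        raise ValueError(f"invalid combination range: n={n}, "
                         f"k_min={k_min}, k_max={k_max}")
    return sum(math.comb(n, k) for k in range(k_min, k_max + 1))


def consensus_score(ps_values: Sequence[float]) -> tuple[float, int]:
    """Average member PSs into a CS and label it (toxic iff CS >= 0.5)."""
    ps = np.asarray(ps_values, dtype=float)
    if ps.size < 2:
        raise ValueError("a consensus needs at least 2 probability scores")
    if ps.min() < 0 or ps.max() > 1:
        raise ValueError("probability scores must lie in [0, 1]")
    cs = float(ps.mean())
    return cs, int(classify_ps(cs))


@dataclass(frozen=True)
class ConsensusResult:
    members: tuple[str, ...]
    metrics: MetricsReport
    cs: np.ndarray

    @property
    def k(self) -> int:
        return len(self.members)


def _rank_key(r: ConsensusResult):
    mcc = r.metrics.mcc
    if math.isnan(mcc):
        mcc = -math.inf
    return (-mcc, r.k, r.members)


def scan_ps_matrix(ps: np.ndarray, y_true: np.ndarray,
                   model_ids: Sequence[str], k_min: int = 2,
                   k_max: int | None = None) -> list["ConsensusResult"]:
    """Evaluate every model combination from a precomputed PS matrix.

    ``ps`` has one row per model (aligned with ``model_ids``) and one column
    per test compound.  Returns all combinations ranked best-first.
    """
    ps = np.asarray(ps, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    n_models = ps.shape[0]
    if len(model_ids) != n_models:
        raise ValueError("model_ids length must match PS matrix rows")
    if ps.shape[1] != y_true.size:
        raise ValueError("PS matrix columns must match the label vector")
    if k_max is None:
        k_max = n_models
    order = np.argsort(np.asarray(model_ids, dtype=object))
    ids_sorted = [model_ids[i] for i in order]
    ps = ps[order]

    results = []
    for k in range(max(2, k_min), k_max + 1):
        for combo in combinations(range(n_models), k):
            cs = ps[list(combo)].mean(axis=0)
            rep = evaluate(y_true, classify_ps(cs))
            results.append(ConsensusResult(
                members=tuple(ids_sorted[i] for i in combo),
                metrics=rep, cs=cs))
    results.sort(key=_rank_key)
    return results


def exhaustive_scan(models: dict[str, TrainedClassifier],
                    test: Sequence[LabeledCompound],
                    k_min: int = 2) -> list[ConsensusResult]:
    """Scan all >=2-member combinations of ``models`` on a held-out test set.

    All models must belong to the same endpoint ensemble; each model's PS
    vector is computed once.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to form a consensus")
    model_ids = sorted(models)
    mols = [r.mol for r in test]
    y = np.array([r.label for r in test], dtype=int)
    ps = np.vstack([predict_ps(models[m], mols) for m in model_ids])
    return scan_ps_matrix(ps, y, model_ids, k_min=k_min)


def select_best(results: Sequence[ConsensusResult]) -> ConsensusResult:
    """Deterministic best combination: maximal MCC, then fewest members,
    then lexicographically smallest member tuple."""
    if not results:
        raise ValueError("no consensus results to select from")
    return min(results, key=_rank_key)


def write_ranked_csv(results: Sequence[ConsensusResult], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["members", "k", "precision", "recall", "specificity",
                    "accuracy", "mcc"])
        for r in results:
            m = r.metrics
            w.writerow(["|".join(r.members), r.k, m.precision, m.recall,
                        m.specificity, m.accuracy, m.mcc])


def write_best_manifest(best: ConsensusResult, path) -> None:
    with open(path, "w") as fh:
        json.dump({"members": list(best.members), "k": best.k,
                   "metrics": best.metrics.as_dict()}, fh, indent=2)


def load_best_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
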