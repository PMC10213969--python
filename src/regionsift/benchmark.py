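"""Tool-comparison metrics: detection overlap, truth-set confusion,
fold-change concordance, rank correlation, and iterative threshold matching.

These are the quantitative comparisons used to argue that find-then-annotate
quantification matches classical read summarization: upset-style tallies of
which methods detect which features, sensitivity/specificity against planted
truth, Pearson/Spearman agreement of per-gene log2 fold changes, Spearman
correlation of p-value-sorted result lists, and a grid search for the
(low-count filter, alpha) pair that makes one method's significant set agree
best with a reference method's.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEParams, run_de

__all__ = [
    "detection_overlap",
    "confusion_vs_truth",
    "fc_correlation",
    "rank_correlation",
    "match_thresholds",
]


def detection_overlap(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Count IDs detected by exactly each non-empty combination of methods.

    The tallies partition the union: summing them recovers the union size.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    union = set().union(*sets.values())
    tallies: dict[frozenset, int] = {}
    for item in union:
        combo = frozenset(n for n in names if item in sets[n])
        tallies[combo] = tallies.get(combo, 0) + 1
    return tallies


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")


def confusion_vs_truth(calls: set, truth_de: set, universe: set) -> Confusion:
    """Confusion of DE calls against planted truth over a stated universe.

    ``truth_de`` holds the truly differential IDs; everything else in the
    universe is null.  Sensitivity is TP/(TP+FN) over truly-DE rows and
    specificity TN/(TN+FP) over null rows; an empty class yields NaN.
    """
    if not calls <= universe:
        raise ValueError("calls must be a subset of the universe")
    pos = truth_de & universe
    neg = universe - pos
    tp = len(calls & pos)
    fp = len(calls & neg)
    return Confusion(tp=tp, fp=fp, tn=len(neg) - fp, fn=len(pos) - tp)


def fc_correlation(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, float]:
    """Pearson r and Spearman rho of log2FC over the shared row IDs."""
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared IDs; need >= 3")
    x = a.loc[shared, "logFC"].to_numpy(dtype=float)
    y = b.loc[shared, "logFC"].to_numpy(dtype=float)
    return {
        "pearson_r": float(stats.pearsonr(x, y).statistic),
        "spearman_rho": float(stats.spearmanr(x, y).statistic),
        "n_shared": int(len(shared)),
    }


def rank_correlation(a: Sequence[str], b: Sequence[str]) -> dict[str, float]:
    """Spearman rho of shared labels' positions in two sorted lists.

    Ranks are the labels' positions within each *full* list (so a label's
    rank reflects everything it outranks, shared or not); rho is computed
    over the shared labels only.
    """
    pos_a = {label: i for i, label in enumerate(a)}
    pos_b = {label: i for i, label in enumerate(b)}
    shared = [label for label in a if label in pos_b]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared labels; need >= 3")
    ra = [pos_a[s] for s in shared]
    rb = [pos_b[s] for s in shared]
    return {
        "spearman_rho": float(stats.spearmanr(ra, rb).statistic),
        "n_shared": len(shared),
    }


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0  # two empty call sets agree perfectly by convention
    return len(a & b) / len(a | b)


def match_thresholds(
    method_counts: pd.DataFrame,
    reference_counts: pd.DataFrame,
    groups: Sequence,
    grid: Sequence[tuple[int, float]],
    reference_params: DEParams | None = None,
    min_samples: int = 2,
) -> dict:
    """Grid-search (min_count, alpha) to best match a reference call set.

    The reference's significant set is computed once under
    ``reference_params``; for every grid point the method's DE pipeline is
    re-run with that low-count filter and the significant sets compared by
    Jaccard index.  Ties go to the lexicographically smallest
    (min_count, alpha).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    reference_params = reference_params or DEParams()
    ref_de = run_de(reference_counts, groups, reference_params)
    ref_calls = set(ref_de.index[ref_de["FDR"] < reference_params.alpha])

    best = None
    records = []
    for min_count, alpha in sorted(grid):
        params = DEParams(min_count=min_count, min_samples=min_samples, alpha=alpha)
        de = run_de(method_counts, groups, params)
        calls = set(de.index[de["FDR"] < alpha]) if not de.empty else set()
        j = _jaccard(calls, ref_calls)
        records.append({"min_count": min_count, "alpha": alpha, "jaccard": j,
                        "n_calls": len(calls)})
        if best is None or j > best["jaccard"]:
            best = records[-1]
    return {
        "best_min_count": best["min_count"],
        "best_alpha": best["alpha"],
        "best_jaccard": best["jaccard"],
        "n_reference_calls": len(ref_calls),
        "grid": pd.DataFrame.from_records(records),
    }
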