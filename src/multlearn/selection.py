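"""Two-stage marker selection: KS relevance then correlation-redundancy pruning.

Markers (genes or clinical features) are screened by a two-sample, two-sided
Kolmogorov-Smirnov test between the two outcome classes; markers whose
p-value exceeds ``alpha`` are irrelevant.  Surviving markers are then pruned
for linear redundancy: when two relevant markers have an absolute Pearson
correlation above ``beta`` (default 0.75), the one with the larger KS p-value
is excluded as redundant to the other.

Markers are processed most-significant first (ascending p-value, ties broken
lexicographically by name), each marker compared once against the markers not
yet analysed; already-excluded markers are skipped on both sides of the
comparison.  Under this order the kept member of every correlated pair is the
more significant one, and the result is fully deterministic.  No second
pruning pass is made, so two survivors whose comparison was never anchored can
in principle remain correlated; in practice the significance-ordered sweep
compares every surviving pair against the most significant member of its
correlation cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ContractError

STATUS_SELECTED = "selected"
STATUS_IRRELEVANT = "excluded_irrelevant"
STATUS_REDUNDANT = "excluded_redundant"


def ks_pvalue(values_class0, values_class1) -> float:
    """Two-sample two-sided KS p-value (exact for small samples)."""
    a = np.asarray(values_class0, dtype=float)
    b = np.asarray(values_class1, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("KS test requires non-empty samples in both classes")
    return float(stats.ks_2samp(a, b, alternative="two-sided", method="auto").pvalue)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson r|; defined as 0 when either vector has zero variance."""
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class SelectionReport:
    """Per-marker outcome of the selection sweep.

    ``table`` has one row per input marker with columns
    ``marker, p_value, status, redundant_to`` (``redundant_to`` set only for
    redundancy exclusions).  ``selected`` lists the surviving set F' in
    processing order (ascending p-value).
    """

    table: pd.DataFrame
    alpha: float
    beta: float

    @property
    def selected(self) -> list[str]:
        sel = self.table[self.table["status"] == STATUS_SELECTED]
        return list(sel["marker"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def select_markers(F: pd.DataFrame, c, alpha: float = 0.05,
                   beta: float = 0.75) -> SelectionReport:
    """Select outcome-relevant, non-redundant markers from ``F``.

    ``F`` is a patients x markers matrix (normalized), ``c`` a binary outcome
    vector aligned with its rows.  Returns a :class:`SelectionReport`; the
    surviving markers all have KS p-value <= ``alpha`` and, within every
    compared correlated pair, the smaller p-value.
    """
    c = np.asarray(c)
    if len(c) != len(F):
        raise ContractError(
            f"outcome length {len(c)} does not match {len(F)} patients")
    classes = np.unique(c)
    if len(classes) != 2:
        raise ContractError(
            f"outcome must be binary with both classes present, got {classes}")
    mask1 = c == classes.max()

    cols = {m: F[m].to_numpy(dtype=float) for m in F.columns}
    pvals = {m: ks_pvalue(v[~mask1], v[mask1]) for m, v in cols.items()}

    # most-significant-first sweep, lexicographic tie-break
    order = sorted(F.columns, key=lambda m: (pvals[m], m))
    position = {m: i for i, m in enumerate(order)}

    excluded: dict[str, str] = {}   # marker -> redundant_to ("" if irrelevant)
    analysed: set[str] = set()
    for m1 in order:
        analysed.add(m1)
        if m1 in excluded:
            continue
        if pvals[m1] > alpha:
            excluded[m1] = ""
            continue
        for m2 in order[position[m1] + 1:]:
            if m2 in analysed or m2 in excluded:
                continue
            if pvals[m2] > alpha:
                excluded[m2] = ""
            elif abs(_pearson(cols[m1], cols[m2])) > beta:
                if pvals[m2] >= pvals[m1]:
                    excluded[m2] = m1
                else:  # unreachable under ascending-p order; kept for fidelity
                    excluded[m1] = m2
                    break

    rows = []
    for m in order:
        if m not in excluded:
            status, red = STATUS_SELECTED, ""
        elif excluded[m]:
            status, red = STATUS_REDUNDANT, excluded[m]
        else:
            status, red = STATUS_IRRELEVANT, ""
        rows.append({"marker": m, "p_value": pvals[m],
                     "status": status, "redundant_to": red})
    table = pd.DataFrame(rows, columns=["marker", "p_value", "status",
                                        "redundant_to"])
    return SelectionReport(table=table, alpha=alpha, beta=beta)
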