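"""Treatment-sensitivity outcome definition from ordered response classes.

The six treatment-response (TR) categories are ordered by depth of response,
PD < SD < PR < VGPR < CR < SCR.  The binary treatment-sensitivity (TS)
outcome labels a patient sensitive when their TR class is at or above a
cutpoint; the cutpoint is chosen among the five possible cuts as the one
whose TS grouping best stratifies days-to-disease-progression survival,
measured by the Cox score test for a single binary covariate — i.e. the
log-rank test.  On real myeloma cohorts this procedure selects the cut that
groups stringent complete response with complete response (SCR, CR sensitive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .core import RESPONSE_CLASSES, ContractError, DataError


@dataclass
class TSDefinition:
    """An ordered-class cutpoint defining the binary TS outcome.

    ``classes[cut_index:]`` are the sensitive classes.  ``pvalues`` records
    the survival-stratification p-value of every candidate cut evaluated.
    """

    classes: list[str] = field(default_factory=lambda: list(RESPONSE_CLASSES))
    cut_index: int = 4  # sensitive = {CR, SCR}
    pvalues: dict[int, float] = field(default_factory=dict)

    @property
    def sensitive_classes(self) -> list[str]:
        return self.classes[self.cut_index:]


def derive_ts(response: pd.Series, definition: TSDefinition) -> pd.Series:
    """Binary TS vector: 1 iff the TR class is at or above the cut."""
    values = response.astype(str)
    unknown = set(values) - set(definition.classes)
    if unknown:
        raise DataError(
            f"unknown response class(es): {sorted(unknown)} "
            f"(vocabulary: {definition.classes})")
    rank = values.map({c: i for i, c in enumerate(definition.classes)})
    return (rank >= definition.cut_index).astype(int)


def stratification_pvalue(ts, time, event) -> float:
    """Survival-stratification p-value of a binary TS grouping.

    The Cox partial-likelihood score test for a single binary covariate,
    which is exactly the log-rank test (Breslow tie handling).  Returns 1.0
    with a warning when either group has no events.
    """
    ts = np.asarray(ts).astype(int)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    g1 = ts == 1
    if event[g1].sum() == 0 or event[~g1].sum() == 0:
        warnings.warn("a TS group has no events; stratification p-value set to 1")
        return 1.0
    res = logrank_test(time[~g1], time[g1],
                       event_observed_A=event[~g1], event_observed_B=event[g1])
    return float(res.p_value)


def select_ts_definition(response: pd.Series, time, event,
                         classes=None) -> TSDefinition:
    """Choose the TS cutpoint minimizing the stratification p-value.

    Evaluates the five candidate cuts over the six ordered classes and
    returns the minimizing cut with the full p-value table (ties resolved to
    the lowest cut index).
    """
    classes = list(classes) if classes is not None else list(RESPONSE_CLASSES)
    observed = set(response.astype(str))
    if len(observed & set(classes)) < 2:
        raise DataError("need at least two distinct response classes")
    pvals: dict[int, float] = {}
    for cut in range(1, len(classes)):
        ts = derive_ts(response, TSDefinition(classes=classes, cut_index=cut))
        if ts.nunique() < 2:
            pvals[cut] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[cut] = stratification_pvalue(ts, time, event)
    if not pvals:
        raise DataError("no valid TS cut could be evaluated")
    best = min(pvals, key=lambda c: (pvals[c], c))
    return TSDefinition(classes=classes, cut_index=best, pvalues=pvals)
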