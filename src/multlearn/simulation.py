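"""Counterfactual treatment simulation.

For every patient the trained predictor is queried once per candidate
treatment: the one-hot treatment block of the patient's feature row is
overwritten with the candidate, every other feature untouched, and the TS
score recomputed.  The simulated treatment kappa is the score argmax; the
switch indicator zeta is 1 when kappa differs from the actual treatment.  On
an exact score tie the patient's actual treatment wins if it is among the
maximizers, otherwise the lexicographically first maximizer — so a
treatment-blind predictor never reports a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Cohort, ContractError
from .training import TSPredictor


@dataclass
class SimulationTable:
    """Per-patient counterfactual scores and treatment reassignments.

    ``table`` columns: ``actual``, one ``score_<t>`` per candidate,
    ``kappa`` (score-maximizing treatment) and ``switch`` (0/1).
    """

    table: pd.DataFrame
    candidates: list[str]

    @property
    def switch_fraction(self) -> float:
        """Fraction of patients whose best simulated treatment differs."""
        return float(self.table["switch"].mean())

    def write(self, path) -> None:
        self.table.rename_axis("patient_id").to_csv(path, sep="\t")


def simulate_treatments(predictor: TSPredictor, cohort: Cohort,
                        candidate_treatments=None) -> SimulationTable:
    """Score every patient under every candidate treatment.

    Candidates default to the predictor's training treatment vocabulary and
    must be a subset of it.  The cohort is never mutated.
    """
    candidates = (list(candidate_treatments)
                  if candidate_treatments is not None
                  else list(predictor.treatment_vocab))
    unknown = set(candidates) - set(predictor.treatment_vocab)
    if unknown:
        raise ContractError(
            f"candidate treatment(s) outside the training vocabulary: "
            f"{sorted(unknown)}")

    scores = pd.DataFrame(
        {f"score_{t}": predictor.score(cohort, treatment_override=t)
         for t in candidates})
    mat = scores.to_numpy()
    kappa = []
    actual = cohort.treatment
    for i, pid in enumerate(scores.index):
        best = mat[i].max()
        winners = [candidates[j] for j in range(len(candidates))
                   if mat[i, j] == best]
        act = actual.loc[pid]
        kappa.append(act if act in winners else sorted(winners)[0])
    table = scores.copy()
    table.insert(0, "actual", actual)
    table["kappa"] = kappa
    table["switch"] = (table["kappa"] != table["actual"]).astype(int)
    return SimulationTable(table=table, candidates=candidates)


def reallocation_matrix(sim: SimulationTable) -> pd.DataFrame:
    """Actual x simulated treatment matrix of patient percentages.

    Entry (a, b) is the percentage of patients actually on treatment ``a``
    whose simulated best treatment is ``b``; each row sums to 100.
    Treatments with zero patients are omitted.
    """
    t = sim.table
    if len(t) == 0:
        raise ContractError("cannot build a reallocation matrix from an empty table")
    counts = pd.crosstab(t["actual"], t["kappa"])
    counts = counts.reindex(columns=sim.candidates, fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    pct.index.name = "actual"
    pct.columns.name = "simulated"
    return pct


def pooled_simulation(predictors: list[TSPredictor], cohort: Cohort,
                      plan, candidates=None) -> SimulationTable:
    """Per-fold counterfactual simulation pooled over CV validation sets.

    Each fold's predictor scores only its own validation patients; the
    per-patient rows are concatenated in cohort order.
    """
    parts = []
    cand = None
    for k, pred in enumerate(predictors):
        val_ids = list(plan.fold.index[plan.fold == k])
        if not val_ids:
            continue
        sim = simulate_treatments(pred, cohort.subset(val_ids), candidates)
        cand = sim.candidates if cand is None else cand
        parts.append(sim.table)
    if not parts:
        raise ContractError("no folds produced simulation rows")
    table = pd.concat(parts)
    table = table.loc[[p for p in cohort.clinical.index if p in table.index]]
    return SimulationTable(table=table, candidates=cand)
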