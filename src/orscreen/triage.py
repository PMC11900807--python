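"""Per-receptor triage of a screened library and workflow evaluation.

The screen partitions molecules, per receptor, into:

* potential binders — the best-ranked top fraction (default 6%), minus
  suspected decoys;
* suspected decoys — molecules appearing in the top fraction of at
  least 70% of the supplied receptors, interpreted as scoring
  artifacts rather than genuine broad activity (global status);
* potential non-binders — the worst-ranked bottom fraction (default
  45%);
* unclassified — everything else.

Decoy frequency is computed over whichever receptor subset is supplied
(pheromone receptors are typically excluded upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import ACTIVE, top_k
from .rescoring import RankedList

BINDER = "binder"
NONBINDER_OR_DECOY = "nonbinder_or_decoy"


@dataclass
class TriageResult:
    """Outcome of the triage filters over a set of receptors."""

    potential_binders: dict[str, set[str]]      # receptor -> molecule ids
    potential_nonbinders: dict[str, set[str]]   # receptor -> molecule ids
    suspected_decoys: dict[str, float]          # molecule id -> top-set frequency
    top_sets: dict[str, set[str]]               # receptor -> raw top-fraction set
    top_fraction: float
    promiscuity_threshold: float
    bottom_fraction: float

    def classes_for(self, receptor: str) -> dict[str, str]:
        """molecule -> {potential_binder, suspected_decoy,
        potential_nonbinder, unclassified} for one receptor."""
        out: dict[str, str] = {}
        binders = self.potential_binders[receptor]
        nonbinders = self.potential_nonbinders[receptor]
        for mol in binders:
            out[mol] = "potential_binder"
        for mol in self.suspected_decoys:
            out[mol] = "suspected_decoy"
        for mol in nonbinders:
            out.setdefault(mol, "potential_nonbinder")
        return out


def triage(
    ranked: Mapping[str, RankedList],
    top_fraction: float = 0.06,
    promiscuity_threshold: float = 0.7,
    bottom_fraction: float = 0.45,
) -> TriageResult:
    """Run the three triage filters over per-receptor rankings.

    The promiscuity threshold is inclusive: a molecule in the top set
    of exactly 70% of receptors is a suspected decoy at the default.
    """
    if not ranked:
        raise ValueError("no ranked lists supplied")
    universes = {r: frozenset(rl.order) for r, rl in ranked.items()}
    universe = next(iter(universes.values()))
    if any(u != universe for u in universes.values()):
        raise ValueError("ranked lists cover different molecule universes")
    if not universe:
        raise ValueError("empty ranked lists")

    n = len(universe)
    n_receptors = len(ranked)

    top_sets = {
        rec: set(rl.order[: top_k(top_fraction, n)]) for rec, rl in ranked.items()
    }
    counts: dict[str, int] = {}
    for top in top_sets.values():
        for mol in top:
            counts[mol] = counts.get(mol, 0) + 1
    freq = {mol: c / n_receptors for mol, c in counts.items()}
    decoys = {mol: f for mol, f in freq.items() if f >= promiscuity_threshold}

    binders = {rec: top - set(decoys) for rec, top in top_sets.items()}

    n_bottom = int(np.floor(bottom_fraction * n))
    nonbinders = {
        rec: set(rl.order[n - n_bottom:]) if n_bottom else set()
        for rec, rl in ranked.items()
    }

    return TriageResult(
        potential_binders=binders,
        potential_nonbinders=nonbinders,
        suspected_decoys=decoys,
        top_sets=top_sets,
        top_fraction=top_fraction,
        promiscuity_threshold=promiscuity_threshold,
        bottom_fraction=bottom_fraction,
    )


def triage_frame(result: TriageResult, ranked: Mapping[str, RankedList]) -> pd.DataFrame:
    """Long-form per-receptor table: molecule, class, rank, score, decoy_frequency."""
    rows = []
    for rec in sorted(ranked):
        rl = ranked[rec]
        for mol in rl.order:
            if mol in result.suspected_decoys:
                cls_ = "suspected_decoy"
            elif mol in result.potential_binders[rec]:
                cls_ = "potential_binder"
            elif mol in result.potential_nonbinders[rec]:
                cls_ = "potential_nonbinder"
            else:
                cls_ = "unclassified"
            rows.append(
                {
                    "receptor": rec,
                    "molecule": mol,
                    "class": cls_,
                    "rank": rl.rank[mol],
                    "score": rl.scores[mol],
                    "decoy_frequency": result.suspected_decoys.get(mol, float("nan")),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PredictionEvaluation:
    """Contingency of predicted binders against experimental activity.

    Ratios that are undefined (zero denominator) are reported as None,
    never as 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision_pct: float | None = field(init=False)
    accuracy: float = field(init=False)
    tpr: float | None = field(init=False)
    fpr: float | None = field(init=False)

    def __post_init__(self) -> None:
        total = self.tp + self.fp + self.tn + self.fn
        if total == 0:
            raise ValueError("empty contingency")
        pred_pos = self.tp + self.fp
        actual_pos = self.tp + self.fn
        actual_neg = self.fp + self.tn
        self.precision_pct = 100.0 * self.tp / pred_pos if pred_pos else None
        self.accuracy = (self.tp + self.tn) / total
        self.tpr = self.tp / actual_pos if actual_pos else None
        self.fpr = self.fp / actual_neg if actual_neg else None


def evaluate_predictions(
    predicted: Mapping[str, str], observed: Mapping[str, str]
) -> PredictionEvaluation:
    """Score workflow predictions against experimental outcomes.

    *predicted* maps molecule -> {binder, nonbinder_or_decoy};
    *observed* maps molecule -> {active, inactive}. The molecule sets
    must coincide.
    """
    if set(predicted) != set(observed):
        raise ValueError("predicted and observed molecule sets differ")
    tp = fp = tn = fn = 0
    for mol, pred in predicted.items():
        if pred not in (BINDER, NONBINDER_OR_DECOY):
            raise ValueError(f"unknown prediction {pred!r} for {mol!r}")
        is_active = observed[mol] == ACTIVE
        if pred == BINDER:
            tp += is_active
            fp += not is_active
        else:
            fn += is_active
            tn += not is_active
    return PredictionEvaluation(tp=tp, fp=fp, tn=tn, fn=fn)
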