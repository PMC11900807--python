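"""Scoring-function calibration against an experimental activity panel.

Given per-receptor rankings under several scoring methods and a
receptor x odorant activity matrix (binary labels, or p-values
thresholded at p < 0.001), this module computes per-receptor ROC AUCs
and enrichment factors, optimizes the top-fraction cutoff by the
TPR/FPR ratio, and derives the non-binder fraction as the median
normalized rank at which the true-positive rate first reaches 1.

Receptors carry a class tag (pheromone receptors vs non-pheromonal),
because the two classes behave very differently under raw docking
scores; threshold derivation excludes pheromone receptors by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .rescoring import RankedList, ScoreTable, rank

ACTIVE = "active"
INACTIVE = "inactive"
PHEROMONE = "pheromone_receptor"
NON_PHEROMONAL = "non_pheromonal"

DEFAULT_P_THRESHOLD = 0.001
#: Default cutoff grid: 1%..100% in 1% steps.
DEFAULT_GRID = tuple(np.round(np.arange(0.01, 1.001, 0.01), 2))


@dataclass
class ActivityMatrix:
    """Receptor x molecule experimental activity labels.

    Labels may be given directly or derived from p-values with
    ``active <=> p < p_threshold`` (strict inequality).
    """

    receptor_class: dict[str, str]
    labels: dict[tuple[str, str], str]
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def receptors(self) -> list[str]:
        return sorted(self.receptor_class)

    @property
    def molecules(self) -> list[str]:
        return sorted({m for _, m in self.labels})

    def labels_for(self, receptor: str) -> dict[str, str]:
        return {m: lab for (r, m), lab in self.labels.items() if r == receptor}

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        receptor_class: Mapping[str, str] | None = None,
        p_threshold: float = DEFAULT_P_THRESHOLD,
    ) -> "ActivityMatrix":
        """Build from a (receptor, molecule, label | p_value) table."""
        labels: dict[tuple[str, str], str] = {}
        p_values: dict[tuple[str, str], float] = {}
        for _, row in df.iterrows():
            key = (str(row["receptor"]), str(row["molecule"]))
            if "label" in df.columns and not pd.isna(row.get("label")):
                lab = str(row["label"])
                if lab not in (ACTIVE, INACTIVE):
                    raise ValueError(f"unknown label {lab!r} for {key}")
            elif "p_value" in df.columns and not pd.isna(row.get("p_value")):
                p = float(row["p_value"])
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"p-value out of [0,1] for {key}")
                p_values[key] = p
                lab = ACTIVE if p < p_threshold else INACTIVE
            else:
                raise ValueError(f"row {key} has neither label nor p_value")
            labels[key] = lab
        classes = dict(receptor_class) if receptor_class else {}
        for rec, _ in labels:
            classes.setdefault(rec, NON_PHEROMONAL)
        return cls(receptor_class=classes, labels=labels, p_values=p_values)


def _check_labels(labels: Mapping[str, str], molecules: Sequence[str]) -> np.ndarray:
    y = np.array([labels[m] == ACTIVE for m in molecules], dtype=bool)
    if y.all() or not y.any():
        raise ValueError("AUC/TPR-FPR undefined: labels are all-active or all-inactive")
    return y


def roc_auc(ranked: RankedList, labels: Mapping[str, str]) -> float:
    """ROC AUC of a ranking as the Mann-Whitney statistic.

    Equals the fraction of (active, inactive) pairs where the active
    molecule has the better (more negative) score; tied scores count 0.5.
    """
    mols = ranked.order
    y = _check_labels(labels, mols)
    # midranks on "goodness" so tied scores share credit
    goodness = rankdata([-ranked.scores[m] for m in mols])
    n_act = int(y.sum())
    n_inact = len(mols) - n_act
    u = goodness[y].sum() - n_act * (n_act + 1) / 2.0
    return float(u / (n_act * n_inact))


def top_k(fraction: float, n: int) -> int:
    """Top-set size: max(1, round-half-up(fraction * n))."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, int(np.floor(fraction * n + 0.5)))


def enrichment_factor(
    ranked: RankedList, labels: Mapping[str, str], fraction: float
) -> float:
    """EF = (active rate in the top fraction) / (active rate overall)."""
    mols = ranked.order
    n = len(mols)
    n_act = sum(labels[m] == ACTIVE for m in mols)
    if n_act == 0:
        raise ValueError("enrichment factor undefined with zero actives")
    k = top_k(fraction, n)
    act_top = sum(labels[m] == ACTIVE for m in mols[:k])
    return (act_top / k) / (n_act / n)


def max_enrichment_factor(
    ranked: RankedList, labels: Mapping[str, str], grid: Sequence[float] = DEFAULT_GRID
) -> float:
    """Maximum EF over a fraction grid (single pass via cumulative actives)."""
    mols = ranked.order
    n = len(mols)
    act = np.array([labels[m] == ACTIVE for m in mols], dtype=float)
    n_act = act.sum()
    if n_act == 0:
        raise ValueError("enrichment factor undefined with zero actives")
    cum = np.cumsum(act)
    ks = sorted({top_k(f, n) for f in grid})
    return float(max((cum[k - 1] / k) / (n_act / n) for k in ks))


def tpr_fpr(
    ranked: RankedList, labels: Mapping[str, str], fraction: float
) -> tuple[float, float]:
    """TPR and FPR of the top-fraction cut; FPR=0 gets a continuity
    correction of 0.5/negatives so ratios stay finite."""
    mols = ranked.order
    y = _check_labels(labels, mols)
    k = top_k(fraction, len(mols))
    top = np.zeros(len(mols), dtype=bool)
    top[:k] = True
    n_act = int(y.sum())
    n_inact = len(mols) - n_act
    tpr = float((top & y).sum() / n_act)
    fp = int((top & ~y).sum())
    fpr = fp / n_inact if fp > 0 else 0.5 / n_inact
    return tpr, fpr


def optimal_top_fraction(
    ranked: RankedList,
    labels: Mapping[str, str],
    grid: Sequence[float] = DEFAULT_GRID,
) -> tuple[float, float]:
    """Grid fraction maximizing TPR/FPR; smallest fraction wins ties."""
    if not len(grid):
        raise ValueError("empty fraction grid")
    best_frac, best_ratio = None, -np.inf
    for frac in sorted(grid):
        tpr, fpr = tpr_fpr(ranked, labels, frac)
        ratio = tpr / fpr
        if ratio > best_ratio:
            best_frac, best_ratio = frac, ratio
    return float(best_frac), float(best_ratio)


def tpr_saturation_rank(ranked: RankedList, labels: Mapping[str, str]) -> int:
    """First (best) rank at which TPR reaches 1: the rank of the
    worst-ranked active molecule."""
    worst = max(ranked.rank[m] for m in ranked.order if labels[m] == ACTIVE)
    return int(worst)


@dataclass
class CalibrationReport:
    """Per-(receptor, method) metrics plus class medians and the derived
    workflow thresholds."""

    per_receptor: pd.DataFrame  # receptor, class, method, auc, max_ef, optimal_fraction
    median_auc: dict[tuple[str, str], float]  # (class, method) -> median AUC
    median_max_ef: dict[tuple[str, str], float]
    chosen_method: str
    chosen_top_fraction: float
    nonbinder_fraction: float

    def to_json(self) -> str:
        payload = {
            "chosen_method": self.chosen_method,
            "chosen_top_fraction": self.chosen_top_fraction,
            "nonbinder_fraction": self.nonbinder_fraction,
            "median_auc": {f"{c}|{m}": v for (c, m), v in self.median_auc.items()},
            "median_max_ef": {f"{c}|{m}": v for (c, m), v in self.median_max_ef.items()},
            "per_receptor": self.per_receptor.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def calibrate(
    tables: Mapping[str, Mapping[str, ScoreTable]],
    activity: ActivityMatrix,
    grid: Sequence[float] = DEFAULT_GRID,
    threshold_class: str = NON_PHEROMONAL,
    select_method: str | None = None,
) -> CalibrationReport:
    """Evaluate every (receptor, method) cell and derive the workflow
    thresholds.

    Parameters
    ----------
    tables
        receptor id -> method -> ScoreTable. Every receptor of the
        activity matrix must have a table for every method.
    threshold_class
        Receptor class over which the top fraction and non-binder
        fraction medians are taken (pheromone receptors excluded by
        default, since they are calibrated separately).
    select_method
        Scoring method used for threshold derivation; default picks
        the method with the highest median AUC within threshold_class.
    """
    receptors = activity.receptors
    methods = sorted({m for per in tables.values() for m in per})
    rows = []
    for rec in receptors:
        if rec not in tables:
            raise KeyError(f"no score tables for receptor {rec!r}")
        labels = activity.labels_for(rec)
        for method in methods:
            if method not in tables[rec]:
                raise KeyError(f"missing table for ({rec!r}, {method!r})")
            ranked = rank(tables[rec][method])
            auc = roc_auc(ranked, labels)
            max_ef = max_enrichment_factor(ranked, labels, grid)
            opt_frac, _ = optimal_top_fraction(ranked, labels, grid)
            rows.append(
                {
                    "receptor": rec,
                    "receptor_class": activity.receptor_class[rec],
                    "method": method,
                    "auc": auc,
                    "max_ef": max_ef,
                    "optimal_fraction": opt_frac,
                }
            )
    per_receptor = pd.DataFrame(rows)

    median_auc: dict[tuple[str, str], float] = {}
    median_max_ef: dict[tuple[str, str], float] = {}
    for (cls_, method), sub in per_receptor.groupby(["receptor_class", "method"]):
        median_auc[(cls_, method)] = float(sub["auc"].median())
        median_max_ef[(cls_, method)] = float(sub["max_ef"].median())

    pool = per_receptor[per_receptor["receptor_class"] == threshold_class]
    if pool.empty:
        raise ValueError(f"no receptors of class {threshold_class!r} for threshold derivation")
    if select_method is None:
        select_method = max(
            (m for m in methods), key=lambda m: median_auc[(threshold_class, m)]
        )
    sel = pool[pool["method"] == select_method]
    chosen_top_fraction = float(sel["optimal_fraction"].median())

    sat_fracs = []
    for rec in sorted(sel["receptor"]):
        ranked = rank(tables[rec][select_method])
        labels = activity.labels_for(rec)
        sat_fracs.append(tpr_saturation_rank(ranked, labels) / len(ranked))
    nonbinder_fraction = float(np.median(sat_fracs))

    return CalibrationReport(
        per_receptor=per_receptor,
        median_auc=median_auc,
        median_max_ef=median_max_ef,
        chosen_method=select_method,
        chosen_top_fraction=chosen_top_fraction,
        nonbinder_fraction=nonbinder_fraction,
    )
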