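"""Binding-pocket descriptor regression of receptor tuning breadth.

A receptor's tuning breadth — how many of the tested odorants activate
it — appears to be partly encoded in the geometry and chemistry of its
binding pocket: in moth odorant receptors, larger and less hydrophobic
pockets tend to have narrower recognition spectra. This module fits
ordinary-least-squares models predicting the per-receptor count of
active molecules from cavity descriptors (volume in Å^3, solvent
accessible surface area in Å^2, hydrophobicity and polarity scores as
produced by cavity-analysis tools and consumed here as opaque data).

Reported metrics are in-sample (Pearson r between fitted and observed
counts, RMSE in molecule-count units); a leave-one-out variant is
available but not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import ACTIVE, DEFAULT_P_THRESHOLD, ActivityMatrix

STANDARD_DESCRIPTORS = ("volume", "sasa", "hydrophobicity", "polarity")


def count_actives(
    activity: ActivityMatrix, p_threshold: float = DEFAULT_P_THRESHOLD
) -> dict[str, int]:
    """Active-molecule count per receptor.

    When p-values are present they are re-thresholded at *p_threshold*
    (strict inequality, p < threshold); otherwise stored labels are
    counted.
    """
    counts: dict[str, int] = {r: 0 for r in activity.receptors}
    for (rec, mol), label in activity.labels.items():
        key = (rec, mol)
        if key in activity.p_values:
            active = activity.p_values[key] < p_threshold
        else:
            active = label == ACTIVE
        counts[rec] += bool(active)
    return counts


@dataclass
class TuningModel:
    """OLS fit of active-molecule counts on pocket descriptors."""

    variables: list[str]
    intercept: float
    coefficients: dict[str, float]
    coef_se: dict[str, float]
    fitted: dict[str, float]
    observed: dict[str, float]
    pearson_r: float
    rmse: float
    n: int

    def predict(self, descriptors: pd.DataFrame) -> pd.Series:
        X = descriptors[self.variables].to_numpy(dtype=float)
        beta = np.array([self.coefficients[v] for v in self.variables])
        return pd.Series(self.intercept + X @ beta, index=descriptors.index)

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "n": self.n,
            "fitted": self.fitted,
        }


def _validate_design(X: np.ndarray, variables: Sequence[str]) -> None:
    if len(set(variables)) != len(variables):
        dup = sorted({v for v in variables if list(variables).count(v) > 1})
        raise ValueError(f"duplicated variables: {dup}")
    design = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the offending columns: constant or collinear
        bad = [v for i, v in enumerate(variables) if np.ptp(X[:, i]) == 0]
        detail = f"constant columns {bad}" if bad else "collinear columns"
        raise ValueError(f"rank-deficient design ({detail}) for variables {list(variables)}")


def fit_tuning_model(
    descriptors: pd.DataFrame,
    counts: Mapping[str, float],
    variables: Sequence[str],
) -> TuningModel:
    """Fit counts ~ intercept + descriptors[variables] by OLS.

    *descriptors* is indexed by receptor id (or has a ``receptor``
    column). Requires n > len(variables) + 1 receptors.
    """
    df = descriptors.copy()
    if "receptor" in df.columns:
        df = df.set_index("receptor")
    receptors = sorted(set(df.index) & set(counts))
    if not receptors:
        raise ValueError("no receptors shared between descriptors and counts")
    missing_vars = [v for v in variables if v not in df.columns]
    if missing_vars:
        raise ValueError(f"descriptor columns missing: {missing_vars}")
    df = df.loc[receptors]
    if df[list(variables)].isna().any().any():
        raise ValueError("missing values in modeled descriptor columns")

    n = len(receptors)
    if n <= len(variables) + 1:
        raise ValueError(f"need n > {len(variables) + 1} receptors, have {n}")

    X = df[list(variables)].to_numpy(dtype=float)
    y = np.array([float(counts[r]) for r in receptors])
    if np.ptp(y) == 0:
        raise ValueError("constant response: correlation undefined")
    _validate_design(X, variables)

    design = np.column_stack([np.ones(n), X])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    dof = n - design.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))

    r = float(stats.pearsonr(fitted, y)[0]) if np.ptp(fitted) > 0 else float("nan")
    if np.ptp(fitted) == 0:
        raise ValueError("constant fitted values: correlation undefined")
    rmse = float(np.sqrt(np.mean(resid**2)))

    return TuningModel(
        variables=list(variables),
        intercept=float(beta[0]),
        coefficients={v: float(b) for v, b in zip(variables, beta[1:])},
        coef_se={v: float(s) for v, s in zip(variables, se[1:])},
        fitted={rec: float(f) for rec, f in zip(receptors, fitted)},
        observed={rec: float(v) for rec, v in zip(receptors, y)},
        pearson_r=r,
        rmse=rmse,
        n=n,
    )


def loo_metrics(
    descriptors: pd.DataFrame,
    counts: Mapping[str, float],
    variables: Sequence[str],
) -> tuple[float, float]:
    """Leave-one-out Pearson r and RMSE (optional stricter check)."""
    df = descriptors.copy()
    if "receptor" in df.columns:
        df = df.set_index("receptor")
    receptors = sorted(set(df.index) & set(counts))
    preds, obs = [], []
    for rec in receptors:
        rest = [r for r in receptors if r != rec]
        model = fit_tuning_model(df.loc[rest], {r: counts[r] for r in rest}, variables)
        preds.append(float(model.predict(df.loc[[rec]]).iloc[0]))
        obs.append(float(counts[rec]))
    preds_a, obs_a = np.array(preds), np.array(obs)
    r = float(stats.pearsonr(preds_a, obs_a)[0])
    rmse = float(np.sqrt(np.mean((preds_a - obs_a) ** 2)))
    return r, rmse


def compare_variable_subsets(
    descriptors: pd.DataFrame,
    counts: Mapping[str, float],
    subsets: Sequence[Sequence[str]],
) -> pd.DataFrame:
    """Fit one model per variable subset; returns a comparison table."""
    rows = []
    for subset in subsets:
        model = fit_tuning_model(descriptors, counts, subset)
        rows.append(
            {
                "variables": "+".join(subset),
                "n_vars": len(subset),
                "pearson_r": model.pearson_r,
                "rmse": model.rmse,
            }
        )
    return pd.DataFrame(rows)
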