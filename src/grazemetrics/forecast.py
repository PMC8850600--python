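"""Forecasting intermediate average daily gain (iADG) by multiple linear
regression, and its evaluation by Pearson correlation and mean square error.

iADG (kg/day) is the body-weight gain per day over a 28-day experimental
period, from non-fasted start and end weights.  Predictors are the intake
frequency derived from classified behaviors plus genetic group (dummy-coded
against the Nellore-dry reference), day index, supplement level and the
forage covariates CP, NDF, ADF, forage mass, %Leaf and %Stem.  Fitting is
ordinary least squares through statsmodels; MSE uses the plain 1/n mean of
squared errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .behaviors import GENETIC_GROUPS, GENETIC_GROUP_REFERENCE

DEFAULT_PREDICTORS = (
    "intake_frequency",
    "supplement_level",
    "day",
    "cp_pct",
    "ndf_pct",
    "adf_pct",
    "forage_mass_kg_ha",
    "leaf_pct",
    "stem_pct",
)


@dataclass
class MLRModel:
    """Fitted OLS model with its design bookkeeping."""

    params: pd.Series
    bse: pd.Series
    predictors: tuple[str, ...]
    group_levels: tuple[str, ...]
    results: object  # statsmodels RegressionResults

    @property
    def intercept(self) -> float:
        return float(self.params["const"])


@dataclass
class ForecastEval:
    pearson_r: float
    mse: float
    scope: str = "overall"
    n: int = 0


def _design(
    records: pd.DataFrame,
    predictors: tuple[str, ...],
    group_levels: tuple[str, ...],
    include_group: bool,
) -> pd.DataFrame:
    missing = [p for p in predictors if p not in records.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {', '.join(missing)}")
    X = records[list(predictors)].astype(float)
    if include_group:
        unseen = set(records["genetic_group"]) - set(group_levels)
        if unseen:
            raise ValueError(
                f"unseen genetic_group level(s): {', '.join(sorted(unseen))}"
            )
        for level in group_levels:
            if level == GENETIC_GROUP_REFERENCE:
                continue
            X[f"group_{level}"] = (records["genetic_group"] == level).astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_mlr(
    records: pd.DataFrame,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    include_group: bool = True,
    response: str = "iadg_observed",
) -> MLRModel:
    """Ordinary least squares fit of iADG on the given predictors.

    Raises on constant predictors or rank deficiency, naming the offending
    columns.
    """
    group_levels = GENETIC_GROUPS if include_group else ()
    X = _design(records, predictors, group_levels, include_group)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows to fit {p - 1} predictors")
    constant = [
        c for c in X.columns if c != "const" and X[c].nunique(dropna=False) <= 1
    ]
    if constant:
        raise ValueError(f"constant predictor column(s): {', '.join(constant)}")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < p:
        # identify a minimal set of collinear columns by QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(p) if abs(r[i, i]) < 1e-8]
        raise ValueError(
            "rank-deficient design; collinear predictor(s): "
            + ", ".join(map(str, bad or X.columns))
        )
    results = sm.OLS(records[response].astype(float), X).fit()
    return MLRModel(
        params=results.params,
        bse=results.bse,
        predictors=predictors,
        group_levels=group_levels,
        results=results,
    )


def predict_iadg(model: MLRModel, records: pd.DataFrame) -> np.ndarray:
    """Evaluate the fitted linear predictor on new animal-period rows."""
    X = _design(
        records, model.predictors, model.group_levels, bool(model.group_levels)
    )
    return X.to_numpy() @ model.params.to_numpy()


def evaluate_forecast(
    observed,
    predicted,
    scope: str = "overall",
) -> ForecastEval:
    """Pearson r and MSE between observed and predicted iADG."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(observed) == 0:
        raise ValueError("observed iADG is constant; Pearson r is undefined")
    r = float(stats.pearsonr(observed, predicted).statistic)
    mse = float(np.mean((observed - predicted) ** 2))
    return ForecastEval(pearson_r=r, mse=mse, scope=scope, n=observed.size)


def evaluate_forecast_by_group(
    records: pd.DataFrame,
    observed_col: str = "iadg_observed",
    predicted_col: str = "iadg_predicted",
) -> dict[str, ForecastEval]:
    """Overall plus per-genetic-group forecast evaluation."""
    out = {
        "overall": evaluate_forecast(
            records[observed_col], records[predicted_col], scope="overall"
        )
    }
    for group, sub in records.groupby("genetic_group"):
        if len(sub) >= 3 and np.ptp(sub[observed_col].to_numpy()) > 0:
            out[str(group)] = evaluate_forecast(
                sub[observed_col], sub[predicted_col], scope=str(group)
            )
    return out


def summarize_iadg(values) -> tuple[float, float, float]:
    """(max, min, mean) of a non-empty iADG vector."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty vector")
    return float(values.max()), float(values.min()), float(values.mean())
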