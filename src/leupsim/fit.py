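"""Goodness-of-fit of ensemble model predictions to observed data.

For each observable ``j`` (speed, vorticity) measured at densities
``i = 1..N``:

    chi2_j = sum_i ((Ohat_i_j - O_i_j) / sigmahat_i_j) ** 2

where ``O`` are the observed values and ``Ohat``, ``sigmahat`` the mean
and standard deviation of the ensemble model predictions.  The reduced
statistic divides the summed chi2 by ``dof = (observables) * N`` with no
parameter-count correction; each standardized residual is a z-score.
Values near 1 indicate predictions consistent with the observations
given the ensemble spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

__all__ = [
    "ObservableTable",
    "ChiSquareResult",
    "chi_square",
    "build_prediction_table",
    "synthetic_observation_table",
]

TABLE_COLUMNS = ("density", "observable", "observed", "pred_mean", "pred_sd")


@dataclass
class ObservableTable:
    """Joined observed/predicted values, one row per (density, observable)."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in TABLE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observable table misses columns {missing}")
        if len(self.data) < 1:
            raise ValueError("observable table is empty")

    @property
    def observables(self) -> List[str]:
        return sorted(self.data["observable"].unique().tolist())


@dataclass
class ChiSquareResult:
    chi2_per_observable: Dict[str, float]
    dof: int
    reduced_chi2: float
    z_scores: pd.DataFrame = field(repr=False)

    def report(self) -> str:
        lines = ["chi-square goodness of fit", "-" * 30]
        for name, val in self.chi2_per_observable.items():
            lines.append(f"chi2[{name}] = {val:.4f}")
        lines.append(f"dof = {self.dof}")
        lines.append(f"reduced chi2 = {self.reduced_chi2:.4f}")
        return "\n".join(lines)


def chi_square(table: ObservableTable) -> ChiSquareResult:
    """Per-observable chi-square and the reduced statistic over all rows."""
    df = table.data.copy()
    bad = df.index[df["pred_sd"] <= 0]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            "non-positive prediction sd at density "
            f"{row['density']} observable {row['observable']}"
        )
    df["z"] = (df["pred_mean"] - df["observed"]) / df["pred_sd"]
    chi2 = {
        str(name): float((grp["z"] ** 2).sum())
        for name, grp in df.groupby("observable", sort=True)
    }
    dof = len(df)
    total = sum(chi2.values())
    return ChiSquareResult(
        chi2_per_observable=chi2,
        dof=dof,
        reduced_chi2=total / dof,
        z_scores=df[["density", "observable", "observed", "pred_mean", "pred_sd", "z"]],
    )


def build_prediction_table(
    predictions: pd.DataFrame,
    observations: pd.DataFrame,
    density_tol: float = 1e-6,
) -> ObservableTable:
    """Join ensemble predictions with an observation table on density.

    ``predictions`` needs columns (density, observable, pred_mean,
    pred_sd); ``observations`` needs (density, observable, value).
    Density grids are matched with absolute tolerance ``density_tol``;
    unmatched observation rows raise an error listing them.
    """
    rows = []
    unmatched = []
    for _, obs in observations.iterrows():
        cand = predictions[
            (predictions["observable"] == obs["observable"])
            & (np.abs(predictions["density"] - obs["density"]) <= density_tol)
        ]
        if len(cand) == 0:
            unmatched.append((float(obs["density"]), str(obs["observable"])))
            continue
        pred = cand.iloc[0]
        rows.append(
            {
                "density": float(obs["density"]),
                "observable": str(obs["observable"]),
                "observed": float(obs["value"]),
                "pred_mean": float(pred["pred_mean"]),
                "pred_sd": float(pred["pred_sd"]),
            }
        )
    if unmatched:
        raise ValueError(f"observation rows without matching predictions: {unmatched}")
    return ObservableTable(pd.DataFrame(rows))


def synthetic_observation_table(
    predictions: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Synthetic stand-in observations drawn from the model's own
    predictive distribution (``pred_mean + pred_sd * z``, z standard
    normal).

    A fit of the model against this table is self-consistent by
    construction, so its reduced chi-square concentrates near 1; the
    table has the same (density, observable) shape as the predictions.
    """
    z = rng.standard_normal(len(predictions))
    return pd.DataFrame(
        {
            "density": predictions["density"].to_numpy(),
            "observable": predictions["observable"].to_numpy(),
            "value": predictions["pred_mean"].to_numpy()
            + predictions["pred_sd"].to_numpy() * z,
        }
    )
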