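"""Linear risk-score application and concordance-index evaluation.

The shipped default model is the published five-covariate linear score with
its stratification threshold; the module applies the score and measures
discrimination — it does not fit anything.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_COVARIATES = ("AC106881.1", "PRRT3-AS1", "AC004148.2", "AP000844.2", "AL354710.2")
DEFAULT_COEFFICIENTS = (-0.56041, 0.81588, 1.234135, 0.511379, 0.297335)
DEFAULT_THRESHOLD = 0.8789252


@dataclass(frozen=True)
class RiskModel:
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    coefficients: tuple[float, ...] = DEFAULT_COEFFICIENTS
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.covariates) != len(self.coefficients):
            raise ValueError("coefficient count must equal covariate count")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariate names must be unique")

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            covariates=tuple(d["covariates"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            threshold=float(d["threshold"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "covariates": list(self.covariates),
                    "coefficients": list(self.coefficients),
                    "threshold": self.threshold,
                },
                indent=2,
            )
            + "\n"
        )


def risk_score(expr: pd.DataFrame, model: RiskModel | None = None) -> pd.DataFrame:
    """Apply the linear risk model to a covariates x samples matrix.

    score = sum_i coefficient_i * expression_i; stratum "high" iff
    score > threshold (a score exactly at the threshold is "low").
    """
    model = model or RiskModel()
    missing = [c for c in model.covariates if c not in expr.index]
    if missing:
        raise KeyError(f"missing covariate(s): {missing}")
    X = expr.loc[list(model.covariates)].to_numpy(dtype=float)
    scores = np.asarray(model.coefficients, dtype=float) @ X
    strata = np.where(scores > model.threshold, "high", "low")
    return pd.DataFrame({"score": scores, "stratum": strata}, index=expr.columns)


def concordance_index(scores: pd.Series, surv: pd.DataFrame) -> float:
    """Harrell's C over permissible pairs.

    A pair is permissible when the earlier time belongs to an event; the
    pair is concordant when the earlier-failing sample has the higher score;
    score ties count 0.5. No events is an error.
    """
    common = scores.index.intersection(surv.index)
    s = scores.reindex(common).to_numpy(dtype=float)
    t = surv.reindex(common)["time"].to_numpy(dtype=float)
    e = surv.reindex(common)["event"].to_numpy().astype(bool)
    if len(s) < 2 or not e.any():
        raise ValueError("need >= 2 samples and >= 1 event")

    num = 0.0
    den = 0
    for i in np.flatnonzero(e):
        permissible = t > t[i]
        den += int(permissible.sum())
        num += float((s[i] > s[permissible]).sum())
        num += 0.5 * float((s[i] == s[permissible]).sum())
    if den == 0:
        raise ValueError("no permissible pairs")
    return num / den
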