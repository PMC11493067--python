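"""Evaluation triple: MAPE, explained variance, and Gamma deviance.

Gamma deviance follows the summed (not averaged) form

    D_gamma(y, mu) = 2 * sum_i[ (y_i - mu_i)/mu_i - log(y_i / mu_i) ],

which is nonnegative and zero exactly at y = mu.  Explained variance uses
the population (1/n) variance convention via scikit-learn's
``explained_variance_score``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import explained_variance_score


class MetricDomainError(ValueError):
    """Inputs outside a metric's domain (zeros, nonpositive values...)."""


def _pair(observed, predicted):
    y = np.asarray(observed, dtype=float)
    mu = np.asarray(predicted, dtype=float)
    if y.shape != mu.shape:
        raise MetricDomainError(f"shape mismatch: {y.shape} vs {mu.shape}")
    if y.size == 0:
        raise MetricDomainError("empty input")
    return y, mu


def mape(observed, predicted) -> float:
    """Mean absolute percentage error, as a fraction of the observed values."""
    y, mu = _pair(observed, predicted)
    if np.any(y == 0):
        raise MetricDomainError("MAPE undefined: observed values contain zeros")
    return float(np.mean(np.abs(y - mu) / np.abs(y)))


def explained_variance(observed, predicted) -> float:
    """1 - Var(y - yhat) / Var(y); 1 means perfect prediction."""
    y, mu = _pair(observed, predicted)
    if y.size < 2 or np.var(y) == 0:
        raise MetricDomainError("explained variance undefined for constant/short y")
    return float(explained_variance_score(y, mu))


def gamma_deviance(observed, predicted) -> float:
    """Summed Gamma deviance; requires strictly positive y and mu."""
    y, mu = _pair(observed, predicted)
    if np.any(y <= 0) or np.any(mu <= 0):
        raise MetricDomainError("Gamma deviance requires strictly positive inputs")
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


@dataclass
class EvalReport:
    """Evaluation metrics for one model on one test partition."""

    model_id: str
    mape: float
    evar: float
    gamma_deviance: float
    n_cases: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_predictions(observed, predicted, model_id: str) -> EvalReport:
    """All three metrics on identical cases."""
    y, mu = _pair(observed, predicted)
    return EvalReport(
        model_id=model_id,
        mape=mape(y, mu),
        evar=explained_variance(y, mu),
        gamma_deviance=gamma_deviance(y, mu),
        n_cases=int(y.size),
    )


def comparison_table(primary: EvalReport, benchmarks: list[EvalReport]) -> str:
    """Side-by-side metric table with each benchmark as a % of the primary."""
    lines = ["model\tMAPE (% of primary)\tEVar (% of primary)\tD_gamma (% of primary)"]

    def pct(v, ref):
        return f"{v:.4g} ({100.0 * v / ref:.1f}%)" if ref != 0 else f"{v:.4g} (n/a)"

    for rep in benchmarks:
        lines.append(
            f"{rep.model_id}\t{pct(rep.mape, primary.mape)}\t"
            f"{pct(rep.evar, primary.evar)}\t"
            f"{pct(rep.gamma_deviance, primary.gamma_deviance)}"
        )
    lines.append(
        f"{primary.model_id}\t{primary.mape:.4g}\t{primary.evar:.4g}\t"
        f"{primary.gamma_deviance:.4g}"
    )
    return "\n".join(lines)
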