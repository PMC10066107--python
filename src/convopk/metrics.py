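"""Model-comparison statistics: AIC, BIC and percent prediction error.

Conventions: lower AIC/BIC is better; the parameter count ``k`` includes
every estimated quantity (structural thetas plus variance terms sigma and
any omegas).  Percent prediction error is 100*(obs - pred)/obs, so
under-prediction is positive; records with obs = 0 are excluded and the
exclusion count reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["aic", "bic", "percent_pe", "PercentPE", "ComparisonReport", "compare"]


def aic(neg2_loglik: float, k: int) -> float:
    """Akaike information criterion: -2LL + 2k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(neg2_loglik + 2.0 * k)


def bic(neg2_loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion: -2LL + k*ln(n)."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    return float(neg2_loglik + k * np.log(n))


@dataclass(frozen=True)
class PercentPE:
    """Per-point %PE with its mean and 95% confidence interval."""

    per_point: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_used: int
    n_excluded: int


def percent_pe(
    obs,
    pred,
    *,
    ci: str = "normal",
    n_boot: int = 2000,
    seed: int = 0,
) -> PercentPE:
    """Percent prediction error 100*(obs - pred)/obs with a 95% CI of the mean.

    ``ci='normal'`` gives mean +/- 1.96*SE; ``ci='bootstrap'`` a percentile
    bootstrap (seeded).  Zero observations are excluded with their count
    reported.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have matching shapes")
    keep = obs != 0
    n_excluded = int((~keep).sum())
    obs, pred = obs[keep], pred[keep]
    if obs.size == 0:
        raise ValueError("all observations are zero; %PE undefined")
    pe = 100.0 * (obs - pred) / obs
    mean = float(np.mean(pe))
    if ci == "normal":
        se = float(np.std(pe, ddof=1) / np.sqrt(len(pe))) if len(pe) > 1 else 0.0
        lo, hi = mean - 1.96 * se, mean + 1.96 * se
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(pe), size=(n_boot, len(pe)))
        means = pe[idx].mean(axis=1)
        lo, hi = (float(q) for q in np.percentile(means, [2.5, 97.5]))
    else:
        raise ValueError("ci must be 'normal' or 'bootstrap'")
    return PercentPE(pe, mean, float(lo), float(hi), int(len(pe)), n_excluded)


@dataclass
class ComparisonReport:
    """Side-by-side AIC/BIC/%PE table for two or more fitted models."""

    table: pd.DataFrame  # one row per model
    ranking: list[str]  # model names, best (lowest AIC) first

    def to_markdown(self) -> str:
        return self.table.to_markdown(index=False, floatfmt=".3f")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare(fit_results, *, ci: str = "normal", seed: int = 0) -> ComparisonReport:
    """Build a comparison report from >= 2 fit results.

    Accepts :class:`convopk.estimators.FitResult` objects (or anything with
    ``model``, ``neg2_loglik``, ``n_params``, ``n_obs``, ``predictions``,
    ``observations`` attributes).
    """
    fit_results = list(fit_results)
    if len(fit_results) < 2:
        raise ValueError("compare requires at least two fit results")
    rows = []
    for fr in fit_results:
        pe = percent_pe(fr.observations, fr.predictions, ci=ci, seed=seed)
        rows.append(
            {
                "model": fr.model,
                "AIC": aic(fr.neg2_loglik, fr.n_params),
                "BIC": bic(fr.neg2_loglik, fr.n_params, fr.n_obs),
                "mean_PE_percent": pe.mean,
                "PE_CI95_low": pe.ci_low,
                "PE_CI95_high": pe.ci_high,
                "n": fr.n_obs,
                "k": fr.n_params,
            }
        )
    table = pd.DataFrame(rows)
    ranking = list(table.sort_values("AIC")["model"])
    return ComparisonReport(table=table, ranking=ranking)
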