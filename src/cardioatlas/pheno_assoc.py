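"""Observational phenotype analyses.

Pearson correlations of PC scores with continuous traits, stepwise (AIC,
bidirectional) covariate selection for each binary outcome, and logistic
regressions giving the odds ratio per SD of PC score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class AssociationRecord:
    pc: str
    outcome: str
    odds_ratio: float
    ci95: tuple
    p_value: float
    n_cases: int
    covariates_used: list = field(default_factory=list)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must share length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _fit_logit(y: np.ndarray, x: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, x).fit(disp=False, maxiter=200)


def stepwise_covariates(
    outcome: np.ndarray,
    candidates: pd.DataFrame,
    max_steps: int = 50,
) -> list[str]:
    """Bidirectional stepwise logistic selection by AIC.

    Starts from the intercept-only model; at each step tries adding every
    unused candidate and dropping every included one, taking the single
    move with the best AIC improvement. Deterministic given column order
    (ties broken by order; an exact duplicate of an included column never
    improves AIC, so only the first of a collinear pair enters).
    Candidates whose fit fails (separation, non-convergence) are dropped
    with a warning.
    """
    y = np.asarray(outcome, dtype=float)
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate covariate")
    names = list(candidates.columns)

    def aic_of(sel: list[str]) -> float:
        x = sm.add_constant(candidates[sel].to_numpy(), has_constant="add")
        res = _fit_logit(y, x)
        if not np.all(np.isfinite(res.params)):
            raise ValueError("non-finite fit")
        return float(res.aic)

    selected: list[str] = []
    current = aic_of(selected)
    bad: set[str] = set()
    for _ in range(max_steps):
        best_move, best_aic = None, current
        for name in names:
            if name in selected or name in bad:
                continue
            try:
                a = aic_of(selected + [name])
            except Exception:
                warnings.warn(f"dropping candidate {name}: fit failed", stacklevel=2)
                bad.add(name)
                continue
            if a < best_aic - 1e-9:
                best_move, best_aic = ("add", name), a
        for name in selected:
            a = aic_of([s for s in selected if s != name])
            if a < best_aic - 1e-9:
                best_move, best_aic = ("drop", name), a
        if best_move is None:
            break
        kind, name = best_move
        if kind == "add":
            selected.append(name)
        else:
            selected.remove(name)
        current = best_aic
    return selected


def logistic_odds_ratio(
    score: np.ndarray,
    outcome: np.ndarray,
    covars: pd.DataFrame | None = None,
    pc: str = "PC",
    outcome_name: str = "outcome",
) -> AssociationRecord:
    """Odds ratio per SD of score from maximum-likelihood logistic fit.

    The score is standardized internally; CI is Wald on the log-odds scale.
    Perfect separation raises with the offending column named.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n_cases = int(y.sum())
    if n_cases < 10:
        raise ValueError("need at least 10 cases")
    zs = (score - score.mean()) / score.std()
    cols = [zs]
    names = ["score"]
    if covars is not None and covars.shape[1] > 0:
        cols.extend(covars[c].to_numpy(dtype=float) for c in covars.columns)
        names.extend(covars.columns)
    x = sm.add_constant(np.column_stack(cols), has_constant="add")
    try:
        res = _fit_logit(y, x)
    except Exception as exc:  # statsmodels PerfectSeparationError or LinAlg
        raise ValueError(f"logistic fit failed (separation?); columns: {names}") from exc
    if not np.all(np.isfinite(res.bse)):
        bad = [names[i - 1] for i in range(1, len(res.bse)) if not np.isfinite(res.bse[i])]
        raise ValueError(f"perfect separation involving column(s): {bad}")
    b, se = res.params[1], res.bse[1]
    orr = float(np.exp(b))
    ci = (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)))
    p = float(2 * stats.norm.sf(abs(b) / se))
    return AssociationRecord(pc, outcome_name, orr, ci, p, n_cases, names[1:])


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
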