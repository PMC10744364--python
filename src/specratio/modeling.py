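"""Stepwise multiple logistic regression for diagnosis (patient vs control).

Forward entry by likelihood-ratio test (enter the best candidate with
p < 0.05), backward elimination by Wald test (remove any included variable
with p > 0.1), iterated to stability. Continuous predictors are
standardized internally for numerical stability and the fitted
coefficients are reported on the original scale. Complete or
quasi-complete separation is detected and flagged rather than reported as
a diverged fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "SeparationError",
    "LogisticFit",
    "LogisticModelReport",
    "logistic_fit",
    "stepwise_select",
    "classification_accuracy",
]

_Z95 = 1.959963984540054


class SeparationError(RuntimeError):
    """The outcome is (quasi-)completely separated by the predictors."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit on the original predictor scale."""

    params: pd.Series  # includes 'const'
    cov: pd.DataFrame
    llf: float
    n: int

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def predict(self, design: pd.DataFrame) -> np.ndarray:
        X = sm.add_constant(design[self.params.index.drop("const")], has_constant="add")
        lin = X.to_numpy() @ self.params.reindex(X.columns).to_numpy()
        return 1.0 / (1.0 + np.exp(-lin))


@dataclass
class LogisticModelReport:
    """Selected-model summary: per-variable Wald statistics and odds ratios."""

    selected: list[str]
    table: pd.DataFrame  # rows: variables; cols: coef, se, wald, or, or_lo, or_hi
    accuracy: float  # percent correctly classified at probability 0.5
    n: int
    fit: LogisticFit | None = None
    note: str = ""


def _standardize(design: pd.DataFrame):
    """Z-scale non-degenerate continuous columns; binary 0/1 columns pass
    through. Returns (scaled design, centers, scales)."""
    centers, scales = {}, {}
    out = {}
    for col in design.columns:
        x = design[col].astype(float)
        vals = np.unique(x.dropna())
        if set(vals) <= {0.0, 1.0} or x.std(ddof=0) == 0:
            centers[col], scales[col] = 0.0, 1.0
            out[col] = x
        else:
            centers[col], scales[col] = float(x.mean()), float(x.std(ddof=0))
            out[col] = (x - centers[col]) / scales[col]
    return pd.DataFrame(out, index=design.index), centers, scales


def logistic_fit(design: pd.DataFrame, outcome, maxiter: int = 100,
                 tol: float = 1e-8) -> LogisticFit:
    """Fit a logistic regression by Newton-type maximum likelihood.

    ``design`` holds the predictors (no constant column — it is added
    here); ``outcome`` is binary 0/1. Raises :class:`SeparationError` on
    complete or quasi-complete separation.
    """
    y = np.asarray(outcome, dtype=float)
    if design.shape[0] != y.size:
        raise ValueError("design and outcome lengths differ")
    if design.shape[1] and (design.nunique() <= 1).any():
        bad = design.columns[(design.nunique() <= 1)].tolist()
        raise ValueError(f"constant predictor column(s): {bad}")
    if y.size <= design.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    scaled, centers, scales = _standardize(design)
    X = sm.add_constant(scaled, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        # near-separated candidate fits overflow benignly before the
        # explicit separation check below
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=maxiter, tol=tol, disp=False
            )
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix (possible separation): {exc}"
            ) from exc
    if design.shape[1] and np.abs(res.params.drop("const")).max() > 30:
        # slopes this large on a z-scaled predictor mean the likelihood is
        # drifting to a separating hyperplane
        raise SeparationError(
            "diverging coefficients on the standardized scale; "
            "outcome is (quasi-)separated"
        )
    # back-transform to the original predictor scale
    names = list(X.columns)
    s = np.array([1.0] + [scales[c] for c in design.columns])
    c = np.array([0.0] + [centers[c] for c in design.columns])
    T = np.diag(1.0 / s)
    T[1:, 0] = 0.0
    T[0, 1:] = -(c[1:] / s[1:])
    params = T @ res.params.to_numpy()
    cov = T @ np.asarray(res.cov_params()) @ T.T
    return LogisticFit(
        params=pd.Series(params, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        llf=float(res.llf),
        n=int(y.size),
    )


def _wald_pvalues(fit: LogisticFit) -> pd.Series:
    z2 = (fit.params / fit.se) ** 2
    return pd.Series(sstats.chi2.sf(z2, df=1), index=fit.params.index)


def classification_accuracy(fit: LogisticFit, design: pd.DataFrame, outcome
                            ) -> float:
    """Percent of subjects whose 0.5-thresholded predicted probability
    matches the outcome (on the fitting sample)."""
    y = np.asarray(outcome, dtype=float)
    pred = (fit.predict(design) >= 0.5).astype(float)
    return 100.0 * float(np.mean(pred == y))


def _report_from_fit(fit: LogisticFit, selected, design, outcome, note=""
                     ) -> LogisticModelReport:
    rows = []
    for var in selected:
        coef = fit.params[var]
        se = fit.se[var]
        wald = (coef / se) ** 2
        rows.append(
            {
                "variable": var,
                "wald": wald,
                "coef": coef,
                "se": se,
                "or": math.exp(coef),
                "or_lo": math.exp(coef - _Z95 * se),
                "or_hi": math.exp(coef + _Z95 * se),
                "p": float(sstats.chi2.sf(wald, df=1)),
            }
        )
    table = pd.DataFrame(rows).set_index("variable") if rows else pd.DataFrame()
    acc = classification_accuracy(fit, design, outcome)
    return LogisticModelReport(
        selected=list(selected), table=table, accuracy=acc, n=fit.n,
        fit=fit, note=note,
    )


def stepwise_select(candidates: pd.DataFrame, outcome, p_enter: float = 0.05,
                    p_remove: float = 0.10) -> LogisticModelReport:
    """Stepwise logistic regression over candidate predictors.

    Forward step: fit each excluded candidate on top of the current model
    and enter the one with the smallest likelihood-ratio p-value if it is
    below ``p_enter``. Backward step: remove, one at a time, the included
    variable with the largest Wald p-value above ``p_remove``. Iterate to
    stability (deterministic given the data; ties resolved by column
    order). Candidates that separate the outcome are skipped with a note.
    """
    if candidates.shape[1] == 0:
        raise ValueError("candidate set is empty")
    y = np.asarray(outcome, dtype=float)
    selected: list[str] = []
    notes: list[str] = []
    null_fit = logistic_fit(candidates[[]], y)
    current = null_fit

    def fit_subset(cols):
        return logistic_fit(candidates[list(cols)], y)

    for _ in range(2 * candidates.shape[1] + 1):
        changed = False
        # forward entry by LR test
        best = None
        for var in candidates.columns:
            if var in selected:
                continue
            try:
                cand_fit = fit_subset(selected + [var])
            except SeparationError:
                notes.append(f"{var}: separation, skipped")
                continue
            lr = 2 * (cand_fit.llf - current.llf)
            p = float(sstats.chi2.sf(max(lr, 0.0), df=1))
            if p < p_enter and (best is None or p < best[0]):
                best = (p, var, cand_fit)
        if best is not None:
            selected.append(best[1])
            current = best[2]
            changed = True
        # backward removal by Wald test
        while selected:
            pw = _wald_pvalues(current).drop("const")
            worst = pw.idxmax()
            if pw[worst] > p_remove:
                selected.remove(worst)
                current = fit_subset(selected)
                changed = True
            else:
                break
        if not changed:
            break
    note = "; ".join(dict.fromkeys(notes))
    if not selected:
        note = ("no variable met the entry criterion; intercept-only model. "
                + note).strip("; ")
        return _report_from_fit(null_fit, [], candidates[[]], y, note)
    return _report_from_fit(current, selected, candidates[selected], y, note)
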