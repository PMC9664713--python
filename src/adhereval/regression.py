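"""Adjusted logistic regression of detectable viral load on non-adherence.

Each adherence measure is fitted in its own model (one model per
measure x cut-off cell): detectable viral load on a non-adherence indicator
at the cut-off, adjusted for sex (male vs female) and regimen class (TLE,
the tenofovir--lamivudine--efavirenz combination, vs any other regimen).
Reference levels are female and non-TLE.  Inference is Wald: standard
errors from the observed information, symmetric 95% confidence intervals on
the log-odds scale exponentiated to odds ratios, two-sided normal p-values.

Quasi-complete separation (a cell of the 2x2 with zero count, as happens for
highly specific measures at high cut-offs) is *flagged*, never silently
penalized: estimates are reported as-is with ``separation=True``.  An
optional Firth (Jeffreys-prior penalized) fit is available but off by
default, since penalization changes the estimand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .classify import CutoffGrid, DEFAULT_CUTOFFS, add_composites, measure_column

__all__ = ["LogisticFit", "encode_design", "fit_logistic", "regression_sweep"]

logger = logging.getLogger(__name__)

TERMS = ("const", "nonadherent", "male", "tle")

_SEPARATION_PROB_TOL = 1e-6
_SEPARATION_COEF = 8.0  # |log-odds| beyond which a boundary fit is diverging


@dataclass
class LogisticFit:
    """Wald summary of one logistic model.

    ``table`` has one row per term: coefficient, standard error, odds ratio,
    95% CI bounds and two-sided p-value.  ``separation`` marks (quasi-)
    complete separation; the estimates are then boundary-diverging and their
    Wald intervals unreliable.
    """

    table: pd.DataFrame
    converged: bool
    separation: bool
    n_obs: int
    measure: str | None = None
    cutoff: float | None = None

    def __post_init__(self) -> None:
        t = self.table
        assert np.allclose(t["odds_ratio"], np.exp(t["coef"]), equal_nan=True)

    @property
    def params(self) -> pd.Series:
        return self.table.set_index("term")["coef"]


def encode_design(
    panel: pd.DataFrame, measure: str, cutoff: float
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Design matrix (const, nonadherent, male, tle) and outcome vector.

    Rows with the measure missing are dropped; the dropped count is returned
    and logged.
    """
    if not (0.0 < cutoff <= 100.0):
        raise ValueError(f"cutoff {cutoff!r} outside (0, 100]")
    panel = add_composites(panel)
    col = measure_column(measure)
    keep = panel[col].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropping %d participants missing %s for regression", n_dropped, measure
        )
    sub = panel.loc[keep]
    if sub.empty:
        raise ValueError(f"measure {measure!r} is absent for all participants")
    X = pd.DataFrame(
        {
            "const": 1.0,
            "nonadherent": (sub[col] < cutoff).astype(float),
            "male": (sub["sex"] == "male").astype(float),
            "tle": (sub["regimen_class"] == "TLE").astype(float),
        },
        index=sub.index,
    )
    y = sub["vl_detectable"].astype(float)
    return X, y, n_dropped


def fit_logistic(
    X: pd.DataFrame,
    y: pd.Series,
    firth: bool = False,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference.

    Newton/IRLS to gradient tolerance ``tol``; with ``firth=True`` a
    Jeffreys-prior penalized fit (useful under separation) replaces plain ML.
    """
    y_arr = np.asarray(y, dtype=float)
    X_arr = np.asarray(X, dtype=float)
    if y_arr.min() == y_arr.max():
        raise ValueError("outcome has a single class; need at least one case and one control")
    for j, name in enumerate(X.columns):
        if name != "const" and X_arr[:, j].min() == X_arr[:, j].max():
            raise ValueError(f"predictor {name!r} is constant")

    if firth:
        params, se, converged = _fit_firth(X_arr, y_arr, maxiter=maxiter, tol=tol)
        fitted = _expit(X_arr @ params)
    else:
        model = sm.Logit(y_arr, X_arr)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            # boundary likelihood: refit with a gradient method and flag below
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(method="bfgs", maxiter=10 * maxiter, disp=0)
        params = np.asarray(res.params, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            se = np.asarray(res.bse, dtype=float)
        converged = bool(res.mle_retvals.get("converged", True))
        fitted = _expit(X_arr @ params)

    boundary = (fitted < _SEPARATION_PROB_TOL) | (fitted > 1.0 - _SEPARATION_PROB_TOL)
    separation = bool(boundary.any() and np.abs(params).max() > _SEPARATION_COEF)
    if separation:
        warnings.warn(
            "quasi-complete separation detected; estimates are boundary-"
            "diverging and Wald intervals unreliable",
            stacklevel=2,
        )
    elif not converged:
        raise RuntimeError(
            "logistic fit did not converge and no separation was detected; "
            f"max |coef|={np.abs(params).max():.3g}"
        )

    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        table = pd.DataFrame(
            {
                "term": list(X.columns),
                "coef": params,
                "se": se,
                "odds_ratio": np.exp(params),
                "ci_low": np.exp(params - z * se),
                "ci_high": np.exp(params + z * se),
                "p": 2.0 * stats.norm.sf(np.abs(params / se)),
            }
        )
    return LogisticFit(
        table=table,
        converged=converged,
        separation=separation,
        n_obs=len(y_arr),
    )


def _expit(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _fit_firth(
    X: np.ndarray, y: np.ndarray, maxiter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Firth penalized-likelihood logistic regression via modified IRLS.

    The score is augmented with the Jeffreys-prior term
    ``X' (h * (1/2 - p))`` where h are hat-matrix diagonals; keeps estimates
    finite under separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(maxiter):
        p = _expit(X @ beta)
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.abs(score).max() < tol:
            converged = True
            break
    p = _expit(X @ beta)
    w = p * (1.0 - p)
    se = np.sqrt(np.diag(np.linalg.pinv(X.T @ (X * w[:, None]))))
    return beta, se, converged


def regression_sweep(
    panel: pd.DataFrame,
    measures: Sequence[str],
    grid: CutoffGrid | Sequence[float] = DEFAULT_CUTOFFS,
    firth: bool = False,
) -> pd.DataFrame:
    """One adjusted fit per (measure, cutoff) cell; failures recorded, not raised.

    Returns a long table (measure, cutoff, term, coef, se, odds_ratio,
    ci_low, ci_high, p, separation, converged, error); a cell whose fit
    fails contributes a single row with the error message and NaN estimates.
    """
    grid = grid if isinstance(grid, CutoffGrid) else CutoffGrid(tuple(grid))
    rows = []
    for measure in measures:
        for cutoff in grid:
            try:
                X, y, _ = encode_design(panel, measure, cutoff)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_logistic(X, y, firth=firth)
            except (ValueError, RuntimeError) as exc:
                logger.warning("fit failed for %s at %s%%: %s", measure, cutoff, exc)
                rows.append(
                    {
                        "measure": measure, "cutoff": cutoff, "term": None,
                        "coef": np.nan, "se": np.nan, "odds_ratio": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                        "separation": False, "converged": False, "error": str(exc),
                    }
                )
                continue
            for _, term_row in fit.table.iterrows():
                rows.append(
                    {
                        "measure": measure,
                        "cutoff": cutoff,
                        **term_row.to_dict(),
                        "separation": fit.separation,
                        "converged": fit.converged,
                        "error": "",
                    }
                )
    return pd.DataFrame(rows)
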