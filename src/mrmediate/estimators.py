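"""Regression and instrumental-variable primitives.

OLS and two-stage least squares (univariable and multivariable) are
implemented directly on the normal equations — the Monte-Carlo layers fit
hundreds of thousands of small regressions, so the hot path stays in
numpy/scipy linear algebra.  Logistic fits (for log odds ratio scales)
delegate to statsmodels.  2SLS standard errors use the conventional IV
variance: residuals are computed with the OBSERVED exposures at the
second-stage estimates.

Instrument-strength diagnostics: the joint first-stage F-statistic and the
Sanderson-Windmeijer conditional F-statistic for multivariable MR, with the
conventional weak-instrument flag at F < 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .dgp import IndividualDataset

__all__ = [
    "FitResult",
    "InstrumentDiagnostics",
    "DegenerateFitError",
    "UnderIdentifiedError",
    "ols",
    "tsls",
    "logistic_fit",
    "logistic_second_stage",
    "first_stage_F",
    "conditional_F_sw",
]

WEAK_F_THRESHOLD = 10.0


class DegenerateFitError(ValueError):
    """Design matrix rank-deficient, outcome degenerate, or fit non-convergent."""


class UnderIdentifiedError(ValueError):
    """Fewer instruments than instrumented exposures."""


@dataclass
class InstrumentDiagnostics:
    f_stats: dict[str, float] = field(default_factory=dict)
    conditional_f: dict[str, float] = field(default_factory=dict)
    threshold: float = WEAK_F_THRESHOLD

    @property
    def weak(self) -> bool:
        relevant = list(self.conditional_f.values()) or list(self.f_stats.values())
        return any(f < self.threshold for f in relevant)


@dataclass
class FitResult:
    params: dict[str, float]
    bse: dict[str, float]
    nobs: int
    df_resid: int
    sigma2: float
    method: str  # ols / tsls / mv-tsls / logistic / logistic-second-stage
    scale: str  # linear / risk-difference / log-odds
    cov: np.ndarray | None = None
    names: list[str] | None = None
    diagnostics: InstrumentDiagnostics | None = None
    degenerate: bool = False


def _columns(data, names) -> np.ndarray:
    if isinstance(data, IndividualDataset):
        return data.array(list(names))
    return data[list(names)].to_numpy(dtype=float)


def _design(mat: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(mat.shape[0]), mat])


def _solve_ols(xmat: np.ndarray, y: np.ndarray):
    """Least-squares solve with an explicit rank check; returns (beta, xtx_inv)."""
    gram = xmat.T @ xmat
    if np.linalg.matrix_rank(gram, hermitian=True) < gram.shape[0]:
        raise DegenerateFitError("rank-deficient design matrix")
    try:
        cf = scipy.linalg.cho_factor(gram)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateFitError("rank-deficient design matrix") from exc
    beta = scipy.linalg.cho_solve(cf, xmat.T @ y)
    xtx_inv = scipy.linalg.cho_solve(cf, np.eye(gram.shape[0]))
    return beta, xtx_inv


def _package(names, beta, cov, n, df, sigma2, method, scale, diagnostics=None):
    se = np.sqrt(np.diag(cov))
    return FitResult(
        params=dict(zip(names, beta.tolist())),
        bse=dict(zip(names, se.tolist())),
        nobs=n,
        df_resid=df,
        sigma2=float(sigma2),
        method=method,
        scale=scale,
        cov=cov,
        names=list(names),
        diagnostics=diagnostics,
    )


def ols(data, outcome: str, regressors: list[str], robust: bool = False) -> FitResult:
    """OLS of ``outcome`` on ``regressors`` plus intercept.

    Homoskedastic SEs by default, HC0 sandwich with ``robust=True``.
    """
    y = _columns(data, [outcome]).ravel()
    xmat = _design(_columns(data, regressors))
    n, k = xmat.shape
    beta, xtx_inv = _solve_ols(xmat, y)
    resid = y - xmat @ beta
    df = n - k
    sigma2 = resid @ resid / df
    if robust:
        meat = (xmat * resid[:, None] ** 2).T @ xmat
        cov = xtx_inv @ meat @ xtx_inv
    else:
        cov = sigma2 * xtx_inv
    scale = "risk-difference" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    return _package(["const"] + list(regressors), beta, cov, n, df, sigma2, "ols", scale)


def _first_stage(data, exposures, instruments):
    """Regress each exposure on all instruments jointly; return predicted values."""
    zmat = _design(_columns(data, instruments))
    wmat = _columns(data, exposures)
    bz, _ = _solve_ols(zmat, wmat)
    return zmat @ bz, wmat


def tsls(
    data,
    outcome: str,
    exposures: list[str],
    instruments: list[str],
    robust: bool = False,
    diagnostics: bool = True,
) -> FitResult:
    """Two-stage least squares, univariable or multivariable.

    Stage 1 regresses every exposure on ALL instruments jointly; stage 2
    regresses the outcome on the predicted exposures.  The variance uses
    residuals from the observed exposures at the second-stage estimates.
    """
    if len(instruments) < len(exposures):
        raise UnderIdentifiedError(
            f"{len(exposures)} instrumented exposures but only "
            f"{len(instruments)} instruments"
        )
    y = _columns(data, [outcome]).ravel()
    what, wobs = _first_stage(data, exposures, instruments)
    xhat = _design(what)
    n, k = xhat.shape
    beta, xtx_inv = _solve_ols(xhat, y)
    resid = y - _design(wobs) @ beta
    df = n - k
    sigma2 = resid @ resid / df
    if robust:
        meat = (xhat * resid[:, None] ** 2).T @ xhat
        cov = xtx_inv @ meat @ xtx_inv
    else:
        cov = sigma2 * xtx_inv
    diag = None
    if diagnostics:
        diag = InstrumentDiagnostics(
            f_stats={e: first_stage_F(data, e, instruments) for e in exposures}
        )
        if len(exposures) >= 2:
            diag.conditional_f = {
                e: conditional_F_sw(data, exposures, instruments, e) for e in exposures
            }
    method = "mv-tsls" if len(exposures) > 1 else "tsls"
    scale = "risk-difference" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    return _package(["const"] + list(exposures), beta, cov, n, df, sigma2, method, scale, diag)


def logistic_fit(data, outcome: str, regressors: list[str]) -> FitResult:
    """Maximum-likelihood logistic regression; coefficients on the log-odds scale."""
    y = _columns(data, [outcome]).ravel()
    if len(np.unique(y)) < 2:
        raise DegenerateFitError("binary outcome has no variation")
    xmat = _design(_columns(data, regressors))
    if np.linalg.matrix_rank(xmat.T @ xmat, hermitian=True) < xmat.shape[1]:
        raise DegenerateFitError("rank-deficient design matrix")
    try:
        with warnings.catch_warnings():
            # statsmodels downgraded perfect separation to a warning; treat it
            # as the degenerate fit it is
            warnings.filterwarnings("error", category=PerfectSeparationWarning)
            res = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparation{Error,Warning} and friends
        raise DegenerateFitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise DegenerateFitError("logistic fit did not converge")
    names = ["const"] + list(regressors)
    return FitResult(
        params=dict(zip(names, res.params.tolist())),
        bse=dict(zip(names, res.bse.tolist())),
        nobs=int(res.nobs),
        df_resid=int(res.df_resid),
        sigma2=float("nan"),
        method="logistic",
        scale="log-odds",
        cov=np.asarray(res.cov_params()),
        names=names,
    )


def logistic_second_stage(
    data, outcome: str, exposures: list[str], instruments: list[str]
) -> FitResult:
    """IV logistic regression by predictor substitution.

    First-stage linear predictions of the exposures are substituted into a
    logistic model for the binary outcome (two-stage predictor substitution).
    Reported SEs are the naive second-stage ML SEs; use the bootstrap for
    inference.
    """
    if len(instruments) < len(exposures):
        raise UnderIdentifiedError(
            f"{len(exposures)} instrumented exposures but only "
            f"{len(instruments)} instruments"
        )
    what, _ = _first_stage(data, exposures, instruments)
    df = pd.DataFrame(what, columns=[f"{e}_hat" for e in exposures])
    df[outcome] = _columns(data, [outcome]).ravel()
    res = logistic_fit(df, outcome, [f"{e}_hat" for e in exposures])
    names = ["const"] + list(exposures)
    return FitResult(
        params=dict(zip(names, [res.params["const"]] + [res.params[f"{e}_hat"] for e in exposures])),
        bse=dict(zip(names, [res.bse["const"]] + [res.bse[f"{e}_hat"] for e in exposures])),
        nobs=res.nobs,
        df_resid=res.df_resid,
        sigma2=float("nan"),
        method="logistic-second-stage",
        scale="log-odds",
        cov=res.cov,
        names=names,
    )


def first_stage_F(data, exposure: str, instruments: list[str]) -> float:
    """Joint F-statistic for the instruments in the first-stage regression."""
    x = _columns(data, [exposure]).ravel()
    zmat = _design(_columns(data, instruments))
    n, kz1 = zmat.shape
    q = kz1 - 1
    if n <= q + 1:
        raise ValueError("need n > #instruments + 1 for the first-stage F")
    beta, _ = _solve_ols(zmat, x)
    resid = x - zmat @ beta
    rss = resid @ resid
    tss = np.sum((x - x.mean()) ** 2)
    df_den = n - q - 1
    return float(((tss - rss) / q) / (rss / df_den))


def conditional_F_sw(
    data, exposures: list[str], instruments: list[str], target: str
) -> float:
    """Sanderson-Windmeijer conditional F-statistic for ``target``.

    Strength of the instruments for one exposure conditional on the others:
    the target exposure is regressed on the other exposures by 2SLS using
    the instruments, and the F-statistic of the instruments is computed on
    those residuals with degrees of freedom adjusted for the exposures
    partialled out (numerator df = #instruments - #other exposures,
    denominator df = n - #instruments - #other exposures).
    """
    if len(exposures) < 2:
        raise ValueError("conditional F requires at least two instrumented exposures")
    if target not in exposures:
        raise ValueError(f"target {target!r} is not among the exposures")
    if len(instruments) < len(exposures):
        raise UnderIdentifiedError(
            f"{len(exposures)} instrumented exposures but only "
            f"{len(instruments)} instruments"
        )
    others = [e for e in exposures if e != target]
    x1 = _columns(data, [target]).ravel()
    fit = tsls(data, target, others, instruments, diagnostics=False)
    beta = np.array([fit.params["const"]] + [fit.params[o] for o in others])
    resid = x1 - _design(_columns(data, others)) @ beta

    zmat = _design(_columns(data, instruments))
    n, kz1 = zmat.shape
    q_num = (kz1 - 1) - len(others)
    df_den = n - (kz1 - 1) - len(others)
    if q_num <= 0 or df_den <= 0:
        raise UnderIdentifiedError("not enough instruments for a conditional F")
    bz, _ = _solve_ols(zmat, resid)
    rz = resid - zmat @ bz
    rss = rz @ rz
    tss = np.sum((resid - resid.mean()) ** 2)
    return float(((tss - rss) / q_num) / (rss / df_den))
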