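"""Effect decomposition: total, direct and indirect effects of an exposure.

Four decomposition methods are provided, two non-IV and two instrumental:

* ``noniv_difference`` — total from Y~X, direct from Y~X+M; indirect is the
  difference of coefficients.
* ``noniv_product`` — a from M~X, b from Y~M+X; indirect is the product a*b.
* ``mvmr_mediation`` — total from univariable 2SLS of Y on X, direct from
  multivariable 2SLS of Y on X and the mediator(s); indirect by difference.
* ``twostep_mr`` — A from univariable 2SLS of M on X, B from the
  multivariable second stage of Y on X and M jointly (which also yields the
  direct effect); indirect is the product A*B.

Scales: ``linear`` (continuous outcomes), ``rd`` (risk difference — the
binary outcome treated numerically), ``logor`` (logistic / two-stage
predictor substitution), and ``or`` (log-odds decomposition exponentiated,
flagged as known-biased by non-collapsibility).  Total and direct effects
within one result are always computed on the same scale.

Also here: the proportion mediated with its small-total-effect guard rails,
nonparametric bootstrap confidence intervals, multiple-mediator analysis
(joint MVMR vs summed per-mediator two-step), and instrument-overlap
validation.
"""

from __future__ import annotations

import inspect
import math
from dataclasses import dataclass, field

import numpy as np

from .dgp import OUTCOME_BINARY, OUTCOME_CONTINUOUS, IndividualDataset
from .estimators import (
    InstrumentDiagnostics,
    UnderIdentifiedError,
    logistic_fit,
    logistic_second_stage,
    ols,
    tsls,
)

__all__ = [
    "MediationResult",
    "OverlapReport",
    "BootstrapResult",
    "noniv_difference",
    "noniv_product",
    "mvmr_mediation",
    "twostep_mr",
    "multiple_mediators",
    "proportion_mediated",
    "bootstrap_ci",
    "check_instrument_overlap",
    "MEDIATION_METHODS",
]

SCALES = ("linear", "rd", "logor", "or")

# |total| / SE(total) below this triggers the weak-total-effect warning
WEAK_TOTAL_RATIO = 2.0


@dataclass
class MediationResult:
    method: str
    scale: str
    total: float
    direct: float
    indirect: float
    indirect_per_mediator: dict[str, float]
    proportion_mediated: float | None
    total_se: float | None = None
    direct_se: float | None = None
    warnings: list[str] = field(default_factory=list)
    diagnostics: InstrumentDiagnostics | None = None
    extras: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def estimands(self) -> dict[str, float | None]:
        return {
            "total": self.total,
            "direct": self.direct,
            "indirect": self.indirect,
            "proportion_mediated": self.proportion_mediated,
        }


def _resolve_scale(ds: IndividualDataset, scale: str | None) -> str:
    if scale is None:
        return "linear" if ds.roles.outcome_type == OUTCOME_CONTINUOUS else "rd"
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    if scale == "linear" and ds.roles.outcome_type == OUTCOME_BINARY:
        raise ValueError("use scale='rd' for a binary outcome analysed linearly")
    if scale in ("rd", "logor", "or") and ds.roles.outcome_type == OUTCOME_CONTINUOUS:
        raise ValueError(f"scale {scale!r} requires a binary outcome")
    return scale


def _mediator_subset(ds: IndividualDataset, mediators) -> list[str]:
    if mediators is None:
        return list(ds.roles.mediators)
    mediators = [mediators] if isinstance(mediators, str) else list(mediators)
    unknown = [m for m in mediators if m not in ds.roles.mediators]
    if unknown:
        raise ValueError(f"not mediators of this dataset: {unknown}")
    return mediators


def proportion_mediated(
    indirect: float,
    total: float,
    total_se: float | None = None,
    direct: float | None = None,
) -> tuple[float | None, list[str]]:
    """indirect / total, with guard-rail warnings for fragile settings.

    Returns ``(None, warnings)`` when the total effect is exactly zero.
    Warns (but still reports) when the total effect is weak relative to its
    standard error or when direct and indirect effects oppose in sign —
    settings in which the proportion mediated is not interpretable as a
    proportion.
    """
    warnings: list[str] = []
    if total == 0:
        warnings.append("total effect is zero: proportion mediated is undefined")
        return None, warnings
    if total_se is not None and total_se > 0 and abs(total) / total_se < WEAK_TOTAL_RATIO:
        warnings.append(
            "weak total effect (|total|/SE < 2): the proportion mediated is "
            "imprecise and should be interpreted with caution"
        )
    if direct is not None and direct * indirect < 0:
        warnings.append(
            "direct and indirect effects act in opposing directions: the "
            "'proportion mediated' is not a proportion"
        )
    return indirect / total, warnings


# ---------------------------------------------------------------------------
# non-IV methods
# ---------------------------------------------------------------------------

def _fit_total_direct_noniv(ds, scale, mediators):
    x, y = ds.roles.exposure, ds.roles.outcome
    if scale in ("linear", "rd"):
        total_fit = ols(ds, y, [x])
        direct_fit = ols(ds, y, [x] + mediators)
    else:  # logor / or computed on the log-odds scale
        total_fit = logistic_fit(ds, y, [x])
        direct_fit = logistic_fit(ds, y, [x] + mediators)
    return total_fit, direct_fit


def _finalize(result: MediationResult, as_or: bool) -> MediationResult:
    """Exponentiate a log-odds decomposition onto the OR scale when asked."""
    if not as_or:
        return result
    result.scale = "or"
    result.total = math.exp(result.total)
    result.direct = math.exp(result.direct)
    result.indirect = math.exp(result.indirect)
    result.indirect_per_mediator = {
        k: math.exp(v) for k, v in result.indirect_per_mediator.items()
    }
    result.total_se = result.direct_se = None
    result.warnings.append(
        "odds-ratio scale decomposition (exponentiated log-odds): known to be "
        "biased by non-collapsibility; proportion mediated is computed on the "
        "log-odds scale"
    )
    return result


def noniv_difference(
    ds: IndividualDataset, scale: str | None = None, mediators=None
) -> MediationResult:
    """Difference-in-coefficients mediation without instruments."""
    scale = _resolve_scale(ds, scale)
    mediators = _mediator_subset(ds, mediators)
    x = ds.roles.exposure
    total_fit, direct_fit = _fit_total_direct_noniv(
        ds, scale, mediators
    )
    total, direct = total_fit.params[x], direct_fit.params[x]
    indirect = total - direct
    pm, warns = proportion_mediated(indirect, total, total_fit.bse[x], direct)
    res = MediationResult(
        method="noniv-difference",
        scale="logor" if scale == "or" else scale,
        total=total,
        direct=direct,
        indirect=indirect,
        indirect_per_mediator={},  # difference method yields the combined effect only
        proportion_mediated=pm,
        total_se=total_fit.bse[x],
        direct_se=direct_fit.bse[x],
        warnings=warns,
    )
    return _finalize(res, scale == "or")


def noniv_product(
    ds: IndividualDataset, scale: str | None = None, mediator: str | None = None
) -> MediationResult:
    """Product-of-coefficients mediation without instruments (single mediator)."""
    scale = _resolve_scale(ds, scale)
    if mediator is None:
        if len(ds.roles.mediators) != 1:
            raise ValueError("noniv_product handles one mediator per call")
        mediator = ds.roles.mediators[0]
    (mediator,) = _mediator_subset(ds, mediator)
    x, y = ds.roles.exposure, ds.roles.outcome
    a_fit = ols(ds, mediator, [x])
    if scale in ("linear", "rd"):
        b_fit = ols(ds, y, [mediator, x])
        total_fit = ols(ds, y, [x])
    else:
        b_fit = logistic_fit(ds, y, [mediator, x])
        total_fit = logistic_fit(ds, y, [x])
    a, b = a_fit.params[x], b_fit.params[mediator]
    indirect = a * b
    total, direct = total_fit.params[x], b_fit.params[x]
    pm, warns = proportion_mediated(indirect, total, total_fit.bse[x], direct)
    res = MediationResult(
        method="noniv-product",
        scale="logor" if scale == "or" else scale,
        total=total,
        direct=direct,
        indirect=indirect,
        indirect_per_mediator={mediator: indirect},
        proportion_mediated=pm,
        total_se=total_fit.bse[x],
        direct_se=b_fit.bse[x],
        warnings=warns,
        extras={"a": a, "b": b},
    )
    return _finalize(res, scale == "or")


# ---------------------------------------------------------------------------
# MR methods
# ---------------------------------------------------------------------------

def _instruments_for(ds: IndividualDataset, variables: list[str]) -> list[str]:
    cols: list[str] = []
    for v in variables:
        vcols = ds.roles.instruments.get(v, [])
        if not vcols:
            raise UnderIdentifiedError(f"no instruments declared for {v!r}")
        cols.extend(vcols)
    return cols


def _validate_overlap(ds: IndividualDataset, variables: list[str]) -> list[str]:
    sets = {v: ds.roles.instruments.get(v, []) for v in variables}
    report = check_instrument_overlap(sets, data=ds.data)
    if not report.passed:
        raise ValueError(
            "instrument sets overlap "
            f"(shared: {report.shared}); with shared instruments an attenuation "
            "of the direct effect cannot be distinguished from pleiotropy, so "
            "the mediation decomposition is not identified"
        )
    return [
        f"instrument scores for {p[0]} and {p[1]} are highly correlated "
        f"(|r|={r:.3f}); mediation and pleiotropy may be indistinguishable"
        for p, r in report.correlated
    ]


def _iv_outcome_fit(ds, scale, exposures, instruments, diagnostics):
    y = ds.roles.outcome
    if scale in ("linear", "rd"):
        return tsls(ds, y, exposures, instruments, diagnostics=diagnostics)
    return logistic_second_stage(ds, y, exposures, instruments)


def mvmr_mediation(
    ds: IndividualDataset,
    scale: str | None = None,
    mediators=None,
    diagnostics: bool = True,
    validate_instruments: bool = True,
) -> MediationResult:
    """MVMR difference-method decomposition.

    Total effect from univariable 2SLS of the outcome on the exposure;
    direct effect from multivariable 2SLS on exposure and mediator(s)
    jointly; indirect by difference.  Conditional F diagnostics attached.
    """
    scale = _resolve_scale(ds, scale)
    mediators = _mediator_subset(ds, mediators)
    x = ds.roles.exposure
    warns = _validate_overlap(ds, [x] + mediators) if validate_instruments else []
    total_fit = _iv_outcome_fit(ds, scale, [x], _instruments_for(ds, [x]), diagnostics)
    direct_fit = _iv_outcome_fit(
        ds, scale, [x] + mediators, _instruments_for(ds, [x] + mediators), diagnostics
    )
    total, direct = total_fit.params[x], direct_fit.params[x]
    indirect = total - direct
    pm, pm_warns = proportion_mediated(indirect, total, total_fit.bse[x], direct)
    diag = direct_fit.diagnostics
    if diag is not None and diag.weak:
        warns = warns + ["weak instruments: conditional F below 10"]
    res = MediationResult(
        method="mvmr-difference",
        scale="logor" if scale == "or" else scale,
        total=total,
        direct=direct,
        indirect=indirect,
        indirect_per_mediator={},
        proportion_mediated=pm,
        total_se=total_fit.bse[x],
        direct_se=direct_fit.bse[x],
        warnings=warns + pm_warns,
        diagnostics=diag,
    )
    return _finalize(res, scale == "or")


def twostep_mr(
    ds: IndividualDataset,
    scale: str | None = None,
    mediator: str | None = None,
    diagnostics: bool = True,
    validate_instruments: bool = True,
) -> MediationResult:
    """Two-step MR product-method decomposition (single mediator).

    Step 1: univariable 2SLS of the mediator on the exposure (coefficient A).
    Step 2: multivariable 2SLS of the outcome on exposure and mediator
    jointly — the mediator coefficient is B and the exposure coefficient the
    direct effect.  Indirect effect = A * B.
    """
    scale = _resolve_scale(ds, scale)
    if mediator is None:
        if len(ds.roles.mediators) != 1:
            raise ValueError("twostep_mr handles one mediator per call")
        mediator = ds.roles.mediators[0]
    (mediator,) = _mediator_subset(ds, mediator)
    x = ds.roles.exposure
    warns = _validate_overlap(ds, [x, mediator]) if validate_instruments else []
    inst_x = _instruments_for(ds, [x])
    inst_all = _instruments_for(ds, [x, mediator])
    a_fit = tsls(ds, mediator, [x], inst_x, diagnostics=diagnostics)
    second = _iv_outcome_fit(ds, scale, [x, mediator], inst_all, diagnostics)
    total_fit = _iv_outcome_fit(ds, scale, [x], inst_x, diagnostics)
    a, b = a_fit.params[x], second.params[mediator]
    indirect = a * b
    total, direct = total_fit.params[x], second.params[x]
    pm, pm_warns = proportion_mediated(indirect, total, total_fit.bse[x], direct)
    diag = second.diagnostics
    if diag is not None and diag.weak:
        warns = warns + ["weak instruments: conditional F below 10"]
    res = MediationResult(
        method="twostep-mr",
        scale="logor" if scale == "or" else scale,
        total=total,
        direct=direct,
        indirect=indirect,
        indirect_per_mediator={mediator: indirect},
        proportion_mediated=pm,
        total_se=total_fit.bse[x],
        direct_se=second.bse[x],
        warnings=warns + pm_warns,
        diagnostics=diag,
        extras={"a": a, "b": b},
    )
    return _finalize(res, scale == "or")


def multiple_mediators(
    ds: IndividualDataset,
    mode: str = "joint",
    scale: str | None = None,
    diagnostics: bool = True,
    validate_instruments: bool = True,
) -> MediationResult:
    """Mediation through several mediators at once.

    ``mode="joint"``: one MVMR fit controlling for all mediators; the
    combined indirect effect is total minus joint direct effect.
    ``mode="summed"``: each mediator analysed separately by two-step MR
    (using only that mediator's and the exposure's instruments) and the
    per-mediator indirect effects summed.  When one mediator causes another,
    the summed mode double-counts the chained pathway and over-estimates the
    combined proportion mediated; that is the documented behaviour of the
    method, not an implementation artefact.
    """
    mediators = list(ds.roles.mediators)
    if len(mediators) < 2:
        raise ValueError("multiple_mediators requires at least two mediators")
    if mode == "joint":
        res = mvmr_mediation(
            ds,
            scale=scale,
            mediators=mediators,
            diagnostics=diagnostics,
            validate_instruments=validate_instruments,
        )
        res.method = "multimediator-joint"
        return res
    if mode != "summed":
        raise ValueError(f"unknown mode {mode!r}; expected 'joint' or 'summed'")
    scale_r = _resolve_scale(ds, scale)
    per: dict[str, float] = {}
    warns: list[str] = []
    total = total_se = None
    for m in mediators:
        step = twostep_mr(
            ds,
            scale=scale,
            mediator=m,
            diagnostics=diagnostics,
            validate_instruments=validate_instruments,
        )
        per[m] = step.indirect
        total, total_se = step.total, step.total_se
        warns.extend(w for w in step.warnings if w not in warns)
    if scale_r == "or":
        # multiplicative scale: combined indirect is the product of per-mediator ORs
        indirect = float(np.prod(list(per.values())))
        direct = total / indirect
        pm, pm_warns = proportion_mediated(math.log(indirect), math.log(total))
    else:
        indirect = float(sum(per.values()))
        direct = total - indirect
        pm, pm_warns = proportion_mediated(indirect, total, total_se, direct)
    return MediationResult(
        method="multimediator-summed",
        scale=scale_r,
        total=total,
        direct=direct,
        indirect=indirect,
        indirect_per_mediator=per,
        proportion_mediated=pm,
        total_se=total_se,
        warnings=warns + pm_warns,
    )


MEDIATION_METHODS = {
    "noniv_difference": noniv_difference,
    "noniv_product": noniv_product,
    "mvmr": mvmr_mediation,
    "twostep": twostep_mr,
}


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    ci: dict[str, tuple[float, float]]
    level: float
    n_boot: int
    n_skipped: int
    warnings: list[str] = field(default_factory=list)


def bootstrap_ci(
    method,
    ds: IndividualDataset,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    **method_kwargs,
) -> BootstrapResult:
    """Nonparametric bootstrap percentile intervals for a decomposition.

    Individuals are resampled with replacement and the full decomposition
    re-estimated on every resample; percentile intervals are reported for
    the total, direct and indirect effects and the proportion mediated.
    Degenerate resamples (estimation failures, e.g. an all-zero binary
    outcome) are skipped and counted; more than 10% skipped raises a
    warning.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if isinstance(method, str):
        method = MEDIATION_METHODS[method]
    params = inspect.signature(method).parameters
    for switch in ("diagnostics", "validate_instruments"):
        if switch in params:  # skip per-resample diagnostics; validate once up front
            method_kwargs.setdefault(switch, False)
    rng = np.random.default_rng(seed)
    n = ds.n
    draws: dict[str, list[float]] = {
        "total": [], "direct": [], "indirect": [], "proportion_mediated": []
    }
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            res = method(ds.take(idx), **method_kwargs)
        except (ValueError, RuntimeError):
            skipped += 1
            continue
        for key, val in res.estimands().items():
            draws[key].append(np.nan if val is None else val)
    warnings = []
    if skipped > 0.10 * n_boot:
        warnings.append(
            f"{skipped}/{n_boot} bootstrap resamples were degenerate and skipped"
        )
    alpha = (1 - level) / 2
    ci = {}
    for key, vals in draws.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0 or np.all(np.isnan(arr)):
            continue
        lo, hi = np.nanpercentile(arr, [100 * alpha, 100 * (1 - alpha)])
        ci[key] = (float(lo), float(hi))
    return BootstrapResult(ci, level, n_boot, skipped, warnings)


# ---------------------------------------------------------------------------
# instrument overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    passed: bool
    shared: dict[tuple[str, str], list[str]]
    correlated: list[tuple[tuple[str, str], float]]
    message: str


def check_instrument_overlap(
    instrument_sets: dict[str, list[str]],
    data=None,
    corr_threshold: float = 0.9,
) -> OverlapReport:
    """Validate that instrument sets for different variables are independent.

    Fails if any identifier is shared between two sets.  When the score
    columns are supplied via ``data``, pairs of instruments from different
    sets whose sample correlation exceeds ``corr_threshold`` are flagged as
    warnings: near-collinear instruments make an attenuation of the direct
    effect indistinguishable from pleiotropy even without shared IDs.
    """
    if len(instrument_sets) < 2:
        raise ValueError("need at least two named instrument sets to compare")
    names = list(instrument_sets)
    shared: dict[tuple[str, str], list[str]] = {}
    correlated: list[tuple[tuple[str, str], float]] = []
    for i, vi in enumerate(names):
        for vj in names[i + 1:]:
            common = sorted(set(instrument_sets[vi]) & set(instrument_sets[vj]))
            if common:
                shared[(vi, vj)] = common
            elif data is not None:
                sub_i = data[list(instrument_sets[vi])].to_numpy(dtype=float)
                sub_j = data[list(instrument_sets[vj])].to_numpy(dtype=float)
                cc = np.corrcoef(sub_i, sub_j, rowvar=False)
                block = cc[: sub_i.shape[1], sub_i.shape[1]:]
                r = float(np.nanmax(np.abs(block)))
                if r > corr_threshold:
                    correlated.append(((vi, vj), r))
    passed = not shared
    if shared:
        message = (
            f"shared instrument identifiers between sets: {shared}; mediation "
            "cannot be distinguished from pleiotropy with overlapping instruments"
        )
    elif correlated:
        message = f"instrument sets are disjoint but highly correlated: {correlated}"
    else:
        message = "instrument sets are disjoint"
    return OverlapReport(passed, shared, correlated, message)
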