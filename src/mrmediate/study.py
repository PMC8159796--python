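"""Monte-Carlo bias study: scenario runner, scenario grids and presets.

``run_scenario`` simulates replicate datasets under one ScenarioConfig,
applies the requested decomposition methods and aggregates the estimates
against the path-traced truth into per-estimand bias summaries (mean,
absolute and relative bias, SD across replicates).  ``run_grid`` crosses
configuration fields — including the derived ``total_effect`` and
``proportion_mediated`` knobs — into a long-format table of bias summaries.
``applied_analysis`` runs the same decomposition code path on a
user-supplied individual-level file.

Each replicate gets its own RNG stream derived from (master seed,
replicate index), so grids are reproducible and trivially parallelisable.
"""

from __future__ import annotations

import dataclasses
import inspect
import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import mediation
from .dgp import (
    OUTCOME_BINARY,
    IndividualDataset,
    ScenarioConfig,
    gamma_for_target_f,
    simulate,
    true_effects,
)

__all__ = [
    "BiasSummary",
    "run_scenario",
    "run_grid",
    "applied_analysis",
    "config_for_total_pm",
    "presets",
    "DEFAULT_REPLICATES",
]

DEFAULT_REPLICATES = 200  # desk scale; the full-scale studies use 1000
MAX_FAILURE_FRACTION = 0.10

ESTIMANDS = ("total", "direct", "indirect", "proportion_mediated")


@dataclass
class BiasSummary:
    scenario: str
    method: str
    estimand: str
    truth: float | None
    mean: float
    abs_bias: float | None
    rel_bias: float | None
    sd: float
    n_replicates: int
    n_failed: int

    @staticmethod
    def frame(rows: list["BiasSummary"]) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def _truth_for_scale(config: ScenarioConfig, scale: str | None):
    if config.outcome_type == OUTCOME_BINARY and (scale is None or scale == "rd"):
        return true_effects(config, scale="rd")
    # log-odds analyses are judged against the structural (log-odds) truth;
    # continuous outcomes are structural by definition
    return true_effects(config)


def _resolve_method(m):
    if callable(m):
        return getattr(m, "__name__", "custom"), m
    if m not in mediation.MEDIATION_METHODS:
        raise ValueError(
            f"unknown method {m!r}; expected one of {sorted(mediation.MEDIATION_METHODS)}"
        )
    return m, mediation.MEDIATION_METHODS[m]


def run_scenario(
    config: ScenarioConfig,
    methods=("noniv_difference", "noniv_product", "mvmr", "twostep"),
    replicates: int = DEFAULT_REPLICATES,
    master_seed: int = 0,
    scale: str | None = None,
    scenario_id: str = "scenario",
) -> pd.DataFrame:
    """Simulate ``replicates`` datasets and summarise each method's bias."""
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    resolved = [_resolve_method(m) for m in methods]
    truth = _truth_for_scale(config, scale)
    truths = {
        "total": truth.total,
        "direct": truth.direct,
        "indirect": truth.indirect,
        "proportion_mediated": truth.proportion_mediated,
    }
    estimates: dict[str, dict[str, list[float]]] = {
        name: {e: [] for e in ESTIMANDS} for name, _ in resolved
    }
    failures = {name: 0 for name, _ in resolved}
    for rep in range(replicates):
        ds = simulate(config, seed=(master_seed, rep))
        for name, fn in resolved:
            try:
                params = inspect.signature(fn).parameters
            except (TypeError, ValueError):
                params = {}
            kwargs = {"scale": scale} if "scale" in params else {}
            try:
                res = fn(ds, **kwargs)
            except (ValueError, RuntimeError):
                failures[name] += 1
                continue
            for est, val in res.estimands().items():
                estimates[name][est].append(np.nan if val is None else val)
    rows: list[BiasSummary] = []
    for name, _ in resolved:
        if failures[name] > MAX_FAILURE_FRACTION * replicates:
            raise RuntimeError(
                f"method {name!r} failed on {failures[name]}/{replicates} replicates"
            )
        for est in ESTIMANDS:
            vals = np.asarray(estimates[name][est], dtype=float)
            mean = float(np.nanmean(vals)) if vals.size else float("nan")
            sd = float(np.nanstd(vals, ddof=1)) if vals.size > 1 else float("nan")
            t = truths[est]
            abs_bias = mean - t if t is not None else None
            rel_bias = abs_bias / t if t not in (None, 0) else None
            rows.append(
                BiasSummary(
                    scenario=scenario_id,
                    method=name,
                    estimand=est,
                    truth=t,
                    mean=mean,
                    abs_bias=abs_bias,
                    rel_bias=rel_bias,
                    sd=sd,
                    n_replicates=replicates,
                    n_failed=failures[name],
                )
            )
    return BiasSummary.frame(rows)


def config_for_total_pm(
    total_effect: float,
    pm: float,
    b_path: float = 0.5,
    base: ScenarioConfig | None = None,
    **overrides,
) -> ScenarioConfig:
    """Single-mediator config with the requested total effect and proportion mediated.

    The mediator->outcome path is held at ``b_path``; the exposure->mediator
    path is a = pm*total/b and the direct effect c' = total*(1-pm).
    """
    base = base or ScenarioConfig()
    indirect = pm * total_effect
    return dataclasses.replace(
        base,
        a_paths=[indirect / b_path],
        b_paths=[b_path],
        c_prime=total_effect - indirect,
        **overrides,
    )


_GRID_SPECIAL = ("total_effect", "proportion_mediated")


def run_grid(
    grid: dict[str, list],
    base: ScenarioConfig | None = None,
    methods=("noniv_difference", "noniv_product", "mvmr", "twostep"),
    replicates: int = DEFAULT_REPLICATES,
    master_seed: int = 0,
    scale: str | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Cross-product of config fields -> one bias table per cell plus a long table.

    ``grid`` maps ScenarioConfig field names (or the derived knobs
    ``total_effect``/``proportion_mediated``) to lists of values.
    Deterministic given ``master_seed``; each cell gets its own seed stream.
    """
    base = base or ScenarioConfig()
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must map at least one field to a non-empty list")
    valid = {f.name for f in dataclasses.fields(ScenarioConfig)} | set(_GRID_SPECIAL)
    for key in grid:
        if key not in valid:
            raise ValueError(f"unknown grid field: {key!r}")
    keys = list(grid)
    tables = []
    for cell_idx, values in enumerate(itertools.product(*(grid[k] for k in keys))):
        cell = dict(zip(keys, values))
        special = {k: cell.pop(k) for k in _GRID_SPECIAL if k in cell}
        if special:
            cfg = config_for_total_pm(
                special.get("total_effect", 0.5),
                special.get("proportion_mediated", 0.4),
                base=base,
                **cell,
            )
        else:
            cfg = dataclasses.replace(base, **cell)
        scenario_id = "__".join(
            f"{k}={v}" for k, v in zip(keys, values)
        )
        table = run_scenario(
            cfg,
            methods=methods,
            replicates=replicates,
            master_seed=master_seed + 1000 * cell_idx,
            scale=scale,
            scenario_id=scenario_id,
        )
        tables.append(table)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            safe = scenario_id.replace("=", "-").replace(".", "p")
            table.to_csv(out_dir / f"bias_{safe}.tsv", sep="\t", index=False)
    combined = pd.concat(tables, ignore_index=True)
    if out_dir is not None:
        combined.to_csv(Path(out_dir) / "bias_combined.tsv", sep="\t", index=False)
    return combined


def applied_analysis(
    dataset,
    methods=("mvmr", "twostep"),
    scale: str | None = None,
    n_boot: int | None = None,
    seed: int = 0,
    level: float = 0.95,
    out=None,
) -> pd.DataFrame:
    """Run decompositions (with optional bootstrap CIs) on real or simulated data.

    ``dataset`` is an IndividualDataset or a path to a delimited file using
    the iv_x / iv_m1 / x / m1 / y column convention.  The code path is
    identical to the one used on simulated data.
    """
    if not isinstance(dataset, IndividualDataset):
        dataset = IndividualDataset.from_csv(dataset)
    dataset.validate()
    records = []
    for m in methods:
        name, fn = _resolve_method(m)
        res = fn(dataset) if scale is None else fn(dataset, scale=scale)
        rec = {
            "method": res.method,
            "scale": res.scale,
            "total": res.total,
            "direct": res.direct,
            "indirect": res.indirect,
            "proportion_mediated": res.proportion_mediated,
            "total_se": res.total_se,
            "direct_se": res.direct_se,
            "warnings": "; ".join(res.warnings),
        }
        if res.diagnostics is not None:
            rec["weak_instruments"] = res.diagnostics.weak
            for k, v in res.diagnostics.f_stats.items():
                rec[f"F_{k}"] = v
            for k, v in res.diagnostics.conditional_f.items():
                rec[f"condF_{k}"] = v
        if n_boot:
            kwargs = {"scale": scale} if scale is not None else {}
            boot = mediation.bootstrap_ci(
                fn, dataset, n_boot=n_boot, seed=seed, level=level, **kwargs
            )
            for key, (lo, hi) in boot.ci.items():
                rec[f"{key}_ci_low"], rec[f"{key}_ci_high"] = lo, hi
            rec["bootstrap_skipped"] = boot.n_skipped
        records.append(rec)
    frame = pd.DataFrame(records)
    if out is not None:
        frame.to_csv(out, sep="\t", index=False)
    return frame


# ---------------------------------------------------------------------------
# shipped scenario presets — every bias mechanism as a switchable flag
# ---------------------------------------------------------------------------

def presets() -> dict[str, ScenarioConfig]:
    """Named scenario presets exercising each bias mechanism once.

    All use n = 5000 with a = 0.4, b = 0.5, c' = 0.3 (total effect 0.5,
    proportion mediated 0.4) unless the mechanism itself requires otherwise.
    """
    from .dgp import ConfounderLoadings, IntermediateConfounder

    from .dgp import NoiseSDs

    conf = ConfounderLoadings(x=0.5, m=0.5, y=0.5)
    base = ScenarioConfig(confounder=conf)
    # measurement-error scenarios run without confounding to isolate the
    # mechanism, with a mediator strongly determined by the exposure — the
    # regime in which classical error on the exposure leaks the direct effect
    # into the mediator's coefficient and over-estimates the mediated effect
    me_base = ScenarioConfig(
        a_paths=[1.0], b_paths=[0.25], c_prime=0.25,
        gamma_m=0.3, noise_sds=NoiseSDs(m=0.3),
    )
    weak_gamma = gamma_for_target_f(4.0, 5000, residual_var=1.25, n_instruments=10)
    return {
        "baseline": ScenarioConfig(),
        "confounded": base,
        "intermediate_confounding": ScenarioConfig(
            intermediate=IntermediateConfounder(x_to_l=0.5, m=0.4, y=0.4)
        ),
        "me_exposure": dataclasses.replace(me_base, me_exposure_sd=0.5),
        "me_mediator": dataclasses.replace(me_base, me_mediator_sd=0.5),
        "weak_x": dataclasses.replace(
            base, instrument_mode="snps", gamma_x=weak_gamma
        ),
        "weak_m": dataclasses.replace(
            base, instrument_mode="snps", gamma_m=weak_gamma
        ),
        "pleiotropy_xy": dataclasses.replace(base, pleiotropy_xy=0.2),
        "pleiotropy_my": dataclasses.replace(base, pleiotropy_my=0.2),
        "interaction": dataclasses.replace(
            base, interaction_theta=0.5, m_means=1.0
        ),
        "null_total": dataclasses.replace(
            base, a_paths=[0.4], b_paths=[0.5], c_prime=-0.2
        ),
        "small_total": config_for_total_pm(0.1, 0.4, base=base),
        "chain_mediators": dataclasses.replace(
            base,
            a_paths=[0.2, 0.3, 0.1],
            b_paths=[0.25, 0.25, 0.5],
            mediator_chain=[("m2", "m3", 0.2)],
            c_prime=0.295,
        ),
        "binary_rare": dataclasses.replace(
            base, outcome_type="binary", prevalence=0.05
        ),
        "binary_common": dataclasses.replace(
            base, outcome_type="binary", prevalence=0.25
        ),
    }
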