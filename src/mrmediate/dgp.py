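"""Structural data-generating processes for individual-level MR mediation studies.

The generative model is a linear structural equation system

    X   = mu_x + gamma_x * G_X + u_x * U + eps_X
    L   = lambda_L * X + eps_L                      (intermediate confounder)
    M_j = mu_mj + a_j * X + sum_i d_ij * M_i + gamma_mj * G_Mj
          + u_mj * U + l_mj * L + eps_Mj
    eta = c' * X + sum_j b_j * M_j + theta * X * M_1
          + u_y * U + l_y * L + p_x * G_X + sum_j p_mj * G_Mj + eps_Y

with independent standard-normal polygenic-score instruments G (or,
optionally, biallelic SNP dosage panels), a shared standard-normal
confounder U, and Gaussian residuals.  Continuous outcomes are Y = eta;
binary outcomes are Bernoulli(expit(b0 + eta)) with the intercept b0
solved so the sample prevalence matches the target.  Classical
measurement error is added to the observed exposure/mediators after all
structural equations.

Alongside the simulator the module provides closed-form ground truth:
path-traced total/direct/indirect effects, the risk-difference scaling
factor for binary outcomes, and the probability limits of (biased)
non-IV regression coefficients via model-implied covariance algebra.
"""

from __future__ import annotations

import dataclasses
import graphlib
import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.special import expit

__all__ = [
    "ScenarioConfig",
    "ConfounderLoadings",
    "IntermediateConfounder",
    "NoiseSDs",
    "RoleMap",
    "IndividualDataset",
    "TrueEffects",
    "simulate",
    "true_effects",
    "rd_scale_factor",
    "binary_link_stats",
    "plim_noniv_oracle",
    "model_covariance",
    "gamma_for_target_f",
]

OUTCOME_CONTINUOUS = "continuous"
OUTCOME_BINARY = "binary"


def _broadcast(value, k: int, name: str) -> list[float]:
    """Broadcast a scalar to a per-mediator list, validating length."""
    if np.isscalar(value):
        return [float(value)] * k
    out = [float(v) for v in value]
    if len(out) != k:
        raise ValueError(f"{name} must have one entry per mediator ({k}), got {len(out)}")
    return out


@dataclass
class ConfounderLoadings:
    """Loadings of the shared N(0,1) confounder U on exposure, mediators, outcome."""

    x: float = 0.0
    m: float | list[float] = 0.0
    y: float = 0.0


@dataclass
class IntermediateConfounder:
    """Exposure-caused mediator-outcome confounder L = x_to_l * X + eps."""

    x_to_l: float = 0.0
    m: float | list[float] = 0.0
    y: float = 0.0
    noise_sd: float = 1.0


@dataclass
class NoiseSDs:
    x: float = 1.0
    m: float | list[float] = 1.0
    y: float = 1.0


@dataclass
class ScenarioConfig:
    """Full specification of one simulation scenario.

    ``a_paths``/``b_paths`` are the exposure->mediator and mediator->outcome
    structural effects (one per mediator); ``c_prime`` is the direct
    exposure->outcome effect.  ``mediator_chain`` lists (source, target,
    effect) triples between mediators, e.g. ``[("m2", "m3", 0.2)]``.
    All remaining knobs switch on one bias mechanism each and default to
    "off".
    """

    n: int = 5000
    outcome_type: str = OUTCOME_CONTINUOUS
    prevalence: float = 0.25
    c_prime: float = 0.3
    a_paths: list[float] = field(default_factory=lambda: [0.4])
    b_paths: list[float] = field(default_factory=lambda: [0.5])
    mediator_chain: list[tuple] = field(default_factory=list)
    gamma_x: float = 1.0
    gamma_m: float | list[float] = 1.0
    confounder: ConfounderLoadings = field(default_factory=ConfounderLoadings)
    intermediate: IntermediateConfounder = field(default_factory=IntermediateConfounder)
    me_exposure_sd: float = 0.0
    me_mediator_sd: float | list[float] = 0.0
    pleiotropy_xy: float = 0.0
    pleiotropy_my: float | list[float] = 0.0
    interaction_theta: float = 0.0
    x_mean: float = 0.0
    m_means: float | list[float] = 0.0
    noise_sds: NoiseSDs = field(default_factory=NoiseSDs)
    instrument_mode: str = "score"  # "score" (1 PGS per variable) or "snps"
    n_snps: int = 10
    maf: float = 0.3
    seed: int = 0

    # -- derived, normalised views -------------------------------------
    @property
    def n_mediators(self) -> int:
        return len(self.a_paths)

    def mediator_names(self) -> list[str]:
        return [f"m{j + 1}" for j in range(self.n_mediators)]

    def _chain_edges(self) -> list[tuple[int, int, float]]:
        """Chain triples normalised to 0-based mediator indices."""
        edges = []
        k = self.n_mediators
        for src, dst, eff in self.mediator_chain:
            idx = []
            for node in (src, dst):
                if isinstance(node, str):
                    m = re.fullmatch(r"m(\d+)", node)
                    if not m:
                        raise ValueError(f"bad mediator name in chain: {node!r}")
                    i = int(m.group(1)) - 1
                else:
                    i = int(node) - 1
                if not 0 <= i < k:
                    raise ValueError(f"mediator_chain references undeclared mediator: {node!r}")
                idx.append(i)
            edges.append((idx[0], idx[1], float(eff)))
        return edges

    def _topo_order(self) -> list[int]:
        edges = self._chain_edges()
        deps: dict[int, set[int]] = {j: set() for j in range(self.n_mediators)}
        for src, dst, _ in edges:
            deps[dst].add(src)
        try:
            return list(graphlib.TopologicalSorter(deps).static_order())
        except graphlib.CycleError as exc:
            raise ValueError(f"mediator_chain is cyclic: {exc.args}") from exc

    def __post_init__(self) -> None:
        k = self.n_mediators
        if k < 1:
            raise ValueError("at least one mediator is required")
        if len(self.b_paths) != k:
            raise ValueError("a_paths and b_paths must have equal length")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.outcome_type not in (OUTCOME_CONTINUOUS, OUTCOME_BINARY):
            raise ValueError(f"unknown outcome_type: {self.outcome_type!r}")
        if self.outcome_type == OUTCOME_BINARY and not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1) for binary outcomes")
        if self.instrument_mode not in ("score", "snps"):
            raise ValueError(f"unknown instrument_mode: {self.instrument_mode!r}")
        for name in ("me_exposure_sd",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in _broadcast(self.me_mediator_sd, k, "me_mediator_sd")):
            raise ValueError("me_mediator_sd must be >= 0")
        sds = [self.noise_sds.x, self.noise_sds.y, self.intermediate.noise_sd]
        sds += _broadcast(self.noise_sds.m, k, "noise_sds.m")
        if any(s < 0 for s in sds):
            raise ValueError("noise SDs must be >= 0")
        self._topo_order()  # validates chain references and acyclicity

    # -- structured-text round trip ------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["mediator_chain"] = [list(t) for t in d["mediator_chain"]]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        d = yaml.safe_load(text)
        for key, sub in (
            ("confounder", ConfounderLoadings),
            ("intermediate", IntermediateConfounder),
            ("noise_sds", NoiseSDs),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "mediator_chain" in d:
            d["mediator_chain"] = [tuple(t) for t in d["mediator_chain"]]
        return cls(**d)


@dataclass
class RoleMap:
    """Names the column(s) playing each part in an IndividualDataset."""

    outcome: str
    exposure: str
    mediators: list[str]
    instruments: dict[str, list[str]]  # instrumented variable -> instrument columns
    outcome_type: str = OUTCOME_CONTINUOUS

    def all_instrument_columns(self) -> list[str]:
        cols: list[str] = []
        for target in [self.exposure] + list(self.mediators):
            cols.extend(self.instruments.get(target, []))
        return cols


@dataclass
class IndividualDataset:
    """Rectangular per-individual table plus the role map describing it."""

    data: pd.DataFrame
    roles: RoleMap
    latent: dict[str, str] = field(default_factory=dict)  # observed col -> latent col
    _mat: np.ndarray | None = field(default=None, repr=False, compare=False)
    _colidx: dict[str, int] | None = field(default=None, repr=False, compare=False)

    @property
    def has_measurement_error(self) -> bool:
        return bool(self.latent)

    def _cache(self) -> None:
        if self._mat is None:
            self._mat = self.data.to_numpy(dtype=float)
            self._colidx = {c: i for i, c in enumerate(self.data.columns)}

    def array(self, names: list[str]) -> np.ndarray:
        """Columns as a float matrix (cached; the Monte-Carlo hot path)."""
        self._cache()
        return self._mat[:, [self._colidx[n] for n in names]]

    @property
    def n(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        r = self.roles
        needed = [r.outcome, r.exposure, *r.mediators, *r.all_instrument_columns()]
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset is missing role columns: {missing}")
        orphans = set(r.instruments) - ({r.exposure} | set(r.mediators))
        if orphans:
            raise ValueError(
                f"instruments declared for variables with no role: {sorted(orphans)}"
            )
        if self.data[needed].isna().any().any():
            raise ValueError("dataset contains missing values in role columns")
        if r.outcome_type == OUTCOME_BINARY:
            vals = set(np.unique(self.data[r.outcome].to_numpy()))
            if not vals <= {0, 1}:
                raise ValueError("binary outcome column must contain only {0,1}")

    def take(self, idx: np.ndarray) -> "IndividualDataset":
        """Row-resample (used by the bootstrap); keeps roles and latent map."""
        self._cache()
        df = pd.DataFrame(self._mat[idx], columns=self.data.columns)
        return IndividualDataset(df, self.roles, self.latent, self._mat[idx], self._colidx)

    # delimited-text round trip; roles are carried by the column-name
    # convention iv_x / iv_m1 / x / m1 / y (SNP panels: iv_x_1, iv_x_2, ...)
    def to_csv(self, path_or_buf=None):
        return self.data.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path) -> "IndividualDataset":
        df = pd.read_csv(path)
        return cls.from_dataframe(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IndividualDataset":
        cols = list(df.columns)
        if "y" not in cols or "x" not in cols:
            raise ValueError("dataset must contain 'x' and 'y' columns")
        mediators = sorted(
            (c for c in cols if re.fullmatch(r"m\d+", c)), key=lambda c: int(c[1:])
        )
        instruments: dict[str, list[str]] = {}
        for c in cols:
            m = re.fullmatch(r"iv_(x|m\d+)(?:_\d+)?", c)
            if m:
                instruments.setdefault(m.group(1), []).append(c)
        latent = {
            c[: -len("_latent")]: c for c in cols if c.endswith("_latent")
        }
        yvals = df["y"].to_numpy()
        outcome_type = (
            OUTCOME_BINARY if set(np.unique(yvals)) <= {0, 1} else OUTCOME_CONTINUOUS
        )
        ds = cls(
            df,
            RoleMap("y", "x", mediators, instruments, outcome_type),
            latent,
        )
        ds.validate()
        return ds


@dataclass
class TrueEffects:
    """Path-traced causal effects on the linear structural scale."""

    total: float
    direct: float
    indirect_per_mediator: dict[str, float]
    indirect: float
    proportion_mediated: float | None
    scale: str = "structural"


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _instrument_scores(config: ScenarioConfig, rng: np.random.Generator):
    """Draw instruments; return (score arrays used structurally, dosage columns)."""
    n, k = config.n, config.n_mediators
    targets = ["x"] + config.mediator_names()
    scores, columns = {}, {}
    for t in targets:
        if config.instrument_mode == "score":
            g = rng.standard_normal(n)
            scores[t] = g
            columns[f"iv_{t}"] = g
        else:
            dosages = rng.binomial(2, config.maf, size=(n, config.n_snps)).astype(float)
            for i in range(config.n_snps):
                columns[f"iv_{t}_{i + 1}"] = dosages[:, i]
            # unweighted allele score, standardised to unit variance so that
            # gamma keeps the same meaning as in score mode
            s = dosages.sum(axis=1)
            sd = np.sqrt(config.n_snps * 2 * config.maf * (1 - config.maf))
            scores[t] = (s - config.n_snps * 2 * config.maf) / sd
    return scores, columns


def simulate(config: ScenarioConfig, seed=None, keep_latent_confounders: bool = False) -> IndividualDataset:
    """Generate one individual-level dataset under ``config``.

    Deterministic given ``seed`` (defaults to ``config.seed``); ``seed`` may
    be an int or a sequence such as ``(master_seed, replicate)``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, k = config.n, config.n_mediators
    gamma_m = _broadcast(config.gamma_m, k, "gamma_m")
    u_m = _broadcast(config.confounder.m, k, "confounder.m")
    l_m = _broadcast(config.intermediate.m, k, "intermediate.m")
    sd_m = _broadcast(config.noise_sds.m, k, "noise_sds.m")
    me_m = _broadcast(config.me_mediator_sd, k, "me_mediator_sd")
    p_my = _broadcast(config.pleiotropy_my, k, "pleiotropy_my")
    mu_m = _broadcast(config.m_means, k, "m_means")
    a, b = config.a_paths, config.b_paths

    scores, iv_columns = _instrument_scores(config, rng)
    u = rng.standard_normal(n)
    eps_l = rng.standard_normal(n)
    eps_x = rng.standard_normal(n)
    eps_m = rng.standard_normal((k, n))
    eps_y = rng.standard_normal(n)

    x = (
        config.x_mean
        + config.gamma_x * scores["x"]
        + config.confounder.x * u
        + config.noise_sds.x * eps_x
    )
    lvar = config.intermediate.x_to_l * x + config.intermediate.noise_sd * eps_l

    m = np.empty((k, n))
    chain = config._chain_edges()
    for j in config._topo_order():
        mj = (
            mu_m[j]
            + a[j] * x
            + gamma_m[j] * scores[f"m{j + 1}"]
            + u_m[j] * u
            + l_m[j] * lvar
            + sd_m[j] * eps_m[j]
        )
        for src, dst, eff in chain:
            if dst == j:
                mj = mj + eff * m[src]
        m[j] = mj

    eta = (
        config.c_prime * x
        + b @ m
        + config.interaction_theta * x * m[0]
        + config.confounder.y * u
        + config.intermediate.y * lvar
        + config.pleiotropy_xy * scores["x"]
        + config.noise_sds.y * eps_y
    )
    for j in range(k):
        eta = eta + p_my[j] * scores[f"m{j + 1}"]

    if config.outcome_type == OUTCOME_BINARY:
        b0 = _solve_intercept(eta, config.prevalence)
        y = rng.binomial(1, expit(b0 + eta)).astype(float)
    else:
        y = eta

    cols: dict[str, np.ndarray] = dict(iv_columns)
    latent: dict[str, str] = {}
    if config.me_exposure_sd > 0:
        cols["x"] = x + config.me_exposure_sd * rng.standard_normal(n)
        cols["x_latent"] = x
        latent["x"] = "x_latent"
    else:
        cols["x"] = x
    for j in range(k):
        name = f"m{j + 1}"
        if me_m[j] > 0:
            cols[name] = m[j] + me_m[j] * rng.standard_normal(n)
            cols[f"{name}_latent"] = m[j]
            latent[name] = f"{name}_latent"
        else:
            cols[name] = m[j]
    cols["y"] = y
    if keep_latent_confounders:
        cols["_u"] = u
        cols["_l"] = lvar

    roles = RoleMap(
        outcome="y",
        exposure="x",
        mediators=config.mediator_names(),
        instruments={
            t: [c for c in iv_columns if re.fullmatch(rf"iv_{t}(_\d+)?", c)]
            for t in ["x"] + config.mediator_names()
        },
        outcome_type=config.outcome_type,
    )
    ds = IndividualDataset(pd.DataFrame(cols), roles, latent)
    ds.validate()
    return ds


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept b0 with mean(expit(b0 + eta)) = prevalence (bisection/brentq)."""

    def f(b0):
        return expit(b0 + eta).mean() - prevalence

    lo, hi = -40.0, 40.0
    flo, fhi = f(lo), f(hi)
    if not flo < 0 < fhi:
        achieved = expit(eta).mean()
        raise RuntimeError(
            f"could not calibrate binary intercept: achieved prevalence {achieved:.4f} "
            f"for target {prevalence:.4f}"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# ground truth: path tracing
# ---------------------------------------------------------------------------

def _total_effects_on_mediators(config: ScenarioConfig) -> list[float]:
    """Total effect of X on each mediator, including chained mediator paths."""
    k = config.n_mediators
    t = [0.0] * k
    chain = config._chain_edges()
    for j in config._topo_order():
        t[j] = config.a_paths[j] + sum(eff * t[src] for src, dst, eff in chain if dst == j)
    return t


def true_effects(config: ScenarioConfig, scale: str = "structural") -> TrueEffects:
    """Path-traced total/direct/indirect effects and proportion mediated.

    ``scale="rd"`` rescales effects for a binary outcome onto the risk
    difference scale (see :func:`rd_scale_factor`); the proportion mediated
    is scale-free.  Defined only for ``interaction_theta == 0``: with an
    exposure-mediator interaction there is no single linear estimand.
    """
    if config.interaction_theta != 0:
        raise ValueError(
            "true_effects is undefined when interaction_theta != 0: the "
            "exposure effect varies with the mediator, so no single linear "
            "estimand exists"
        )
    t = _total_effects_on_mediators(config)
    per = {
        name: t[j] * config.b_paths[j] for j, name in enumerate(config.mediator_names())
    }
    indirect = sum(per.values())
    direct = config.c_prime
    total = direct + indirect  # exact by construction
    pm = indirect / total if total != 0 else None
    if scale == "rd":
        if config.outcome_type != OUTCOME_BINARY:
            raise ValueError("rd scale applies to binary outcomes only")
        kfac = rd_scale_factor(config)
        per = {k_: v * kfac for k_, v in per.items()}
        indirect, direct, total = indirect * kfac, direct * kfac, total * kfac
    elif scale != "structural":
        raise ValueError(f"unknown truth scale: {scale!r}")
    return TrueEffects(total, direct, per, indirect, pm, scale)


# ---------------------------------------------------------------------------
# ground truth: covariance algebra
# ---------------------------------------------------------------------------

def _shock_matrix(config: ScenarioConfig) -> tuple[list[str], np.ndarray]:
    """Represent every model variable as a linear combination of unit shocks.

    Returns (variable names, coefficient matrix A); the model-implied
    covariance is A @ A.T because all shocks are independent with unit
    variance (SDs are folded into the coefficients).  Requires theta = 0.
    """
    if config.interaction_theta != 0:
        raise ValueError("covariance algebra requires interaction_theta == 0")
    k = config.n_mediators
    gamma_m = _broadcast(config.gamma_m, k, "gamma_m")
    u_m = _broadcast(config.confounder.m, k, "confounder.m")
    l_m = _broadcast(config.intermediate.m, k, "intermediate.m")
    sd_m = _broadcast(config.noise_sds.m, k, "noise_sds.m")
    me_m = _broadcast(config.me_mediator_sd, k, "me_mediator_sd")
    p_my = _broadcast(config.pleiotropy_my, k, "pleiotropy_my")

    # shock order: g_x, g_m(1..k), u, e_l, e_x, e_m(1..k), e_y, me_x, me_m(1..k)
    dim = 3 * k + 6
    idx = {"g_x": 0}
    idx.update({f"g_m{j + 1}": 1 + j for j in range(k)})
    idx["u"] = k + 1
    idx["e_l"] = k + 2
    idx["e_x"] = k + 3
    idx.update({f"e_m{j + 1}": k + 4 + j for j in range(k)})
    idx["e_y"] = 2 * k + 4
    idx["me_x"] = 2 * k + 5
    idx.update({f"me_m{j + 1}": 2 * k + 6 + j for j in range(k)})

    rows: dict[str, np.ndarray] = {}

    def unit(shock):
        v = np.zeros(dim)
        v[idx[shock]] = 1.0
        return v

    rows["iv_x"] = unit("g_x")
    for j in range(k):
        rows[f"iv_m{j + 1}"] = unit(f"g_m{j + 1}")
    rows["u"] = unit("u")
    x = (
        config.gamma_x * rows["iv_x"]
        + config.confounder.x * rows["u"]
        + config.noise_sds.x * unit("e_x")
    )
    rows["x_latent"] = x
    lvar = config.intermediate.x_to_l * x + config.intermediate.noise_sd * unit("e_l")
    rows["l"] = lvar

    m_rows: list[np.ndarray | None] = [None] * k
    chain = config._chain_edges()
    for j in config._topo_order():
        mj = (
            config.a_paths[j] * x
            + gamma_m[j] * rows[f"iv_m{j + 1}"]
            + u_m[j] * rows["u"]
            + l_m[j] * lvar
            + sd_m[j] * unit(f"e_m{j + 1}")
        )
        for src, dst, eff in chain:
            if dst == j:
                mj = mj + eff * m_rows[src]
        m_rows[j] = mj
        rows[f"m{j + 1}_latent"] = mj

    y = (
        config.c_prime * x
        + config.confounder.y * rows["u"]
        + config.intermediate.y * lvar
        + config.pleiotropy_xy * rows["iv_x"]
        + config.noise_sds.y * unit("e_y")
    )
    for j in range(k):
        y = y + config.b_paths[j] * m_rows[j] + p_my[j] * rows[f"iv_m{j + 1}"]
    rows["y"] = y

    # observed (possibly error-laden) columns carry the dataset names
    rows["x"] = x + config.me_exposure_sd * unit("me_x")
    for j in range(k):
        rows[f"m{j + 1}"] = m_rows[j] + me_m[j] * unit(f"me_m{j + 1}")

    names = list(rows)
    return names, np.vstack([rows[n] for n in names])


def model_covariance(config: ScenarioConfig) -> pd.DataFrame:
    """Model-implied covariance matrix of instruments, confounders and phenotypes.

    Variable names match dataset columns (``x``/``m1`` are the observed,
    possibly error-laden versions; ``*_latent`` the error-free ones; ``y``
    is the continuous outcome / linear predictor).
    """
    names, amat = _shock_matrix(config)
    cov = amat @ amat.T
    return pd.DataFrame(cov, index=names, columns=names)


def plim_noniv_oracle(
    config: ScenarioConfig, outcome: str = "y", regressors: list[str] | None = None
) -> dict[str, float]:
    """Probability limits of OLS coefficients of ``outcome`` on ``regressors``.

    Solves the population normal equations in the model-implied covariance,
    giving the exact asymptotic value (including omitted-variable and
    measurement-error bias) that Monte-Carlo OLS means must converge to.
    Continuous outcome, no interaction.
    """
    if config.outcome_type != OUTCOME_CONTINUOUS:
        raise ValueError("the non-IV plim oracle is defined for continuous outcomes")
    if regressors is None:
        regressors = ["x"] + config.mediator_names()
    cov = model_covariance(config)
    srr = cov.loc[regressors, regressors].to_numpy()
    sry = cov.loc[regressors, outcome].to_numpy()
    if np.linalg.matrix_rank(srr) < len(regressors):
        raise np.linalg.LinAlgError("singular regressor covariance")
    beta = np.linalg.solve(srr, sry)
    return dict(zip(regressors, beta.tolist()))


# ---------------------------------------------------------------------------
# binary-outcome link calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(101)


def binary_link_stats(config: ScenarioConfig) -> tuple[float, float]:
    """Population intercept b0 and derivative factor k = E[p(1-p)].

    The linear predictor eta is Gaussian under the structural model; its
    variance comes from the covariance algebra.  b0 solves
    E[expit(b0 + eta)] = prevalence by Gauss-Hermite quadrature.
    """
    if config.outcome_type != OUTCOME_BINARY:
        raise ValueError("binary_link_stats applies to binary outcomes only")
    cov = model_covariance(config)
    sd = float(np.sqrt(cov.loc["y", "y"]))
    z = np.sqrt(2.0) * sd * _GH_NODES
    w = _GH_WEIGHTS / np.sqrt(np.pi)

    def mean_p(b0):
        return float(w @ expit(b0 + z)) - config.prevalence

    b0 = optimize.brentq(mean_p, -40, 40, xtol=1e-12)
    p = expit(b0 + z)
    kfac = float(w @ (p * (1 - p)))
    return b0, kfac


def rd_scale_factor(config: ScenarioConfig) -> float:
    """Factor mapping structural log-odds effects to risk-difference estimands.

    For jointly Gaussian regressors and linear predictor, Stein's lemma gives
    cov(Y, Z) = E[p(1-p)] * cov(eta, Z) for every linear combination Z of the
    model's Gaussian variables, so each linear or IV regression estimand on
    the binary outcome is exactly k times its structural counterpart.
    """
    return binary_link_stats(config)[1]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def gamma_for_target_f(
    f_target: float, n: int, residual_var: float = 1.0, n_instruments: int = 1
) -> float:
    """First-stage coefficient giving expected F of ``f_target``.

    Uses E[F] ~ 1 + n * gamma^2 * Var(score) / (q * Var(residual)) with a
    unit-variance instrument score spread over q instrument columns.
    """
    if f_target <= 1:
        raise ValueError("target F must exceed its null expectation of 1")
    return float(np.sqrt((f_target - 1) * n_instruments * residual_var / n))
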