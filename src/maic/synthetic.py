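"""Synthetic two-trial scenarios with known truth.

Emulates the standard population-adjustment setting: an AB trial providing
subject-level data and a (large) AC trial summarized into aggregate targets,
with populations that differ in effect-modifying covariates. Because the
outcome model is known, the true marginal contrast of C vs B **in the AC
population** — the estimand of an anchored population-adjusted comparison —
is available in closed form for gaussian outcomes and by seeded Monte Carlo
integration for binary (logistic) outcomes, so bias of adjusted and
unadjusted estimators can be measured exactly.

The outcome model is a generalized linear model on the natural link:

    η_i = β₀ + β'x_i + δ_k + γ_k' x_i ,   k ∈ {A, B, C}, δ_A = 0, γ_A = 0,

where nonzero interaction coefficients γ make the corresponding covariate
an effect modifier; between-trial differences in such covariates are
exactly what biases the standard indirect comparison and what MAIC
reweighting removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .comparison import adjusted_comparison, unadjusted_comparison
from .data_model import (
    ARM_A,
    ARM_B,
    AggregateTarget,
    CovariateTarget,
    IPDTable,
    Link,
    MomentSpec,
)
from .exceptions import ConfigError
from .moments import build_moment_matrix
from .weights import effective_sample_size

_TRUTH_DRAWS = 1_000_000  # Monte Carlo size for the logistic-truth integral


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate's distribution in each trial population.

    ``dist`` is ``"normal"`` (params ``{"mean": μ, "sd": σ}``) or
    ``"bernoulli"`` (params ``{"p": π}``); ``ab``/``ac`` give the per-trial
    parameters — their difference is the population imbalance under test.
    """

    name: str
    dist: str
    ab: Mapping[str, float]
    ac: Mapping[str, float]

    def __post_init__(self):
        if self.dist not in ("normal", "bernoulli"):
            raise ConfigError(
                f"covariate {self.name!r}: dist must be 'normal' or "
                f"'bernoulli', got {self.dist!r}"
            )
        for label, params in (("ab", self.ab), ("ac", self.ac)):
            if self.dist == "normal":
                if "mean" not in params or "sd" not in params:
                    raise ConfigError(
                        f"covariate {self.name!r} ({label}): normal needs "
                        "'mean' and 'sd'"
                    )
                if params["sd"] <= 0:
                    raise ConfigError(f"covariate {self.name!r}: sd must be > 0")
            else:
                p = params.get("p")
                if p is None or not 0.0 < p < 1.0:
                    raise ConfigError(
                        f"covariate {self.name!r} ({label}): bernoulli needs "
                        "'p' in (0, 1)"
                    )

    def draw(self, rng: np.random.Generator, n: int, trial: str) -> np.ndarray:
        params = self.ab if trial == "ab" else self.ac
        if self.dist == "normal":
            return rng.normal(params["mean"], params["sd"], size=n)
        return rng.binomial(1, params["p"], size=n).astype(float)


@dataclass(frozen=True)
class OutcomeModel:
    """GLM generating outcomes; interactions make covariates effect modifiers."""

    family: str  # "gaussian" | "bernoulli-logit"
    intercept: float
    main: Mapping[str, float] = field(default_factory=dict)
    effects: Mapping[str, float] = field(default_factory=dict)  # δ_B, δ_C
    interactions: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sigma_y: float = 1.0

    def __post_init__(self):
        if self.family not in ("gaussian", "bernoulli-logit"):
            raise ConfigError(
                f"outcome family must be 'gaussian' or 'bernoulli-logit', "
                f"got {self.family!r}"
            )
        if self.family == "gaussian" and self.sigma_y <= 0:
            raise ConfigError("sigma_y must be positive")
        for k in self.effects:
            if k not in ("B", "C"):
                raise ConfigError(f"treatment effects keyed by 'B'/'C'; got {k!r}")
        for k in self.interactions:
            if k not in ("B", "C"):
                raise ConfigError(f"interactions keyed by 'B'/'C'; got {k!r}")

    @property
    def link(self) -> Link:
        return Link.identity if self.family == "gaussian" else Link.logit

    def linear_predictor(self, X: pd.DataFrame, arm: str) -> np.ndarray:
        eta = np.full(len(X), self.intercept, dtype=float)
        for name, coef in self.main.items():
            eta += coef * X[name].to_numpy(dtype=float)
        if arm != "A":
            eta += self.effects.get(arm, 0.0)
            for name, coef in self.interactions.get(arm, {}).items():
                eta += coef * X[name].to_numpy(dtype=float)
        return eta

    def draw_outcome(
        self, rng: np.random.Generator, X: pd.DataFrame, arm: str
    ) -> np.ndarray:
        eta = self.linear_predictor(X, arm)
        if self.family == "gaussian":
            return eta + rng.normal(0.0, self.sigma_y, size=len(X))
        return rng.binomial(1, expit(eta)).astype(float)


@dataclass(frozen=True)
class ScenarioConfig:
    """A complete two-trial scenario: populations, outcome model, sizes."""

    n_ab: int
    n_ac: int
    covariates: tuple[CovariateSpec, ...]
    outcome: OutcomeModel
    seed: int = 0

    def __post_init__(self):
        if self.n_ab < 2:
            raise ConfigError(f"n_ab must be at least 2, got {self.n_ab}")
        if self.n_ac < 2:
            raise ConfigError(f"n_ac must be at least 2, got {self.n_ac}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate covariate names {names}")
        known = set(names)
        for name in self.outcome.main:
            if name not in known:
                raise ConfigError(f"outcome main effect on unknown covariate {name!r}")
        for arm, terms in self.outcome.interactions.items():
            for name in terms:
                if name not in known:
                    raise ConfigError(
                        f"interaction for arm {arm!r} on unknown covariate {name!r}"
                    )

    @property
    def is_effect_modified(self) -> bool:
        return any(
            any(v != 0 for v in terms.values())
            for terms in self.outcome.interactions.values()
        )

    # -- (de)serialization for the CLI ------------------------------------

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "ScenarioConfig":
        try:
            covs = tuple(
                CovariateSpec(
                    name=str(c["name"]), dist=str(c["dist"]),
                    ab=dict(c["ab"]), ac=dict(c["ac"]),
                )
                for c in doc["covariates"]
            )
            out = doc["outcome"]
            outcome = OutcomeModel(
                family=str(out["family"]),
                intercept=float(out.get("intercept", 0.0)),
                main={str(k): float(v) for k, v in (out.get("main") or {}).items()},
                effects={
                    str(k): float(v) for k, v in (out.get("effects") or {}).items()
                },
                interactions={
                    str(k): {str(n): float(v) for n, v in terms.items()}
                    for k, terms in (out.get("interactions") or {}).items()
                },
                sigma_y=float(out.get("sigma_y", 1.0)),
            )
            return cls(
                n_ab=int(doc["n_ab"]),
                n_ac=int(doc.get("n_ac", 100_000)),
                covariates=covs,
                outcome=outcome,
                seed=int(doc.get("seed", 0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid scenario config: {exc}") from exc

    def to_mapping(self) -> dict:
        return {
            "n_ab": self.n_ab,
            "n_ac": self.n_ac,
            "seed": self.seed,
            "covariates": [
                {"name": c.name, "dist": c.dist, "ab": dict(c.ab), "ac": dict(c.ac)}
                for c in self.covariates
            ],
            "outcome": {
                "family": self.outcome.family,
                "intercept": self.outcome.intercept,
                "main": dict(self.outcome.main),
                "effects": dict(self.outcome.effects),
                "interactions": {
                    k: dict(v) for k, v in self.outcome.interactions.items()
                },
                "sigma_y": self.outcome.sigma_y,
            },
        }


def default_demo_config(
    n_ab: int = 500, n_ac: int = 100_000, seed: int = 0, shift: float = 1.0
) -> ScenarioConfig:
    """Demo scenario: one shifted normal effect modifier, one balanced
    bernoulli covariate, logistic outcome.

    The AB population sits ``shift`` standard deviations above the AC
    population on the effect modifier ``x1``, whose interaction with
    treatment B (γ_B = −0.3) makes the naive indirect comparison biased.
    """
    return ScenarioConfig(
        n_ab=n_ab,
        n_ac=n_ac,
        seed=seed,
        covariates=(
            CovariateSpec(
                "x1", "normal",
                ab={"mean": shift, "sd": 1.0}, ac={"mean": 0.0, "sd": 1.0},
            ),
            CovariateSpec("sex", "bernoulli", ab={"p": 0.3}, ac={"p": 0.3}),
        ),
        outcome=OutcomeModel(
            family="bernoulli-logit",
            intercept=-0.5,
            main={"x1": 0.5, "sex": 0.3},
            effects={"B": -1.0, "C": -0.5},
            interactions={"B": {"x1": -0.3}},
        ),
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _split_arms(rng: np.random.Generator, n: int) -> np.ndarray:
    """1:1 randomized allocation (permuted block of the whole trial)."""
    half = n // 2
    alloc = np.array([0] * half + [1] * (n - half))
    rng.shuffle(alloc)
    return alloc


def true_contrast(
    config: ScenarioConfig,
    seed: int | None = None,
    n_draws: int = _TRUTH_DRAWS,
) -> dict:
    """Exact marginal contrasts in the AC population.

    Gaussian outcomes: closed form on the identity scale,
    d_BC = (δ_C − δ_B) + (γ_C − γ_B)'μ_AC. Logistic outcomes: the marginal
    log odds ratio logit(E_AC[p_C]) − logit(E_AC[p_B]) via an ``n_draws``
    Monte Carlo integral over the AC covariate distribution (marginal and
    conditional log odds ratios differ — non-collapsibility — so the
    estimand is deliberately the marginal one, matching what the weighted
    estimator targets).
    """
    model = config.outcome
    if model.family == "gaussian":
        mu_ac = {
            c.name: (c.ac["mean"] if c.dist == "normal" else c.ac["p"])
            for c in config.covariates
        }

        def marginal_lp(arm: str) -> float:
            val = model.intercept + sum(
                coef * mu_ac[name] for name, coef in model.main.items()
            )
            if arm != "A":
                val += model.effects.get(arm, 0.0)
                val += sum(
                    coef * mu_ac[name]
                    for name, coef in model.interactions.get(arm, {}).items()
                )
            return val

        d_ab = marginal_lp("B") - marginal_lp("A")
        d_ac = marginal_lp("C") - marginal_lp("A")
    else:
        rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
        X = pd.DataFrame(
            {c.name: c.draw(rng, n_draws, "ac") for c in config.covariates}
        )
        means = {
            arm: float(expit(model.linear_predictor(X, arm)).mean())
            for arm in ("A", "B", "C")
        }
        d_ab = float(logit(means["B"]) - logit(means["A"]))
        d_ac = float(logit(means["C"]) - logit(means["A"]))
    return {
        "d_AB": d_ab,
        "d_AC": d_ac,
        "d_BC": d_ac - d_ab,
        "link": model.link.value,
    }


def simulate_scenario(
    config: ScenarioConfig,
    compute_truth: bool = True,
) -> tuple[IPDTable, AggregateTarget, dict]:
    """Draw one AB trial (IPD) and one AC trial (summarized to aggregates).

    Returns the subject-level AB data, the AC trial reduced to an
    :class:`AggregateTarget` (covariate means/variances, d̂_AC on the
    natural link with its standard error, ȳ_C, n), and a truth record with
    the exact population contrasts in the AC population. Fully determined
    by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    # --- AB trial: subject-level ---
    X_ab = pd.DataFrame(
        {c.name: c.draw(rng, config.n_ab, "ab") for c in config.covariates}
    )
    alloc = _split_arms(rng, config.n_ab)
    arm_ab = np.where(alloc == 0, ARM_A, ARM_B)
    y_ab = np.empty(config.n_ab)
    for role in (ARM_A, ARM_B):
        mask = arm_ab == role
        y_ab[mask] = config.outcome.draw_outcome(rng, X_ab[mask], role)
    ipd = IPDTable.from_frame(
        pd.DataFrame(
            {
                "subject_id": [f"ab{i:06d}" for i in range(config.n_ab)],
                "arm": arm_ab,
                **{c.name: X_ab[c.name] for c in config.covariates},
                "outcome": y_ab,
            }
        ),
        [c.name for c in config.covariates],
    )

    # --- AC trial: simulated then summarized ---
    X_ac = pd.DataFrame(
        {c.name: c.draw(rng, config.n_ac, "ac") for c in config.covariates}
    )
    alloc_ac = _split_arms(rng, config.n_ac)
    arm_ac = np.where(alloc_ac == 0, "A", "C")
    y_ac = np.empty(config.n_ac)
    for role in ("A", "C"):
        mask = arm_ac == role
        y_ac[mask] = config.outcome.draw_outcome(rng, X_ac[mask], role)

    targets = []
    for c in config.covariates:
        x = X_ac[c.name].to_numpy(dtype=float)
        if c.dist == "bernoulli":
            targets.append(CovariateTarget(c.name, float(x.mean()), binary=True))
        else:
            targets.append(
                CovariateTarget(
                    c.name, float(x.mean()), variance=float(x.var(ddof=1))
                )
            )

    y_a, y_c = y_ac[arm_ac == "A"], y_ac[arm_ac == "C"]
    if config.outcome.family == "gaussian":
        d_ac = float(y_c.mean() - y_a.mean())
        se_ac = float(
            np.sqrt(y_a.var(ddof=1) / y_a.size + y_c.var(ddof=1) / y_c.size)
        )
    else:
        e_a, e_c = y_a.sum(), y_c.sum()
        d_ac = float(logit(y_c.mean()) - logit(y_a.mean()))
        se_ac = float(
            np.sqrt(
                1 / e_a + 1 / (y_a.size - e_a) + 1 / e_c + 1 / (y_c.size - e_c)
            )
        )
    target = AggregateTarget(
        covariate_targets=targets,
        reported_effect=d_ac,
        reported_effect_se=se_ac,
        link=config.outcome.link,
        n_target=config.n_ac,
        reported_absolute_outcome=float(y_c.mean()),
    )

    truth = true_contrast(config) if compute_truth else {}
    return ipd, target, truth


def make_base_weight_scenario(
    config: ScenarioConfig,
    sd_log: float = 0.5,
    compute_truth: bool = True,
) -> tuple[IPDTable, AggregateTarget, dict]:
    """Scenario variant with non-uniform per-subject base weights attached.

    Base weights are drawn log-normally (log-scale sd ``sd_log``) and
    normalized — a stand-in for a prior weighting step such as a
    treatment-switching adjustment whose output the entropy-balancing
    solver should stay close to. The truth record is unchanged.
    """
    ipd, target, truth = simulate_scenario(config, compute_truth=compute_truth)
    rng = np.random.default_rng(config.seed + 2_000_003)
    bw = rng.lognormal(mean=0.0, sigma=sd_log, size=ipd.n)
    data = ipd.data.assign(base_weight=bw / bw.sum())
    return IPDTable(data, ipd.covariate_names), target, truth


# ---------------------------------------------------------------------------
# Study harnesses
# ---------------------------------------------------------------------------

def replicate_bias_study(
    config: ScenarioConfig,
    n_reps: int = 500,
    seed: int = 0,
    spec: MomentSpec | None = None,
    method="entropy_balancing",
) -> dict:
    """Bias of the MAIC-adjusted vs the standard indirect comparison.

    Re-simulates the scenario ``n_reps`` times (fresh seeds spawned from
    ``seed``), estimating d_BC with MAIC weights and with uniform weights
    (the standard Bucher comparison), and reports mean estimates, absolute
    biases against the exact truth, Monte Carlo standard errors, and the
    mean effective sample size.
    """
    truth = true_contrast(config, seed=seed + 999_983)["d_BC"]
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    adjusted = np.empty(n_reps)
    unadjusted = np.empty(n_reps)
    ess = np.empty(n_reps)
    for r in range(n_reps):
        rep_config = replace(config, seed=int(seeds[r]))
        ipd, target, _ = simulate_scenario(rep_config, compute_truth=False)
        sol, res = adjusted_comparison(ipd, target, spec, method=method)
        adjusted[r] = res.d_BC
        unadjusted[r] = unadjusted_comparison(ipd, target).d_BC
        ess[r] = effective_sample_size(sol.weights)
    return {
        "truth": truth,
        "n_reps": n_reps,
        "mean_adjusted": float(adjusted.mean()),
        "mean_unadjusted": float(unadjusted.mean()),
        "bias_adjusted": float(abs(adjusted.mean() - truth)),
        "bias_unadjusted": float(abs(unadjusted.mean() - truth)),
        "mc_se_adjusted": float(adjusted.std(ddof=1) / np.sqrt(n_reps)),
        "mc_se_unadjusted": float(unadjusted.std(ddof=1) / np.sqrt(n_reps)),
        "mean_ess": float(ess.mean()),
    }


def random_moment_instance(
    n: int, p: int, seed: int = 0, binary_fraction: float = 0.4
):
    """Random feasible weighting instance for certification grids.

    Draws ``p`` covariates (a ``binary_fraction`` share bernoulli, the rest
    standard normal) for ``n`` subjects and sets the target means to a
    randomly tilted weighted sample mean, which is guaranteed to lie
    strictly inside the sample's convex hull. Returns the centered moment
    matrix built through the standard pipeline.
    """
    rng = np.random.default_rng(seed)
    n_bin = int(round(binary_fraction * p))
    cols = {}
    kinds = []
    for j in range(p):
        name = f"v{j}"
        if j < n_bin:
            pr = rng.uniform(0.2, 0.8)
            x = rng.binomial(1, pr, size=n).astype(float)
            while x.min() == x.max():  # need both levels present
                x = rng.binomial(1, pr, size=n).astype(float)
            kinds.append("bernoulli")
        else:
            x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2.0), size=n)
            kinds.append("normal")
        cols[name] = x
    X = pd.DataFrame(cols)
    tilt = rng.uniform(0.5, 1.5, size=n)
    tilt /= tilt.sum()
    targets = []
    for j, name in enumerate(X.columns):
        m = float(tilt @ X[name].to_numpy())
        targets.append(
            CovariateTarget(name, m, binary=(kinds[j] == "bernoulli"))
        )
    arm = np.where(np.arange(n) % 2 == 0, ARM_A, ARM_B)
    ipd = IPDTable.from_frame(
        pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)], "arm": arm, **cols}),
        list(X.columns),
        outcome=None,
    )
    target = AggregateTarget(covariate_targets=targets)
    return build_moment_matrix(ipd, target, MomentSpec.means(list(X.columns)))
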