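"""Population-adjusted indirect comparison estimators.

Given MAIC weights, mean outcomes on the IPD arms are estimated in the
aggregate-trial population by within-arm weighted averages,

    ŷ_k = Σ_{i∈arm k} y_i w_i / Σ_{i∈arm k} w_i ,

and contrasted on the link scale g:

* **anchored** (both trials share comparator A):
  d̂_AB = g(ŷ_B) − g(ŷ_A) and d̂_BC = d̂_AC − d̂_AB, where d̂_AC is the
  aggregate trial's reported relative effect. Randomization is preserved
  because only the relative effects are compared across trials.
* **unanchored** (single-arm or disconnected evidence):
  d̂_BC = g(ȳ_C) − g(ŷ_B), comparing absolute outcomes directly. This
  relies on the much stronger assumption that all prognostic factors — not
  just effect modifiers — are balanced by the weights, and every unanchored
  result carries a warning to that effect.

Uncertainty is estimated by a stratified nonparametric bootstrap that
re-solves the weights per replicate, so weight-estimation noise propagates
into the standard error; the aggregate trial's reported variance is added
on the assumption that the two trials are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit

from .data_model import ARM_A, ARM_B, AggregateTarget, IPDTable, Link, MomentSpec
from .exceptions import ConfigError, DataError, UsageError
from .moments import CenteredMomentMatrix, balance_table, build_moment_matrix
from .weights import Method, WeightSolution, effective_sample_size, solve_weights

logger = logging.getLogger("maic")

UNANCHORED_WARNING = (
    "Unanchored comparison: validity relies on the much stronger assumption "
    "that the weights balance ALL prognostic factors and effect modifiers "
    "between populations, not just the effect modifiers an anchored "
    "comparison requires."
)


def apply_link(value: float, link: Link | str) -> float:
    """Transform a mean outcome onto the analysis scale g(·)."""
    link = Link.parse(link)
    if link is Link.identity:
        return float(value)
    if link is Link.logit:
        if not 0.0 < value < 1.0:
            raise DataError(
                f"logit link requires a value in (0, 1); got {value!r}"
            )
        return float(logit(value))
    if link is Link.log:
        if value <= 0.0:
            raise DataError(f"log link requires a positive value; got {value!r}")
        return float(np.log(value))
    raise ConfigError(f"unhandled link {link!r}")  # pragma: no cover


def weighted_outcome(ipd: IPDTable, weights, arm: str) -> float:
    """Weighted mean outcome of one IPD arm (within-arm renormalization).

    Invariant to any common rescaling of the weight vector.
    """
    if arm not in (ARM_A, ARM_B):
        raise UsageError(f"arm must be 'A' or 'B', got {arm!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (ipd.n,):
        raise UsageError(f"weights must have length {ipd.n}")
    mask = ipd.arm == arm
    if not mask.any():
        raise DataError(f"arm {arm!r} has no subjects")
    mass = w[mask].sum()
    if not mass > 0 or not np.isfinite(mass):
        raise DataError(
            f"arm {arm!r} carries no weight mass — extreme imbalance between "
            "the IPD and the target population"
        )
    return float(np.sum(ipd.outcome[mask] * w[mask]) / mass)


@dataclass
class ComparisonResult:
    """A population-adjusted treatment contrast on the link scale."""

    d_BC: float
    mode: str  # "anchored" | "unanchored"
    link: Link
    y_hat_A: float | None = None
    y_hat_B: float | None = None
    d_AB_adjusted: float | None = None
    se_d_BC: float | None = None
    ci: tuple[float, float] | None = None
    ess: float | None = None
    warning: str | None = None

    def __post_init__(self):
        if self.ci is not None:
            lo, hi = self.ci
            if not lo <= self.d_BC <= hi:
                raise UsageError(
                    f"confidence interval {self.ci} does not bracket the "
                    f"point estimate {self.d_BC}"
                )

    def to_dict(self) -> dict:
        return {
            "d_BC": self.d_BC,
            "mode": self.mode,
            "link": self.link.value,
            "y_hat_A": self.y_hat_A,
            "y_hat_B": self.y_hat_B,
            "d_AB_adjusted": self.d_AB_adjusted,
            "se_d_BC": self.se_d_BC,
            "ci": list(self.ci) if self.ci is not None else None,
            "ess": self.ess,
            "warning": self.warning,
        }


def anchored_contrast(
    y_hat_A: float,
    y_hat_B: float,
    target: AggregateTarget,
    ess: float | None = None,
) -> ComparisonResult:
    """Anchored indirect comparison d̂_BC = d̂_AC − (g(ŷ_B) − g(ŷ_A))."""
    if target.reported_effect is None:
        raise ConfigError(
            "anchored comparison requires the aggregate trial's reported "
            "relative effect (effect.value in the target config)"
        )
    d_AB = apply_link(y_hat_B, target.link) - apply_link(y_hat_A, target.link)
    return ComparisonResult(
        d_BC=float(target.reported_effect - d_AB),
        mode="anchored",
        link=target.link,
        y_hat_A=float(y_hat_A),
        y_hat_B=float(y_hat_B),
        d_AB_adjusted=float(d_AB),
        ess=ess,
    )


def unanchored_contrast(
    y_hat_B: float,
    target: AggregateTarget,
    ess: float | None = None,
) -> ComparisonResult:
    """Unanchored comparison d̂_BC = g(ȳ_C) − g(ŷ_B) of absolute outcomes."""
    if target.reported_absolute_outcome is None:
        raise ConfigError(
            "unanchored comparison requires the aggregate trial's absolute "
            "outcome on C (absolute_outcome in the target config)"
        )
    d_BC = apply_link(target.reported_absolute_outcome, target.link) - apply_link(
        y_hat_B, target.link
    )
    logger.warning(UNANCHORED_WARNING)
    return ComparisonResult(
        d_BC=float(d_BC),
        mode="unanchored",
        link=target.link,
        y_hat_B=float(y_hat_B),
        ess=ess,
        warning=UNANCHORED_WARNING,
    )


def adjusted_comparison(
    ipd: IPDTable,
    target: AggregateTarget,
    spec: MomentSpec | None = None,
    *,
    method: Method = "entropy_balancing",
    mode: str = "anchored",
    base_weights=None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[WeightSolution, ComparisonResult]:
    """Full MAIC point-estimation pipeline: moments → weights → contrast."""
    mm = build_moment_matrix(ipd, target, spec)
    bw = ipd.base_weight if base_weights is None else base_weights
    solution = solve_weights(
        mm, method=method, base_weights=bw, tol=tol, max_iter=max_iter
    )
    ess = effective_sample_size(solution.weights)
    if mode == "anchored":
        y_a = weighted_outcome(ipd, solution.weights, ARM_A)
        y_b = weighted_outcome(ipd, solution.weights, ARM_B)
        result = anchored_contrast(y_a, y_b, target, ess=ess)
    elif mode == "unanchored":
        y_b = weighted_outcome(ipd, solution.weights, ARM_B)
        result = unanchored_contrast(y_b, target, ess=ess)
    else:
        raise UsageError(f"mode must be 'anchored' or 'unanchored', got {mode!r}")
    return solution, result


def unadjusted_comparison(
    ipd: IPDTable, target: AggregateTarget, mode: str = "anchored"
) -> ComparisonResult:
    """Standard (Bucher) indirect comparison with uniform weights."""
    uniform = np.full(ipd.n, 1.0 / ipd.n)
    if mode == "anchored":
        return anchored_contrast(
            weighted_outcome(ipd, uniform, ARM_A),
            weighted_outcome(ipd, uniform, ARM_B),
            target,
            ess=float(ipd.n),
        )
    if mode == "unanchored":
        return unanchored_contrast(
            weighted_outcome(ipd, uniform, ARM_B), target, ess=float(ipd.n)
        )
    raise UsageError(f"mode must be 'anchored' or 'unanchored', got {mode!r}")


# ---------------------------------------------------------------------------
# Bootstrap uncertainty
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Bootstrap SE and percentile interval for the adjusted contrast."""

    se: float
    se_boot: float
    ci: tuple[float, float]
    conf_level: float
    n_boot: int
    n_failed: int
    replicates: np.ndarray = field(repr=False)

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.n_boot

    def to_dict(self) -> dict:
        return {
            "se": self.se,
            "se_boot": self.se_boot,
            "ci": list(self.ci),
            "conf_level": self.conf_level,
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "failure_fraction": self.failure_fraction,
        }


def bootstrap_uncertainty(
    ipd: IPDTable,
    target: AggregateTarget,
    spec: MomentSpec | None = None,
    *,
    method: Method = "entropy_balancing",
    mode: str = "anchored",
    n_boot: int = 1000,
    seed: int = 0,
    conf_level: float = 0.95,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> BootstrapResult:
    """Stratified nonparametric bootstrap of the adjusted contrast.

    Subjects are resampled with replacement within each arm; the weights and
    contrast are re-estimated per replicate. Replicates where the solver
    fails (infeasible resample, no convergence, empty weight mass) are
    dropped and counted; more than 20% failures aborts with a diagnosis of
    poor population overlap. In anchored mode the aggregate trial's reported
    variance is added to the bootstrap variance (independent trials), and
    the percentile interval draws the reported effect per replicate from
    N(d̂_AC, se_AC²) so both noise sources enter the interval.
    """
    if n_boot < 100:
        raise UsageError(f"n_boot must be at least 100, got {n_boot}")
    if not 0.0 < conf_level < 1.0:
        raise UsageError("conf_level must be in (0, 1)")
    if mode not in ("anchored", "unanchored"):
        raise UsageError(f"mode must be 'anchored' or 'unanchored', got {mode!r}")

    # one full-data build to fix the matched moment functions and centers
    mm_full = build_moment_matrix(ipd, target, spec)
    M = mm_full.Z + mm_full.centers  # raw per-subject moment functions
    y = ipd.outcome
    bw = ipd.base_weight
    arm = ipd.arm
    idx_a = np.flatnonzero(arm == ARM_A)
    idx_b = np.flatnonzero(arm == ARM_B)
    if mode == "anchored" and target.reported_effect is None:
        raise ConfigError("anchored bootstrap requires a reported effect")
    if mode == "unanchored" and target.reported_absolute_outcome is None:
        raise ConfigError("unanchored bootstrap requires an absolute outcome")

    rng = np.random.default_rng(seed)
    replicates = np.empty(n_boot)
    n_failed = 0
    n_kept = 0
    for _ in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx_a, size=idx_a.size, replace=True),
                rng.choice(idx_b, size=idx_b.size, replace=True),
            ]
        )
        Zr = M[take] - mm_full.centers
        # feasibility of the resample: every centered column must straddle 0
        if Zr.shape[1] and not (
            np.all(Zr.min(axis=0) < 0) and np.all(Zr.max(axis=0) > 0)
        ):
            n_failed += 1
            continue
        try:
            sol = solve_weights(
                Zr, method=method, base_weights=bw[take], tol=tol,
                max_iter=max_iter,
            )
            w = sol.weights
            na = idx_a.size
            if mode == "anchored":
                y_a = np.sum(y[take[:na]] * w[:na]) / w[:na].sum()
                y_b = np.sum(y[take[na:]] * w[na:]) / w[na:].sum()
                stat = apply_link(y_b, target.link) - apply_link(y_a, target.link)
            else:
                y_b = np.sum(y[take[na:]] * w[na:]) / w[na:].sum()
                stat = apply_link(y_b, target.link)
        except Exception:
            n_failed += 1
            continue
        replicates[n_kept] = stat
        n_kept += 1

    if n_failed / n_boot > 0.20:
        raise DataError(
            f"{n_failed}/{n_boot} bootstrap replicates failed — population "
            "overlap too poor for stable adjustment"
        )
    reps = replicates[:n_kept]

    se_ac = target.reported_effect_se
    if mode == "anchored":
        d_bc_reps = float(target.reported_effect) - reps
        se_boot = float(reps.std(ddof=1)) if n_kept > 1 else 0.0
        if se_ac is not None:
            se = float(np.hypot(se_boot, se_ac))
            d_bc_reps = d_bc_reps + se_ac * rng.standard_normal(n_kept)
        else:
            se = se_boot
    else:
        g_c = apply_link(target.reported_absolute_outcome, target.link)
        d_bc_reps = g_c - reps
        se_boot = float(reps.std(ddof=1)) if n_kept > 1 else 0.0
        se = se_boot

    a = (1.0 - conf_level) / 2.0
    lo, hi = np.quantile(d_bc_reps, [a, 1.0 - a])
    return BootstrapResult(
        se=se,
        se_boot=se_boot,
        ci=(float(lo), float(hi)),
        conf_level=conf_level,
        n_boot=n_boot,
        n_failed=n_failed,
        replicates=d_bc_reps,
    )


__all__ = [
    "UNANCHORED_WARNING",
    "ComparisonResult",
    "BootstrapResult",
    "apply_link",
    "weighted_outcome",
    "anchored_contrast",
    "unanchored_contrast",
    "adjusted_comparison",
    "unadjusted_comparison",
    "bootstrap_uncertainty",
]
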