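"""Centered moment matrix construction.

Both weight-estimation objectives operate on per-subject moment functions
centered at the aggregate-trial targets, so that a weighted sample whose
moments equal the targets has weighted column means of exactly zero:

* mean matching for covariate x contributes the column ``x_i − μ_target``;
* variance matching contributes ``x_i² − (σ²_target + μ²_target)``, the
  squared covariate centered at the target's *second raw moment*. Centering
  x² at σ² + μ² (rather than centering squared deviations at σ²) keeps every
  constraint linear in the weights, which is what makes the exponential-
  tilting objectives convex with a unique optimum.

Feasibility is checked up front: nonnegative weights can only move a
weighted mean inside the convex hull of the sample, so a target outside
``[min x, max x]`` (strictly, outside the open interval unless the covariate
is constant at the target) is rejected here rather than surfacing later as
solver divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AggregateTarget, IPDTable, MomentSpec
from .exceptions import DataError, FeasibilityError

logger = logging.getLogger("maic")


@dataclass
class CenteredMomentMatrix:
    """Per-subject moment functions centered at the aggregate targets.

    Attributes
    ----------
    Z
        N × p array; row i holds subject i's centered moment functions.
    column_labels
        Names like ``"age.mean"``, ``"age.var"``, ``"sex.mean"``.
    target_record
        The :class:`AggregateTarget` used for centering.
    centers
        The target raw moments subtracted from each column (μ for mean
        columns, σ² + μ² for variance columns).
    column_scale
        Sample standard deviation of each column, used internally to
        standardize the solver's coordinates; weights are invariant to it.
    """

    Z: np.ndarray
    column_labels: tuple[str, ...]
    target_record: AggregateTarget
    centers: np.ndarray
    column_scale: np.ndarray

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def p(self) -> int:
        return self.Z.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, columns=list(self.column_labels))


def _check_column(values: np.ndarray, center: float, label: str) -> bool:
    """Validate one centered column; return False if it should be dropped
    (covariate constant at the target — trivially balanced)."""
    centered = values - center
    if np.ptp(values) == 0.0:
        if centered[0] == 0.0:
            logger.warning(
                "moment %s is constant and already equals its target; "
                "dropping it as trivially balanced", label,
            )
            return False
        raise DataError(
            f"moment {label!r} is constant in the IPD and cannot be "
            "balanced; drop it or fix the data"
        )
    lo, hi = values.min(), values.max()
    if not lo < center < hi:
        raise FeasibilityError(
            f"moment {label!r}: target value {center!r} lies outside the "
            f"open sample range ({lo!r}, {hi!r}); no strictly positive "
            "weights can achieve balance"
        )
    return True


def build_moment_matrix(
    ipd: IPDTable,
    target: AggregateTarget,
    spec: MomentSpec | None = None,
) -> CenteredMomentMatrix:
    """Build the centered moment matrix Z consumed by the weight solvers.

    ``spec`` defaults to matching means only, for every covariate in the
    target; pass :meth:`MomentSpec.means_and_variances` (or a custom spec)
    to additionally balance variances.
    """
    if spec is None:
        spec = MomentSpec.for_target(target, match_variances=False)
        logger.info(
            "no moment spec given; matching means only for %s", spec.names
        )
    spec.validate_against(target)
    missing = [n for n in target.names if n not in ipd.covariate_names]
    if missing:
        raise DataError(
            f"aggregate target names covariate(s) {missing} absent from the IPD"
        )

    columns, labels, centers = [], [], []
    for name, match_mean, match_variance in spec.entries:
        t = target.target_for(name)
        x = ipd.covariate(name)
        if match_mean:
            label = f"{name}.mean"
            if _check_column(x, t.mean, label):
                columns.append(x - t.mean)
                labels.append(label)
                centers.append(t.mean)
        if match_variance:
            label = f"{name}.var"
            second_moment = t.variance + t.mean**2
            if _check_column(x**2, second_moment, label):
                columns.append(x**2 - second_moment)
                labels.append(label)
                centers.append(second_moment)

    if columns:
        Z = np.column_stack(columns)
        scale = Z.std(axis=0, ddof=1)
    else:
        Z = np.empty((ipd.n, 0))
        scale = np.empty(0)
    return CenteredMomentMatrix(
        Z=Z,
        column_labels=tuple(labels),
        target_record=target,
        centers=np.asarray(centers, dtype=float),
        column_scale=scale,
    )


def balance_table(moment_matrix: CenteredMomentMatrix, weights: np.ndarray) -> pd.DataFrame:
    """Weighted raw moment vs target for each matched moment function.

    ``delta`` is the weighted mean of the centered column; at a converged
    solution every delta is ~0 (first-order condition of the objectives).
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    deltas = w @ moment_matrix.Z
    return pd.DataFrame(
        {
            "moment": list(moment_matrix.column_labels),
            "target": moment_matrix.centers,
            "weighted_value": moment_matrix.centers + deltas,
            "delta": deltas,
        }
    )
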