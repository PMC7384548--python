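"""Trial data structures for matching-adjusted indirect comparison.

Two sources of evidence enter a MAIC analysis:

* **Individual patient data (IPD)** from the trial comparing the common
  comparator A with treatment B — one row per subject with an arm label,
  covariate values, an outcome, and an optional base weight
  (:class:`IPDTable`).
* **Aggregate data** from the trial comparing A with treatment C — published
  covariate summaries (means, and variances for continuous covariates), the
  reported relative effect of C vs A on its link scale, and optionally the
  absolute outcome on C for unanchored comparisons (:class:`AggregateTarget`).

The IPD is reweighted so that its covariate moments match the aggregate
targets; :class:`MomentSpec` records which moments (means, and optionally
variances) are matched for each covariate.

Missing covariate values are a hard error everywhere: the weighting theory
assumes complete covariates, and imputation is a caller responsibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, DataError, ParseError, SchemaError

logger = logging.getLogger("maic")

#: Canonical arm roles. "A" is the common comparator shared (conceptually)
#: with the aggregate trial; "B" is the treatment only observed in the IPD.
ARM_A = "A"
ARM_B = "B"


class Link(str, Enum):
    """Scale on which relative effects are additive."""

    identity = "identity"
    logit = "logit"
    log = "log"

    @classmethod
    def parse(cls, value: "Link | str") -> "Link":
        if isinstance(value, Link):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ConfigError(
                f"unknown link {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class CovariateTarget:
    """Published summary of one covariate in the aggregate (AC) trial."""

    name: str
    mean: float
    variance: float | None = None
    binary: bool = False

    def __post_init__(self):
        if self.binary:
            if not 0.0 < self.mean < 1.0:
                raise ConfigError(
                    f"binary covariate {self.name!r}: target proportion "
                    f"{self.mean} must lie strictly in (0, 1)"
                )
            if self.variance is not None:
                raise ConfigError(
                    f"binary covariate {self.name!r}: a target variance is "
                    "redundant (it is a function of the proportion) and must "
                    "not be supplied"
                )
        elif self.variance is not None and self.variance <= 0:
            raise ConfigError(
                f"covariate {self.name!r}: target variance must be positive, "
                f"got {self.variance}"
            )


@dataclass
class AggregateTarget:
    """Aggregate-trial moments and reported effect used as matching targets.

    Parameters
    ----------
    covariate_targets
        One :class:`CovariateTarget` per matched covariate.
    reported_effect
        The AC trial's relative effect of C vs A (``d_AC``) on ``link`` scale.
    reported_effect_se
        Its standard error, if published.
    link
        Scale of ``reported_effect`` (identity, logit, log).
    n_target
        Aggregate-trial sample size, if published.
    reported_absolute_outcome
        Mean outcome on treatment C, required for unanchored comparisons.
    """

    covariate_targets: list[CovariateTarget]
    reported_effect: float | None = None
    reported_effect_se: float | None = None
    link: Link = Link.identity
    n_target: int | None = None
    reported_absolute_outcome: float | None = None

    def __post_init__(self):
        self.link = Link.parse(self.link)
        names = [t.name for t in self.covariate_targets]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate covariate targets in {names}")
        if self.reported_effect_se is not None and self.reported_effect_se <= 0:
            raise ConfigError("reported_effect_se must be positive")
        if self.n_target is not None and self.n_target <= 0:
            raise ConfigError("n_target must be a positive integer")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.covariate_targets]

    def target_for(self, name: str) -> CovariateTarget:
        for t in self.covariate_targets:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class MomentSpec:
    """Which moments to match, per covariate, in order.

    ``entries`` maps covariate name -> (match_mean, match_variance).
    Variance matching requires mean matching and is rejected for binary
    covariates (their variance is determined by the proportion).
    """

    entries: tuple[tuple[str, bool, bool], ...]

    def __post_init__(self):
        for name, match_mean, match_variance in self.entries:
            if match_variance and not match_mean:
                raise ConfigError(
                    f"covariate {name!r}: variance matching requires mean "
                    "matching"
                )

    @classmethod
    def means(cls, names: Sequence[str]) -> "MomentSpec":
        return cls(tuple((n, True, False) for n in names))

    @classmethod
    def means_and_variances(cls, names: Sequence[str]) -> "MomentSpec":
        return cls(tuple((n, True, True) for n in names))

    @classmethod
    def for_target(
        cls, target: AggregateTarget, match_variances: bool = False
    ) -> "MomentSpec":
        """Match every targeted covariate's mean, plus the variance wherever
        ``match_variances`` is set and the target publishes one."""
        entries = []
        for t in target.covariate_targets:
            mv = bool(match_variances and not t.binary and t.variance is not None)
            entries.append((t.name, True, mv))
        return cls(tuple(entries))

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def validate_against(self, target: AggregateTarget) -> None:
        for name, _, match_variance in self.entries:
            try:
                t = target.target_for(name)
            except KeyError:
                raise ConfigError(
                    f"moment spec names covariate {name!r} absent from the "
                    "aggregate target"
                ) from None
            if match_variance and t.binary:
                raise ConfigError(
                    f"binary covariate {name!r}: variance matching is "
                    "redundant and not allowed"
                )
            if match_variance and t.variance is None:
                raise ConfigError(
                    f"covariate {name!r}: variance matching requested but the "
                    "aggregate target has no variance"
                )


@dataclass
class IPDTable:
    """Validated subject-level data from the AB trial.

    ``data`` holds one row per subject with columns ``subject_id``, ``arm``
    (role labels "A"/"B"), the covariates, optionally ``outcome``, and
    ``base_weight`` (normalized to sum to 1; uniform unless supplied).
    """

    data: pd.DataFrame
    covariate_names: tuple[str, ...]

    def __post_init__(self):
        df = self.data
        for col in ("subject_id", "arm", "base_weight", *self.covariate_names):
            if col not in df.columns:
                raise SchemaError(f"IPDTable is missing column {col!r}")
        arms = set(df["arm"].unique())
        if not arms <= {ARM_A, ARM_B} or len(arms) != 2:
            raise DataError(
                f"exactly two arms required with roles {{A, B}}; got {sorted(arms)}"
            )
        if len(df) < 2:
            raise DataError("at least 2 subjects required")
        for name in self.covariate_names:
            col = df[name]
            if not np.issubdtype(col.dtype, np.number):
                raise ParseError(f"covariate {name!r} is not numeric")
            if col.isna().any():
                bad = df.loc[col.isna(), "subject_id"].tolist()
                raise DataError(
                    f"missing values in covariate {name!r} for subjects {bad}; "
                    "covariates must be complete (imputation is a caller "
                    "responsibility)"
                )
        if self.has_outcome and df["outcome"].isna().any():
            bad = df.loc[df["outcome"].isna(), "subject_id"].tolist()
            raise DataError(f"missing outcome for subjects {bad}")
        bw = df["base_weight"].to_numpy(dtype=float)
        if np.any(~np.isfinite(bw)) or np.any(bw <= 0):
            raise DataError("base weights must be finite and strictly positive")
        # store normalized: rescaling base weights by any constant is a no-op
        # (skip the division when already normalized so round-trips are exact)
        if abs(bw.sum() - 1.0) > 1e-12:
            bw = bw / bw.sum()
        self.data = df.assign(base_weight=bw).reset_index(drop=True)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        covariate_names: Sequence[str],
        outcome: str | None = "outcome",
    ) -> "IPDTable":
        df = df.copy()
        if "base_weight" not in df.columns:
            df["base_weight"] = 1.0 / len(df) if len(df) else 1.0
        if outcome is not None and outcome in df.columns and outcome != "outcome":
            df = df.rename(columns={outcome: "outcome"})
        return cls(df, tuple(covariate_names))

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def has_outcome(self) -> bool:
        return "outcome" in self.data.columns

    @property
    def arm(self) -> np.ndarray:
        return self.data["arm"].to_numpy()

    @property
    def outcome(self) -> np.ndarray:
        if not self.has_outcome:
            raise DataError("this IPDTable carries no outcome column")
        return self.data["outcome"].to_numpy(dtype=float)

    @property
    def base_weight(self) -> np.ndarray:
        return self.data["base_weight"].to_numpy(dtype=float)

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.covariate_names:
            raise KeyError(name)
        return self.data[name].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        return self.data[list(self.covariate_names)].to_numpy(dtype=float)

    def n_arm(self, role: str) -> int:
        return int((self.data["arm"] == role).sum())

    def to_csv(self, path: str | Path) -> None:
        cols = ["subject_id", "arm", *self.covariate_names]
        if self.has_outcome:
            cols.append("outcome")
        cols.append("base_weight")
        self.data[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

_DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "arm": "arm",
    "outcome": "outcome",
    "base_weight": "base_weight",
}


def read_ipd(path: str | Path, schema: Mapping) -> IPDTable:
    """Read subject-level trial data from a comma-delimited file.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8, decimal point).
    schema
        Mapping with keys:

        ``covariates``
            required list of covariate column names;
        ``subject_id``, ``arm``, ``outcome``, ``base_weight``
            column names (defaults ``subject_id``/``arm``/``outcome``/
            ``base_weight``; outcome and base_weight are optional columns);
        ``arm_roles``
            mapping ``{"A": <label>, "B": <label>}`` naming which arm label
            plays the common-comparator role A. Required unless the arm
            column already uses the literal labels "A" and "B".
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if "covariates" not in schema:
        raise SchemaError("schema must list the covariate columns")
    covariates = list(schema["covariates"])
    id_col = schema.get("subject_id", _DEFAULT_SCHEMA["subject_id"])
    arm_col = schema.get("arm", _DEFAULT_SCHEMA["arm"])
    outcome_col = schema.get("outcome", _DEFAULT_SCHEMA["outcome"])
    bw_col = schema.get("base_weight", _DEFAULT_SCHEMA["base_weight"])

    required = [id_col, arm_col, *covariates]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path} is missing required column(s) {missing}")
    if len(raw) < 2:
        raise DataError(f"{path}: at least 2 subjects required, got {len(raw)}")

    df = pd.DataFrame({"subject_id": raw[id_col].astype(str)})

    # arm labels -> roles
    labels = raw[arm_col].astype(str)
    observed = sorted(labels.unique())
    if len(observed) != 2:
        raise DataError(
            f"exactly two arms required; column {arm_col!r} has levels {observed}"
        )
    arm_roles = schema.get("arm_roles")
    if arm_roles is None:
        if set(observed) == {ARM_A, ARM_B}:
            arm_roles = {ARM_A: ARM_A, ARM_B: ARM_B}
        else:
            raise SchemaError(
                f"arm labels {observed} are not literal 'A'/'B'; the schema "
                "must map them to roles via arm_roles={'A': <common "
                "comparator label>, 'B': <treatment label>}"
            )
    if set(arm_roles) != {ARM_A, ARM_B} or set(arm_roles.values()) != set(observed):
        raise SchemaError(
            f"arm_roles {arm_roles} must map roles 'A' and 'B' onto the "
            f"observed labels {observed}"
        )
    label_to_role = {v: k for k, v in arm_roles.items()}
    df["arm"] = labels.map(label_to_role)

    # numeric columns, with cell-level diagnostics
    def parse_numeric(col_name: str, allow_missing: bool) -> pd.Series:
        cells = raw[col_name].str.strip()
        empty = cells == ""
        if empty.any() and not allow_missing:
            bad = df.loc[empty, "subject_id"].tolist()
            raise DataError(
                f"{path}: missing value(s) in column {col_name!r} for "
                f"subject(s) {bad}"
            )
        values = np.empty(len(cells))
        for row, cell in enumerate(cells):
            try:
                # Python's float() round-trips repr output exactly, unlike
                # pandas' fast approximate parser
                values[row] = float(cell) if cell else np.nan
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} in column "
                    f"{col_name!r} at data row {row}"
                ) from None
        return pd.Series(values, index=cells.index)

    for name in covariates:
        df[name] = parse_numeric(name, allow_missing=False)
    if outcome_col in raw.columns:
        df["outcome"] = parse_numeric(outcome_col, allow_missing=False)
    if bw_col in raw.columns:
        df["base_weight"] = parse_numeric(bw_col, allow_missing=False)

    return IPDTable.from_frame(df, covariates)


def read_target(path: str | Path) -> AggregateTarget:
    """Read an aggregate-target config from a YAML (or JSON) document.

    Expected layout::

        covariates:
          age: {mean: 55.0, variance: 64.0}
          sex: {mean: 0.4, binary: true}
        effect: {value: -0.5, se: 0.2}      # d_AC on the link scale
        link: logit                          # default identity, with warning
        n: 300                               # optional AC sample size
        absolute_outcome: 0.35               # optional, for unanchored mode
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return target_from_mapping(doc, origin=str(path))


def target_from_mapping(doc: Mapping, origin: str = "<config>") -> AggregateTarget:
    if "covariates" not in doc or not doc["covariates"]:
        raise ConfigError(f"{origin}: 'covariates' section is required")
    targets = []
    for name, entry in dict(doc["covariates"]).items():
        if not isinstance(entry, Mapping) or "mean" not in entry:
            raise ConfigError(
                f"{origin}: covariate {name!r} must be a mapping with a 'mean'"
            )
        targets.append(
            CovariateTarget(
                name=str(name),
                mean=float(entry["mean"]),
                variance=(
                    float(entry["variance"]) if entry.get("variance") is not None
                    else None
                ),
                binary=bool(entry.get("binary", False)),
            )
        )
    if "link" in doc and doc["link"] is not None:
        link = Link.parse(doc["link"])
    else:
        link = Link.identity
        logger.warning("%s: no link specified; defaulting to identity", origin)
    effect = doc.get("effect") or {}
    if effect and not isinstance(effect, Mapping):
        raise ConfigError(f"{origin}: 'effect' must be a mapping with value/se")
    return AggregateTarget(
        covariate_targets=targets,
        reported_effect=(
            float(effect["value"]) if effect.get("value") is not None else None
        ),
        reported_effect_se=(
            float(effect["se"]) if effect.get("se") is not None else None
        ),
        link=link,
        n_target=int(doc["n"]) if doc.get("n") is not None else None,
        reported_absolute_outcome=(
            float(doc["absolute_outcome"])
            if doc.get("absolute_outcome") is not None
            else None
        ),
    )


def target_to_mapping(target: AggregateTarget) -> dict:
    """Inverse of :func:`target_from_mapping` (round-trips exactly)."""
    cov = {}
    for t in target.covariate_targets:
        entry: dict = {"mean": float(t.mean)}
        if t.variance is not None:
            entry["variance"] = float(t.variance)
        if t.binary:
            entry["binary"] = True
        cov[t.name] = entry
    doc: dict = {"covariates": cov, "link": target.link.value}
    if target.reported_effect is not None or target.reported_effect_se is not None:
        doc["effect"] = {}
        if target.reported_effect is not None:
            doc["effect"]["value"] = float(target.reported_effect)
        if target.reported_effect_se is not None:
            doc["effect"]["se"] = float(target.reported_effect_se)
    if target.n_target is not None:
        doc["n"] = int(target.n_target)
    if target.reported_absolute_outcome is not None:
        doc["absolute_outcome"] = float(target.reported_absolute_outcome)
    return doc


def write_target(target: AggregateTarget, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(target_to_mapping(target), sort_keys=False),
        encoding="utf-8",
    )
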