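"""Rearrangement of expression tables into model-ready tensors.

An experiment is a normalized expression matrix (rows = features, columns =
samples) together with a design: ordered time points, condition names, an
optional control condition and a replicate count.  Each condition is
rearranged into a 3-D tensor ``features x replicates x time``, so that every
feature contributes one short observation sequence per condition.  The delta
transform then replaces expression levels by consecutive-time differences,
removing each feature's baseline offset: two profiles with the same shape but
different offsets become identical.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigurationError,
    DesignError,
    ValidationError,
)

REPLICATE_SUMMARIES = ("none", "mean", "median")

DEFAULT_SHUFFLE_SEED = 1729


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a time-course experiment.

    Parameters
    ----------
    time_points
        Strictly increasing numeric time labels, at least two.
    conditions
        Ordered condition names (at least one).
    replicates
        Biological replicates per condition (>= 1).
    control
        Name of the control condition, or ``None`` for single-condition
        mode.  When given it must be one of ``conditions`` and at least one
        non-control condition must exist.
    replicate_summary
        ``"none"`` keeps replicates as a multivariate observation;
        ``"mean"``/``"median"`` collapse them to one value per time point.
    """

    time_points: tuple[float, ...]
    conditions: tuple[str, ...]
    replicates: int
    control: str | None = None
    replicate_summary: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_points", tuple(float(t) for t in self.time_points))
        object.__setattr__(self, "conditions", tuple(str(c) for c in self.conditions))
        if len(self.time_points) < 2:
            raise DesignError("at least two time points are required")
        if np.any(np.diff(self.time_points) <= 0):
            raise DesignError("time points must be strictly increasing")
        if len(self.conditions) < 1:
            raise DesignError("at least one condition is required")
        if len(set(self.conditions)) != len(self.conditions):
            raise DesignError("condition names must be unique")
        if self.replicates < 1:
            raise DesignError("replicates must be a positive integer")
        if self.control is not None:
            if self.control not in self.conditions:
                raise DesignError(
                    f"control {self.control!r} is not one of the conditions"
                )
            if len(self.conditions) < 2:
                raise DesignError("a control requires at least two conditions")
        if self.replicate_summary not in REPLICATE_SUMMARIES:
            raise ConfigurationError(
                f"replicate_summary must be one of {REPLICATE_SUMMARIES}, "
                f"got {self.replicate_summary!r}"
            )

    @property
    def n_timepoints(self) -> int:
        return len(self.time_points)

    @property
    def n_deltas(self) -> int:
        """Length of a differenced sequence: one fewer than the time points."""
        return len(self.time_points) - 1

    @property
    def case_conditions(self) -> tuple[str, ...]:
        """Conditions other than the control (all of them if no control)."""
        if self.control is None:
            return self.conditions
        return tuple(c for c in self.conditions if c != self.control)


def _validate_block(values: np.ndarray, feature_ids: Sequence[str], what: str) -> None:
    if values.ndim != 3:
        raise ValidationError(f"{what} values must be 3-D, got ndim={values.ndim}")
    if len(feature_ids) != values.shape[0]:
        raise ValidationError(
            f"{what}: {len(feature_ids)} feature ids for {values.shape[0]} rows"
        )
    if len(set(feature_ids)) != len(feature_ids):
        raise ValidationError(f"{what}: duplicated feature ids")
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what}: non-finite or missing values present")


@dataclass(frozen=True)
class ConditionTensor:
    """Expression values for one condition: ``features x replicates x time``."""

    condition: str
    values: np.ndarray
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        _validate_block(self.values, self.feature_ids, f"condition {self.condition!r}")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class DeltaTensor:
    """Consecutive-time expression differences: ``features x replicates x (T-1)``."""

    condition: str
    deltas: np.ndarray
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", np.asarray(self.deltas, dtype=float))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        _validate_block(self.deltas, self.feature_ids, f"deltas {self.condition!r}")

    @property
    def n_features(self) -> int:
        return self.deltas.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.deltas.shape[1]

    @property
    def n_steps(self) -> int:
        return self.deltas.shape[2]

    def sequences(self) -> np.ndarray:
        """Per-feature observation sequences, shape ``(features, T-1, R)``."""
        return np.ascontiguousarray(self.deltas.transpose(0, 2, 1))


# ---------------------------------------------------------------------------
# table input/output
# ---------------------------------------------------------------------------

def _table_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read an expression table; first column holds feature identifiers."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_table_sep(path), index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"duplicated feature id {dup!r} in {path}")
    return frame


def read_column_map(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read a sample map with columns (sample, condition, time, replicate)."""
    if isinstance(source, pd.DataFrame):
        cmap = source.copy()
    else:
        path = Path(source)
        cmap = pd.read_csv(path, sep=_table_sep(path))
    required = {"sample", "condition", "time", "replicate"}
    missing = required - set(cmap.columns)
    if missing:
        raise DesignError(f"column map is missing columns: {sorted(missing)}")
    cmap["condition"] = cmap["condition"].astype(str)
    cmap["time"] = cmap["time"].astype(float)
    cmap["replicate"] = cmap["replicate"].astype(int)
    return cmap


def _numeric_column(frame: pd.DataFrame, sample: str) -> np.ndarray:
    col = frame[sample]
    numeric = pd.to_numeric(col, errors="coerce")
    bad = numeric.isna() & col.notna()
    if bad.any():
        row = col.index[bad][0]
        raise ValidationError(
            f"non-numeric entry at feature {row!r}, sample {sample!r}: "
            f"{col.loc[row]!r}"
        )
    if numeric.isna().any():
        row = col.index[numeric.isna()][0]
        raise ValidationError(
            f"missing value at feature {row!r}, sample {sample!r}; "
            "missing data are rejected, not imputed"
        )
    return numeric.to_numpy(dtype=float)


def load_expression(
    matrix_file: str | Path | pd.DataFrame,
    design: ExperimentDesign,
    column_map: str | Path | pd.DataFrame,
) -> list[ConditionTensor]:
    """Load and rearrange an expression table into per-condition tensors.

    Every ``(condition, time, replicate)`` cell of the design must map to
    exactly one sample column.  If conditions come with unequal replicate
    counts the replicates cannot form one fixed-width observation vector;
    in that case all conditions are collapsed to their per-time mean
    (``R = 1``) with a warning.
    """
    frame = matrix_file if isinstance(matrix_file, pd.DataFrame) else read_matrix(matrix_file)
    cmap = read_column_map(column_map)

    lookup: dict[tuple[str, float, int], str] = {}
    for rec in cmap.itertuples(index=False):
        key = (rec.condition, float(rec.time), int(rec.replicate))
        if key in lookup:
            raise DesignError(
                f"duplicated sample column for condition={key[0]!r}, "
                f"time={key[1]}, replicate={key[2]}"
            )
        lookup[key] = str(rec.sample)

    # replicate labels actually present per condition
    rep_labels: dict[str, tuple[int, ...]] = {}
    for cond in design.conditions:
        labels = sorted({r for (c, _, r) in lookup if c == cond})
        if not labels:
            raise DesignError(f"no samples mapped for condition {cond!r}")
        rep_labels[cond] = tuple(labels)

    counts = {cond: len(labels) for cond, labels in rep_labels.items()}
    uneven = len(set(counts.values())) > 1
    if not uneven and counts[design.conditions[0]] != design.replicates:
        raise DesignError(
            f"design declares {design.replicates} replicates but the column "
            f"map provides {counts[design.conditions[0]]}"
        )

    feature_ids = tuple(str(i) for i in frame.index)
    tensors: list[ConditionTensor] = []
    for cond in design.conditions:
        reps = rep_labels[cond]
        block = np.empty((len(feature_ids), len(reps), design.n_timepoints))
        for ri, rep in enumerate(reps):
            for ti, t in enumerate(design.time_points):
                key = (cond, t, rep)
                if key not in lookup:
                    raise DesignError(
                        f"no sample column for condition={cond!r}, time={t}, "
                        f"replicate={rep}"
                    )
                sample = lookup[key]
                if sample not in frame.columns:
                    raise DesignError(
                        f"sample {sample!r} (condition={cond!r}, time={t}, "
                        f"replicate={rep}) is not a column of the matrix"
                    )
                block[:, ri, ti] = _numeric_column(frame, sample)
        tensors.append(ConditionTensor(cond, block, feature_ids))

    if uneven:
        warnings.warn(
            "unequal replicate counts across conditions "
            f"({counts}); collapsing replicates to their mean (R=1)",
            stacklevel=2,
        )
        tensors = [summarize_replicates(t, "mean") for t in tensors]
    return tensors


def tensors_to_frame(
    tensors: Sequence[ConditionTensor], design: ExperimentDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten tensors back to a 2-D table plus its column map.

    Columns are ordered condition-major, then time, then replicate, and named
    ``{condition}_T{time_index}_R{replicate}``.  This is the exact inverse of
    :func:`load_expression` for the written column map.
    """
    columns: dict[str, np.ndarray] = {}
    records = []
    for tensor in tensors:
        for ti in range(tensor.n_timepoints):
            for ri in range(tensor.n_replicates):
                name = f"{tensor.condition}_T{ti}_R{ri + 1}"
                columns[name] = tensor.values[:, ri, ti]
                records.append(
                    {
                        "sample": name,
                        "condition": tensor.condition,
                        "time": design.time_points[ti],
                        "replicate": ri + 1,
                    }
                )
    frame = pd.DataFrame(columns, index=pd.Index(tensors[0].feature_ids, name="feature_id"))
    return frame, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def delta_transform(tensor: ConditionTensor) -> DeltaTensor:
    """Difference consecutive time points, removing each feature's offset."""
    if tensor.n_timepoints < 2:
        raise DesignError("delta transform requires at least two time points")
    deltas = np.diff(tensor.values, axis=2)
    return DeltaTensor(tensor.condition, deltas, tensor.feature_ids)


def summarize_replicates(tensor: ConditionTensor, method: str) -> ConditionTensor:
    """Collapse the replicate axis to its mean or median (returns R = 1)."""
    if method not in ("mean", "median"):
        raise ConfigurationError(
            f"replicate summary must be 'mean' or 'median', got {method!r}"
        )
    if tensor.n_replicates == 1:
        return tensor
    reducer = np.mean if method == "mean" else np.median
    values = reducer(tensor.values, axis=1, keepdims=True)
    return ConditionTensor(tensor.condition, values, tensor.feature_ids)


def shuffle_features(
    deltas: Sequence[DeltaTensor], seed: int = DEFAULT_SHUFFLE_SEED
) -> tuple[list[DeltaTensor], np.ndarray]:
    """Apply one seeded random permutation to every condition's feature axis.

    The same permutation is used for all conditions so that per-feature
    paths stay aligned across conditions.  Returns the shuffled tensors and
    the permutation; :func:`invert_permutation` maps results back to the
    original order.
    """
    if not deltas:
        raise AlignmentError("no delta tensors to shuffle")
    ids = deltas[0].feature_ids
    for d in deltas[1:]:
        if d.feature_ids != ids:
            raise AlignmentError(
                "feature ids differ between conditions; cannot shuffle jointly"
            )
    perm = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [
        DeltaTensor(d.condition, d.deltas[perm], tuple(ids[i] for i in perm))
        for d in deltas
    ]
    return shuffled, perm


def invert_permutation(perm: np.ndarray) -> np.ndarray:
    """Inverse of a permutation array: ``inv[perm] == arange(n)``."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return inv
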