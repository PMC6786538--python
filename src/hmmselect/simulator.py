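"""Synthetic two-condition time-course expression data with known truth.

The generator draws data from the same two-state model the pipeline fits.
Control-group features follow the all-N path (no change over time); a
configurable fraction of case-group features is perturbed, their state paths
sampled from a row-stochastic transition matrix conditioned on containing at
least one change state.  Given a path, each replicate's consecutive-time
differences are drawn independently from the state-conditional Gaussian
(sd 1.0 for change, 0.2 for no change by default); expression profiles are
rebuilt by cumulative summation from a random baseline offset and white
measurement noise is added per replicate.

The default transition matrix [[0.9, 0.1], [0.5, 0.5]] makes the no-change
state persistent and the change state transient, i.e. changes are sparse,
short excursions — started from the chain's stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .preprocessing import ConditionTensor, ExperimentDesign, tensors_to_frame


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; the defaults reproduce the reference design:

    10,000 transcripts, 6 time points, 3 replicates, 10% of case features
    perturbed, change/no-change emission standard deviations 1.0 / 0.2,
    white replicate noise of sd 0.1.
    """

    n_features: int = 10_000
    n_timepoints: int = 6
    n_replicates: int = 3
    frac_perturbed: float = 0.10
    sd_change: float = 1.0
    sd_nochange: float = 0.2
    replicate_noise_sd: float = 0.1
    transition: tuple[tuple[float, float], tuple[float, float]] = (
        (0.9, 0.1),
        (0.5, 0.5),
    )
    offset_range: tuple[float, float] = (2.0, 12.0)
    seed: int = 1729
    control_name: str = "control"
    case_name: str = "case"

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_timepoints < 2 or self.n_replicates < 1:
            raise ConfigurationError(
                "need n_features >= 1, n_timepoints >= 2, n_replicates >= 1"
            )
        if not 0.0 <= self.frac_perturbed <= 1.0:
            raise ConfigurationError("frac_perturbed must be in [0, 1]")
        if not self.sd_change > self.sd_nochange > 0:
            raise ConfigurationError("require sd_change > sd_nochange > 0")
        if self.replicate_noise_sd < 0:
            raise ConfigurationError("replicate_noise_sd must be >= 0")
        a = np.asarray(self.transition, dtype=float)
        if a.shape != (2, 2) or np.any(a < 0) or not np.allclose(a.sum(axis=1), 1.0):
            raise ConfigurationError("transition must be a 2x2 row-stochastic matrix")

    @property
    def design(self) -> ExperimentDesign:
        return ExperimentDesign(
            time_points=tuple(float(t) for t in range(self.n_timepoints)),
            conditions=(self.control_name, self.case_name),
            replicates=self.n_replicates,
            control=self.control_name,
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for scoring detection."""

    feature_ids: tuple[str, ...]
    has_change: np.ndarray  # bool per feature: any C in the case path
    true_paths: Mapping[str, tuple[str, ...]]  # condition -> per-feature paths

    def changed_ids(self) -> frozenset[str]:
        return frozenset(
            fid for fid, flag in zip(self.feature_ids, self.has_change) if flag
        )


@dataclass(frozen=True)
class DetectionResult:
    """Confusion counts plus the two headline rates.

    ``precision`` is ``None`` (undefined, distinct from 0) when nothing was
    selected.
    """

    sensitivity: float
    precision: float | None
    tp: int
    fp: int
    fn: int
    tn: int


def _stationary_distribution(transition: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eig(transition.T)
    idx = int(np.argmin(np.abs(evals - 1.0)))
    pi = np.real(evecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _sample_perturbed_paths(
    n: int, length: int, transition: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Markov-chain paths conditioned (by rejection) on >= 1 change state."""
    pi = _stationary_distribution(transition)
    out = np.empty((n, length), dtype=np.int8)
    got = 0
    while got < n:
        batch = max(n - got, 16)
        states = np.empty((batch, length), dtype=np.int8)
        states[:, 0] = rng.random(batch) < pi[1]
        for t in range(1, length):
            p_change = transition[states[:, t - 1], 1]
            states[:, t] = rng.random(batch) < p_change
        keep = states.any(axis=1)
        kept = states[keep][: n - got]
        out[got : got + len(kept)] = kept
        got += len(kept)
    return out


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[list[ConditionTensor], GroundTruth]:
    """Generate (control, case) tensors plus ground truth, all seeded.

    Which case features are perturbed is a seeded random subset of size
    ``round(frac_perturbed * n_features)``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    g, t, r = config.n_features, config.n_timepoints, config.n_replicates
    length = t - 1
    feature_ids = tuple(f"gene{i:05d}" for i in range(g))

    n_perturbed = int(round(config.frac_perturbed * g))
    perturbed = rng.choice(g, size=n_perturbed, replace=False)
    has_change = np.zeros(g, dtype=bool)
    has_change[perturbed] = True

    state_paths = {
        config.control_name: np.zeros((g, length), dtype=np.int8),
        config.case_name: np.zeros((g, length), dtype=np.int8),
    }
    if n_perturbed:
        state_paths[config.case_name][perturbed] = _sample_perturbed_paths(
            n_perturbed, length, np.asarray(config.transition, dtype=float), rng
        )

    sds = np.array([config.sd_nochange, config.sd_change])
    tensors: list[ConditionTensor] = []
    for cond in (config.control_name, config.case_name):
        # per-replicate deltas emitted independently from the state Gaussian
        step_sd = sds[state_paths[cond]]  # (G, L)
        deltas = rng.normal(0.0, 1.0, size=(g, r, length)) * step_sd[:, None, :]
        offsets = rng.uniform(*config.offset_range, size=(g, 1, 1))
        profiles = np.concatenate(
            [np.zeros((g, r, 1)), np.cumsum(deltas, axis=2)], axis=2
        )
        values = offsets + profiles
        if config.replicate_noise_sd > 0:
            values = values + rng.normal(0.0, config.replicate_noise_sd, size=(g, r, t))
        tensors.append(ConditionTensor(cond, values, feature_ids))

    truth = GroundTruth(
        feature_ids=feature_ids,
        has_change=has_change,
        true_paths={
            cond: tuple(
                "".join("C" if s else "N" for s in row) for row in state_paths[cond]
            )
            for cond in state_paths
        },
    )
    return tensors, truth


def evaluate_detection(
    selected: Sequence[str] | frozenset[str], truth: GroundTruth
) -> DetectionResult:
    """Sensitivity and precision of a selected feature set against truth."""
    if len(truth.feature_ids) == 0:
        raise ValidationError("ground truth is empty")
    selected_set = set(selected)
    unknown = selected_set - set(truth.feature_ids)
    if unknown:
        raise ValidationError(
            f"selected ids not present in the simulation: {sorted(unknown)[:5]}"
        )
    y_true = truth.has_change.astype(int)
    y_pred = np.array(
        [1 if fid in selected_set else 0 for fid in truth.feature_ids], dtype=int
    )
    from sklearn.metrics import confusion_matrix

    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else None
    return DetectionResult(
        sensitivity=float(sensitivity),
        precision=None if precision is None else float(precision),
        tp=int(tp),
        fp=int(fp),
        fn=int(fn),
        tn=int(tn),
    )


def write_dataset(
    outdir: str | Path,
    tensors: Sequence[ConditionTensor],
    truth: GroundTruth,
    design: ExperimentDesign,
) -> dict[str, Path]:
    """Write matrix.tsv, column_map.tsv and truth.tsv; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame, cmap = tensors_to_frame(tensors, design)
    matrix_path = outdir / "matrix.tsv"
    cmap_path = outdir / "column_map.tsv"
    truth_path = outdir / "truth.tsv"
    frame.to_csv(matrix_path, sep="\t")
    cmap.to_csv(cmap_path, sep="\t", index=False)
    truth_frame = pd.DataFrame(
        {
            "feature_id": list(truth.feature_ids),
            "has_change": truth.has_change.astype(int),
            **{
                f"true_path_{cond}": list(paths)
                for cond, paths in truth.true_paths.items()
            },
        }
    )
    truth_frame.to_csv(truth_path, sep="\t", index=False)
    return {"matrix": matrix_path, "column_map": cmap_path, "truth": truth_path}
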