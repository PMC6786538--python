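"""Flag relevant features by comparing decoded state paths across conditions.

With a control condition, a feature is relevant when its control path is the
null path (all ``N``) while at least one other condition's path contains a
change.  Features whose control path itself contains a change are excluded:
a change under control conditions means the observed dynamics cannot be
attributed to the treatment.  Without a control, any feature whose single
path contains a change is kept and flat features are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import AlignmentError, ConfigurationError, ShapeError
from .hmm import StatePath
from .preprocessing import ExperimentDesign

SELECTION_MODES = ("whole-path", "per-step")

# reasons attached to each SelectionResult
REASON_SELECTED = "control-flat-case-change"
REASON_FLAT = "flat-everywhere"
REASON_CONTROL = "control-changes"
REASON_SINGLE_CHANGE = "single-condition-change"
REASON_SINGLE_FLAT = "single-condition-flat"


@dataclass(frozen=True)
class SelectionResult:
    """Per-feature selection outcome with the paths that produced it."""

    feature_id: str
    relevant: bool
    paths: Mapping[str, StatePath]
    reason: str


def null_path(length: int) -> str:
    """The null hypothesis path: ``length`` consecutive no-change states."""
    if length < 1:
        raise ShapeError("a state path must have length >= 1")
    return "N" * length


def _check_paths(
    feature_id: str,
    condition_paths: Mapping[str, StatePath],
    design: ExperimentDesign,
) -> None:
    missing = set(design.conditions) - set(condition_paths)
    if missing:
        raise AlignmentError(
            f"feature {feature_id!r} has no decoded path for conditions {sorted(missing)}"
        )


def _classify_with_control(
    condition_paths: Mapping[str, StatePath],
    design: ExperimentDesign,
    mode: str,
) -> tuple[bool, str]:
    control = condition_paths[design.control].states
    case_states = [condition_paths[c].states for c in design.case_conditions]
    if mode == "whole-path":
        if "C" in control:
            return False, REASON_CONTROL
        if any("C" in s for s in case_states):
            return True, REASON_SELECTED
        return False, REASON_FLAT
    # per-step: a case change at step t counts only if the control is N at t
    hit = any(
        s[t] == "C" and control[t] == "N"
        for s in case_states
        for t in range(len(control))
    )
    if hit:
        return True, REASON_SELECTED
    if any("C" in s for s in case_states):
        return False, REASON_CONTROL
    return False, REASON_FLAT


def select_relevant(
    paths: Mapping[str, Mapping[str, StatePath]],
    design: ExperimentDesign,
    mode: str = "whole-path",
) -> list[SelectionResult]:
    """Classify every feature from its per-condition decoded paths.

    Parameters
    ----------
    paths
        Mapping ``feature_id -> condition -> StatePath``; every feature must
        have exactly one path per design condition.
    mode
        ``"whole-path"`` (default) requires the control path to be entirely
        flat; ``"per-step"`` counts a case change only at steps where the
        control is simultaneously flat.

    Results preserve the input feature order and each carries exactly one
    reason, so relevant + not-relevant counts always add up to the total.
    """
    if mode not in SELECTION_MODES:
        raise ConfigurationError(f"mode must be one of {SELECTION_MODES}, got {mode!r}")
    results: list[SelectionResult] = []
    for feature_id, condition_paths in paths.items():
        _check_paths(feature_id, condition_paths, design)
        if design.control is None:
            # single-condition (or uncontrolled multi-condition) mode:
            # discard flat features
            any_change = any("C" in condition_paths[c].states for c in design.conditions)
            relevant = any_change
            reason = REASON_SINGLE_CHANGE if any_change else REASON_SINGLE_FLAT
        else:
            relevant, reason = _classify_with_control(condition_paths, design, mode)
        results.append(
            SelectionResult(
                feature_id=feature_id,
                relevant=relevant,
                paths=dict(condition_paths),
                reason=reason,
            )
        )
    return results
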