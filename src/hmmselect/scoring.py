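"""Scores and ranking for selected features.

Three scores are computed per relevant feature, summed over all conditions:

* ``n_changes`` — number of decoded change states across time and
  conditions; more changes rank higher.
* ``magnitude`` — total absolute expression change, summed over conditions,
  time steps and replicates; larger ranks higher, so a feature with a single
  but very large change still scores well.
* ``replicate_score`` — total absolute deviation of replicates 2..R from
  replicate 1 over all time points (on the raw expression values, before
  differencing).  It measures replicate disagreement, so *smaller* is
  better; with one replicate it is identically zero.

No score combination weights are imposed: the default ranking is
lexicographic (changes desc, magnitude desc, replicate disagreement asc,
feature id), and per-score ranks are exposed so users can re-rank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import AlignmentError, ShapeError, ValidationError
from .hmm import StatePath

#: default lexicographic ranking policy: (field, direction) pairs applied in
#: order, with feature_id as the final deterministic tie-break.
DEFAULT_POLICY: tuple[tuple[str, str], ...] = (
    ("n_changes", "desc"),
    ("magnitude", "desc"),
    ("replicate_score", "asc"),
)


@dataclass(frozen=True)
class FeatureReport:
    """Scores (and, once ranked, the rank) for one relevant feature."""

    feature_id: str
    n_changes: int
    magnitude: float
    replicate_score: float
    rank: int = 0


def score_changes(paths: Iterable[StatePath]) -> int:
    """Count decoded change states over all conditions and time steps."""
    paths = list(paths)
    if not paths:
        raise ShapeError("no paths given")
    return sum(p.states.count("C") for p in paths)


def score_magnitude(delta_blocks: Iterable[np.ndarray]) -> float:
    """Sum of absolute delta values over conditions, steps and replicates."""
    blocks = [np.asarray(b, dtype=float) for b in delta_blocks]
    if not blocks:
        raise AlignmentError("no delta blocks given")
    return float(sum(np.abs(b).sum() for b in blocks))


def score_replicates(value_blocks: Iterable[np.ndarray]) -> float:
    """Total absolute deviation of replicates 2..R from replicate 1.

    Operates on raw (pre-difference) expression blocks of shape
    ``(R, T)``, one per condition; the replicate counts must agree across
    conditions.  Returns 0 when R = 1.
    """
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in value_blocks]
    if not blocks:
        raise AlignmentError("no value blocks given")
    if len({b.shape[0] for b in blocks}) > 1:
        raise AlignmentError("replicate counts differ across conditions")
    return float(sum(np.abs(b[0] - b[1:]).sum() for b in blocks))


def rank_features(
    reports: Sequence[FeatureReport],
    policy: Sequence[tuple[str, str]] = DEFAULT_POLICY,
) -> list[FeatureReport]:
    """Order reports by the ranking policy and assign 1-based ranks.

    The policy is a sequence of ``(field, "asc"|"desc")`` pairs applied
    lexicographically; ``feature_id`` ascending is always appended so the
    order is total and input order never matters.
    """
    ids = [r.feature_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate feature ids in ranking input")
    for field_name, direction in policy:
        if field_name not in ("n_changes", "magnitude", "replicate_score"):
            raise ValidationError(f"unknown ranking field {field_name!r}")
        if direction not in ("asc", "desc"):
            raise ValidationError(f"unknown ranking direction {direction!r}")

    def key(report: FeatureReport):
        parts = []
        for field_name, direction in policy:
            value = getattr(report, field_name)
            parts.append(-value if direction == "desc" else value)
        parts.append(report.feature_id)
        return tuple(parts)

    ordered = sorted(reports, key=key)
    return [replace(r, rank=i + 1) for i, r in enumerate(ordered)]


def per_score_ranks(reports: Sequence[FeatureReport]) -> dict[str, np.ndarray]:
    """1-based rank of each feature under each single score.

    Changes and magnitude rank descending (bigger is better), replicate
    disagreement ascending (smaller is better); ties share the minimum rank.
    """
    from scipy.stats import rankdata

    out: dict[str, np.ndarray] = {}
    for field_name, direction in DEFAULT_POLICY:
        values = np.array([getattr(r, field_name) for r in reports], dtype=float)
        if direction == "desc":
            values = -values
        out[field_name] = rankdata(values, method="min").astype(int)
    return out
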