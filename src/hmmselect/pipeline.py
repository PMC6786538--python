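"""End-to-end pipeline: load -> delta -> shuffle -> fit -> decode -> select
-> score -> rank, plus the report writers the CLI exposes.

The core entry point is :func:`run_core`, which works on in-memory tensors
(used by tests and the simulator-driven checks); :func:`run_pipeline` wraps
it with file input/output and artifact writing.  All randomness is seeded
through the configuration, so a rerun with the same config reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .errors import HmmSelectError
from .hmm import EMConfig, FitReport, StatePath, decode_tensor, em_fit
from .preprocessing import (
    ConditionTensor,
    DeltaTensor,
    DEFAULT_SHUFFLE_SEED,
    ExperimentDesign,
)
from .scoring import (
    DEFAULT_POLICY,
    FeatureReport,
    per_score_ranks,
    rank_features,
    score_changes,
    score_magnitude,
    score_replicates,
)
from .selection import SelectionResult, select_relevant

logger = logging.getLogger("hmmselect")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serialized next to its outputs."""

    matrix: str
    column_map: str
    design: ExperimentDesign
    outdir: str
    em: EMConfig = field(default_factory=EMConfig)
    shuffle_seed: int = DEFAULT_SHUFFLE_SEED
    selection_mode: str = "whole-path"
    ranking_policy: Sequence[tuple[str, str]] = DEFAULT_POLICY

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["design"] = dataclasses.asdict(self.design)
        doc["em"] = dataclasses.asdict(self.em)
        doc["ranking_policy"] = [list(p) for p in self.ranking_policy]
        return doc


@dataclass
class CoreResult:
    """In-memory outcome of one pipeline run."""

    fit: FitReport
    paths: dict[str, dict[str, StatePath]]  # feature -> condition -> path
    selections: list[SelectionResult]
    reports: list[FeatureReport]  # ranked, relevant features only
    tensors: list[ConditionTensor]
    deltas: list[DeltaTensor]

    @property
    def relevant_ids(self) -> list[str]:
        return [s.feature_id for s in self.selections if s.relevant]


def run_core(
    tensors: Sequence[ConditionTensor],
    design: ExperimentDesign,
    em_config: EMConfig | None = None,
    shuffle_seed: int = DEFAULT_SHUFFLE_SEED,
    selection_mode: str = "whole-path",
    ranking_policy: Sequence[tuple[str, str]] = DEFAULT_POLICY,
) -> CoreResult:
    """Run fit/decode/select/score/rank on already-loaded tensors."""
    tensors = list(tensors)
    if design.replicate_summary != "none":
        tensors = [
            prep.summarize_replicates(t, design.replicate_summary) for t in tensors
        ]
    deltas = [prep.delta_transform(t) for t in tensors]
    logger.info(
        "delta transform: %d features, %d conditions, %d steps",
        deltas[0].n_features,
        len(deltas),
        deltas[0].n_steps,
    )

    shuffled, _ = prep.shuffle_features(deltas, seed=shuffle_seed)
    fit = em_fit(shuffled, em_config)
    logger.info(
        "EM fit: %d sequences, %d iterations, converged=%s, loglik=%.3f",
        fit.n_sequences,
        fit.iterations,
        fit.converged,
        fit.log_likelihood_trace[-1],
    )

    feature_ids = deltas[0].feature_ids
    paths: dict[str, dict[str, StatePath]] = {fid: {} for fid in feature_ids}
    for delta in deltas:
        for path in decode_tensor(fit.parameters, delta):
            paths[path.feature_id][path.condition] = path

    selections = select_relevant(paths, design, mode=selection_mode)
    relevant = [s for s in selections if s.relevant]
    logger.info("selection: %d of %d features relevant", len(relevant), len(selections))

    index = {fid: i for i, fid in enumerate(feature_ids)}
    reports = []
    for sel in relevant:
        g = index[sel.feature_id]
        reports.append(
            FeatureReport(
                feature_id=sel.feature_id,
                n_changes=score_changes(sel.paths.values()),
                magnitude=score_magnitude(d.deltas[g] for d in deltas),
                replicate_score=score_replicates(t.values[g] for t in tensors),
            )
        )
    ranked = rank_features(reports, ranking_policy)
    return CoreResult(fit, paths, selections, ranked, tensors, deltas)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def selection_frame(result: CoreResult, design: ExperimentDesign) -> pd.DataFrame:
    rows = []
    for sel in result.selections:
        row = {"feature_id": sel.feature_id, "relevant": int(sel.relevant), "reason": sel.reason}
        for cond in design.conditions:
            row[f"path_{cond}"] = sel.paths[cond].states
        rows.append(row)
    return pd.DataFrame(rows)


def ranked_frame(result: CoreResult, design: ExperimentDesign) -> pd.DataFrame:
    columns = [
        "feature_id",
        "rank",
        "n_changes",
        "magnitude",
        "replicate_score",
        "rank_changes",
        "rank_magnitude",
        "rank_replicates",
        *(f"path_{cond}" for cond in design.conditions),
    ]
    if not result.reports:
        return pd.DataFrame(columns=columns)
    single = per_score_ranks(result.reports)
    rows = []
    for i, rep in enumerate(result.reports):
        row = {
            "feature_id": rep.feature_id,
            "rank": rep.rank,
            "n_changes": rep.n_changes,
            "magnitude": rep.magnitude,
            "replicate_score": rep.replicate_score,
            "rank_changes": single["n_changes"][i],
            "rank_magnitude": single["magnitude"][i],
            "rank_replicates": single["replicate_score"][i],
        }
        for cond in design.conditions:
            row[f"path_{cond}"] = result.paths[rep.feature_id][cond].states
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline from files and write all artifacts.

    Returns the paths of ranked.tsv, selection.tsv, model.json,
    run_config.json and run.log.  On any stage failure the partially
    written outputs of this run are removed before the error propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {
        "ranked": outdir / "ranked.tsv",
        "selection": outdir / "selection.tsv",
        "model": outdir / "model.json",
        "run_config": outdir / "run_config.json",
        "log": outdir / "run.log",
    }

    handler = logging.FileHandler(artifacts["log"], mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        tensors = prep.load_expression(config.matrix, config.design, config.column_map)
        logger.info(
            "loaded %d features x %d conditions from %s",
            tensors[0].n_features,
            len(tensors),
            config.matrix,
        )
        result = run_core(
            tensors,
            config.design,
            em_config=config.em,
            shuffle_seed=config.shuffle_seed,
            selection_mode=config.selection_mode,
            ranking_policy=config.ranking_policy,
        )
        ranked_frame(result, config.design).to_csv(
            artifacts["ranked"], sep="\t", index=False
        )
        selection_frame(result, config.design).to_csv(
            artifacts["selection"], sep="\t", index=False
        )
        model_doc = result.fit.parameters.to_dict()
        model_doc["em"] = dataclasses.asdict(result.fit.config)
        model_doc["log_likelihood"] = result.fit.log_likelihood_trace[-1]
        model_doc["iterations"] = result.fit.iterations
        model_doc["converged"] = result.fit.converged
        model_doc["n_sequences"] = result.fit.n_sequences
        artifacts["model"].write_text(json.dumps(model_doc, indent=2) + "\n")
        artifacts["run_config"].write_text(
            json.dumps(config.to_dict(), indent=2) + "\n"
        )
    except HmmSelectError:
        handler.close()
        logger.removeHandler(handler)
        for path in artifacts.values():
            path.unlink(missing_ok=True)
        raise
    else:
        handler.close()
        logger.removeHandler(handler)
    return artifacts
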