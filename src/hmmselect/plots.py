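"""Small plotting helpers (EM trace, per-feature profiles)."""

from __future__ import annotations

import numpy as np

from .hmm import FitReport
from .preprocessing import ConditionTensor, ExperimentDesign


def plot_loglik_trace(fit: FitReport, ax=None):
    """Plot the per-iteration total log-likelihood of an EM fit."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(range(1, fit.iterations + 1), fit.log_likelihood_trace, marker=".")
    ax.set_xlabel("EM iteration")
    ax.set_ylabel("total log-likelihood")
    return ax


def plot_feature_profile(
    tensors: list[ConditionTensor],
    design: ExperimentDesign,
    feature_id: str,
    ax=None,
):
    """Plot one feature's replicate expression profiles per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    times = np.asarray(design.time_points)
    for tensor in tensors:
        g = tensor.feature_ids.index(feature_id)
        for r in range(tensor.n_replicates):
            ax.plot(
                times,
                tensor.values[g, r],
                alpha=0.6,
                label=tensor.condition if r == 0 else None,
            )
    ax.set_xlabel("time")
    ax.set_ylabel("expression")
    ax.set_title(feature_id)
    ax.legend()
    return ax
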