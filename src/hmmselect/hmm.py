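"""Two-state Gaussian hidden Markov model over expression differences.

The model has hidden states ``N`` (no relevant change, the null state) and
``C`` (relevant change).  Each state emits an R-dimensional vector — the
consecutive-time expression differences of the R biological replicates —
from a multivariate normal distribution.  Every feature in every condition
is one observation sequence of length T-1, and all sequences are pooled as
independent draws for parameter estimation, which is what lets the model be
fitted even when an experiment has very few samples.

Emission means are constrained to the zero vector by default: the model
describes the *magnitude* of expression change rather than expression level,
and fitted means on real data sit at zero anyway, so the constraint removes
parameters that small experiments cannot afford.  States are identified
after fitting by their dispersion: the state with the larger covariance
trace is labelled ``C``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .errors import ConfigurationError, NumericalError, ShapeError
from .preprocessing import DeltaTensor

STATES = ("N", "C")
_N, _C = 0, 1

_SIMPLEX_TOL = 1e-10


def _check_simplex(vec: np.ndarray, what: str) -> None:
    if np.any(vec < -_SIMPLEX_TOL) or abs(vec.sum() - 1.0) > _SIMPLEX_TOL:
        raise NumericalError(f"{what} is not a probability distribution: {vec}")


@dataclass(frozen=True)
class HMMParameters:
    """Parameters of the two-state model.

    ``initial`` and ``transition`` are over the fixed state order
    ``("N", "C")``; ``means`` is ``(2, R)`` and ``covariances`` ``(2, R, R)``
    with R the emission dimension (number of replicates, or 1 after
    replicate summarization).
    """

    initial: np.ndarray
    transition: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial", np.asarray(self.initial, dtype=float))
        object.__setattr__(self, "transition", np.asarray(self.transition, dtype=float))
        object.__setattr__(self, "means", np.atleast_2d(np.asarray(self.means, dtype=float)))
        cov = np.asarray(self.covariances, dtype=float)
        if cov.ndim == 1:  # scalar variances for R=1
            cov = cov.reshape(2, 1, 1)
        object.__setattr__(self, "covariances", cov)
        if self.initial.shape != (2,) or self.transition.shape != (2, 2):
            raise ShapeError("initial must be (2,) and transition (2, 2)")
        _check_simplex(self.initial, "initial distribution")
        for row in self.transition:
            _check_simplex(row, "transition row")
        r = self.means.shape[1]
        if self.means.shape != (2, r) or self.covariances.shape != (2, r, r):
            raise ShapeError("means must be (2, R) and covariances (2, R, R)")
        for k in range(2):
            c = self.covariances[k]
            if not np.allclose(c, c.T, atol=1e-8):
                raise NumericalError(f"covariance of state {STATES[k]} not symmetric")

    @property
    def n_dim(self) -> int:
        return self.means.shape[1]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": list(STATES),
            "initial": self.initial.tolist(),
            "transition": self.transition.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "HMMParameters":
        return cls(
            np.array(doc["initial"]),
            np.array(doc["transition"]),
            np.array(doc["means"]),
            np.array(doc["covariances"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "HMMParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class StatePath:
    """Decoded hidden-state sequence for one feature in one condition.

    ``states`` is a string over ``{"N", "C"}`` of length T-1;
    ``log_probability`` is the joint log-probability of the decoded path and
    the observations.
    """

    feature_id: str
    condition: str
    states: str
    log_probability: float

    def __post_init__(self) -> None:
        if len(self.states) < 1 or set(self.states) - set(STATES):
            raise ShapeError(f"invalid state string {self.states!r}")

    @property
    def n_changes(self) -> int:
        return self.states.count("C")

    @property
    def is_flat(self) -> bool:
        return "C" not in self.states


@dataclass
class EMConfig:
    """Settings for Baum-Welch estimation.

    tol:
        stop when the relative log-likelihood improvement drops below this.
    restarts:
        number of independently initialized runs; the best final
        log-likelihood wins.  Restart 0 uses the deterministic default
        initialization, later restarts jitter it with seeded noise.
    zero_mean:
        constrain emission means to the zero vector (the default model).
    covariance:
        "full" or "diag" emission covariance over replicates.
    """

    tol: float = 1e-6
    max_iter: int = 500
    restarts: int = 3
    seed: int = 1729
    zero_mean: bool = True
    covariance: str = "full"
    var_floor: float = 1e-8
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        if self.covariance not in ("full", "diag"):
            raise ConfigurationError(
                f"covariance must be 'full' or 'diag', got {self.covariance!r}"
            )
        if self.tol <= 0 or self.max_iter < 1 or self.restarts < 1:
            raise ConfigurationError("tol, max_iter and restarts must be positive")


@dataclass
class FitReport:
    """Outcome of one EM fit (best restart)."""

    parameters: HMMParameters
    log_likelihood_trace: list[float]
    iterations: int
    converged: bool
    n_sequences: int
    config: EMConfig = field(repr=False, default_factory=EMConfig)


@dataclass(frozen=True)
class ForwardBackwardResult:
    """Posterior quantities for one observation sequence."""

    gamma: np.ndarray  # (L, 2) per-step state posteriors
    xi: np.ndarray  # (L-1, 2, 2) pairwise transition posteriors
    log_likelihood: float


# ---------------------------------------------------------------------------
# emission densities
# ---------------------------------------------------------------------------

def _as_sequences(x: np.ndarray, r: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None] if r == 1 else x[None, :]
    if x.ndim != 2 or x.shape[1] != r:
        raise ShapeError(f"expected an (L, {r}) observation block, got {x.shape}")
    if x.shape[0] < 1:
        raise ShapeError("observation sequence must have length >= 1")
    return x


def _log_emissions(params: HMMParameters, flat: np.ndarray) -> np.ndarray:
    """Log emission densities for a flat (n, R) array -> (n, 2)."""
    out = np.empty((flat.shape[0], 2))
    for k in range(2):
        try:
            out[:, k] = multivariate_normal.logpdf(
                flat, mean=params.means[k], cov=params.covariances[k]
            )
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
            raise NumericalError(
                f"covariance of state {STATES[k]} is not positive definite"
            ) from exc
    return out


def emission_logdensity(
    params: HMMParameters, observation: np.ndarray, state: str
) -> float:
    """Log-density of one R-vector under a state's emission Gaussian."""
    if state not in STATES:
        raise ConfigurationError(f"state must be 'N' or 'C', got {state!r}")
    obs = np.atleast_1d(np.asarray(observation, dtype=float))
    if obs.shape != (params.n_dim,):
        raise ShapeError(
            f"observation has dimension {obs.shape}, emission expects ({params.n_dim},)"
        )
    k = STATES.index(state)
    return float(
        multivariate_normal.logpdf(obs, mean=params.means[k], cov=params.covariances[k])
    )


# ---------------------------------------------------------------------------
# forward-backward (log-space, vectorized over a batch of sequences)
# ---------------------------------------------------------------------------

def _batch_log_emissions(params: HMMParameters, x: np.ndarray) -> np.ndarray:
    s, length, r = x.shape
    return _log_emissions(params, x.reshape(s * length, r)).reshape(s, length, 2)


def _batch_forward(log_pi, log_a, log_b):
    s, length, k = log_b.shape
    log_alpha = np.empty((s, length, k))
    log_alpha[:, 0] = log_pi[None, :] + log_b[:, 0]
    for t in range(1, length):
        trans = log_alpha[:, t - 1, :, None] + log_a[None, :, :]
        log_alpha[:, t] = logsumexp(trans, axis=1) + log_b[:, t]
    return log_alpha, logsumexp(log_alpha[:, -1], axis=1)


def _batch_backward(log_a, log_b):
    s, length, k = log_b.shape
    log_beta = np.zeros((s, length, k))
    for t in range(length - 2, -1, -1):
        nxt = log_a[None, :, :] + (log_b[:, t + 1] + log_beta[:, t + 1])[:, None, :]
        log_beta[:, t] = logsumexp(nxt, axis=2)
    return log_beta


def _batch_posteriors(params: HMMParameters, x: np.ndarray):
    """gamma (S,L,2), xi (S,L-1,2,2), loglik (S,) for a batch of sequences."""
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial)
        log_a = np.log(params.transition)
    log_b = _batch_log_emissions(params, x)
    log_alpha, loglik = _batch_forward(log_pi, log_a, log_b)
    log_beta = _batch_backward(log_a, log_b)
    log_gamma = log_alpha + log_beta - loglik[:, None, None]
    gamma = np.exp(log_gamma)
    length = x.shape[1]
    if length > 1:
        log_xi = (
            log_alpha[:, :-1, :, None]
            + log_a[None, None, :, :]
            + (log_b[:, 1:] + log_beta[:, 1:])[:, :, None, :]
            - loglik[:, None, None, None]
        )
        xi = np.exp(log_xi)
    else:
        xi = np.zeros((x.shape[0], 0, 2, 2))
    return gamma, xi, loglik


def forward_backward(
    params: HMMParameters, sequence: np.ndarray
) -> ForwardBackwardResult:
    """Posterior state and transition probabilities for one sequence.

    ``sequence`` is an (L, R) block of delta observations.  Posteriors are
    computed in log space and sum to one at every step.
    """
    x = _as_sequences(sequence, params.n_dim)[None, :, :]
    gamma, xi, loglik = _batch_posteriors(params, x)
    return ForwardBackwardResult(gamma[0], xi[0], float(loglik[0]))


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def _batch_viterbi(params: HMMParameters, x: np.ndarray):
    """Most probable paths for a batch; ties resolved in favour of N."""
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.initial)
        log_a = np.log(params.transition)
    log_b = _batch_log_emissions(params, x)
    s, length, k = log_b.shape
    score = log_pi[None, :] + log_b[:, 0]
    pointers = np.empty((s, length - 1, k), dtype=np.int8)
    for t in range(1, length):
        cand = score[:, :, None] + log_a[None, :, :]  # (S, prev, next)
        # ">=" keeps the null state N (index 0) on exact ties
        best_prev = np.where(cand[:, _N, :] >= cand[:, _C, :], _N, _C)
        pointers[:, t - 1] = best_prev
        score = np.take_along_axis(cand, best_prev[:, None, :], axis=1)[:, 0, :]
        score += log_b[:, t]
    last = np.where(score[:, _N] >= score[:, _C], _N, _C)
    logp = np.take_along_axis(score, last[:, None], axis=1)[:, 0]
    paths = np.empty((s, length), dtype=np.int8)
    paths[:, -1] = last
    for t in range(length - 2, -1, -1):
        paths[:, t] = np.take_along_axis(
            pointers[:, t], paths[:, t + 1][:, None], axis=1
        )[:, 0]
    return paths, logp


def _states_string(path: np.ndarray) -> str:
    return "".join(STATES[i] for i in path)


def viterbi_decode(
    params: HMMParameters,
    sequence: np.ndarray,
    feature_id: str = "",
    condition: str = "",
) -> StatePath:
    """Maximum-probability state path for one (L, R) observation block."""
    x = _as_sequences(sequence, params.n_dim)[None, :, :]
    paths, logp = _batch_viterbi(params, x)
    return StatePath(feature_id, condition, _states_string(paths[0]), float(logp[0]))


def decode_tensor(params: HMMParameters, deltas: DeltaTensor) -> list[StatePath]:
    """Viterbi-decode every feature of one condition's delta tensor."""
    x = deltas.sequences()
    if x.shape[2] != params.n_dim:
        raise ShapeError(
            f"delta tensor has R={x.shape[2]} but the model emits R={params.n_dim}"
        )
    paths, logp = _batch_viterbi(params, x)
    return [
        StatePath(fid, deltas.condition, _states_string(paths[g]), float(logp[g]))
        for g, fid in enumerate(deltas.feature_ids)
    ]


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _pool_sequences(deltas: Sequence[DeltaTensor]) -> np.ndarray:
    if not deltas:
        raise ShapeError("no delta tensors given")
    blocks = [d.sequences() for d in deltas]
    shapes = {b.shape[1:] for b in blocks}
    if len(shapes) > 1:
        raise ShapeError(f"conditions have inconsistent (T-1, R) shapes: {shapes}")
    return np.concatenate(blocks, axis=0)


def _floor_covariance(cov: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
    cov = (cov + cov.T) / 2.0
    evals, evecs = np.linalg.eigh(cov)
    if np.all(evals >= floor):
        return cov, False
    evals = np.maximum(evals, floor)
    return (evecs * evals) @ evecs.T, True


def _initial_parameters(
    x: np.ndarray, config: EMConfig, rng: np.random.Generator | None
) -> HMMParameters:
    r = x.shape[2]
    pooled_var = max(float(np.var(x)), config.var_floor)
    scales = np.array([0.25, 2.0]) * pooled_var
    transition = np.array([[0.9, 0.1], [0.1, 0.9]])
    initial = np.array([0.5, 0.5])
    if rng is not None:  # jittered restart
        scales = scales * np.exp(rng.normal(0.0, 0.5, size=2))
        transition = transition + rng.uniform(0.0, 0.2, size=(2, 2))
        transition /= transition.sum(axis=1, keepdims=True)
        initial = initial + rng.uniform(0.0, 0.2, size=2)
        initial /= initial.sum()
    covs = np.stack([np.eye(r) * s for s in scales])
    return HMMParameters(initial, transition, np.zeros((2, r)), covs)


def _m_step(
    x: np.ndarray, gamma: np.ndarray, xi: np.ndarray, config: EMConfig
) -> HMMParameters:
    s, length, r = x.shape
    initial = gamma[:, 0, :].sum(axis=0)
    initial /= initial.sum()
    if length > 1:
        trans = xi.sum(axis=(0, 1))
        transition = trans / trans.sum(axis=1, keepdims=True)
    else:
        transition = np.array([[0.9, 0.1], [0.1, 0.9]])
    flat = x.reshape(s * length, r)
    w = gamma.reshape(s * length, 2)
    means = np.zeros((2, r))
    covs = np.empty((2, r, r))
    floored = False
    for k in range(2):
        wk = w[:, k]
        denom = wk.sum()
        if not config.zero_mean:
            means[k] = wk @ flat / denom
        diff = flat - means[k]
        cov = (wk[:, None] * diff).T @ diff / denom
        if config.covariance == "diag":
            cov = np.diag(np.diag(cov))
        cov, hit = _floor_covariance(cov, config.var_floor)
        floored = floored or hit
        covs[k] = cov
    if floored:
        warnings.warn(
            "emission variance collapsed; variance floor applied", stacklevel=3
        )
    return HMMParameters(initial, transition, means, covs)


def _order_states(params: HMMParameters) -> HMMParameters:
    """Relabel so the larger-trace (more dispersed) state is C."""
    traces = [np.trace(params.covariances[k]) for k in range(2)]
    if traces[_N] <= traces[_C]:
        return params
    sw = [1, 0]
    return HMMParameters(
        params.initial[sw],
        params.transition[np.ix_(sw, sw)],
        params.means[sw],
        params.covariances[sw],
    )


def _run_em(
    x: np.ndarray, start: HMMParameters, config: EMConfig
) -> tuple[HMMParameters, list[float], bool]:
    params = start
    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        gamma, xi, loglik = _batch_posteriors(params, x)
        total = float(loglik.sum())
        if trace and total < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            warnings.warn(
                f"log-likelihood decreased ({trace[-1]:.6f} -> {total:.6f})",
                stacklevel=3,
            )
        if trace and abs(total - trace[-1]) < config.tol * abs(trace[-1]):
            trace.append(total)
            converged = True
            break
        trace.append(total)
        params = _m_step(x, gamma, xi, config)
    return params, trace, converged


def em_fit(deltas: Sequence[DeltaTensor], config: EMConfig | None = None) -> FitReport:
    """Fit the two-state model by Baum-Welch over all pooled sequences.

    Every feature in every condition contributes one independent observation
    sequence.  The best of ``config.restarts`` runs (by final total
    log-likelihood) is returned, with states relabelled so that ``C`` is the
    larger-dispersion state.
    """
    config = config or EMConfig()
    x = _pool_sequences(deltas)
    if x.shape[0] < 2:
        raise ShapeError("need at least two observation sequences to fit")
    best: tuple[HMMParameters, list[float], bool] | None = None
    seeds = np.random.SeedSequence(config.seed).spawn(config.restarts)
    for j in range(config.restarts):
        rng = None if j == 0 else np.random.default_rng(seeds[j])
        start = _initial_parameters(x, config, rng)
        fitted, trace, converged = _run_em(x, start, config)
        if best is None or trace[-1] > best[1][-1]:
            best = (fitted, trace, converged)
    assert best is not None
    params, trace, converged = best
    return FitReport(
        parameters=_order_states(params),
        log_likelihood_trace=trace,
        iterations=len(trace),
        converged=converged,
        n_sequences=x.shape[0],
        config=config,
    )
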