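"""Discrete-state, Gaussian-emission hidden Markov models.

This module implements the standard HMM machinery the alignment model is
built on: exact likelihood evaluation by the forward recursion, Viterbi
decoding, and Baum-Welch (EM) estimation pooled over many independent
emission sequences that share one parameter set ``lambda = {a, A, B}``.

Sequences here are scaled gene expression profiles: one real value per
weekly time point, linearly mapped to [0, 1] upstream.  Because the scaled
values pile up at the interval endpoints, every M-step clamps the emission
variances to a configurable floor (default 0.001) so no state collapses
onto a point mass.

All user-facing state and time indices are 1-based; internal arrays are
0-based.  Recursions use scaled linear-space forward/backward passes with a
per-position shift of the emission log-densities, so per-sequence
log-likelihoods are accumulated exactly in log space while the inner loops
stay as dense matrix products.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HMMParams",
    "Profile",
    "ViterbiResult",
    "PooledFit",
    "forward_loglik",
    "viterbi",
    "baum_welch_pooled",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

_PROB_ATOL = 1e-10  # tolerance on probability normalisation


class ParameterError(ValueError):
    """Raised when an HMM parameter set violates its invariants."""


class InputError(ValueError):
    """Raised when observation data are unusable (non-finite, empty, mismatched)."""


@dataclass
class HMMParams:
    """Parameter set of an N-state Gaussian-emission HMM.

    Parameters
    ----------
    initial_probs : (N,) array
        Initial state distribution ``a``.
    transition_matrix : (N, N) array
        Row-stochastic transition matrix ``A``.
    emission_means : (N,) array
        Per-state Gaussian means, on the scaled-expression ([0, 1]) scale.
    emission_variances : (N,) array
        Per-state Gaussian variances; each must be >= ``variance_floor``.
    variance_floor : float
        Lower bound imposed on fitted variances, guarding against point
        masses at the scaled endpoints 0 and 1.  May be 0 for synthetic
        generation with degenerate (noise-free) emissions.
    """

    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    emission_means: np.ndarray
    emission_variances: np.ndarray
    variance_floor: float = 0.001

    def __post_init__(self) -> None:
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        self.emission_means = np.asarray(self.emission_means, dtype=float)
        self.emission_variances = np.asarray(self.emission_variances, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.initial_probs.shape[0]

    def validate(self) -> None:
        n = self.initial_probs.shape[0]
        if n < 1:
            raise ParameterError("need at least one state")
        if self.transition_matrix.shape != (n, n):
            raise ParameterError("transition matrix must be N x N")
        if self.emission_means.shape != (n,) or self.emission_variances.shape != (n,):
            raise ParameterError("emission parameter vectors must have length N")
        if np.any(self.initial_probs < 0) or np.any(self.transition_matrix < 0):
            raise ParameterError("probabilities must be nonnegative")
        if abs(self.initial_probs.sum() - 1.0) > _PROB_ATOL:
            raise ParameterError("initial probabilities must sum to 1")
        rows = self.transition_matrix.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > _PROB_ATOL):
            raise ParameterError("transition rows must sum to 1")
        if self.variance_floor < 0:
            raise ParameterError("variance floor must be nonnegative")
        if np.any(self.emission_variances < self.variance_floor):
            raise ParameterError("emission variances must respect the variance floor")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_states": int(self.n_states),
            "initial_probs": self.initial_probs.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "emission_means": self.emission_means.tolist(),
            "emission_variances": self.emission_variances.tolist(),
            "variance_floor": float(self.variance_floor),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        params = cls(
            initial_probs=np.asarray(d["initial_probs"], dtype=float),
            transition_matrix=np.asarray(d["transition_matrix"], dtype=float),
            emission_means=np.asarray(d["emission_means"], dtype=float),
            emission_variances=np.asarray(d["emission_variances"], dtype=float),
            variance_floor=float(d.get("variance_floor", 0.001)),
        )
        if "n_states" in d and int(d["n_states"]) != params.n_states:
            raise ParameterError("n_states field disagrees with vector lengths")
        return params

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "HMMParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class Profile:
    """One site's expression profile for one gene: an ordered value per time point."""

    gene_id: str
    site: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise InputError(f"profile {self.gene_id}/{self.site}: need a 1-d value vector")
        if not np.all(np.isfinite(self.values)):
            raise InputError(f"profile {self.gene_id}/{self.site}: non-finite values")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class ViterbiResult:
    """A decoded state path (1-based state indices) and its joint log-probability."""

    states: np.ndarray
    log_prob: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)


@dataclass
class PooledFit:
    """Baum-Welch output: fitted parameters plus the convergence record."""

    params: HMMParams
    loglik: float
    loglik_history: np.ndarray = field(repr=False)
    n_iter: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# Emission densities and batched recursions
# ---------------------------------------------------------------------------

def gaussian_log_density(x: np.ndarray, params: HMMParams) -> np.ndarray:
    """Per-state Gaussian log-densities: shape ``x.shape + (N,)``."""
    var = params.emission_variances
    if np.any(var <= 0):
        raise ParameterError("emission variances must be positive to evaluate densities")
    x = np.asarray(x, dtype=float)
    d = x[..., None] - params.emission_means
    return -0.5 * (_LOG_2PI + np.log(var) + d * d / var)


def _forward_batch(logB: np.ndarray, params: HMMParams) -> np.ndarray:
    """Scaled forward pass over a (K, T, N) emission log-density array.

    Returns the (K,) vector of per-sequence log-likelihoods.
    """
    K, T, N = logB.shape
    shift = logB.max(axis=2)  # (K, T)
    B = np.exp(logB - shift[..., None])
    A = params.transition_matrix
    alpha = params.initial_probs * B[:, 0]
    c = alpha.sum(axis=1)
    if np.any(c <= 0):
        raise InputError("zero forward mass at the first position")
    alpha /= c[:, None]
    ll = np.log(c) + shift[:, 0]
    for t in range(1, T):
        alpha = (alpha @ A) * B[:, t]
        c = alpha.sum(axis=1)
        if np.any(c <= 0):
            raise InputError("zero forward mass; model assigns probability 0 to the data")
        alpha /= c[:, None]
        ll += np.log(c) + shift[:, t]
    return ll


def _forward_backward_batch(logB: np.ndarray, params: HMMParams):
    """Scaled forward-backward: per-sequence log-likelihoods, posteriors, and
    expected transition counts.

    Returns
    -------
    ll : (K,) log-likelihoods
    gamma : (K, T, N) state posteriors
    xi_sum : (N, N) expected transition counts summed over sequences and time
    """
    K, T, N = logB.shape
    shift = logB.max(axis=2)
    B = np.exp(logB - shift[..., None])
    A = params.transition_matrix

    alphas = np.empty((K, T, N))
    alpha = params.initial_probs * B[:, 0]
    c = alpha.sum(axis=1)
    if np.any(c <= 0):
        raise InputError("zero forward mass at the first position")
    alpha /= c[:, None]
    alphas[:, 0] = alpha
    ll = np.log(c) + shift[:, 0]
    for t in range(1, T):
        alpha = (alpha @ A) * B[:, t]
        c = alpha.sum(axis=1)
        if np.any(c <= 0):
            raise InputError("zero forward mass; model assigns probability 0 to the data")
        alpha /= c[:, None]
        alphas[:, t] = alpha
        ll += np.log(c) + shift[:, t]

    betas = np.empty((K, T, N))
    beta = np.ones((K, N))
    betas[:, T - 1] = beta
    xi_sum = np.zeros((N, N))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta  # (K, N)
        # xi_t[k, i, j] proportional to alpha_t[k,i] A[i,j] bb[k,j]
        xi = alphas[:, t, :, None] * A[None] * bb[:, None, :]
        denom = xi.sum(axis=(1, 2))
        xi_sum += (xi / denom[:, None, None]).sum(axis=0)
        beta = bb @ A.T
        beta /= beta.max(axis=1, keepdims=True)  # rescale only; gamma normalised below
        betas[:, t] = beta

    gamma = alphas * betas
    gamma /= gamma.sum(axis=2, keepdims=True)
    return ll, gamma, xi_sum


def _viterbi_batch(logB: np.ndarray, params: HMMParams):
    """Batched Viterbi over a (K, T, N) emission log-density array.

    Ties at every argmax resolve to the smallest state index (the first
    maximiser), so decoding is deterministic.

    Returns 0-based paths (K, T) and path log-probabilities (K,).
    """
    K, T, N = logB.shape
    with np.errstate(divide="ignore"):
        log_a = np.log(params.initial_probs)
        log_A = np.log(params.transition_matrix)
    delta = log_a + logB[:, 0]  # (K, N)
    back = np.empty((K, T, N), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, :, None] + log_A[None]  # (K, prev, next)
        back[:, t] = scores.argmax(axis=1)
        delta = scores.max(axis=1) + logB[:, t]
    paths = np.empty((K, T), dtype=np.intp)
    paths[:, T - 1] = delta.argmax(axis=1)
    log_prob = delta.max(axis=1)
    rows = np.arange(K)
    for t in range(T - 2, -1, -1):
        paths[:, t] = back[rows, t + 1, paths[:, t + 1]]
    return paths, log_prob


# ---------------------------------------------------------------------------
# Public single-profile operations
# ---------------------------------------------------------------------------

def _profile_values(profile) -> np.ndarray:
    values = profile.values if isinstance(profile, Profile) else np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InputError("profile contains non-finite values")
    return np.asarray(values, dtype=float)


def forward_loglik(profile, params: HMMParams) -> float:
    """Exact log-likelihood ``log p(x_1..x_T | lambda)`` by the forward recursion."""
    values = _profile_values(profile)
    logB = gaussian_log_density(values, params)[None]
    return float(_forward_batch(logB, params)[0])


def viterbi(profile, params: HMMParams) -> ViterbiResult:
    """Most probable state path; returns 1-based states and the path log-probability."""
    values = _profile_values(profile)
    logB = gaussian_log_density(values, params)[None]
    paths, lp = _viterbi_batch(logB, params)
    return ViterbiResult(states=paths[0] + 1, log_prob=float(lp[0]))


# ---------------------------------------------------------------------------
# Pooled Baum-Welch
# ---------------------------------------------------------------------------

def _initial_params(
    values: np.ndarray,
    n_states: int,
    variance_floor: float,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> HMMParams:
    """Deterministic starting point: means evenly spaced over the data range,
    pooled sample variance, uniform initial distribution, and a
    near-uniform transition matrix with a boosted diagonal."""
    lo, hi = float(values.min()), float(values.max())
    if n_states == 1:
        means = np.array([0.5 * (lo + hi)])
    else:
        means = lo + np.linspace(0.0, 1.0, n_states) * (hi - lo)
    if jitter > 0 and rng is not None:
        means = np.sort(means + rng.normal(0.0, jitter * (hi - lo + 1e-12), n_states))
    var = max(float(values.var()), variance_floor, 1e-8)
    a = np.full(n_states, 1.0 / n_states)
    A = np.full((n_states, n_states), 1.0 / n_states) + 0.1 * np.eye(n_states)
    A /= A.sum(axis=1, keepdims=True)
    return HMMParams(
        initial_probs=a,
        transition_matrix=A,
        emission_means=means,
        emission_variances=np.full(n_states, var),
        variance_floor=variance_floor,
    )


def _group_by_length(profiles: Sequence) -> list[np.ndarray]:
    groups: dict[int, list[np.ndarray]] = {}
    for p in profiles:
        v = _profile_values(p)
        groups.setdefault(v.size, []).append(v)
    return [np.vstack(vs) for _, vs in sorted(groups.items())]


def _em_m_step(
    stats: dict, n_states: int, variance_floor: float, prev: HMMParams
) -> HMMParams:
    a = stats["gamma0"] / stats["gamma0"].sum()
    A = stats["xi"].copy()
    row = A.sum(axis=1, keepdims=True)
    dead = row[:, 0] <= 0
    A[dead] = prev.transition_matrix[dead]  # starved state: keep previous row
    A[~dead] /= row[~dead]
    den = stats["den"]
    means = np.where(den > 0, stats["num_x"] / np.maximum(den, 1e-300), prev.emission_means)
    var = np.where(
        den > 0,
        stats["num_xx"] / np.maximum(den, 1e-300) - means**2,
        prev.emission_variances,
    )
    var = np.maximum(var, variance_floor)
    return HMMParams(a, A, means, var, variance_floor)


def baum_welch_pooled(
    profiles: Iterable,
    n_states: int,
    variance_floor: float = 0.001,
    init: HMMParams | str = "even",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    n_starts: int = 1,
) -> PooledFit:
    """Fit one Gaussian HMM to many independent profiles by pooled EM.

    All profiles (which may have different lengths) are treated as
    independent emission sequences of the same chain; the E-step accumulates
    sufficient statistics over every sequence and the M-step re-estimates a
    single shared parameter set, clamping each variance to
    ``variance_floor``.

    The default start is deterministic (``init="even"``: evenly spaced means
    over the observed range).  With ``n_starts > 1`` and a seed, additional
    jittered starts are run and the fit with the highest final
    log-likelihood is returned.

    Returns a :class:`PooledFit`; its ``loglik_history`` is non-decreasing
    (EM monotonicity) and ends at the log-likelihood of the reported
    parameters.
    """
    profiles = list(profiles)
    if not profiles:
        raise InputError("need at least one profile")
    if n_states < 1:
        raise ParameterError("n_states must be >= 1")
    groups = _group_by_length(profiles)
    all_values = np.concatenate([g.ravel() for g in groups])

    rng = np.random.default_rng(seed)
    starts: list[HMMParams] = []
    if isinstance(init, HMMParams):
        starts.append(init)
    elif init == "even":
        starts.append(_initial_params(all_values, n_states, variance_floor))
    else:
        raise ParameterError(f"unknown init scheme: {init!r}")
    for _ in range(1, n_starts):
        starts.append(_initial_params(all_values, n_states, variance_floor, rng, jitter=0.05))

    best: PooledFit | None = None
    for start in starts:
        fit = _run_em(groups, start, variance_floor, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def _run_em(
    groups: list[np.ndarray],
    start: HMMParams,
    variance_floor: float,
    tol: float,
    max_iter: int,
) -> PooledFit:
    params = start
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        stats = {
            "gamma0": np.zeros(params.n_states),
            "xi": np.zeros((params.n_states, params.n_states)),
            "num_x": np.zeros(params.n_states),
            "num_xx": np.zeros(params.n_states),
            "den": np.zeros(params.n_states),
        }
        total_ll = 0.0
        for X in groups:
            logB = gaussian_log_density(X, params)
            ll, gamma, xi = _forward_backward_batch(logB, params)
            total_ll += float(ll.sum())
            stats["gamma0"] += gamma[:, 0].sum(axis=0)
            stats["xi"] += xi
            stats["num_x"] += np.einsum("ktn,kt->n", gamma, X)
            stats["num_xx"] += np.einsum("ktn,kt->n", gamma, X * X)
            stats["den"] += gamma.sum(axis=(0, 1))
        history.append(total_ll)
        if len(history) > 1:
            prev = history[-2]
            if abs(total_ll - prev) <= tol * abs(prev):
                converged = True
                break
        params = _em_m_step(stats, params.n_states, variance_floor, params)
    if not converged:
        warnings.warn(
            "Baum-Welch did not converge within max_iter; returning current estimate",
            RuntimeWarning,
            stacklevel=2,
        )
    return PooledFit(
        params=params,
        loglik=history[-1],
        loglik_history=np.asarray(history),
        n_iter=len(history),
        converged=converged,
    )
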