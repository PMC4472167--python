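"""The alignment HMM for pairs of unequal-length expression profiles.

A pair of profiles (lengths T1 = T and T2 <= T1) is modelled as two
emission sequences of a single latent state sequence S_1..S_T.  The long
profile's time points map one-to-one onto the state positions; the short
profile skips a set of "gap positions" -- state positions at which it has
no observation -- and those gap positions are parameters shared by every
gene.  For the motivating grapevine data T = 19, T2 = 17 and there are
exactly two gaps 1 < g1 < g2 <= 19; position 1 is never a gap because the
first measurements at the two sites are constrained to align.

Fitting is the two-step procedure: (1) pool every individual profile from
both sites into one standard-HMM Baum-Welch fit, giving a parameter
estimate that is robust to pairs that do not align; (2) enumerate all
admissible gap sets and pick the one maximising the summed alignment
log-likelihood at those fixed parameters.  The full maximum-likelihood
alternative -- EM on the alignment model itself at fixed gaps -- is also
provided; on contaminated data it inflates the emission variances, which
is itself a useful diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hmm import (
    HMMParams,
    InputError,
    ParameterError,
    PooledFit,
    Profile,
    ViterbiResult,
    _forward_backward_batch,
    _forward_batch,
    _initial_params,
    _viterbi_batch,
    baum_welch_pooled,
    gaussian_log_density,
)

__all__ = [
    "ProfilePair",
    "AlignmentMap",
    "GapSearchResult",
    "tau_from_gaps",
    "pair_loglik",
    "total_loglik",
    "gap_grid_search",
    "joint_viterbi",
    "average_profile",
    "fit_full_mle",
    "fit_two_step",
]


@dataclass
class ProfilePair:
    """One gene's two profiles: the longer site first (length T1 >= T2)."""

    gene_id: str
    profile_long: Profile
    profile_short: Profile

    def __post_init__(self) -> None:
        t1, t2 = len(self.profile_long), len(self.profile_short)
        if t1 < 2 or t2 < 1 or t2 > t1:
            raise InputError(
                f"pair {self.gene_id}: need T1 >= 2 and 1 <= T2 <= T1, got ({t1}, {t2})"
            )

    @property
    def t1(self) -> int:
        return len(self.profile_long)

    @property
    def t2(self) -> int:
        return len(self.profile_short)


@dataclass
class AlignmentMap:
    """The tau mapping from observed time indices to common state positions.

    ``tau_long`` is the identity 1..T; ``tau_short`` is the strictly
    increasing complement of ``gap_positions`` within 1..T, starting at 1.
    All indices are 1-based.
    """

    total_positions: int
    tau_long: np.ndarray
    tau_short: np.ndarray
    gap_positions: tuple[int, ...]

    @classmethod
    def from_gap_set(cls, gaps: Sequence[int], total_positions: int) -> "AlignmentMap":
        T = int(total_positions)
        gaps = tuple(sorted(int(g) for g in gaps))
        if len(set(gaps)) != len(gaps):
            raise ParameterError("gap positions must be distinct")
        if gaps and (gaps[0] <= 1 or gaps[-1] > T):
            raise ParameterError(
                "gap positions must lie in 2..T (the first time points are constrained to align)"
            )
        tau_short = np.array([u for u in range(1, T + 1) if u not in gaps], dtype=int)
        return cls(
            total_positions=T,
            tau_long=np.arange(1, T + 1, dtype=int),
            tau_short=tau_short,
            gap_positions=gaps,
        )

    @property
    def t2(self) -> int:
        return int(self.tau_short.size)


def tau_from_gaps(g1: int, g2: int, T: int, T2: int | None = None) -> AlignmentMap:
    """Two-gap alignment map: short-profile index t maps to t, t+1 or t+2
    according to whether it falls before g1, between the gaps, or after g2."""
    if not (1 < g1 < g2 <= T):
        raise ParameterError(f"need 1 < g1 < g2 <= T, got g1={g1}, g2={g2}, T={T}")
    if T2 is not None and T2 != T - 2:
        raise ParameterError(f"two gaps require T2 = T - 2, got T2={T2}, T={T}")
    return AlignmentMap.from_gap_set((g1, g2), T)


@dataclass
class GapSearchResult:
    """Log-likelihood surface over admissible gap sets and its argmax."""

    surface: dict[tuple[int, ...], float]
    best_gaps: tuple[int, ...]
    ties: list[tuple[int, ...]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        n_gaps = len(self.best_gaps)
        cols = [f"g{i + 1}" for i in range(n_gaps)]
        rows = [list(k) + [v] for k, v in sorted(self.surface.items())]
        return pd.DataFrame(rows, columns=cols + ["loglik"])

    def peak_sharpness(self) -> float:
        """Peak height above the surface median; large when the argmax is well determined."""
        vals = np.fromiter(self.surface.values(), dtype=float)
        return float(vals.max() - np.median(vals))


# ---------------------------------------------------------------------------
# Stacking and composite emissions
# ---------------------------------------------------------------------------

def _stack_pairs(pairs: Sequence[ProfilePair]) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        raise InputError("need at least one profile pair")
    t1, t2 = pairs[0].t1, pairs[0].t2
    if any(p.t1 != t1 or p.t2 != t2 for p in pairs):
        raise InputError("all pairs must share the same profile lengths (T1, T2)")
    W = np.vstack([p.profile_long.values for p in pairs])
    C = np.vstack([p.profile_short.values for p in pairs])
    return W, C


def _check_map(t1: int, t2: int, amap: AlignmentMap) -> None:
    if amap.total_positions != t1 or amap.t2 != t2:
        raise InputError(
            f"alignment map (T={amap.total_positions}, T2={amap.t2}) does not match "
            f"pair lengths ({t1}, {t2})"
        )


def _composite_logB(LW: np.ndarray, LC: np.ndarray, amap: AlignmentMap) -> np.ndarray:
    """Per-position emission log-weights for the alignment model.

    Position u carries the long profile's density always, plus the short
    profile's density when some short index maps to u; gap positions carry
    the long term only.
    """
    logB = LW.copy()
    idx = amap.tau_short - 1
    logB[:, idx, :] += LC
    return logB


# ---------------------------------------------------------------------------
# Likelihood, decoding, representations
# ---------------------------------------------------------------------------

def _pair_logliks(
    W: np.ndarray, C: np.ndarray, params: HMMParams, amap: AlignmentMap
) -> np.ndarray:
    LW = gaussian_log_density(W, params)
    LC = gaussian_log_density(C, params)
    return _forward_batch(_composite_logB(LW, LC, amap), params)


def pair_loglik(pair: ProfilePair, params: HMMParams, amap: AlignmentMap) -> float:
    """Alignment log-likelihood of one pair: the forward sum over the common
    state sequence with both profiles' emission densities at their mapped
    positions."""
    _check_map(pair.t1, pair.t2, amap)
    W = pair.profile_long.values[None]
    C = pair.profile_short.values[None]
    return float(_pair_logliks(W, C, params, amap)[0])


def total_loglik(
    pairs: Sequence[ProfilePair], params: HMMParams, g1: int, g2: int
) -> float:
    """Summed alignment log-likelihood over all pairs at gap positions (g1, g2)."""
    W, C = _stack_pairs(pairs)
    amap = tau_from_gaps(g1, g2, W.shape[1])
    _check_map(W.shape[1], C.shape[1], amap)
    return float(_pair_logliks(W, C, params, amap).sum())


def joint_viterbi(pair: ProfilePair, params: HMMParams, amap: AlignmentMap) -> ViterbiResult:
    """Most probable common state path for a pair (1-based states, length T)."""
    _check_map(pair.t1, pair.t2, amap)
    LW = gaussian_log_density(pair.profile_long.values[None], params)
    LC = gaussian_log_density(pair.profile_short.values[None], params)
    paths, lp = _viterbi_batch(_composite_logB(LW, LC, amap), params)
    return ViterbiResult(states=paths[0] + 1, log_prob=float(lp[0]))


def average_profile(pair: ProfilePair, amap: AlignmentMap) -> np.ndarray:
    """Common representation: the mean of the two aligned observations at
    doubly observed positions, the long profile's value at gap positions."""
    _check_map(pair.t1, pair.t2, amap)
    out = pair.profile_long.values.astype(float).copy()
    idx = amap.tau_short - 1
    out[idx] = 0.5 * (out[idx] + pair.profile_short.values)
    return out


# ---------------------------------------------------------------------------
# Gap grid search
# ---------------------------------------------------------------------------

def gap_grid_search(
    pairs: Sequence[ProfilePair],
    params: HMMParams,
    max_candidates: int = 100_000,
) -> GapSearchResult:
    """Enumerate every admissible gap set and maximise the total alignment
    log-likelihood at fixed parameters.

    The number of gaps is ``T1 - T2``; candidates are all size-(T1-T2)
    subsets of positions 2..T1 (position 1 is excluded because the first
    time points are constrained to align), C(T1-1, T1-T2) in total.  Ties at
    the maximum are reported and broken toward the lexicographically
    smallest gap set.
    """
    W, C = _stack_pairs(pairs)
    T, T2 = W.shape[1], C.shape[1]
    n_gaps = T - T2
    if n_gaps < 1:
        raise InputError("equal lengths: nothing to search (no gap positions)")
    n_cand = comb(T - 1, n_gaps)
    if n_cand > max_candidates:
        raise InputError(
            f"{n_cand} candidate gap sets exceed the cap of {max_candidates}"
        )
    LW = gaussian_log_density(W, params)
    LC = gaussian_log_density(C, params)
    surface: dict[tuple[int, ...], float] = {}
    for gaps in combinations(range(2, T + 1), n_gaps):
        amap = AlignmentMap.from_gap_set(gaps, T)
        ll = float(_forward_batch(_composite_logB(LW, LC, amap), params).sum())
        surface[gaps] = ll
    best_val = max(surface.values())
    # floating-point exact ties only; break toward the smallest gap set
    ties = sorted(k for k, v in surface.items() if v == best_val)
    return GapSearchResult(surface=surface, best_gaps=ties[0], ties=ties)


# ---------------------------------------------------------------------------
# Estimation: full MLE at fixed gaps, and the two-step procedure
# ---------------------------------------------------------------------------

def fit_full_mle(
    pairs: Sequence[ProfilePair],
    g1: int,
    g2: int | None = None,
    n_states: int = 5,
    variance_floor: float = 0.001,
    init: HMMParams | str = "even",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    gaps: Sequence[int] | None = None,
) -> PooledFit:
    """EM for the alignment HMM itself at fixed gap positions.

    The E-step is forward-backward over the T state positions with composite
    emissions (two Gaussian terms at doubly observed positions, one at
    gaps); the M-step weights BOTH observations mapped to a position by that
    position's posterior, and clamps variances to the floor.

    ``gaps`` may be given instead of ``(g1, g2)`` for gap counts other
    than two.
    """
    pairs = list(pairs)
    W, C = _stack_pairs(pairs)
    T = W.shape[1]
    if gaps is None:
        if g2 is None:
            raise ParameterError("give either (g1, g2) or an explicit gap set")
        amap = tau_from_gaps(int(g1), int(g2), T)
    else:
        amap = AlignmentMap.from_gap_set(gaps, T)
    _check_map(T, C.shape[1], amap)

    all_values = np.concatenate([W.ravel(), C.ravel()])
    if isinstance(init, HMMParams):
        params = init
    elif init == "even":
        params = _initial_params(all_values, n_states, variance_floor)
    else:
        raise ParameterError(f"unknown init scheme: {init!r}")

    idx = amap.tau_short - 1
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        LW = gaussian_log_density(W, params)
        LC = gaussian_log_density(C, params)
        logB = _composite_logB(LW, LC, amap)
        ll, gamma, xi = _forward_backward_batch(logB, params)
        total_ll = float(ll.sum())
        history.append(total_ll)
        if len(history) > 1 and abs(total_ll - history[-2]) <= tol * abs(history[-2]):
            converged = True
            break
        # M-step: every observation mapped to a position contributes with
        # that position's posterior weight.
        gamma_short = gamma[:, idx, :]  # (K, T2, N)
        num_x = np.einsum("ktn,kt->n", gamma, W) + np.einsum("ktn,kt->n", gamma_short, C)
        num_xx = np.einsum("ktn,kt->n", gamma, W * W) + np.einsum(
            "ktn,kt->n", gamma_short, C * C
        )
        den = gamma.sum(axis=(0, 1)) + gamma_short.sum(axis=(0, 1))
        a = gamma[:, 0].sum(axis=0)
        a /= a.sum()
        A = xi.copy()
        row = A.sum(axis=1, keepdims=True)
        dead = row[:, 0] <= 0
        A[dead] = params.transition_matrix[dead]
        A[~dead] /= row[~dead]
        means = np.where(den > 0, num_x / np.maximum(den, 1e-300), params.emission_means)
        var = np.where(
            den > 0,
            num_xx / np.maximum(den, 1e-300) - means**2,
            params.emission_variances,
        )
        params = HMMParams(a, A, means, np.maximum(var, variance_floor), variance_floor)
    if not converged:
        warnings.warn(
            "alignment-model EM did not converge within max_iter",
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


def fit_two_step(
    pairs: Sequence[ProfilePair],
    n_states: int = 5,
    variance_floor: float = 0.001,
    init: HMMParams | str = "even",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
    n_starts: int = 1,
) -> tuple[PooledFit, GapSearchResult]:
    """The robust two-step fit: pooled Baum-Welch over all individual
    profiles from both sites (ignoring the pairing), then an exhaustive gap
    grid search at the fitted parameters."""
    pairs = list(pairs)
    profiles: list[Profile] = []
    for p in pairs:
        profiles.append(p.profile_long)
        profiles.append(p.profile_short)
    fit = baum_welch_pooled(
        profiles,
        n_states=n_states,
        variance_floor=variance_floor,
        init=init,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
        n_starts=n_starts,
    )
    search = gap_grid_search(pairs, fit.params)
    return fit, search
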