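"""Shared fixtures and independent brute-force oracles.

The oracle functions evaluate HMM quantities by explicit enumeration over
all N^T state sequences, independently of the package's recursions, and are
only usable at toy sizes.
"""

from itertools import product

import numpy as np
import pytest

from tcalign.hmm import HMMParams


def _gauss_pdf(x, mu, var):
    return np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2.0 * np.pi * var)


def enum_loglik(values, params):
    """Forward likelihood by summing over every state sequence."""
    values = np.asarray(values, dtype=float)
    N, T = params.n_states, len(values)
    total = 0.0
    for seq in product(range(N), repeat=T):
        p = params.initial_probs[seq[0]]
        for t in range(1, T):
            p *= params.transition_matrix[seq[t - 1], seq[t]]
        for t in range(T):
            p *= _gauss_pdf(values[t], params.emission_means[seq[t]], params.emission_variances[seq[t]])
        total += p
    return float(np.log(total))


def enum_viterbi(values, params):
    """Argmax state sequence by enumeration (0-based); assumes a unique max."""
    values = np.asarray(values, dtype=float)
    N, T = params.n_states, len(values)
    best, best_lp = None, -np.inf
    for seq in product(range(N), repeat=T):
        lp = np.log(params.initial_probs[seq[0]])
        for t in range(1, T):
            lp += np.log(params.transition_matrix[seq[t - 1], seq[t]])
        for t in range(T):
            lp += np.log(
                _gauss_pdf(values[t], params.emission_means[seq[t]], params.emission_variances[seq[t]])
            )
        if lp > best_lp:
            best, best_lp = seq, lp
    return np.asarray(best), float(best_lp)


def enum_pair_loglik(w, c, params, amap):
    """Alignment likelihood by enumeration over the common state sequence."""
    w = np.asarray(w, dtype=float)
    c = np.asarray(c, dtype=float)
    N, T = params.n_states, amap.total_positions
    total = 0.0
    for seq in product(range(N), repeat=T):
        p = params.initial_probs[seq[0]]
        for t in range(1, T):
            p *= params.transition_matrix[seq[t - 1], seq[t]]
        for t, u in enumerate(amap.tau_long):
            j = seq[u - 1]
            p *= _gauss_pdf(w[t], params.emission_means[j], params.emission_variances[j])
        for m, u in enumerate(amap.tau_short):
            j = seq[u - 1]
            p *= _gauss_pdf(c[m], params.emission_means[j], params.emission_variances[j])
        total += p
    return float(np.log(total))


def enum_joint_viterbi(w, c, params, amap):
    """Argmax common state sequence for a pair, by enumeration (0-based)."""
    w = np.asarray(w, dtype=float)
    c = np.asarray(c, dtype=float)
    N, T = params.n_states, amap.total_positions
    best, best_lp = None, -np.inf
    for seq in product(range(N), repeat=T):
        lp = np.log(params.initial_probs[seq[0]])
        for t in range(1, T):
            lp += np.log(params.transition_matrix[seq[t - 1], seq[t]])
        for t, u in enumerate(amap.tau_long):
            j = seq[u - 1]
            lp += np.log(_gauss_pdf(w[t], params.emission_means[j], params.emission_variances[j]))
        for m, u in enumerate(amap.tau_short):
            j = seq[u - 1]
            lp += np.log(_gauss_pdf(c[m], params.emission_means[j], params.emission_variances[j]))
        if lp > best_lp:
            best, best_lp = seq, lp
    return np.asarray(best), float(best_lp)


def pairwise_auc(hammings, labels):
    """AUC as P(H_pos < H_neg) + 0.5 P(tie) over all positive-negative pairs."""
    h = np.asarray(hammings, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = h[y == 1]
    neg = h[y == 0]
    wins = (pos[:, None] < neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def random_params(n_states, rng, variance_floor=1e-4):
    """A random valid parameter set (generic: ties have probability zero)."""
    a = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    means = rng.uniform(0, 1, n_states)
    var = rng.uniform(0.02, 0.3, n_states)
    return HMMParams(a, A, means, var, variance_floor)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def params2(rng):
    return random_params(2, rng)


@pytest.fixture
def params3(rng):
    return random_params(3, rng)
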