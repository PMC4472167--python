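"""Alignment-quality diagnostics and classification of developmental genes.

For each pair of profiles the joint Viterbi path (under the alignment
model) is compared with the two individually decoded paths (under the same
parameters, ignoring the pairing).  The Hamming distance

    H(k) = #{t : joint[tau_long(t)] != path_long[t]}
         + #{m : joint[tau_short(m)] != path_short[m]}

counts the disagreements over both profiles (0..T1+T2).  A pair whose
profiles genuinely share a latent trajectory decodes consistently, so a
small H(k) is evidence the gene is developmentally driven; a threshold on
H(k) (default 10, inclusive) yields the classifier, and when external
labels exist its ROC curve is computed with -H(k) as the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .align import AlignmentMap, ProfilePair, _composite_logB, _stack_pairs, _check_map
from .hmm import HMMParams, InputError, ViterbiResult, _forward_batch, _viterbi_batch, gaussian_log_density

__all__ = [
    "PairDiagnostics",
    "hamming_distance",
    "diagnose_pair",
    "diagnose_pairs",
    "classify",
    "roc_curve",
]

DEVELOPMENTAL = "developmental"
NON_DEVELOPMENTAL = "non-developmental"


@dataclass
class PairDiagnostics:
    """Per-gene alignment diagnostics: likelihood, paths, Hamming distance, label."""

    gene_id: str
    pair_loglik: float
    joint_path: ViterbiResult
    individual_long: ViterbiResult
    individual_short: ViterbiResult
    hamming: int
    label: str | None = None


def hamming_distance(
    joint: ViterbiResult,
    ind_long: ViterbiResult,
    ind_short: ViterbiResult,
    amap: AlignmentMap,
) -> int:
    """Disagreement count between the joint path and the two individual paths
    at their mapped positions."""
    js = np.asarray(joint.states)
    ls = np.asarray(ind_long.states)
    ss = np.asarray(ind_short.states)
    if js.size != amap.total_positions:
        raise InputError("joint path length must equal the number of state positions")
    if ls.size != amap.tau_long.size or ss.size != amap.tau_short.size:
        raise InputError("individual path lengths must match the alignment map")
    h = int((js[amap.tau_long - 1] != ls).sum() + (js[amap.tau_short - 1] != ss).sum())
    return h


def classify(hamming: int, threshold: int = 10) -> str:
    """Label a pair developmental iff H(k) <= threshold (inclusive)."""
    if hamming < 0:
        raise InputError("Hamming distance cannot be negative")
    return DEVELOPMENTAL if hamming <= threshold else NON_DEVELOPMENTAL


def diagnose_pair(
    pair: ProfilePair,
    params: HMMParams,
    amap: AlignmentMap,
    threshold: int = 10,
) -> PairDiagnostics:
    """Assemble the full diagnostic record for one pair under one parameter set."""
    from .align import joint_viterbi, pair_loglik
    from .hmm import viterbi

    joint = joint_viterbi(pair, params, amap)
    ind_long = viterbi(pair.profile_long, params)
    ind_short = viterbi(pair.profile_short, params)
    h = hamming_distance(joint, ind_long, ind_short, amap)
    return PairDiagnostics(
        gene_id=pair.gene_id,
        pair_loglik=pair_loglik(pair, params, amap),
        joint_path=joint,
        individual_long=ind_long,
        individual_short=ind_short,
        hamming=h,
        label=classify(h, threshold),
    )


def diagnose_pairs(
    pairs: Sequence[ProfilePair],
    params: HMMParams,
    amap: AlignmentMap,
    threshold: int = 10,
) -> pd.DataFrame:
    """Vectorised diagnostics for a collection of pairs.

    Returns a DataFrame with columns gene_id, loglik, hamming, label and
    joint_path (comma-joined 1-based states).
    """
    W, C = _stack_pairs(pairs)
    _check_map(W.shape[1], C.shape[1], amap)
    LW = gaussian_log_density(W, params)
    LC = gaussian_log_density(C, params)
    logB = _composite_logB(LW, LC, amap)
    lls = _forward_batch(logB, params)
    joint, _ = _viterbi_batch(logB, params)
    path_long, _ = _viterbi_batch(LW, params)
    path_short, _ = _viterbi_batch(LC, params)
    h = (joint[:, amap.tau_long - 1] != path_long).sum(axis=1)
    h += (joint[:, amap.tau_short - 1] != path_short).sum(axis=1)
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in pairs],
            "loglik": lls,
            "hamming": h.astype(int),
            "label": [classify(int(x), threshold) for x in h],
            "joint_path": [",".join(map(str, row + 1)) for row in joint],
        }
    )


def roc_curve(
    hammings: Sequence[int], labels: Sequence[int]
) -> tuple[pd.DataFrame, float]:
    """ROC curve and trapezoidal AUC for the Hamming classifier.

    ``labels`` are 1 for the positive (developmental) class; a LOW Hamming
    distance indicates the positive class, so -H(k) is the score.  Tied
    scores are swept together, so the AUC equals
    P(H_pos < H_neg) + 0.5 P(H_pos = H_neg).

    Returns a DataFrame (threshold = the H value, fpr, tpr) and the AUC.
    """
    h = np.asarray(hammings, dtype=float)
    y = np.asarray(labels, dtype=int)
    if h.shape != y.shape or h.ndim != 1:
        raise InputError("hammings and labels must be 1-d and the same length")
    if len(np.unique(y)) < 2:
        raise InputError("ROC needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(y, -h, pos_label=1)
    auc = float(_skm.auc(fpr, tpr))
    curve = pd.DataFrame({"threshold": -thr, "fpr": fpr, "tpr": tpr})
    return curve, auc
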