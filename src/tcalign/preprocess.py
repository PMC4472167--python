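"""From replicate-level expression tables to scaled profile pairs.

The pipeline expects one delimited table per site: first column the gene
identifier, remaining columns named ``<time>_<replicate>`` (e.g. ``3_2`` =
time point 3, replicate 2).  Processing is: average replicates within each
time point, keep genes with at least a 2-fold max/min change at either
site, then linearly rescale each retained profile to span [0, 1].

Differential-expression prefiltering (e.g. a moderated-t test across time)
and array-platform masking are upstream concerns: this module assumes its
input has already passed whatever significance screen the study design
calls for, and offers the fold-change filter only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import ProfilePair
from .hmm import InputError, Profile

__all__ = [
    "RawExpressionTable",
    "read_expression_table",
    "average_replicates",
    "fold_change_filter",
    "scale_unit_interval",
    "build_pairs",
]

logger = logging.getLogger(__name__)


@dataclass
class RawExpressionTable:
    """A site's gene x (time x replicate) matrix plus the column-to-time map."""

    site: str
    gene_ids: list[str]
    values: pd.DataFrame  # index gene_id, columns "<time>_<rep>"
    replicate_map: dict[str, int]  # column name -> time point (1-based order)
    time_points: list[int]

    @property
    def n_time_points(self) -> int:
        return len(self.time_points)


def _parse_replicate_columns(columns) -> tuple[dict[str, int], list[int]]:
    rep_map: dict[str, int] = {}
    for col in columns:
        head = str(col).split("_", 1)[0]
        try:
            rep_map[col] = int(head)
        except ValueError as exc:
            raise InputError(
                f"column {col!r} is not of the form <time>_<replicate>"
            ) from exc
    times = sorted(set(rep_map.values()))
    return rep_map, times


def read_expression_table(path, site: str, sep: str | None = None) -> RawExpressionTable:
    """Read a per-site TSV/CSV: first column gene_id, then <time>_<replicate> columns."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise InputError(f"{path}: expected a gene_id column plus value columns")
    df = df.set_index(df.columns[0])
    rep_map, times = _parse_replicate_columns(df.columns)
    return RawExpressionTable(
        site=site,
        gene_ids=list(df.index),
        values=df.astype(float),
        replicate_map=rep_map,
        time_points=times,
    )


def average_replicates(table: RawExpressionTable) -> pd.DataFrame:
    """Mean over replicates at each time point.

    Returns a gene x time DataFrame (columns are the sorted time points).
    Missing values within a replicate set are averaged over the non-missing
    replicates, with a logged warning; a fully missing time point for a gene
    is an error.
    """
    groups = pd.Index([table.replicate_map[c] for c in table.values.columns])
    means = table.values.T.groupby(groups).mean().T  # skipna mean per time point
    if table.values.isna().any().any():
        logger.warning(
            "site %s: missing replicate values averaged over the remaining replicates",
            table.site,
        )
    if means.isna().any().any():
        bad = means.index[means.isna().any(axis=1)]
        raise InputError(
            f"site {table.site}: fully missing time point(s) for genes {list(bad)[:5]}"
        )
    return means[sorted(means.columns)]


def fold_change_filter(
    values_long: np.ndarray, values_short: np.ndarray, threshold: float = 2.0
) -> bool:
    """Keep a gene when max/min >= threshold at EITHER site.

    Values must be on the unlogged (strictly positive) intensity scale; the
    ratio is invariant to positive rescaling of a profile.
    """
    keep = False
    for vals in (values_long, values_short):
        vals = np.asarray(vals, dtype=float)
        if np.any(vals <= 0):
            raise InputError("fold-change filter requires strictly positive intensities")
        if vals.max() / vals.min() >= threshold:
            keep = True
    return keep


def scale_unit_interval(profile):
    """Linearly rescale a profile so its values span [0, 1] exactly.

    Accepts a :class:`Profile` (returns a new Profile) or a plain array.
    A constant profile cannot be scaled and raises; callers filter first.
    """
    if isinstance(profile, Profile):
        return Profile(profile.gene_id, profile.site, scale_unit_interval(profile.values))
    vals = np.asarray(profile, dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        raise InputError("constant profile cannot be rescaled to [0, 1]")
    return (vals - lo) / (hi - lo)


def build_pairs(
    table_long: RawExpressionTable,
    table_short: RawExpressionTable,
    fold_change_threshold: float = 2.0,
) -> tuple[list[ProfilePair], pd.DataFrame]:
    """Full preprocessing: replicate averaging, fold-change filtering and
    [0, 1] scaling for the genes present at both sites.

    Returns the retained, scaled :class:`ProfilePair` list and a drop log
    (gene_id, reason) covering genes missing at a site, failing the
    fold-change rule, or constant (unscalable) at a site.
    """
    means_long = average_replicates(table_long)
    means_short = average_replicates(table_short)
    if means_long.shape[1] < means_short.shape[1]:
        raise InputError(
            "the first table must be the longer (or equal) time course"
        )
    dropped: list[tuple[str, str]] = []
    pairs: list[ProfilePair] = []
    common = [g for g in means_long.index if g in set(means_short.index)]
    for g in means_long.index.union(means_short.index):
        if g not in set(common):
            dropped.append((g, "missing_at_one_site"))
    for g in common:
        w = means_long.loc[g].to_numpy(dtype=float)
        c = means_short.loc[g].to_numpy(dtype=float)
        if not fold_change_filter(w, c, fold_change_threshold):
            dropped.append((g, "fold_change"))
            continue
        if w.max() <= w.min() or c.max() <= c.min():
            dropped.append((g, "constant_profile"))
            continue
        pairs.append(
            ProfilePair(
                gene_id=g,
                profile_long=Profile(g, table_long.site, scale_unit_interval(w)),
                profile_short=Profile(g, table_short.site, scale_unit_interval(c)),
            )
        )
    drop_log = pd.DataFrame(dropped, columns=["gene_id", "reason"])
    return pairs, drop_log
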