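"""Model/Results interface over the alignment HMM.

:class:`AlignmentHMM` is constructed from a collection of profile pairs
(or a long-format DataFrame) and ``fit()`` returns an
:class:`AlignmentHMMResults` carrying the fitted parameters, the gap
log-likelihood surface and argmax, convergence information, per-gene
diagnostics, aligned representations and plotting helpers.

Example
-------
>>> from tcalign import synthetic
>>> from tcalign.model import AlignmentHMM
>>> ds = synthetic.generate_dataset(K=300, contamination_fraction=0.2, seed=7)
>>> res = AlignmentHMM(ds.pairs, n_states=5).fit()
>>> res.gaps
(2, 11)
>>> diag = res.diagnostics()          # gene_id, loglik, hamming, label
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import align as _align
from . import diagnostics as _diag
from .hmm import HMMParams, InputError, PooledFit, Profile
from .align import AlignmentMap, GapSearchResult, ProfilePair

__all__ = ["AlignmentHMM", "AlignmentHMMResults"]


class AlignmentHMM:
    """Alignment HMM for K pairs of unequal-length profiles.

    Parameters
    ----------
    pairs : sequence of ProfilePair
        All pairs must share the same lengths (T1, T2).
    n_states : int
        Number of latent expression levels N (default 5).
    variance_floor : float
        Lower bound on fitted emission variances (default 0.001).
    """

    def __init__(
        self,
        pairs: Sequence[ProfilePair],
        n_states: int = 5,
        variance_floor: float = 0.001,
    ):
        self.pairs = list(pairs)
        if not self.pairs:
            raise InputError("need at least one profile pair")
        self.n_states = int(n_states)
        self.variance_floor = float(variance_floor)
        self.t1 = self.pairs[0].t1
        self.t2 = self.pairs[0].t2

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        site_long: str,
        site_short: str,
        n_states: int = 5,
        variance_floor: float = 0.001,
    ) -> "AlignmentHMM":
        """Build from a long-format frame with columns gene_id, site, time, value."""
        needed = {"gene_id", "site", "time", "value"}
        if not needed.issubset(df.columns):
            raise InputError(f"need columns {sorted(needed)}")
        pairs = []
        for gid, grp in df.groupby("gene_id", sort=False):
            by_site = {
                s: sub.sort_values("time")["value"].to_numpy()
                for s, sub in grp.groupby("site")
            }
            if site_long not in by_site or site_short not in by_site:
                raise InputError(f"gene {gid}: missing one of the two sites")
            pairs.append(
                ProfilePair(
                    str(gid),
                    Profile(str(gid), site_long, by_site[site_long]),
                    Profile(str(gid), site_short, by_site[site_short]),
                )
            )
        return cls(pairs, n_states=n_states, variance_floor=variance_floor)

    def fit(
        self,
        method: str = "two_step",
        gaps: Sequence[int] | None = None,
        tol: float = 1e-6,
        max_iter: int = 500,
        seed: int | None = None,
        n_starts: int = 1,
    ) -> "AlignmentHMMResults":
        """Fit the model.

        ``method="two_step"`` (default): pooled Baum-Welch over all
        individual profiles, then an exhaustive gap grid search.
        ``method="full_mle"``: EM on the alignment model itself at fixed
        gaps; when ``gaps`` is omitted they are first estimated by the
        two-step procedure.
        """
        if method == "two_step":
            fit, search = _align.fit_two_step(
                self.pairs,
                n_states=self.n_states,
                variance_floor=self.variance_floor,
                tol=tol,
                max_iter=max_iter,
                seed=seed,
                n_starts=n_starts,
            )
            return AlignmentHMMResults(self, fit, search, method=method)
        if method == "full_mle":
            search = None
            if gaps is None:
                _, search = _align.fit_two_step(
                    self.pairs,
                    n_states=self.n_states,
                    variance_floor=self.variance_floor,
                    tol=tol,
                    max_iter=max_iter,
                    seed=seed,
                    n_starts=n_starts,
                )
                gaps = search.best_gaps
            fit = _align.fit_full_mle(
                self.pairs,
                g1=0,
                gaps=gaps,
                n_states=self.n_states,
                variance_floor=self.variance_floor,
                tol=tol,
                max_iter=max_iter,
                seed=seed,
            )
            return AlignmentHMMResults(self, fit, search, method=method, fixed_gaps=tuple(gaps))
        raise InputError(f"unknown method: {method!r}")


class AlignmentHMMResults:
    """Fit results: parameters, gap surface, diagnostics and representations."""

    def __init__(
        self,
        model: AlignmentHMM,
        fit: PooledFit,
        gap_result: GapSearchResult | None,
        method: str,
        fixed_gaps: tuple[int, ...] | None = None,
    ):
        self.model = model
        self.params: HMMParams = fit.params
        self.convergence = fit
        self.gap_result = gap_result
        self.method = method
        self.gaps: tuple[int, ...] = (
            fixed_gaps if fixed_gaps is not None else gap_result.best_gaps
        )
        self.alignment_map = AlignmentMap.from_gap_set(self.gaps, model.t1)

    # -- derived quantities -------------------------------------------------

    @property
    def loglik(self) -> float:
        return self.convergence.loglik

    def alignment_loglik(self) -> float:
        """Total alignment log-likelihood of all pairs at the chosen gaps."""
        g = self.gaps
        return _align.total_loglik(self.model.pairs, self.params, g[0], g[1]) if len(g) == 2 else float(
            sum(_align.pair_loglik(p, self.params, self.alignment_map) for p in self.model.pairs)
        )

    def diagnostics(self, threshold: int = 10) -> pd.DataFrame:
        """Per-gene pair log-likelihood, Hamming distance and label."""
        return _diag.diagnose_pairs(
            self.model.pairs, self.params, self.alignment_map, threshold=threshold
        )

    def roc(self, labels: Sequence[int], threshold: int = 10):
        """ROC curve and AUC of the Hamming classifier against external labels."""
        d = self.diagnostics(threshold=threshold)
        return _diag.roc_curve(d["hamming"].to_numpy(), labels)

    def average_profiles(self) -> pd.DataFrame:
        """Gene x position DataFrame of averaged aligned representations."""
        rows = [
            _align.average_profile(p, self.alignment_map) for p in self.model.pairs
        ]
        return pd.DataFrame(
            rows,
            index=[p.gene_id for p in self.model.pairs],
            columns=[f"pos{u}" for u in range(1, self.model.t1 + 1)],
        )

    def summary(self) -> str:
        lines = []
        w = lines.append
        w("Alignment HMM results")
        w("=" * 54)
        w(f"pairs:            {len(self.model.pairs)}  (T1={self.model.t1}, T2={self.model.t2})")
        w(f"states:           {self.model.n_states}")
        w(f"method:           {self.method}")
        w(f"gap positions:    {self.gaps}")
        if self.gap_result is not None:
            w(f"surface size:     {len(self.gap_result.surface)} gap sets")
            w(f"peak sharpness:   {self.gap_result.peak_sharpness():.2f}")
        w(
            f"EM iterations:    {self.convergence.n_iter}"
            f" (converged: {self.convergence.converged})"
        )
        w(f"log-likelihood:   {self.convergence.loglik:.4f}")
        w("-" * 54)
        w("state   mean      variance")
        for j in range(self.model.n_states):
            w(
                f"{j + 1:>5}   {self.params.emission_means[j]:<8.4f}"
                f"  {self.params.emission_variances[j]:<8.4f}"
            )
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------

    def plot_surface(self, ax=None):
        """Heat-map of the gap log-likelihood surface (two-gap case)."""
        if self.gap_result is None:
            raise InputError("no gap search was run (full-MLE fit at fixed gaps)")
        frame = self.gap_result.to_frame()
        if "g2" not in frame.columns:
            raise InputError("surface heat-map is defined for the two-gap case")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = frame.pivot(index="g2", columns="g1", values="loglik")
        im = ax.imshow(
            grid.to_numpy(),
            origin="lower",
            extent=(
                grid.columns.min() - 0.5,
                grid.columns.max() + 0.5,
                grid.index.min() - 0.5,
                grid.index.max() + 0.5,
            ),
            aspect="auto",
        )
        ax.figure.colorbar(im, ax=ax, label="log-likelihood")
        ax.set_xlabel("g1")
        ax.set_ylabel("g2")
        ax.set_title("Alignment log-likelihood over gap positions")
        return ax

    def plot_pair(self, gene_id: str, ax=None):
        """A pair's aligned profiles with the joint Viterbi path at the state means."""
        import matplotlib.pyplot as plt

        pair = next((p for p in self.model.pairs if p.gene_id == gene_id), None)
        if pair is None:
            raise InputError(f"unknown gene_id {gene_id!r}")
        if ax is None:
            _, ax = plt.subplots()
        amap = self.alignment_map
        ax.plot(amap.tau_long, pair.profile_long.values, "o-", label=pair.profile_long.site)
        ax.plot(amap.tau_short, pair.profile_short.values, "s-", label=pair.profile_short.site)
        path = _align.joint_viterbi(pair, self.params, amap)
        ax.step(
            amap.tau_long,
            self.params.emission_means[path.states - 1],
            where="mid",
            color="k",
            alpha=0.7,
            label="joint Viterbi (state means)",
        )
        ax.set_xlabel("state position")
        ax.set_ylabel("scaled expression")
        ax.set_title(gene_id)
        ax.legend()
        return ax
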