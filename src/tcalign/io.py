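"""Readers, writers and run configuration.

All tables are plain TSV.  Profile collections use a long format
(gene_id, site, time, value) with 1-based time indices, which handles the
two sites' unequal lengths without padding.  Fitted parameters travel as
the JSON document defined by :meth:`tcalign.hmm.HMMParams.to_dict`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from .align import GapSearchResult, ProfilePair
from .hmm import InputError, Profile

__all__ = [
    "RunConfig",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_surface_tsv",
    "read_surface_tsv",
]


@dataclass
class RunConfig:
    """Settings for a reproducible run; defaults match the motivating study
    (5 states, variance floor 0.001, Hamming threshold 10, T1/T2 = 19/17)."""

    n_states: int = 5
    variance_floor: float = 0.001
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    t1: int = 19
    t2: int = 17
    fold_change_threshold: float = 2.0
    hamming_threshold: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_pairs_tsv(pairs: list[ProfilePair], path) -> None:
    rows = []
    for p in pairs:
        for site, prof in (("long", p.profile_long), ("short", p.profile_short)):
            for t, v in enumerate(prof.values, start=1):
                rows.append((p.gene_id, site, prof.site, t, v))
    df = pd.DataFrame(rows, columns=["gene_id", "role", "site", "time", "value"])
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[ProfilePair]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    needed = {"gene_id", "role", "site", "time", "value"}
    if not needed.issubset(df.columns):
        raise InputError(f"pairs table must have columns {sorted(needed)}")
    pairs = []
    for gid, grp in df.groupby("gene_id", sort=False):
        profs = {}
        for role, sub in grp.groupby("role"):
            sub = sub.sort_values("time")
            profs[role] = Profile(str(gid), str(sub["site"].iloc[0]), sub["value"].to_numpy())
        if "long" not in profs or "short" not in profs:
            raise InputError(f"gene {gid}: need both a long and a short profile")
        pairs.append(ProfilePair(str(gid), profs["long"], profs["short"]))
    return pairs


def write_surface_tsv(result: GapSearchResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)


def read_surface_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
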