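"""Per-unit characterisation tables: environmental and CLR taxon averages.

A trained codebook plus an assignment partitions the samples into units;
each unit is summarised by the unweighted arithmetic mean of the requested
environmental variables (original units, missing values skipped and
counted) and by the mean CLR value of every taxon over its member samples.
The long-format export is the machine-readable form of the usual
red-to-green heatmap figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositional import CLRMatrix
from .diversity import DiversityTable
from .neuralgas import BMUAssignment
from .tableio import SampleTable

log = logging.getLogger(__name__)


@dataclass
class BMUProfile:
    """Per-unit averages; either part may be absent until computed."""

    member_ids: dict[int, list[str]]
    env_means: pd.DataFrame | None = None   # unit x variable
    env_n: pd.DataFrame | None = None       # unit x variable, non-missing count
    taxon_means: pd.DataFrame | None = None  # unit x taxon (CLR units)

    @property
    def units(self) -> list[int]:
        return sorted(self.member_ids)

    def merge(self, other: "BMUProfile") -> "BMUProfile":
        if self.member_ids != other.member_ids:
            raise ValueError("profiles built from different assignments")
        return BMUProfile(
            member_ids=self.member_ids,
            env_means=self.env_means if other.env_means is None else other.env_means,
            env_n=self.env_n if other.env_n is None else other.env_n,
            taxon_means=self.taxon_means if other.taxon_means is None
            else other.taxon_means,
        )


def profile_environment(assignment: BMUAssignment, metadata: SampleTable,
                        variables: list[str]) -> BMUProfile:
    """Per-unit mean of each requested variable over member samples."""
    unknown = [v for v in variables if v not in metadata.data.columns]
    if unknown:
        raise KeyError(
            f"unknown variable(s) {unknown}; valid names: "
            f"{sorted(metadata.data.columns)}")
    absent = [s for s in assignment.labels.index if s not in metadata.data.index]
    if absent:
        raise KeyError(f"assigned sample(s) missing from metadata: {absent[:5]}")
    units = range(1, assignment.k_units + 1)
    members = assignment.members
    vals = metadata.data[variables].apply(pd.to_numeric, errors="coerce")
    means = pd.DataFrame(index=list(units), columns=variables, dtype=float)
    ns = pd.DataFrame(0, index=list(units), columns=variables, dtype=int)
    for u in units:
        sub = vals.loc[members[u]]
        means.loc[u] = sub.mean(axis=0)        # NaN-skipping
        ns.loc[u] = sub.notna().sum(axis=0)
    n_missing = int(vals.loc[assignment.labels.index].isna().to_numpy().sum())
    if n_missing:
        log.info("profile_environment: skipped %d missing values", n_missing)
    means.index.name = ns.index.name = "unit"
    return BMUProfile(member_ids=members, env_means=means, env_n=ns)


def profile_taxa(assignment: BMUAssignment, clr: CLRMatrix) -> BMUProfile:
    """Per-unit mean CLR value for every taxon."""
    absent = [s for s in assignment.labels.index if s not in clr.data.index]
    if absent:
        raise KeyError(f"assigned sample(s) missing from CLR matrix: {absent[:5]}")
    members = assignment.members
    units = list(range(1, assignment.k_units + 1))
    means = pd.DataFrame(index=units, columns=clr.feature_ids, dtype=float)
    for u in units:
        if members[u]:
            means.loc[u] = clr.data.loc[members[u]].mean(axis=0)
    means.index.name = "unit"
    return BMUProfile(member_ids=members, taxon_means=means)


def join_diversity(profile: BMUProfile, diversity: DiversityTable) -> BMUProfile:
    """Add per-unit means of the diversity indices as env-style columns."""
    cols = ["observed_mean", "shannon_mean", "pielou_mean"]
    div = diversity.data[cols]
    units = profile.units
    means = pd.DataFrame(index=units, columns=cols, dtype=float)
    ns = pd.DataFrame(0, index=units, columns=cols, dtype=int)
    for u in units:
        sub = div.loc[[s for s in profile.member_ids[u] if s in div.index]]
        if len(sub):
            means.loc[u] = sub.mean(axis=0)
        ns.loc[u] = sub.notna().sum(axis=0)
    env_means = means if profile.env_means is None \
        else pd.concat([profile.env_means, means], axis=1)
    env_n = ns if profile.env_n is None \
        else pd.concat([profile.env_n, ns], axis=1)
    return BMUProfile(member_ids=profile.member_ids, env_means=env_means,
                      env_n=env_n, taxon_means=profile.taxon_means)


def export_heatmap_table(profile: BMUProfile, path) -> pd.DataFrame:
    """Write the profile as a long-format TSV (unit, kind, name, mean, n).

    Rows are sorted by (unit, kind, name); empty units carry n = 0 and an
    empty mean.  Returns the frame that was written.
    """
    rows = []
    for u in profile.units:
        size = len(profile.member_ids[u])
        if profile.env_means is not None:
            for name in profile.env_means.columns:
                rows.append({
                    "unit": u, "kind": "env", "name": name,
                    "mean": profile.env_means.at[u, name],
                    "n": int(profile.env_n.at[u, name]),
                })
        if profile.taxon_means is not None:
            for name in profile.taxon_means.columns:
                rows.append({
                    "unit": u, "kind": "taxon", "name": name,
                    "mean": profile.taxon_means.at[u, name],
                    "n": size,
                })
    out = pd.DataFrame(rows, columns=["unit", "kind", "name", "mean", "n"])
    out = out.sort_values(["unit", "kind", "name"], kind="stable")
    out = out.reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)
    return out
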