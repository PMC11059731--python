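"""Filtering, taxonomic agglomeration, CLR transform and Aitchison distances.

Order of preparation fixed as: taxon prevalence filter, then sample depth
filter, then (per rank) agglomeration, then zero replacement + CLR.  The
pseudo-count delta is a single value for the whole matrix: the global
minimum nonzero relative abundance divided by two; a per-sample variant is
available by flag.  After zero replacement rows are NOT re-closed — the
log-mean centering of the CLR absorbs the closure constant.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .tableio import CountTable, TaxonomyTable, RANKS

log = logging.getLogger(__name__)


@dataclass
class CLRMatrix:
    """Samples x features matrix in centered log-ratio units.

    Each row sums to zero (within 1e-9) by construction.
    """

    data: pd.DataFrame
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        rowsums = self.data.to_numpy().sum(axis=1)
        if self.data.shape[1] and np.abs(rowsums).max() > 1e-9:
            raise ValueError("CLR rows must sum to zero (within 1e-9)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


def filter_taxa(counts: CountTable, min_count: int = 2,
                min_prevalence: float = 0.05) -> CountTable:
    """Keep features seen >= `min_count` times in >= ceil(p * n) samples.

    Defaults mirror standard amplicon practice: at least 2 reads in at
    least 5% of samples.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    n = counts.n_samples
    need = math.ceil(min_prevalence * n)
    qualifying = (counts.data >= min_count).sum(axis=0)
    keep = qualifying[qualifying >= need].index
    if len(keep) == 0:
        warnings.warn("taxon filter removed every feature", stacklevel=2)
    log.info("filter_taxa: retained %d/%d features (min_count=%d, "
             "min_prevalence=%g, need>=%d samples)",
             len(keep), counts.n_features, min_count, min_prevalence, need)
    return CountTable(counts.data[keep])


def filter_samples(counts: CountTable, min_depth: int = 2000) -> CountTable:
    """Keep samples whose read depth is >= `min_depth` (boundary kept)."""
    depths = counts.depths()
    keep = depths[depths >= min_depth].index
    if len(keep) == 0:
        warnings.warn("depth filter removed every sample", stacklevel=2)
    log.info("filter_samples: retained %d/%d samples (min_depth=%d)",
             len(keep), counts.n_samples, min_depth)
    return CountTable(counts.data.loc[keep])


def agglomerate(counts: CountTable, taxonomy: TaxonomyTable,
                rank: str) -> CountTable:
    """Sum features sharing a lineage down to `rank`.

    Output feature ids are ';'-joined lineage strings down to `rank`,
    so identically-named genera under different orders stay distinct.
    `rank='asv'` is the identity mapping.
    """
    if rank == "asv":
        return CountTable(counts.data.copy())
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS + ('asv',)}")
    missing = [f for f in counts.feature_ids if f not in taxonomy.data.index]
    if missing:
        raise KeyError(f"features missing from taxonomy: {missing[:5]}")
    lineage = taxonomy.lineage(rank).loc[counts.feature_ids]
    # integer sums conserve per-sample totals exactly
    glommed = counts.data.T.groupby(lineage.values).sum().T
    glommed = glommed.sort_index(axis=1)
    return CountTable(glommed)


def relative_abundance(counts: CountTable) -> pd.DataFrame:
    """Row-normalise counts to proportions (rows sum to 1)."""
    depths = counts.depths()
    zero = depths.index[depths == 0]
    if len(zero):
        raise ValueError(
            f"zero-sum sample(s) {list(zero[:5])}: apply filter_samples first"
        )
    return counts.data.div(depths, axis=0)


def clr_transform(counts: CountTable,
                  pseudocount: float | str = "half_min_rel",
                  per_sample: bool = False) -> CLRMatrix:
    """Centered log-ratio transform with pseudo-count zero replacement.

    Zeros in the relative-abundance matrix are replaced by delta = (minimum
    nonzero relative abundance)/2 — global by default, per-sample with
    `per_sample=True` — or by an explicit value.  CLR(x)_j = ln x_j - mean_k
    ln x_k per row.
    """
    rel = relative_abundance(counts).to_numpy(dtype=float)
    if isinstance(pseudocount, str):
        if pseudocount != "half_min_rel":
            raise ValueError(f"unknown pseudocount rule {pseudocount!r}")
        nz = np.where(rel > 0, rel, np.nan)
        if per_sample:
            delta = np.nanmin(nz, axis=1, keepdims=True) / 2.0
            delta_logged = float(np.nanmin(nz) / 2.0)
        else:
            delta = float(np.nanmin(nz)) / 2.0
            delta_logged = delta
    else:
        delta = float(pseudocount)
        delta_logged = delta
    filled = np.where(rel > 0, rel, delta)
    logx = np.log(filled)
    clr = logx - logx.mean(axis=1, keepdims=True)
    log.info("clr_transform: pseudo-count delta=%.6g (per_sample=%s)",
             delta_logged, per_sample)
    df = pd.DataFrame(clr, index=counts.sample_ids, columns=counts.feature_ids)
    return CLRMatrix(df, pseudocount=delta_logged)


def aitchison_distance(clr: CLRMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance between CLR rows (Aitchison distance)."""
    d = squareform(pdist(clr.data.to_numpy(), metric="euclidean"))
    return DistanceMatrix(d, ids=clr.sample_ids)
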