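"""Readers, writers and validated containers for the three core tables.

The canonical interchange format is tab-separated text.  Count tables are
stored on disk with features as rows (first column = feature id, header =
sample ids), matching common amplicon practice; in memory they are held
samples-as-rows.  Writers sort both axes lexicographically so outputs are
diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
SEASONS = ("Winter", "Spring", "Summer", "Autumn")
LAYERS = ("L1", "L2", "L3", "L4")

#: abiotic water-column variables (temperature degC, salinity, nutrients
#: umol/L, chlorophyll a ug/L)
ABIOTIC_VARS = (
    "Temp", "Sal", "NO3", "NO2", "NH4", "DIN", "NTOT", "PO4", "PTOT",
    "SiO4", "Chl_a",
)
#: biotic variables: heterotrophic bacteria, high-NA bacteria,
#: Synechococcus, Prochlorococcus, picoeukaryotes, nanoflagellates
#: (cells/mL), bacterial production, absolute abundance of aerobic
#: anoxygenic phototrophs (cells/mL)
BIOTIC_VARS = ("UHB", "HNA", "SYN", "PROCHL", "PE", "HNF", "BP", "AAP_abs")
ENV_VARS = ABIOTIC_VARS + BIOTIC_VARS
#: FISH-IR probe columns, as % of AAP cells hybridised per probe
FISH_VARS = ("ALF968", "GAM42a", "ROS537")


class TableValidationError(ValueError):
    """Raised when an input table violates its contract."""


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate {what}: {dups[:5]}")
    if (s.astype(str) == "").any():
        raise TableValidationError(f"empty {what} not allowed")


@dataclass
class CountTable:
    """Samples x features matrix of non-negative integer read counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "feature ids")
        arr = self.data.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise TableValidationError("counts must be numeric")
            if np.isnan(arr.astype(float)).any():
                r, c = np.argwhere(np.isnan(arr.astype(float)))[0]
                raise TableValidationError(
                    f"missing count at sample {self.data.index[r]!r}, "
                    f"feature {self.data.columns[c]!r}"
                )
            if (arr < 0).any():
                r, c = np.argwhere(arr < 0)[0]
                raise TableValidationError(
                    f"negative count at sample {self.data.index[r]!r}, "
                    f"feature {self.data.columns[c]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise TableValidationError(
                    f"non-integer count at sample {self.data.index[r]!r}, "
                    f"feature {self.data.columns[c]!r}"
                )
        self.data = self.data.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample read depth (row sums)."""
        return self.data.sum(axis=1)

    def __eq__(self, other) -> bool:  # field-by-field equality
        return isinstance(other, CountTable) and self.data.equals(other.data)


@dataclass
class TaxonomyTable:
    """Per-feature ranked lineage (domain ... genus).

    Unclassified ranks carry a deterministic placeholder derived from the
    deepest classified rank, e.g. a blank genus under order "Rhodobacterales"
    with blank family becomes ``o:Rhodobacterales_unclassified``.  The
    placeholder embeds the full parent lineage context through its deepest
    named ancestor, which keeps distinct parents distinct after
    agglomeration.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise TableValidationError(f"taxonomy missing rank columns: {missing}")
        _check_unique(self.data.index, "feature ids")
        self.data = fill_placeholders(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, rank: str) -> pd.Series:
        """Full lineage string down to `rank`, ';'-joined."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
        upto = RANKS[: RANKS.index(rank) + 1]
        return self.data[list(upto)].agg(";".join, axis=1)


def fill_placeholders(tax: pd.DataFrame) -> pd.DataFrame:
    """Replace blank/NaN ranks by '<r>:<name>_unclassified' placeholders."""
    tax = tax.copy()
    for col in RANKS:
        tax[col] = tax[col].fillna("").astype(str).str.strip()
    rank_initial = {r: r[0] for r in RANKS}
    for i in tax.index:
        deepest_rank, deepest_name = None, None
        for r in RANKS:
            v = tax.at[i, r]
            if v and not v.endswith("_unclassified"):
                deepest_rank, deepest_name = r, v
            elif not v:
                if deepest_name is None:
                    raise TableValidationError(
                        f"feature {i!r} has no classified rank at all"
                    )
                tax.at[i, r] = (
                    f"{rank_initial[deepest_rank]}:{deepest_name}_unclassified"
                )
    return tax


@dataclass
class SampleTable:
    """Per-sample context: design factors, environment, FISH fractions."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        problems: list[str] = []
        if "season" in self.data.columns:
            bad = set(self.data["season"].dropna()) - set(SEASONS)
            if bad:
                problems.append(f"unknown season token(s) {sorted(bad)}; "
                                f"expected one of {SEASONS}")
        if "layer" in self.data.columns:
            bad = set(self.data["layer"].dropna()) - set(LAYERS)
            if bad:
                problems.append(f"unknown layer token(s) {sorted(bad)}; "
                                f"expected one of {LAYERS}")
        for col in FISH_VARS:
            if col in self.data.columns:
                v = pd.to_numeric(self.data[col], errors="coerce")
                out = self.data.index[(v < 0) | (v > 100)]
                if len(out):
                    problems.append(
                        f"{col} outside [0, 100] for samples {list(out[:5])}"
                    )
        for col in BIOTIC_VARS:
            if col in self.data.columns:
                v = pd.to_numeric(self.data[col], errors="coerce")
                neg = self.data.index[v < 0]
                if len(neg):
                    problems.append(f"{col} negative for samples {list(neg[:5])}")
        if problems:
            raise TableValidationError(
                "metadata validation failed:\n  " + "\n  ".join(problems)
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, sep: str | None = None) -> pd.DataFrame:
    sep = sep or ("," if str(path).endswith(".csv") else "\t")
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def read_count_table(path, orientation: str = "features_as_rows") -> CountTable:
    """Read a count table; `orientation` names how the *file* is laid out."""
    df = _read_tsv(path)
    if orientation == "features_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(df)


def write_count_table(table: CountTable, path) -> None:
    """Write features-as-rows TSV with lexicographically sorted axes."""
    out = table.data.sort_index(axis=0).sort_index(axis=1).T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyTable:
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    out = tax.data.sort_index(axis=0)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleTable:
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return SampleTable(df)


def write_metadata(meta: SampleTable, path) -> None:
    out = meta.data.sort_index(axis=0)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
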