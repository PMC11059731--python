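"""Synthetic community generator with planted compositional clusters.

Emulates a post-denoising marine amplicon survey: ~81 samples, ~661
amplicon variants nested in ~86 genera / 8 orders / 2 proteobacterial
classes, log-normal library sizes floored at 2000 reads, five planted
sample clusters realised as Gaussian centers in CLR space (logistic-normal
compositions), environmental variables covarying with cluster identity,
total phototroph abundances near 1.4e4 cells/mL, and FISH-like class-level
percentages derived from the true compositions plus Gaussian noise.

Ground-truth cluster labels are returned so downstream cluster recovery
can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tableio import (ABIOTIC_VARS, BIOTIC_VARS, CountTable, FISH_VARS,
                      SampleTable, TaxonomyTable, write_count_table,
                      write_metadata, write_taxonomy)

log = logging.getLogger(__name__)

#: per-cluster means of the environmental variables (columns), one row per
#: planted cluster.  Values are realistic for an oligotrophic temperate sea:
#: cluster 1 nutrient-enriched/low salinity, 2 warm shallow, 3 saline
#: low-ammonium, 4 cold nitrite-rich, 5 deep cold saline nutrient-poor.
DEFAULT_ENV_RESPONSE = pd.DataFrame(
    {
        "Temp":   [16.0, 24.0, 20.0, 12.0, 14.0],      # degC
        "Sal":    [36.5, 37.5, 38.5, 38.0, 38.7],
        "NO3":    [1.20, 0.20, 0.15, 0.50, 0.30],      # umol/L
        "NO2":    [0.15, 0.05, 0.08, 0.25, 0.10],
        "NH4":    [0.80, 0.30, 0.10, 0.40, 0.60],
        "NTOT":   [12.0, 6.0, 5.0, 8.0, 7.0],
        "PO4":    [0.08, 0.02, 0.02, 0.04, 0.03],
        "PTOT":   [0.25, 0.10, 0.08, 0.15, 0.12],
        "SiO4":   [3.00, 1.50, 1.20, 2.00, 2.50],
        "Chl_a":  [0.90, 0.20, 0.15, 0.40, 0.50],      # ug/L
        "UHB":    [1.2e6, 4.0e5, 3.5e5, 6.0e5, 5.0e5],  # cells/mL
        "HNA":    [5.0e5, 1.8e5, 1.5e5, 2.5e5, 2.0e5],
        "SYN":    [4.0e4, 1.5e4, 2.5e4, 3.5e4, 1.0e4],
        "PROCHL": [2.0e3, 8.0e3, 6.0e3, 1.0e3, 1.2e4],
        "PE":     [3.0e3, 8.0e2, 7.0e2, 1.5e3, 1.0e3],
        "HNF":    [1.5e3, 5.0e2, 6.0e2, 1.2e3, 4.0e2],
        "BP":     [0.80, 0.30, 0.25, 0.45, 0.35],      # ugC/L/h
    },
    index=[1, 2, 3, 4, 5],
)

#: per-variable Gaussian noise sd: 10% of the across-cluster range
DEFAULT_ENV_NOISE = (DEFAULT_ENV_RESPONSE.max() - DEFAULT_ENV_RESPONSE.min()) * 0.10

#: dominant season per planted cluster (months drawn mostly from it)
_CLUSTER_SEASON = {1: "Spring", 2: "Summer", 3: "Autumn", 4: "Winter",
                   5: "Winter"}
_SEASON_MONTHS = {
    "Winter": (1, 2, 3, 4), "Spring": (5, 6), "Summer": (7, 8, 9, 10),
    "Autumn": (11, 12),
}
_STATIONS = ("ST101", "CJ007", "CJ009")
_DEPTHS_M = (0, 30, 50, 75, 100)

#: FISH probes mapped to synthetic taxa: ALF968 counts class C1 cells,
#: GAM42a class C2, ROS537 the C1.O1 order subset of C1
FISH_PROBE_TAXA = {"ALF968": ("class", "C1"), "GAM42a": ("class", "C2"),
                   "ROS537": ("order", "C1.O1")}


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated survey's conditions."""

    n_samples: int = 81
    n_clusters_true: int = 5
    n_classes: int = 2
    n_orders: int = 8
    n_genera: int = 86
    n_asvs: int = 661
    # log-normal library sizes: median ~58,000 reads, hard floor 2000
    depth_log_mean: float = float(np.log(58_000.0))
    depth_log_sd: float = 0.8
    depth_floor: int = 2000
    # planted structure in CLR space
    cluster_logratio_centers: np.ndarray | None = None
    center_scale: float = 2.0       # sd of generated center coordinates
    within_cluster_sd: float = 1.0  # CLR units
    balanced_labels: bool = False   # fixed-block override for uniform draws
    # environment linked to cluster identity
    env_response: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_ENV_RESPONSE.copy())
    env_noise_sd: pd.Series = field(
        default_factory=lambda: DEFAULT_ENV_NOISE.copy())
    # FISH percentages: truth + Gaussian noise, clipped to [0, 100]
    fish_noise_sd: float = 2.0      # percentage points
    # total AAP abundance, log-normal with mean ~1.43e4, sd ~0.75e4 cells/mL
    aap_log_mean: float = 9.446
    aap_log_sd: float = 0.493
    seed: int = 0

    def __post_init__(self) -> None:
        shape = (self.n_classes, self.n_orders, self.n_genera, self.n_asvs)
        if not (shape[3] >= shape[2] >= shape[1] >= shape[0] >= 1):
            raise ValueError(
                f"taxonomy shape must be nested (asvs >= genera >= orders "
                f">= classes >= 1), got {shape}")
        if self.depth_floor < 2000:
            raise ValueError("depth floor must be >= 2000 reads")
        if self.within_cluster_sd < 0 or self.fish_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if (np.asarray(self.env_noise_sd) < 0).any():
            raise ValueError("env noise sds must be >= 0")
        if self.cluster_logratio_centers is not None:
            c = np.asarray(self.cluster_logratio_centers)
            if c.shape != (self.n_clusters_true, self.n_asvs):
                raise ValueError(
                    f"cluster centers shape {c.shape} does not match "
                    f"(n_clusters={self.n_clusters_true}, n_asvs={self.n_asvs})")
        if len(self.env_response) < self.n_clusters_true:
            raise ValueError("env_response must have one row per cluster")


def generate_taxonomy(shape: tuple[int, int, int, int],
                      seed: int = 0) -> TaxonomyTable:
    """Strictly nested synthetic lineage table.

    `shape` is (classes, orders, genera, asvs).  Children are spread over
    parents as evenly as possible; which parents receive the remainder is
    drawn from the seeded generator, so identical (shape, seed) give
    byte-identical tables.  Names are stable: classes "C1", orders
    "C1.O2", genera "C1.O2.G5", features "ASV0001"...; one family per
    order ("C1.O2.F1").
    """
    n_classes, n_orders, n_genera, n_asvs = shape
    if not (n_asvs >= n_genera >= n_orders >= n_classes >= 1):
        raise ValueError(
            f"shape must be nested (asvs >= genera >= orders >= classes "
            f">= 1), got {shape}")
    rng = np.random.default_rng(seed)

    def split(n_children: int, parents: list[str], label: str) -> list[str]:
        k = len(parents)
        sizes = np.full(k, n_children // k)
        extra = rng.choice(k, size=n_children - sizes.sum(), replace=False)
        sizes[extra] += 1
        out = []
        for parent, size in zip(parents, sizes):
            out += [f"{parent}.{label}{i + 1}" for i in range(size)]
        return out

    classes = [f"C{i + 1}" for i in range(n_classes)]
    orders = split(n_orders, classes, "O")
    genera = split(n_genera, orders, "G")
    genus_of_asv = split(n_asvs, genera, "A")  # names then stripped back

    rows = []
    for i, leaf in enumerate(genus_of_asv):
        genus = leaf.rsplit(".", 1)[0]
        order = genus.rsplit(".", 1)[0]
        klass = order.rsplit(".", 1)[0]
        rows.append({
            "feature_id": f"ASV{i + 1:04d}",
            "domain": "Bacteria", "phylum": "Proteobacteria",
            "class": klass, "order": order, "family": f"{order}.F1",
            "genus": genus,
        })
    df = pd.DataFrame(rows).set_index("feature_id")
    return TaxonomyTable(df)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def generate_dataset(
    config: SimConfig = SimConfig(),
) -> tuple[CountTable, TaxonomyTable, SampleTable, pd.Series]:
    """Draw one synthetic dataset; returns (counts, taxonomy, metadata,
    true cluster labels)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    taxonomy = generate_taxonomy(
        (cfg.n_classes, cfg.n_orders, cfg.n_genera, cfg.n_asvs), cfg.seed)
    n, k, p = cfg.n_samples, cfg.n_clusters_true, cfg.n_asvs

    centers = cfg.cluster_logratio_centers
    if centers is None:
        centers = rng.normal(0.0, cfg.center_scale, size=(k, p))
        centers -= centers.mean(axis=1, keepdims=True)
    centers = np.asarray(centers, dtype=float)

    if cfg.balanced_labels:
        labels = rng.permutation(np.arange(n) % k) + 1
    else:
        labels = rng.integers(1, k + 1, size=n)

    z = centers[labels - 1] + rng.normal(0.0, cfg.within_cluster_sd, (n, p))
    comp = _softmax(z)

    depths = np.maximum(
        np.round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd, n)),
        cfg.depth_floor).astype(np.int64)
    counts = np.vstack([rng.multinomial(depths[i], comp[i]) for i in range(n)])

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    count_table = CountTable(pd.DataFrame(
        counts, index=sample_ids, columns=taxonomy.feature_ids))

    # --- environment linked to cluster identity
    env_vars = [v for v in ABIOTIC_VARS + BIOTIC_VARS
                if v in cfg.env_response.columns]
    meta = pd.DataFrame(index=sample_ids)
    resp = cfg.env_response.to_numpy(dtype=float)
    var_cols = list(cfg.env_response.columns)
    noise = np.asarray(cfg.env_noise_sd.reindex(var_cols).fillna(0.0))
    drawn = resp[labels - 1] + rng.normal(0.0, 1.0, (n, len(var_cols))) * noise
    env = pd.DataFrame(drawn, index=sample_ids, columns=var_cols)
    nonneg = [c for c in var_cols if c != "Temp"]
    env[nonneg] = env[nonneg].clip(lower=0.0)
    for v in env_vars:
        meta[v] = env[v]
    # dissolved inorganic nitrogen is the sum of its components
    meta["DIN"] = meta[["NO3", "NO2", "NH4"]].sum(axis=1)
    meta["AAP_abs"] = rng.lognormal(cfg.aap_log_mean, cfg.aap_log_sd, n)

    # --- design factors: month drawn mostly from the cluster's season
    months = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        season = _CLUSTER_SEASON.get(int(lab), "Winter")
        pool = _SEASON_MONTHS[season] if rng.random() < 0.8 \
            else tuple(range(1, 13))
        months[i] = pool[rng.integers(len(pool))]
    meta["month"] = months
    meta["season"] = [next(s for s, ms in _SEASON_MONTHS.items() if m in ms)
                      for m in months]
    meta["station"] = [_STATIONS[j] for j in rng.integers(0, 3, n)]
    depth_m = np.array([_DEPTHS_M[j] for j in rng.integers(0, 5, n)])
    meta["depth_m"] = depth_m
    meta["layer"] = pd.cut(depth_m, bins=[-1, 29, 49, 74, 1000],
                           labels=["L1", "L2", "L3", "L4"]).astype(str)

    # --- FISH-like fractions: true probe-taxon percentage + noise
    for probe, (rank, taxon) in FISH_PROBE_TAXA.items():
        mask = (taxonomy.data[rank] == taxon).to_numpy()
        truth = 100.0 * comp[:, mask].sum(axis=1)
        noisy = truth + rng.normal(0.0, cfg.fish_noise_sd, n)
        meta[probe] = np.clip(noisy, 0.0, 100.0)

    order = (["station", "depth_m", "month", "season", "layer"]
             + list(ABIOTIC_VARS) + list(BIOTIC_VARS) + list(FISH_VARS))
    meta = meta[[c for c in order if c in meta.columns]]
    metadata = SampleTable(meta)
    truth = pd.Series(labels, index=sample_ids, name="true_cluster")
    return count_table, taxonomy, metadata, truth


def write_dataset(outdir, counts: CountTable, taxonomy: TaxonomyTable,
                  metadata: SampleTable, labels: pd.Series,
                  config: SimConfig | None = None) -> None:
    """Write the three standard tables, the labels file and a config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_table(counts, outdir / "counts.tsv")
    write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
    write_metadata(metadata, outdir / "metadata.tsv")
    lab = labels.rename_axis("sample_id").to_frame().sort_index()
    lab.to_csv(outdir / "labels.tsv", sep="\t")
    if config is not None:
        echo = {k: v for k, v in vars(config).items()
                if isinstance(v, (int, float, bool, str))}
        with open(outdir / "simconfig.yaml", "w") as fh:
            yaml.safe_dump(echo, fh, sort_keys=True)
        log.info("write_dataset: seed=%s -> %s", config.seed, outdir)


def load_sim_config(path) -> SimConfig:
    """Load a SimConfig from a YAML mapping of scalar fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig(**data)
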