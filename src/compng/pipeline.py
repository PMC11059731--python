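"""End-to-end orchestration: filter -> agglomerate -> CLR -> neural gas ->
profiles -> diversity -> permutation tests -> concordance.

Every stage writes plain TSV/JSON so any stage can be re-run standalone,
and a manifest records the configuration, seeds, pseudo-count deltas and
dropped identifiers needed to reproduce the run exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compositional import (aitchison_distance, agglomerate, clr_transform,
                            filter_samples, filter_taxa)
from .diversity import repeated_rarefaction_diversity
from .neuralgas import NGConfig, assign_bmu, relabel_units, train_neural_gas
from .profiling import (export_heatmap_table, join_diversity,
                        profile_environment, profile_taxa)
from .stats import concordance, permanova_oneway, permdisp
from .synthdata import FISH_PROBE_TAXA, SimConfig, generate_dataset, \
    write_dataset
from .tableio import (ABIOTIC_VARS, BIOTIC_VARS, read_count_table,
                      read_metadata, read_taxonomy)

log = logging.getLogger(__name__)

VALID_RANKS = ("order", "genus", "asv")


@dataclass
class PipelineConfig:
    """Full-run settings; exactly one of (input paths, sim) must be set."""

    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    sim: SimConfig | None = None
    ranks: tuple[str, ...] = ("order", "genus", "asv")
    min_count: int = 2
    min_prevalence: float = 0.05
    min_depth: int = 2000
    ng: NGConfig = field(default_factory=NGConfig)
    rarefaction_depth: int = 2000
    rarefaction_repeats: int = 100
    n_perm: int = 9999
    permanova_factor: str = "season"
    concordance_map: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(FISH_PROBE_TAXA))
    outdir: str = "compng_run"
    seed: int = 0

    def __post_init__(self) -> None:
        paths = (self.counts_path, self.taxonomy_path, self.metadata_path)
        have_paths = all(p is not None for p in paths)
        if have_paths == (self.sim is not None):
            raise ValueError(
                "provide exactly one of: the three input table paths, or a "
                "synthetic-data configuration")
        if not self.ranks:
            raise ValueError("at least one agglomeration rank is required")
        bad = [r for r in self.ranks if r not in VALID_RANKS]
        if bad:
            raise ValueError(f"unknown rank(s) {bad}; valid: {VALID_RANKS}")


def config_from_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "sim" in raw and raw["sim"] is not None:
        raw["sim"] = SimConfig(**raw["sim"])
    if "ng" in raw:
        raw["ng"] = NGConfig(**raw["ng"])
    if "ranks" in raw:
        raw["ranks"] = tuple(raw["ranks"])
    if "concordance_map" in raw:
        raw["concordance_map"] = {
            k: tuple(v) for k, v in raw["concordance_map"].items()}
    return PipelineConfig(**raw)


def _fmt(df: pd.DataFrame, path: Path, index_name: str | None = None) -> None:
    out = df.copy()
    if index_name:
        out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "ranks": list(cfg.ranks),
        "filters": {"min_count": cfg.min_count,
                    "min_prevalence": cfg.min_prevalence,
                    "min_depth": cfg.min_depth},
        "ng": asdict(cfg.ng),
        "rarefaction": {"depth": cfg.rarefaction_depth,
                        "repeats": cfg.rarefaction_repeats},
        "n_perm": cfg.n_perm,
        "permanova_factor": cfg.permanova_factor,
        "concordance_map": {k: list(v)
                            for k, v in cfg.concordance_map.items()},
    }

    stage = "load"
    try:
        if cfg.sim is not None:
            counts, taxonomy, metadata, labels = generate_dataset(cfg.sim)
            write_dataset(outdir / "inputs", counts, taxonomy, metadata,
                          labels, cfg.sim)
            manifest["input"] = {"mode": "synthetic", "sim_seed": cfg.sim.seed}
        else:
            counts = read_count_table(cfg.counts_path)
            taxonomy = read_taxonomy(cfg.taxonomy_path)
            metadata = read_metadata(cfg.metadata_path)
            labels = None
            manifest["input"] = {"mode": "files",
                                 "counts": str(cfg.counts_path),
                                 "taxonomy": str(cfg.taxonomy_path),
                                 "metadata": str(cfg.metadata_path)}

        stage = "filter"
        before_taxa = set(counts.feature_ids)
        counts = filter_taxa(counts, cfg.min_count, cfg.min_prevalence)
        dropped_taxa = sorted(before_taxa - set(counts.feature_ids))
        before_samples = set(counts.sample_ids)
        counts = filter_samples(counts, cfg.min_depth)
        dropped_samples = sorted(before_samples - set(counts.sample_ids))
        manifest["dropped"] = {"features": dropped_taxa,
                               "samples": dropped_samples}
        metadata.data = metadata.data.loc[counts.sample_ids]

        stage = "diversity"
        diversity = repeated_rarefaction_diversity(
            counts, cfg.rarefaction_depth, cfg.rarefaction_repeats,
            seed=cfg.seed)
        _fmt(diversity.data, outdir / "diversity.tsv")

        env_vars = [v for v in ABIOTIC_VARS + BIOTIC_VARS
                    if v in metadata.data.columns]
        manifest["ranks_detail"] = {}
        stats_out: dict = {}
        for rank in cfg.ranks:
            stage = f"rank:{rank}"
            rdir = outdir / rank
            rdir.mkdir(exist_ok=True)
            glommed = agglomerate(counts, taxonomy, rank)
            clr = clr_transform(glommed)
            _fmt(clr.data, rdir / "clr.tsv", "sample_id")

            model = train_neural_gas(clr, cfg.ng)
            assignment = assign_bmu(model, clr)
            model, assignment = relabel_units(model, assignment)
            _fmt(model.codebook, rdir / "codebook.tsv", "unit")
            assignment.labels.rename_axis("sample_id").to_frame().to_csv(
                rdir / "assignment.tsv", sep="\t")

            prof = profile_environment(assignment, metadata, env_vars)
            prof = prof.merge(profile_taxa(assignment, clr))
            prof = join_diversity(prof, diversity)
            export_heatmap_table(prof, rdir / "bmu_profile.tsv")

            dist = aitchison_distance(clr)
            factor = metadata.data[cfg.permanova_factor].loc[clr.sample_ids]
            # permutation tests need >= 2 members per level
            level_sizes = factor.value_counts()
            usable = factor[factor.isin(level_sizes[level_sizes >= 2].index)]
            if len(usable) < len(factor):
                log.info("rank %s: excluding singleton %s level(s) %s from "
                         "permutation tests", rank, cfg.permanova_factor,
                         sorted(level_sizes[level_sizes < 2].index))
            sub = dist.filter(list(usable.index))
            pmv = permanova_oneway(sub, usable, cfg.n_perm, seed=cfg.seed)
            pdp = permdisp(sub, usable, cfg.n_perm, seed=cfg.seed)
            stats_out[rank] = {
                "permanova": asdict(pmv), "permdisp": asdict(pdp),
                "quantization_error": model.quantization_error,
            }
            manifest["ranks_detail"][rank] = {
                "n_features": glommed.n_features,
                "pseudocount_delta": clr.pseudocount,
                "unit_sizes": {int(u): int(s)
                               for u, s in assignment.sizes.items()},
            }

        stage = "concordance"
        conc = {}
        if all(p in metadata.data.columns for p in cfg.concordance_map):
            aap = metadata.data["AAP_abs"]
            for probe, (rank, taxon) in cfg.concordance_map.items():
                glommed = agglomerate(counts, taxonomy, rank)
                # agglomerated ids are full lineage strings; match the tail
                match = [c for c in glommed.feature_ids
                         if c == taxon or c.endswith(";" + taxon)
                         or c.split(";")[-1] == taxon]
                rel = glommed.data[match].sum(axis=1) / glommed.depths() * 100
                res = concordance(metadata.data[probe], rel, aap, group=probe)
                conc[probe] = asdict(res)
        stats_out["concordance"] = conc
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=2, sort_keys=True)

        manifest["stats"] = stats_out
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    log.info("pipeline complete -> %s", outdir)
    return outdir
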