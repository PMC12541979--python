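"""End-to-end orchestration: simulate/load -> partition -> diversity -> beta
-> SIMPER -> function profiles -> constrained ordination, with a manifest.

A single :class:`PipelineConfig` (YAML-loadable) drives every stage.  One
global seed is expanded into per-stage seeds through a spawned seed
sequence, so stages can be rerun independently yet reproducibly; the run
manifest records every derived seed, every default that filled a gap in
the upstream protocol (log-abundance regression axis, CLR pseudocount
policy, permutation counts), and a SHA-256 hash of every output file.
Rerunning an identical config+seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import beta, diversity, functions, ordination, partition
from .io import (CountMatrix, read_contribution_table, read_count_table,
                 read_metadata, read_taxonomy_table, remove_singleton_taxa,
                 collapse_to_species_otus, to_relative_abundance,
                 write_count_table)
from .simulate import SimulationConfig, simulate_counts, simulate_pathway_assignments

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; exactly one input source.

    Either ``simulation`` holds a :class:`SimulationConfig`, or
    ``counts_path`` + ``metadata_path`` (and optionally taxonomy and
    contribution tables) point at files on disk.
    """

    output_dir: str = "coresat_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    contributions_path: str | None = None
    mapping_path: str | None = None
    orientation: str = "taxa_by_samples"
    threshold: float = 75.0
    log_abundance: bool = True
    rarefaction_depth: int | None = None
    n_perm: int = 999
    abundance_threshold_pct: float = 1.0
    heatmap_test: str = "anova"
    covariates: list[str] = field(default_factory=list)
    ordination_alpha: float = 0.05
    reference_group: str | None = None

    def __post_init__(self) -> None:
        has_files = self.counts_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError(
                "exactly one of (counts_path+metadata_path, simulation) "
                "must be provided")
        if has_files and self.metadata_path is None:
            raise ValueError("counts_path requires metadata_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulation", None)
        cfg = cls(**raw, simulation=SimulationConfig(**sim) if sim else None)
        return cfg


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2**31))
            for name, c in zip(names, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o: Any) -> Any:
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_all(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage in order and return the manifest (also written to disk).

    Stage order: io -> partition per group -> diversity -> beta (similarity,
    ANOSIM, PCoA, ellipses) -> SIMPER -> function profiles -> constrained
    ordination.  Any stage error aborts with the stage named.  All outputs
    land under ``cfg.output_dir``; the manifest hashes each file.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_names = ["simulate", "rarefaction", "anosim", "simper", "function",
                   "ordination"]
    seeds = _stage_seeds(cfg.seed, stage_names)
    manifest: dict[str, Any] = {
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "stage_seeds": seeds,
        "gap_filling_defaults": {
            "regression_abundance_axis": "log10" if cfg.log_abundance else "linear",
            "relative_abundance_computed": "after singleton removal and collapsing",
            "fisher_alpha_counts": "unrarefied",
            "shannon_counts": "rarefied",
            "simper_scale": "percent relative abundance",
            "clr_pseudocount": "half minimum positive value, multiplicative",
            "pathway_filter": "pooled table, strict > threshold",
            "anosim_p_estimator": "(1 + #{R_perm >= R_obs}) / (1 + n_perm)",
            "n_perm": cfg.n_perm,
            "ordination_response": "hellinger (rda) / relative abundance (cca)",
        },
        "stages": {},
        "files": {},
    }

    def stage(name: str):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(name: str, t0: float, **info: Any) -> None:
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        manifest["stages"][name] = info

    try:
        # ---------------- io / simulate ----------------
        t0 = stage("io")
        contrib = None
        mapping = None
        truth = None
        if cfg.simulation is not None:
            sim_cfg = dataclasses.replace(cfg.simulation, seed=seeds["simulate"])
            m, truth = simulate_counts(sim_cfg)
            contrib = simulate_pathway_assignments(sim_cfg, truth, m)
            write_count_table(m, out / "counts.tsv")
            meta = pd.DataFrame({"sample_id": m.sample_ids,
                                 "group": [m.groups[s] for s in m.sample_ids]})
            meta.to_csv(out / "metadata.csv", index=False)
            contrib.to_csv(out / "contributions.tsv", sep="\t", index=False)
            _write_json({"labels": {t: truth.labels.loc[t].to_dict()
                                    for t in truth.labels.index},
                         "satellite_exclusive_pathways":
                             truth.satellite_exclusive_pathways},
                        out / "ground_truth.json")
        else:
            counts = read_count_table(cfg.counts_path, cfg.orientation)
            meta = read_metadata(cfg.metadata_path)
            m = CountMatrix(counts, meta["group"])
            if cfg.taxonomy_path:
                tax = read_taxonomy_table(cfg.taxonomy_path)
                m = collapse_to_species_otus(m, tax)
            if cfg.contributions_path:
                contrib = read_contribution_table(cfg.contributions_path)
            if cfg.mapping_path:
                mapping = pd.read_csv(cfg.mapping_path, sep="\t")
        m = remove_singleton_taxa(m)
        if contrib is not None:
            # contributions from taxa dropped by the singleton rule leave too
            contrib = contrib[contrib["taxon_id"].isin(m.taxon_ids)]
        rel = to_relative_abundance(m)
        done("io", t0, n_taxa=len(m.taxon_ids), n_samples=len(m.sample_ids),
             groups={g: len(m.samples_in_group(g)) for g in m.group_labels()})

        # ---------------- partition per group ----------------
        t0 = stage("partition")
        parts = partition.partition_all_groups(m, cfg.threshold, cfg.log_abundance)
        part_info = {}
        for g, p in parts.items():
            summary = partition.summarize_taxa(m, g)
            summary["label"] = p.labels
            summary.to_csv(out / f"partition_{g}.tsv", sep="\t")
            share = partition.partition_abundance_share(m, p, g)
            part_info[g] = {
                "counts": p.counts(),
                "regression": dataclasses.asdict(p.regression) if p.regression else None,
                "lognormal_gof": dataclasses.asdict(p.gof) if p.gof else None,
                "mean_core_abundance_share_pct": float(share.loc["mean", "core"]),
            }
        _write_json(part_info, out / "partition_summary.json")
        done("partition", t0, **{g: v["counts"] for g, v in part_info.items()})

        # ---------------- diversity ----------------
        t0 = stage("diversity")
        div_info = {}
        for metric in ("fisher", "shannon"):
            res = diversity.diversity_by_group(
                m, parts, metric=metric, depth=cfg.rarefaction_depth,
                seed=seeds["rarefaction"])
            res.values.to_csv(out / f"diversity_{metric}.tsv", sep="\t",
                              index=False)
            div_info[metric] = {
                stratum: {"H": r.statistic, "p": r.pvalue}
                for stratum, r in res.omnibus.items()
            }
        _write_json(div_info, out / "diversity_tests.json")
        done("diversity", t0)

        # ---------------- beta diversity ----------------
        t0 = stage("beta")
        D = beta.bray_curtis(rel)
        D.data.to_csv(out / "bray_curtis.tsv", sep="\t")
        summary = beta.group_similarity_summary(D, m.groups)
        summary.to_csv(out / "group_similarity.tsv", sep="\t", index=False)
        omnibus = beta.anosim(D, m.groups, n_perm=cfg.n_perm,
                              seed=seeds["anosim"])
        pairwise = beta.pairwise_anosim(D, m.groups, n_perm=cfg.n_perm,
                                        seed=seeds["anosim"])
        ord_res = beta.pcoa(D)
        ord_res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        ellipses = {}
        if ord_res.coordinates.shape[1] >= 2:
            for g in m.group_labels():
                pts = ord_res.coordinates.loc[m.samples_in_group(g)].iloc[:, :2]
                if len(pts) >= 3:
                    ellipses[g] = dataclasses.asdict(
                        beta.confidence_ellipse(pts))
        _write_json(
            {"anosim": dataclasses.asdict(omnibus),
             "pairwise": {f"{a}|{b}": dataclasses.asdict(r)
                          for (a, b), r in pairwise.items()},
             "pcoa_negative_eigenvalues": ord_res.negative_eigenvalues,
             "ellipses": ellipses},
            out / "beta_summary.json")
        done("beta", t0, anosim_R=omnibus.r, anosim_p=omnibus.pvalue)

        # ---------------- SIMPER ----------------
        t0 = stage("simper")
        groups_list = m.group_labels()
        for i, ga in enumerate(groups_list):
            for gb in groups_list[i + 1:]:
                tab = beta.simper(rel, m.groups, ga, gb)
                tab.to_csv(out / f"simper_{ga}_vs_{gb}.tsv", sep="\t")
        done("simper", t0)

        # ---------------- function profiles ----------------
        t0 = stage("function")
        if contrib is not None:
            ref = cfg.reference_group or m.group_labels()[0]
            # taxa absent from the reference group have 0 % prevalence there
            labels = parts[ref].labels.reindex(m.taxon_ids, fill_value="satellite")
            strata = {}
            for stratum in ("whole", "core", "satellite"):
                tab = functions.stratify_by_partition(
                    contrib, labels, stratum, mapping=mapping)
                tab.to_csv(out / f"pathways_{stratum}.tsv", sep="\t")
                strata[stratum] = tab
            excl = functions.satellite_exclusive_pathways(
                strata["core"], strata["satellite"])
            fn_tests = {}
            for stratum in ("core", "satellite"):
                tab = functions.abundant_pathways(
                    strata[stratum], cfg.abundance_threshold_pct)
                if tab.shape[0] == 0 or tab.shape[1] < 4:
                    continue
                clr = functions.clr_transform(tab)
                clr.to_csv(out / f"clr_{stratum}.tsv", sep="\t")
                cmp = functions.compare_pathways(clr, m.groups,
                                                 test=cfg.heatmap_test)
                cmp.to_csv(out / f"pathway_tests_{stratum}.tsv", sep="\t")
                fn_tests[stratum] = int((cmp["adjusted_pvalue"] <= 0.05).sum()) \
                    if "adjusted_pvalue" in cmp else 0
            pc, an = functions.pathway_pcoa(
                strata["whole"], m.groups, n_perm=cfg.n_perm,
                seed=seeds["function"])
            pc.coordinates.to_csv(out / "pathway_pcoa.tsv", sep="\t")
            _write_json(
                {"satellite_exclusive_pathways": excl,
                 "n_significant_pathways": fn_tests,
                 "pathway_anosim": dataclasses.asdict(an) if an else None},
                out / "function_summary.json")
            done("function", t0, n_exclusive=len(excl))
        else:
            done("function", t0, skipped="no contribution table provided")

        # ---------------- constrained ordination ----------------
        t0 = stage("ordination")
        if cfg.simulation is not None:
            covars = pd.DataFrame({"cohort_group": [m.groups[s]
                                                    for s in m.sample_ids]},
                                  index=m.sample_ids)
        else:
            covars = meta.loc[m.sample_ids, cfg.covariates] if cfg.covariates \
                else meta.loc[m.sample_ids, ["group"]]
        Y_rda = ordination.hellinger(rel).T
        sel = ordination.forward_select(
            Y_rda, covars, method="rda", alpha=cfg.ordination_alpha,
            n_perm=cfg.n_perm, seed=seeds["ordination"])
        Y_cca = rel.T
        sel_cca = ordination.forward_select(
            Y_cca, covars, method="cca", alpha=cfg.ordination_alpha,
            n_perm=cfg.n_perm, seed=seeds["ordination"] + 1000)
        _write_json(
            {"rda": {"selected": [dataclasses.asdict(s) for s in sel.selected],
                     "explained_fraction": sel.explained_fraction},
             "cca": {"selected": [dataclasses.asdict(s) for s in sel_cca.selected],
                     "explained_fraction": sel_cca.explained_fraction}},
            out / "ordination.json")
        done("ordination", t0,
             rda_selected=[s.variable for s in sel.selected],
             cca_selected=[s.variable for s in sel_cca.selected])
    except Exception as exc:
        current = [k for k in ("io", "partition", "diversity", "beta", "simper",
                               "function", "ordination")
                   if k not in manifest["stages"]]
        name = current[0] if current else "unknown"
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    _write_json(manifest, out / "manifest.json")
    return manifest
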