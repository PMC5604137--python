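"""End-to-end pipeline driver over the synthetic study design.

Runs simulate -> preprocess -> site models (DPC and sex) -> regions ->
interaction -> network modules -> enrichment -> QTL with one seed, and
returns a run manifest recording parameters and before/after counts at
every filtering step.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oio
from .association import SiteDifferentialModel, direction_enrichment
from .comodules import CoHydroxyNetwork, NetworkConfig
from .enrichment import GenePathwayMap, feature_enrichment, go_enrichment, \
    refine_pathways, summarize_by_feature
from .interaction import ModificationInteractionModel, classify_trajectories
from .preprocess import preprocess_pipeline
from .qtl import QTLModel, filter_snps, heterogeneity_scan
from .regions import call_regions
from .simulate import SimulationConfig, simulate_dataset


@dataclass
class PipelineConfig:
    """All stage parameters with the analysis defaults."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed_p: float = 1e-4
    max_gap: int = 500
    min_region_probes: int = 3
    discovery_p: float = 5e-5
    alpha: float = 0.05
    soft_power: int = 5
    merge_threshold: float = 0.30
    min_module_size: int | None = None
    snp_miss_max: float = 0.01
    snp_hwe_min_p: float = 1e-4
    snp_maf_min: float = 0.05
    snp_group_min: int = 5
    qtl_window_bp: int | None = 1_000_000
    max_interaction_probes: int = 500
    out_dir: str | None = None

    _KNOWN = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim) - sim_known
        if bad:
            raise ValueError(f"unknown simulation keys: {sorted(bad)}")
        return cls(simulation=SimulationConfig(**sim), **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    """Reproducibility ledger: parameters, seed, per-stage counts."""

    seed: int
    parameters: dict
    counts: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages.append(stage)
        for k, v in counts.items():
            self.counts[f"{stage}.{k}"] = v

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        return json.dumps({"seed": self.seed, "stages": self.stages,
                           "parameters": self.parameters,
                           "counts": self.counts}, indent=2, default=default)


def run_all(config: PipelineConfig | None = None, **overrides) -> dict:
    """Run the whole pipeline; returns a dict of stage results.

    Keys: study, dataset, hydroxy, dhp_dpc, dhp_sex, dmp_dpc, direction,
    regions_dpc, regions_sex, interaction, network, enrichment, qtl,
    heterogeneity, manifest.
    """
    if config is None:
        config = PipelineConfig()
    if overrides:
        config = dataclasses.replace(config, **overrides)
    sim = config.simulation
    manifest = RunManifest(seed=sim.seed, parameters=config.to_dict())

    study = simulate_dataset(sim)
    manifest.record("simulate", n_probes=sim.n_probes,
                    n_samples=sim.n_samples,
                    n_snps=len(study.genotypes.dosages))

    dataset, hydroxy, report = preprocess_pipeline(
        study.dataset, qc=study.qc)
    manifest.record("preprocess", tau=hydroxy.tau, **report.to_dict())

    # site models: 5hmC on delta, 5mC on oxBS
    res_hmc = SiteDifferentialModel(
        hydroxy.delta, dataset.samples, signal="5hmC",
        manifest=dataset.manifest).fit()
    res_mc = SiteDifferentialModel(
        dataset.oxbs, dataset.samples, signal="5mC",
        manifest=dataset.manifest).fit()
    dhp_dpc = res_hmc.with_thresholds("dpc", config.alpha, config.discovery_p)
    dhp_sex = res_hmc.with_thresholds("sex", config.alpha, config.discovery_p)
    dmp_dpc = res_mc.with_thresholds("dpc", config.alpha, config.discovery_p)
    direction = direction_enrichment(dhp_dpc, config.discovery_p)
    manifest.record(
        "association",
        n_dpc_tested=len(dhp_dpc),
        n_ddhp_bonferroni=int(dhp_dpc["significant_bonferroni"].sum()),
        n_ddhp_discovery=int(dhp_dpc["significant_discovery"].sum()),
        n_sex_tested=len(dhp_sex),
        n_sdhp_bonferroni=int(dhp_sex["significant_bonferroni"].sum()))

    regions_dpc, _ = call_regions(
        dhp_dpc, seed_p=config.seed_p, max_gap=config.max_gap,
        min_probes=config.min_region_probes)
    regions_sex, _ = call_regions(
        dhp_sex, seed_p=config.seed_p, max_gap=config.max_gap,
        min_probes=config.min_region_probes)
    manifest.record("regions", n_ddhr=len(regions_dpc),
                    n_sex_dhr=len(regions_sex))

    discovery = dhp_dpc[dhp_dpc["significant_discovery"]]["probe"]
    inter_probes = list(discovery[: config.max_interaction_probes])
    interaction_table = pd.DataFrame()
    if len(inter_probes) >= 1:
        inter_res = ModificationInteractionModel(
            dataset.oxbs, hydroxy.delta, dataset.samples,
            probes=inter_probes).fit()
        interaction_table = classify_trajectories(inter_res.table)
        n_sig = int((interaction_table["p_lrt"]
                     < inter_res.bonferroni_p).sum())
        manifest.record("interaction", n_tested=len(interaction_table),
                        n_significant=n_sig)

    net = CoHydroxyNetwork(
        hydroxy.delta, dataset.samples,
        NetworkConfig(soft_power=config.soft_power,
                      merge_threshold=config.merge_threshold,
                      min_module_size=config.min_module_size)).fit()
    manifest.record("modules", n_modules=len(net.modules))

    feat = feature_enrichment(
        set(discovery), dataset.probe_manifest(), feature_col="cgi")
    by_feature = summarize_by_feature(hydroxy, dataset.manifest, "cgi")
    gene_of = dataset.probe_manifest()["genes"]
    test_genes = {g for p in discovery
                  for g in str(gene_of.get(p, "")).split(",") if g}
    pw_map = GenePathwayMap.from_manifest(
        study.pathways, dataset.manifest, tested=set(hydroxy.delta.index))
    go = pd.DataFrame()
    refined = pd.DataFrame()
    if test_genes and pw_map.genes:
        try:
            go = go_enrichment(test_genes, pw_map)
            refined = refine_pathways(go, test_genes, pw_map)
        except ValueError:
            pass
    manifest.record("enrichment", n_pathways_tested=len(go),
                    n_pathways_significant=int(
                        (go["p_enrichment"] < 0.05).sum()) if len(go) else 0)

    geno, snp_report = filter_snps(
        study.genotypes.dosages, miss_max=config.snp_miss_max,
        hwe_min_p=config.snp_hwe_min_p, maf_min=config.snp_maf_min,
        group_min=config.snp_group_min)
    qtl_res = None
    het = pd.DataFrame()
    if len(geno):
        qtl_model = QTLModel(
            {"5mC": dataset.oxbs, "5hmC": hydroxy.delta}, geno,
            study.genotypes.snps, dataset.probe_manifest().reset_index(drop=True),
            dataset.samples, window_bp=config.qtl_window_bp)
        qtl_res = qtl_model.fit()
        het = heterogeneity_scan(qtl_res, dataset.oxbs, hydroxy.delta)
        tested = qtl_res.tested()
        manifest.record(
            "qtl", n_snps_retained=snp_report.n_retained,
            n_pairs_tested=len(tested),
            n_significant=len(qtl_res.significant()),
            n_heterogeneity_tested=len(het))

    results = {
        "study": study, "dataset": dataset, "hydroxy": hydroxy,
        "dhp_dpc": dhp_dpc, "dhp_sex": dhp_sex, "dmp_dpc": dmp_dpc,
        "direction": direction, "regions_dpc": regions_dpc,
        "regions_sex": regions_sex, "interaction": interaction_table,
        "network": net, "feature_enrichment": feat,
        "by_feature": by_feature, "go": go, "go_refined": refined,
        "qtl": qtl_res, "heterogeneity": het, "manifest": manifest,
    }
    if config.out_dir:
        _write_outputs(results, Path(config.out_dir), config)
    return results


def _write_outputs(results: dict, out: Path, config: PipelineConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for name in ("dhp_dpc", "dhp_sex", "dmp_dpc", "interaction",
                 "feature_enrichment", "by_feature", "go", "go_refined"):
        df = results[name]
        if isinstance(df, pd.DataFrame) and not df.empty:
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    for name in ("regions_dpc", "regions_sex"):
        oio.write_regions_bed(results[name], out / f"{name}.bed",
                              {"seed_p": config.seed_p,
                               "max_gap": config.max_gap,
                               "min_probes": config.min_region_probes})
    net = results["network"]
    net.assignment.rename("module").to_csv(out / "modules.tsv", sep="\t")
    net.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
    net.module_trait_association().to_csv(out / "module_traits.tsv",
                                          sep="\t", index=False)
    if results["qtl"] is not None:
        results["qtl"].tested().to_csv(out / "qtl.tsv", sep="\t", index=False)
    if isinstance(results["heterogeneity"], pd.DataFrame) and \
            not results["heterogeneity"].empty:
        results["heterogeneity"].to_csv(out / "heterogeneity.tsv",
                                        sep="\t", index=False)
    (out / "run_manifest.json").write_text(results["manifest"].to_json())
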