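"""Synthetic paired BS/oxBS datasets with a full ground-truth ledger.

The generator emulates the design of a developmental brain hydroxymethylome
study: ~71 samples spanning 23-184 days post-conception with a near-even
sex split, low genome-wide 5hmC (~3%) with positive skew, probes whose true
5hmC changes linearly with developmental age, X-linked sex effects,
correlated probe blocks driven by latent sample profiles, cis-acting
genetic effects on either modification, and independent technical noise on
the two arrays so that delta-beta values can be negative.

The measurement model is

    oxBS  = clip(true_5mc + e1, 0, 1)
    BS    = clip(true_5mc + true_5hmc + e2, 0, 1)

with e1, e2 independent N(0, noise_sd^2).  Every planted signal (slopes,
sex offsets, module assignments, QTL triples) is recorded in a
:class:`GroundTruth` ledger so downstream stages can be tested for
parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PairedBetaDataset, QCMetrics

_FEATURES = np.array(
    ["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic"]
)
_FEATURE_P = np.array([0.12, 0.10, 0.10, 0.06, 0.32, 0.05, 0.25])
_CGI = np.array(["island", "shore", "shelf", "open-sea"])
_CGI_P = np.array([0.31, 0.23, 0.10, 0.36])


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults follow the emulated study design: 71 samples (35 male, 36
    female) spanning 23-184 days post-conception, a genome-wide mean 5hmC
    of 3% with positive skew, and cis genetic effects of 0.07 beta units
    per minor allele.  ``noise_sd`` is the per-array technical standard
    deviation on the beta scale; 0.013 puts the 95th percentile of
    negative delta-beta magnitudes near the 0.036 detection threshold
    typical of oxBS array data.
    """

    n_samples: int = 71
    n_male: int | None = None  # None -> n_samples // 2 (35 of 71)
    dpc_range: tuple[float, float] = (23.0, 184.0)
    n_probes: int = 2000
    n_chromosomes: int = 4
    fraction_x_probes: float = 0.06
    global_mean_5hmc: float = 0.03
    zero_5hmc_fraction: float = 0.3  # probes with no 5hmC at all
    noise_sd: float = 0.013
    noise_sd_probe_range: tuple[float, float] = (0.5, 1.5)  # per-probe scale
    n_ddhp: int = 50
    slope_range: tuple[float, float] = (2e-4, 6e-4)
    hypo_fraction: float = 0.586
    n_sex_probes: int = 20
    sex_effect: float = 0.05
    male_up_fraction: float = 0.9
    n_modules: int = 4
    module_size: int = 50
    module_amplitude: tuple[float, float] = (0.03, 0.05)
    dpc_module_cor: float = 0.6
    n_qtl: int = 20
    qtl_effect: float = 0.07
    n_null_snps: int = 60
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_genotyped: int = 64
    genotype_missing_rate: float = 0.002
    n_pathways: int = 60
    n_enriched_pathways: int = 2
    enrichment_strength: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_probes", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("n_ddhp", "n_sex_probes", "n_modules", "module_size",
                     "n_qtl", "n_null_snps", "n_pathways"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0 <= self.fraction_x_probes <= 1:
            raise ConfigurationError("fraction_x_probes must lie in [0, 1]")
        if not 0 <= self.global_mean_5hmc <= 1:
            raise ConfigurationError("global_mean_5hmc must lie in [0, 1]")
        if self.dpc_range[0] >= self.dpc_range[1]:
            raise ConfigurationError("dpc_range must be increasing")
        if not self.maf_range[0] > 0 or self.maf_range[1] > 0.5:
            raise ConfigurationError("maf_range must lie in (0, 0.5]")
        if self.n_ddhp + self.n_modules * self.module_size > self.n_probes:
            raise ConfigurationError(
                "developmental plus module probes exceed n_probes")
        if self.n_male is not None and self.n_male > self.n_samples:
            raise ConfigurationError("n_male exceeds n_samples")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic child generator for a named stream."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Ledger of every planted signal, for parameter-recovery tests."""

    true_5mc: pd.DataFrame
    true_5hmc: pd.DataFrame
    pre_clamp_bs: pd.DataFrame
    pre_clamp_oxbs: pd.DataFrame
    ddhp: pd.DataFrame            # probe, slope (delta-beta per day)
    sex_probes: pd.DataFrame      # probe, effect (male minus female)
    module_assignments: pd.Series  # probe -> module label
    module_latents: pd.DataFrame   # module x sample latent profiles
    qtl: pd.DataFrame             # snp, probe, effect, target


@dataclass
class GenotypeData:
    """Dosage matrix (SNP x sample, minor-allele counts) with SNP metadata."""

    snps: pd.DataFrame            # snp, chrom, pos, maf
    dosages: pd.DataFrame         # values in {0,1,2} or NaN
    qtl_truth: pd.DataFrame       # snp, probe, effect, target


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Build a probe manifest with clustered positions and annotation.

    Probes are laid out in islands of 1-8 consecutive probes with 30-150 bp
    internal spacing separated by multi-kb gaps, so that spatial region
    calling has realistic dense runs to work with.  Each probe carries a
    genic-feature label, a CpG-island relation and zero or more gene
    symbols (intergenic probes carry none).
    """
    if config.n_probes < 10:
        raise ConfigurationError("n_probes must be at least 10")
    rng = config.rng(0)
    n_x = int(round(config.fraction_x_probes * config.n_probes))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    n_auto = config.n_probes - n_x
    counts = np.full(config.n_chromosomes, n_auto // config.n_chromosomes)
    counts[: n_auto % config.n_chromosomes] += 1
    plan = list(zip(chroms, counts))
    if n_x:
        plan.append(("chrX", n_x))

    rows = []
    probe_no = 0
    for chrom, count in plan:
        pos = 10_000
        remaining = int(count)
        while remaining > 0:
            island = min(int(rng.integers(1, 9)), remaining)
            for _ in range(island):
                rows.append((f"cg{probe_no:08d}", chrom, pos))
                probe_no += 1
                pos += int(rng.integers(30, 151))
            pos += int(rng.integers(2_000, 50_001))
            remaining -= island
    manifest = pd.DataFrame(rows, columns=["probe", "chrom", "pos"])
    n = len(manifest)
    manifest["strand"] = rng.choice(["+", "-"], size=n)
    manifest["feature"] = rng.choice(_FEATURES, size=n, p=_FEATURE_P)
    manifest["cgi"] = rng.choice(_CGI, size=n, p=_CGI_P)

    # genes assigned in runs so neighbouring probes share symbols
    genes = np.empty(n, dtype=object)
    i = 0
    gene_no = 0
    while i < n:
        run = min(int(rng.integers(2, 12)), n - i)
        symbol = f"GENE{gene_no:05d}"
        gene_no += 1
        for j in range(i, i + run):
            if manifest.loc[j, "feature"] == "intergenic":
                genes[j] = ""
            elif rng.random() < 0.1:  # occasional probe tagged to two genes
                genes[j] = f"{symbol},GENE{gene_no:05d}"
            else:
                genes[j] = symbol
        i += run
    manifest["genes"] = genes
    return manifest


def _sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rng = config.rng(1)
    dpc = rng.uniform(*config.dpc_range, size=config.n_samples)
    n_male = (config.n_samples // 2 if config.n_male is None else config.n_male)
    sex = np.array(["M"] * n_male + ["F"] * (config.n_samples - n_male))
    rng.shuffle(sex)
    return pd.DataFrame({
        "sample_id": [f"S{i:03d}" for i in range(config.n_samples)],
        "dpc": np.round(dpc, 1),
        "sex": sex,
    })


def _assign_special_probes(config: SimulationConfig, manifest: pd.DataFrame,
                           rng: np.random.Generator):
    """Pick disjoint ddhp / module / sex / qtl probe sets.

    Half the developmental probes are taken as runs of 3-5 consecutive
    autosomal probes so region calling has true clusters to find.
    """
    auto = manifest.index[manifest["chrom"] != "chrX"].to_numpy()
    x = manifest.index[manifest["chrom"] == "chrX"].to_numpy()
    if config.n_sex_probes > len(x):
        raise ConfigurationError("not enough X probes for n_sex_probes")

    taken = np.zeros(len(manifest), dtype=bool)
    ddhp_idx: list[int] = []
    target_clustered = config.n_ddhp // 2
    while len(ddhp_idx) < target_clustered:
        run = int(rng.integers(3, 6))
        start = int(rng.choice(auto[: len(auto) - run]))
        block = list(range(start, start + run))
        if taken[block].any() or manifest.loc[block, "chrom"].nunique() > 1:
            continue
        ddhp_idx.extend(block)
        taken[block] = True
    free = auto[~taken[auto]]
    extra = rng.choice(free, size=config.n_ddhp - len(ddhp_idx), replace=False)
    ddhp_idx.extend(int(i) for i in extra)
    taken[list(ddhp_idx)] = True

    module_idx: dict[str, np.ndarray] = {}
    for m in range(config.n_modules):
        free = auto[~taken[auto]]
        chosen = rng.choice(free, size=config.module_size, replace=False)
        module_idx[f"M{m + 1}"] = chosen
        taken[chosen] = True

    sex_idx = rng.choice(x, size=config.n_sex_probes, replace=False)
    taken[sex_idx] = True

    free = auto[~taken[auto]]
    qtl_idx = rng.choice(free, size=min(config.n_qtl, len(free)), replace=False)
    taken[qtl_idx] = True
    return np.array(ddhp_idx), module_idx, sex_idx, qtl_idx


def simulate_genotypes(config: SimulationConfig, manifest: pd.DataFrame,
                       qtl_probe_idx: np.ndarray | None = None,
                       ) -> GenotypeData:
    """Simulate Hardy-Weinberg dosages with cis SNPs for the QTL probes.

    Each QTL SNP is placed within 10 kb of its target probe; null SNPs are
    scattered over the genome.  Dosages are Binomial(2, MAF) per sample
    with a small missingness rate.
    """
    if not (0 < config.maf_range[0] <= config.maf_range[1] <= 0.5):
        raise ConfigurationError("MAF range must lie in (0, 0.5]")
    if config.n_qtl > len(manifest):
        raise ConfigurationError("n_qtl exceeds number of probes")
    rng = config.rng(2)
    if qtl_probe_idx is None:
        auto = manifest.index[manifest["chrom"] != "chrX"].to_numpy()
        qtl_probe_idx = rng.choice(auto, size=config.n_qtl, replace=False)

    snp_rows = []
    truth_rows = []
    for k, pi in enumerate(qtl_probe_idx):
        row = manifest.loc[int(pi)]
        snp = f"rs{k:06d}"
        target = "5hmc" if k % 2 == 0 else "5mc"
        snp_rows.append((snp, row["chrom"],
                         int(row["pos"]) + int(rng.integers(-10_000, 10_001)),
                         float(rng.uniform(*config.maf_range))))
        truth_rows.append((snp, row["probe"], config.qtl_effect, target))
    for k in range(config.n_null_snps):
        row = manifest.loc[int(rng.integers(0, len(manifest)))]
        snp_rows.append((f"rs{k + len(qtl_probe_idx):06d}", row["chrom"],
                         int(row["pos"]) + int(rng.integers(-50_000, 50_001)),
                         float(rng.uniform(*config.maf_range))))
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos", "maf"])
    snps["pos"] = snps["pos"].clip(lower=1)

    sheet = _sample_sheet(config)
    geno_samples = list(sheet["sample_id"][: config.n_genotyped])
    dosage = rng.binomial(2, snps["maf"].to_numpy()[:, None],
                          size=(len(snps), len(geno_samples))).astype(float)
    miss = rng.random(dosage.shape) < config.genotype_missing_rate
    dosage[miss] = np.nan
    dosages = pd.DataFrame(dosage, index=snps["snp"], columns=geno_samples)
    qtl_truth = pd.DataFrame(
        truth_rows, columns=["snp", "probe", "effect", "target"])
    return GenotypeData(snps=snps, dosages=dosages, qtl_truth=qtl_truth)


def simulate_paired_betas(config: SimulationConfig, manifest: pd.DataFrame,
                          genotypes: GenotypeData | None = None,
                          ) -> tuple[PairedBetaDataset, GroundTruth]:
    """Simulate the paired beta matrices and the ground-truth ledger.

    True 5mC baselines are drawn from a bimodal Beta mixture (the familiar
    methylation-array two-peak density); true 5hmC baselines are
    exponential with the configured genome-wide mean, giving the positive
    skew seen in oxBS data.  Planted signals modify true 5hmC (slopes, sex
    offsets, module latents, hmQTLs) or true 5mC (mQTLs) before the two
    independent noise draws.
    """
    rng = config.rng(3)
    sheet = _sample_sheet(config)
    n, s = len(manifest), config.n_samples
    dpc = sheet["dpc"].to_numpy()
    male = (sheet["sex"] == "M").to_numpy().astype(float)

    ddhp_idx, module_idx, sex_idx, qtl_idx = _assign_special_probes(
        config, manifest, rng)

    comp = rng.choice(3, size=n, p=[0.45, 0.35, 0.2])
    base_5mc = np.where(
        comp == 0, rng.beta(8, 2, size=n),
        np.where(comp == 1, rng.beta(2, 8, size=n), rng.beta(5, 5, size=n)))
    true_5mc = np.clip(
        base_5mc[:, None] + rng.normal(0, 0.01, size=(n, s)), 0, 0.98)

    # zero-inflated positively-skewed background 5hmC: a sizeable class of
    # probes carries no hydroxymethylation at all, as on real arrays
    if config.global_mean_5hmc > 0:
        zero_frac = min(config.zero_5hmc_fraction, 0.99)
        nonzero = rng.random(n) >= zero_frac
        scale = config.global_mean_5hmc / max(1 - zero_frac, 1e-9)
        base_5hmc = np.where(
            nonzero, np.minimum(rng.exponential(scale, size=n), 0.3), 0.0)
    else:
        base_5hmc = np.zeros(n)
    true_5hmc = np.repeat(base_5hmc[:, None], s, axis=1)

    # developmental slopes, centred at mid-range so baselines stay positive
    dpc_c = dpc - dpc.mean()
    n_hypo = int(round(config.hypo_fraction * len(ddhp_idx)))
    signs = np.array([-1.0] * n_hypo + [1.0] * (len(ddhp_idx) - n_hypo))
    rng.shuffle(signs)
    slopes = signs * rng.uniform(*config.slope_range, size=len(ddhp_idx))
    for i, (pi, slope) in enumerate(zip(ddhp_idx, slopes)):
        base = rng.uniform(0.05, 0.15)
        true_5hmc[pi] = base + slope * dpc_c

    sex_effects = np.where(rng.random(len(sex_idx)) < config.male_up_fraction,
                           config.sex_effect, -config.sex_effect)
    for pi, eff in zip(sex_idx, sex_effects):
        base = rng.uniform(0.05, 0.12)
        true_5hmc[pi] = base + eff * male if eff > 0 else base - eff * (1 - male)

    # module latents: half DPC-driven (alternating sign, as development-
    # associated modules run in both directions), half independent
    z_dpc = (dpc - dpc.mean()) / dpc.std()
    latents = {}
    for m, label in enumerate(module_idx):
        noise = rng.normal(0, 1, size=s)
        if m % 2 == 0 and config.dpc_module_cor > 0:
            r = config.dpc_module_cor * (1 if (m // 2) % 2 == 0 else -1)
            lat = r * z_dpc + np.sqrt(1 - r * r) * noise
        else:
            lat = noise
        lat = (lat - lat.mean()) / lat.std()
        latents[label] = lat
        # positive loadings: a signed network defines modules as
        # sign-coherent, so planted truth must be sign-coherent too
        loads = rng.uniform(*config.module_amplitude,
                            size=len(module_idx[label]))
        for pi, a in zip(module_idx[label], loads):
            base = rng.uniform(0.08, 0.15)
            true_5hmc[pi] = base + a * lat

    # cis genetic effects; mQTLs act on 5mC, hmQTLs on 5hmC
    qtl_truth = pd.DataFrame(columns=["snp", "probe", "effect", "target"])
    if genotypes is None and config.n_qtl > 0:
        genotypes = simulate_genotypes(config, manifest, qtl_probe_idx=qtl_idx)
    if genotypes is not None and len(genotypes.qtl_truth):
        qtl_truth = genotypes.qtl_truth
        probe_pos = {p: i for i, p in enumerate(manifest["probe"])}
        geno_cols = [c for c in genotypes.dosages.columns
                     if c in set(sheet["sample_id"])]
        col_pos = {sid: j for j, sid in enumerate(sheet["sample_id"])}
        for _, row in qtl_truth.iterrows():
            pi = probe_pos[row["probe"]]
            dose = genotypes.dosages.loc[row["snp"], geno_cols]
            shift = np.zeros(s)
            for sid, d in dose.items():
                if np.isfinite(d):
                    shift[col_pos[sid]] = row["effect"] * d
            if row["target"] == "5hmc":
                true_5hmc[pi] = np.clip(
                    rng.uniform(0.04, 0.08) + shift, 0, 0.9)
            else:
                true_5mc[pi] = np.clip(
                    rng.uniform(0.2, 0.5) + shift, 0, 0.98)

    true_5hmc = np.clip(true_5hmc, 0, 1)

    # calibrate the background so the genome-wide mean honours the
    # configured level despite the elevated baselines of planted probes
    special = np.zeros(n, dtype=bool)
    for idx in (ddhp_idx, sex_idx, qtl_idx,
                *(module_idx[m] for m in module_idx)):
        special[np.asarray(idx, dtype=int)] = True
    if config.global_mean_5hmc > 0 and (~special).any():
        target_total = config.global_mean_5hmc * n * s
        planted_total = true_5hmc[special].sum()
        bg_total = true_5hmc[~special].sum()
        if bg_total > 0:
            factor = max(target_total - planted_total, 0.0) / bg_total
            true_5hmc[~special] *= min(factor, 1.0 / max(
                true_5hmc[~special].max(), 1e-9))

    over = true_5mc + true_5hmc > 1
    if over.any():  # keep the ledger invariant 5mC + 5hmC <= 1
        true_5mc = np.where(over, 1 - true_5hmc, true_5mc)

    # per-probe noise scale: array probes differ in technical variance,
    # which is what leaves a subset of zero-5hmC probes never detected
    if config.noise_sd:
        sd_p = config.noise_sd * rng.uniform(*config.noise_sd_probe_range,
                                             size=n)
        e_ox = rng.normal(0, 1, size=(n, s)) * sd_p[:, None]
        e_bs = rng.normal(0, 1, size=(n, s)) * sd_p[:, None]
    else:
        e_ox = e_bs = 0
    pre_ox = true_5mc + e_ox
    pre_bs = true_5mc + true_5hmc + e_bs

    probes = pd.Index(manifest["probe"], name="probe")
    cols = pd.Index(sheet["sample_id"], name="sample_id")

    def frame(a):
        return pd.DataFrame(np.asarray(a, dtype=float), index=probes,
                            columns=cols)

    dataset = PairedBetaDataset(
        bs=frame(np.clip(pre_bs, 0, 1)),
        oxbs=frame(np.clip(pre_ox, 0, 1)),
        samples=sheet, manifest=manifest)
    truth = GroundTruth(
        true_5mc=frame(true_5mc), true_5hmc=frame(true_5hmc),
        pre_clamp_bs=frame(pre_bs), pre_clamp_oxbs=frame(pre_ox),
        ddhp=pd.DataFrame({"probe": manifest.loc[ddhp_idx, "probe"].to_numpy(),
                           "slope": slopes}),
        sex_probes=pd.DataFrame(
            {"probe": manifest.loc[sex_idx, "probe"].to_numpy(),
             "effect": sex_effects}),
        module_assignments=pd.Series(
            {manifest.loc[int(pi), "probe"]: label
             for label, idx in module_idx.items() for pi in idx},
            name="module", dtype=object),
        module_latents=pd.DataFrame(latents, index=cols).T,
        qtl=qtl_truth)
    return dataset, truth


def simulate_pathway_annotation(config: SimulationConfig,
                                manifest: pd.DataFrame,
                                truth_genes: set[str] | None = None,
                                ) -> dict[str, set[str]]:
    """Map genes to pathways, planting enrichment among the truth genes.

    Pathway target sizes span below, inside and above the usual 10-2000
    gene size filter so that the filter is exercised.  For the configured
    number of enriched pathways, membership odds for genes in
    ``truth_genes`` are multiplied by ``enrichment_strength``.
    """
    genes = sorted({g for cell in manifest["genes"] for g in str(cell).split(",")
                    if g})
    if not genes:
        raise ConfigurationError("manifest contains no gene annotations")
    rng = config.rng(4)
    truth_genes = truth_genes or set()
    gene_to_pathways: dict[str, set[str]] = {g: set() for g in genes}
    n_genes = len(genes)
    sizes = rng.choice([5, 8] + [15, 30, 60, 120] * 5 + [2500],
                       size=config.n_pathways)
    for k in range(config.n_pathways):
        name = f"PW{k:04d}"
        p0 = min(sizes[k] / n_genes, 0.9)
        enriched = k < config.n_enriched_pathways
        for g in genes:
            p = p0
            if enriched and g in truth_genes:
                odds = (p0 / (1 - p0)) * config.enrichment_strength
                p = odds / (1 + odds)
            if rng.random() < p:
                gene_to_pathways[g].add(name)
    return gene_to_pathways


def simulate_qc(config: SimulationConfig, dataset: PairedBetaDataset,
                n_fail_beadcount: int = 2, n_fail_detp: int = 3,
                n_fail_samples: int = 0) -> QCMetrics:
    """Bead counts and detection p-values with planted QC failures."""
    rng = config.rng(5)
    shape = dataset.bs.shape
    bead = 3 + rng.poisson(12, size=shape)
    detp = rng.uniform(0, 0.01, size=shape)
    n_probes, n_samples = shape
    bad = rng.choice(n_probes, size=n_fail_beadcount + n_fail_detp,
                     replace=False)
    n_low = max(1, int(np.ceil(0.05 * n_samples)))
    for pi in bad[:n_fail_beadcount]:
        bead[pi, rng.choice(n_samples, size=n_low, replace=False)] = 2
    n_hi = max(1, int(np.ceil(0.011 * n_samples)) + 1)
    for pi in bad[n_fail_beadcount:]:
        detp[pi, rng.choice(n_samples, size=n_hi, replace=False)] = 0.5
    for sj in range(n_fail_samples):
        k = int(np.ceil(0.051 * n_probes))
        detp[rng.choice(n_probes, size=k, replace=False), sj] = 0.5
    return QCMetrics(
        beadcount=pd.DataFrame(bead, index=dataset.bs.index,
                               columns=dataset.bs.columns),
        detection_p=pd.DataFrame(detp, index=dataset.bs.index,
                                 columns=dataset.bs.columns))


@dataclass
class SyntheticStudy:
    """Everything the pipeline needs, generated from one config."""

    config: SimulationConfig
    dataset: PairedBetaDataset
    truth: GroundTruth
    genotypes: GenotypeData
    pathways: dict[str, set[str]]
    qc: QCMetrics


def simulate_dataset(config: SimulationConfig | None = None,
                     **overrides) -> SyntheticStudy:
    """One-call generation of a complete synthetic study."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    manifest = generate_manifest(config)
    dataset, truth = simulate_paired_betas(config, manifest)
    genotypes = _recover_genotypes(config, manifest, truth)
    gene_of = manifest.set_index("probe")["genes"]
    truth_genes = {
        g for probe in truth.ddhp["probe"]
        for g in str(gene_of.loc[probe]).split(",") if g}
    pathways = simulate_pathway_annotation(config, manifest, truth_genes)
    qc = simulate_qc(config, dataset)
    return SyntheticStudy(config=config, dataset=dataset, truth=truth,
                          genotypes=genotypes, pathways=pathways, qc=qc)


def _recover_genotypes(config, manifest, truth) -> GenotypeData:
    """Regenerate the genotype draw used inside simulate_paired_betas.

    simulate_genotypes is deterministic given the QTL probe assignment, so
    replaying it with the probes recorded in the truth ledger reproduces
    exactly the dosages that shaped the beta matrices.
    """
    probe_to_idx = {p: i for i, p in enumerate(manifest["probe"])}
    qtl_idx = np.array([probe_to_idx[p] for p in truth.qtl["probe"]],
                       dtype=int) if len(truth.qtl) else np.array([], int)
    return simulate_genotypes(config, manifest, qtl_probe_idx=qtl_idx)


# ---------------------------------------------------------------------------
# on-disk output


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write the study as plain-text files (TSV/CSV/BED-like/VCF)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.dataset.bs.to_csv(out / "bs.tsv", sep="\t")
    study.dataset.oxbs.to_csv(out / "oxbs.tsv", sep="\t")
    study.dataset.samples.to_csv(out / "samples.csv", index=False)
    m = study.dataset.manifest
    bed = pd.DataFrame({
        "chrom": m["chrom"], "start": m["pos"] - 1, "end": m["pos"],
        "probe": m["probe"], "strand": m["strand"], "feature": m["feature"],
        "cgi": m["cgi"], "genes": m["genes"]})
    bed.to_csv(out / "manifest.bed", sep="\t", index=False)
    study.qc.beadcount.to_csv(out / "qc_beadcount.tsv", sep="\t")
    study.qc.detection_p.to_csv(out / "qc_detection_p.tsv", sep="\t")
    study.genotypes.dosages.to_csv(out / "genotypes_012.tsv", sep="\t")
    _write_vcf(study.genotypes, out / "genotypes.vcf")
    with open(out / "pathways.gmt", "w") as fh:
        inv: dict[str, list[str]] = {}
        for g, pws in study.pathways.items():
            for pw in pws:
                inv.setdefault(pw, []).append(g)
        for pw in sorted(inv):
            fh.write("\t".join([pw, "synthetic"] + sorted(inv[pw])) + "\n")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    study.truth.ddhp.to_csv(truth_dir / "ddhp.tsv", sep="\t", index=False)
    study.truth.sex_probes.to_csv(truth_dir / "sex_probes.tsv", sep="\t",
                                  index=False)
    study.truth.module_assignments.rename("module").to_csv(
        truth_dir / "modules.tsv", sep="\t")
    study.truth.qtl.to_csv(truth_dir / "qtl.tsv", sep="\t", index=False)


def _write_vcf(genotypes: GenotypeData, path: Path) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    samples = list(genotypes.dosages.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        snps = genotypes.snps.sort_values(["chrom", "pos"])
        for _, row in snps.iterrows():
            calls = [gt_map.get(d, "./.") for d in
                     genotypes.dosages.loc[row["snp"], samples]]
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['snp']}\t"
                     f"A\tG\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")
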