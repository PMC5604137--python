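"""Methylation and hydroxymethylation quantitative trait loci.

SNPs are QC-filtered (missingness, Hardy-Weinberg, minor allele
frequency, per-genotype-group minimum), then an additive linear model

    modification ~ dosage + age + sex + PC1 + PC2

is fitted for every cis SNP-probe pair for each modification, and pairs
significant for either modification are tested for heterogeneous genetic
effects with a random-intercept model across the stacked 5mC/5hmC data
(1-df likelihood-ratio test on the genotype-by-modification interaction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import paired_lrt


@dataclass
class SnpFilterReport:
    n_input: int
    n_missingness: int
    n_hwe: int
    n_maf: int
    n_group_min: int
    n_retained: int


def hwe_chisq_p(n0: int, n1: int, n2: int) -> float:
    """Hardy-Weinberg goodness-of-fit p (1-df chi-square) from counts."""
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    p = (2 * n2 + n1) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    obs = np.array([n0, n1, n2], dtype=float)
    nonzero = exp > 0
    chi2 = float(((obs[nonzero] - exp[nonzero]) ** 2 / exp[nonzero]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(dose: np.ndarray) -> tuple[int, int, int]:
    ok = np.isfinite(dose)
    return (int((dose[ok] == 0).sum()), int((dose[ok] == 1).sum()),
            int((dose[ok] == 2).sum()))


def filter_snps(dosages: pd.DataFrame, miss_max: float = 0.01,
                hwe_min_p: float = 1e-4, maf_min: float = 0.05,
                group_min: int = 5,
                ) -> tuple[pd.DataFrame, SnpFilterReport]:
    """Apply the standard SNP QC rules to a dosage matrix.

    A SNP is removed when more than ``miss_max`` of its calls are missing,
    its Hardy-Weinberg p falls below ``hwe_min_p``, its minor allele
    frequency is below ``maf_min``, or any present genotype group (all
    three when three are present, both when only two) has fewer than
    ``group_min`` observations.
    """
    if dosages.empty:
        raise ValueError("no SNPs supplied")
    x = dosages.to_numpy(float)
    n_samples = x.shape[1]
    miss = np.mean(~np.isfinite(x), axis=1)
    fail_miss = miss > miss_max

    fail_hwe = np.zeros(len(dosages), bool)
    fail_maf = np.zeros(len(dosages), bool)
    fail_group = np.zeros(len(dosages), bool)
    for i in range(len(dosages)):
        n0, n1, n2 = _genotype_counts(x[i])
        total = n0 + n1 + n2
        if total == 0:
            fail_maf[i] = True
            continue
        af = (2 * n2 + n1) / (2 * total)
        maf = min(af, 1 - af)
        fail_maf[i] = maf < maf_min
        fail_hwe[i] = hwe_chisq_p(n0, n1, n2) < hwe_min_p
        groups = [c for c in (n0, n1, n2) if c > 0]
        fail_group[i] = len(groups) < 2 or min(groups) < group_min
    fail_any = fail_miss | fail_hwe | fail_maf | fail_group
    report = SnpFilterReport(
        n_input=len(dosages), n_missingness=int(fail_miss.sum()),
        n_hwe=int(fail_hwe.sum()), n_maf=int(fail_maf.sum()),
        n_group_min=int(fail_group.sum()), n_retained=int((~fail_any).sum()))
    return dosages.loc[~fail_any], report


def genotype_pcs(dosages: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Principal components of the mean-imputed, centred dosage matrix.

    Returns a sample x k score frame.  Signs follow a deterministic
    convention: the largest-magnitude loading of each component is made
    positive.
    """
    x = dosages.to_numpy(float).T  # samples x snps
    if x.shape[1] < k or x.shape[0] <= k:
        raise ValueError("need at least k SNPs and k+1 samples")
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(~np.isfinite(x))
    x[inds] = col_mean[inds[1]]
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > 1e-10 * s[0]).sum()) if s.size and s[0] > 0 else 0
    k_eff = min(k, rank)
    if k_eff < k:
        import warnings
        warnings.warn(f"dosage matrix rank {rank} < k={k}; "
                      f"returning {k_eff} components")
    scores = u[:, :k_eff] * s[:k_eff]
    for j in range(k_eff):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=dosages.columns,
                        columns=[f"PC{i + 1}" for i in range(k_eff)])


class QTLModel:
    """Additive cis-QTL scan for one or both modifications.

    Parameters
    ----------
    modifications : dict of str -> DataFrame
        Signal matrices keyed by modification label ('5mC': oxBS betas,
        '5hmC': delta betas); probes x samples.
    dosages : DataFrame
        Filtered minor-allele dosages, SNPs x samples.
    snps, manifest : DataFrame
        Positions for SNPs (snp, chrom, pos) and probes (probe, chrom,
        pos) used to form cis pairs.
    samples : DataFrame
        Sample sheet (``sample_id``, ``dpc``, ``sex``).
    pcs : DataFrame, optional
        Genotype principal-component scores; computed with k=2 if absent.
    window_bp : int or None
        Cis window; ``None`` tests all SNP-probe pairs.
    """

    def __init__(self, modifications: dict, dosages: pd.DataFrame,
                 snps: pd.DataFrame, manifest: pd.DataFrame,
                 samples: pd.DataFrame, pcs: pd.DataFrame | None = None,
                 window_bp: int | None = 1_000_000):
        self.modifications = modifications
        self.dosages = dosages
        self.snps = snps.set_index("snp") if "snp" in snps.columns else snps
        self.manifest = manifest
        self.samples = samples
        self.window_bp = window_bp
        shared = [s for s in samples["sample_id"] if s in dosages.columns]
        if len(shared) < 20:
            raise ValueError("need at least 20 genotyped samples")
        self.shared_samples = shared
        self.pcs = genotype_pcs(dosages[shared]) if pcs is None else \
            pcs.loc[shared]

    def pairs(self) -> list[tuple[str, str]]:
        """Cis SNP-probe pairs under the window (or all pairs)."""
        out = []
        snp_ids = [s for s in self.dosages.index if s in self.snps.index]
        probe_pos = self.manifest.set_index("probe")[["chrom", "pos"]]
        for snp in snp_ids:
            srow = self.snps.loc[snp]
            for probe, prow in probe_pos.iterrows():
                if self.window_bp is None or (
                        srow["chrom"] == prow["chrom"]
                        and abs(int(srow["pos"]) - int(prow["pos"]))
                        <= self.window_bp):
                    out.append((snp, probe))
        return out

    def _covariates(self) -> pd.DataFrame:
        sheet = self.samples.set_index("sample_id").loc[self.shared_samples]
        cov = pd.DataFrame({
            "age": sheet["dpc"].to_numpy(float),
            "sex": (sheet["sex"] == "M").to_numpy(float)},
            index=self.shared_samples)
        return cov.join(self.pcs)

    def fit(self, pairs=None) -> "QTLResults":
        cov = self._covariates().to_numpy(float)
        pairs = self.pairs() if pairs is None else pairs
        rows = []
        for mod, matrix in self.modifications.items():
            sub = matrix[self.shared_samples]
            for snp, probe in pairs:
                if probe not in sub.index:
                    continue
                dose = self.dosages.loc[snp, self.shared_samples] \
                    .to_numpy(float)
                y = sub.loc[probe].to_numpy(float)
                ok = np.isfinite(dose) & np.isfinite(y)
                row = _fit_pair(y[ok], dose[ok], cov[ok])
                if row is None:
                    rows.append({"snp": snp, "probe": probe,
                                 "modification": mod, "skipped": True})
                    continue
                counts = _genotype_counts(dose[ok])
                rows.append({"snp": snp, "probe": probe, "modification": mod,
                             "effect": row[0], "se": row[1], "t": row[2],
                             "p": row[3], "n": int(ok.sum()),
                             "n_geno_0": counts[0], "n_geno_1": counts[1],
                             "n_geno_2": counts[2], "skipped": False})
        table = pd.DataFrame(rows)
        return QTLResults(self, table)


def _fit_pair(y, dose, cov):
    """OLS of one pair: effect, se, t, p for the dosage term."""
    if len(y) < 8 or np.std(dose) == 0:
        return None
    X = np.column_stack([np.ones(len(y)), dose, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    if df <= 0:
        return None
    sigma2 = resid @ resid / df
    se = float(np.sqrt(XtX_inv[1, 1] * sigma2))
    if se == 0:
        return float(beta[1]), 0.0, np.nan, 1.0
    t = float(beta[1] / se)
    p = float(2 * stats.t.sf(abs(t), df))
    return float(beta[1]), se, t, p


class QTLResults:
    def __init__(self, model: QTLModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def tested(self) -> pd.DataFrame:
        if self.table.empty:
            return self.table
        return self.table[~self.table["skipped"]]

    def bonferroni_p(self, alpha: float = 0.05) -> float:
        n = len(self.tested())
        if n == 0:
            raise ValueError("no tested pairs")
        return alpha / n

    def significant(self, p_cut: float | None = None) -> pd.DataFrame:
        cut = self.bonferroni_p() if p_cut is None else p_cut
        t = self.tested()
        return t[t["p"] < cut]

    def summary(self) -> str:
        t = self.tested()
        lines = [f"Additive cis-QTL scan: modification ~ dosage + age + sex "
                 f"+ PC1 + PC2",
                 f"pairs tested: {len(t)}   "
                 f"Bonferroni p < {self.bonferroni_p():.3g}"]
        for mod, grp in t.groupby("modification"):
            sig = grp[grp["p"] < self.bonferroni_p()]
            med = np.median(np.abs(sig["effect"])) if len(sig) else np.nan
            lines.append(f"  {mod}: {len(sig)} significant QTLs"
                         + (f", median |effect| {med:.4f}/allele"
                            if len(sig) else ""))
        return "\n".join(lines)


@dataclass
class HeterogeneityResult:
    snp: str
    probe: str
    interaction: float
    se_interaction: float
    lrt_stat: float
    p_heterogeneity: float
    effect_5mc: float
    effect_5hmc: float
    boundary: bool
    degenerate: bool


def test_heterogeneity(snp: str, probe: str, oxbs_row, delta_row,
                       dose, samples: pd.DataFrame,
                       pcs: pd.DataFrame) -> HeterogeneityResult:
    """Heterogeneous-genetic-effect test for one SNP-probe pair.

    The 5mC and 5hmC values of each individual are stacked with a random
    intercept per individual; fixed effects are genotype, age, sex, two
    genotype PCs, the modification indicator, and (in the full model)
    genotype x modification.  The heterogeneity p comes from the 1-df
    likelihood-ratio comparison of the two fits.
    """
    y_mc = np.asarray(oxbs_row, float)
    y_hmc = np.asarray(delta_row, float)
    dose = np.asarray(dose, float)
    ok = np.isfinite(y_mc) & np.isfinite(y_hmc) & np.isfinite(dose)
    if ok.sum() < 8:
        raise ValueError("need at least 8 complete individuals")
    sheet = samples.loc[ok]
    age = sheet["dpc"].to_numpy(float)
    sex = (sheet["sex"] == "M").to_numpy(float)
    pc = pcs.to_numpy(float)[ok]
    n = int(ok.sum())
    ones, zeros = np.ones(n), np.zeros(n)
    g = dose[ok]
    # columns: 1, geno, age, sex, PCs..., indicator, geno x indicator
    X_mc = np.column_stack([ones, g, age, sex, pc, zeros, zeros])
    X_hmc = np.column_stack([ones, g, age, sex, pc, ones, g])
    inter_col = X_mc.shape[1] - 1
    full, _, stat, p = paired_lrt(y_mc[ok], y_hmc[ok], X_mc, X_hmc,
                                  drop=inter_col)
    eff_mc = float(full.beta[1])
    inter = float(full.beta[inter_col])
    return HeterogeneityResult(
        snp=snp, probe=probe, interaction=inter,
        se_interaction=float(full.se[inter_col]), lrt_stat=stat,
        p_heterogeneity=p, effect_5mc=eff_mc, effect_5hmc=eff_mc + inter,
        boundary=full.boundary, degenerate=full.degenerate)


def heterogeneity_scan(qtl_results: QTLResults, oxbs: pd.DataFrame,
                       delta: pd.DataFrame,
                       p_cut: float | None = None) -> pd.DataFrame:
    """Heterogeneity tests for every pair significant for either mark."""
    model = qtl_results.model
    sig = qtl_results.significant(p_cut)
    pairs = sig[["snp", "probe"]].drop_duplicates()
    shared = model.shared_samples
    rows = []
    for _, pr in pairs.iterrows():
        snp, probe = pr["snp"], pr["probe"]
        if probe not in oxbs.index or probe not in delta.index:
            continue
        r = test_heterogeneity(
            snp, probe, oxbs.loc[probe, shared], delta.loc[probe, shared],
            model.dosages.loc[snp, shared],
            model.samples.set_index("sample_id").loc[shared].reset_index(),
            model.pcs)
        rows.append(r.__dict__)
    return pd.DataFrame(rows)
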