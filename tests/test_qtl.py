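"""SNP filtering, genotype PCs, QTL mapping and heterogeneity tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oxbstools.qtl import QTLModel, filter_snps, genotype_pcs, \
    heterogeneity_scan, hwe_chisq_p
from oxbstools.qtl import test_heterogeneity as heterogeneity_fit


def dosage_frame(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    samples = samples or [f"S{j:03d}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"rs{i:04d}" for i in
                                     range(rows.shape[0])],
                        columns=samples)


def sheet(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "sample_id": [f"S{j:03d}" for j in range(n)],
        "dpc": rng.uniform(23, 184, n),
        "sex": rng.permutation(["M"] * (n // 2) + ["F"] * (n - n // 2))})


class TestHWE:
    def test_perfect_hardy_weinberg(self):
        assert hwe_chisq_p(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_rejected(self):
        # counts (50, 0, 50): chi-square 100
        p = hwe_chisq_p(50, 0, 50)
        assert p == pytest.approx(stats.chi2.sf(100, 1), rel=1e-9)
        assert p < 1e-4


class TestFilterSnps:
    def test_low_maf_removed(self):
        # 100 samples, 8 minor alleles -> MAF 0.04
        row = np.zeros(100)
        row[:8] = 1
        kept, report = filter_snps(dosage_frame([row]), group_min=1)
        assert report.n_maf == 1 and len(kept) == 0

    def test_hwe_failure_removed(self):
        row = np.array([0.0] * 50 + [2.0] * 50)
        kept, report = filter_snps(dosage_frame([row]))
        assert report.n_hwe == 1 and len(kept) == 0

    def test_missingness_rule(self):
        rng = np.random.default_rng(0)
        row = rng.binomial(2, 0.4, 100).astype(float)
        row[:2] = np.nan  # 2% missing > 1%
        kept, report = filter_snps(dosage_frame([row]))
        assert report.n_missingness == 1

    def test_group_minimum(self):
        # only 3 homozygous-minor observations
        row = np.array([0.0] * 80 + [1.0] * 17 + [2.0] * 3)
        kept, report = filter_snps(dosage_frame([row]))
        assert report.n_group_min == 1

    def test_two_group_snp_passes_when_both_big(self):
        row = np.array([0.0] * 60 + [1.0] * 40)
        kept, report = filter_snps(dosage_frame([row]), hwe_min_p=0.0,
                                   maf_min=0.05)
        assert len(kept) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_rule_recheck(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.binomial(2, rng.uniform(0.02, 0.5, 30)[:, None],
                            size=(30, 80)).astype(float)
        rows[rng.random(rows.shape) < 0.01] = np.nan
        dose = dosage_frame(rows)
        kept, _ = filter_snps(dose)

        def brute(row):
            ok = np.isfinite(row)
            if (~ok).mean() > 0.01:
                return False
            counts = [(row[ok] == k).sum() for k in (0, 1, 2)]
            tot = sum(counts)
            af = (2 * counts[2] + counts[1]) / (2 * tot)
            if min(af, 1 - af) < 0.05:
                return False
            if hwe_chisq_p(*counts) < 1e-4:
                return False
            present = [c for c in counts if c > 0]
            if len(present) < 2 or min(present) < 5:
                return False
            return True

        expected = [s for s in dose.index if brute(dose.loc[s].to_numpy())]
        assert list(kept.index) == expected


class TestGenotypePCs:
    def test_two_populations_separate_on_pc1(self):
        rng = np.random.default_rng(1)
        f1 = rng.uniform(0.05, 0.5, 200)
        f2 = np.clip(f1 + rng.choice([-0.3, 0.3], 200), 0.02, 0.95)
        pop1 = rng.binomial(2, f1[:, None], (200, 30)).astype(float)
        pop2 = rng.binomial(2, f2[:, None], (200, 30)).astype(float)
        dose = dosage_frame(np.hstack([pop1, pop2]))
        pcs = genotype_pcs(dose)
        from sklearn.metrics import silhouette_score
        labels = [0] * 30 + [1] * 30
        assert silhouette_score(pcs[["PC1"]], labels) > 0.5

    def test_constant_genotypes_rank_deficient(self):
        dose = dosage_frame(np.ones((5, 10)))
        with pytest.warns(UserWarning, match="rank"):
            pcs = genotype_pcs(dose)
        assert pcs.shape[1] == 0

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(2)
        dose = dosage_frame(rng.binomial(2, 0.3, (40, 25)).astype(float))
        pcs = genotype_pcs(dose)
        x = dose.to_numpy().T
        x = x - x.mean(axis=0)
        # independent oracle: eigenvectors of the sample covariance
        evals, evecs = np.linalg.eigh(np.cov(x.T))
        for j, col in enumerate(["PC1", "PC2"]):
            oracle = x @ evecs[:, -1 - j]
            r = np.corrcoef(pcs[col], oracle)[0, 1]
            assert abs(abs(r) - 1) < 1e-8


def make_qtl_inputs(n=64, n_probes=6, seed=0, effect=0.0, maf=0.3,
                    noise=0.02):
    rng = np.random.default_rng(seed)
    samples = sheet(n, seed)
    dose = rng.binomial(2, maf, n).astype(float)
    probes = [f"cg{i:04d}" for i in range(n_probes)]
    base = rng.uniform(0.05, 0.1, n_probes)
    mat = np.array([base[i] + (effect * dose if i == 0 else 0)
                    + rng.normal(0, noise, n) for i in range(n_probes)])
    matrix = pd.DataFrame(mat, index=probes, columns=samples["sample_id"])
    dosages = dosage_frame([dose] + [rng.binomial(2, 0.4, n).astype(float)
                                     for _ in range(3)],
                           samples=list(samples["sample_id"]))
    snps = pd.DataFrame({"snp": dosages.index, "chrom": "chr1",
                         "pos": [100, 200_000, 400_000, 600_000]})
    manifest = pd.DataFrame({"probe": probes, "chrom": "chr1",
                             "pos": np.arange(n_probes) * 1000 + 150,
                             "strand": "+", "feature": "Body",
                             "cgi": "open-sea", "genes": ""})
    return samples, matrix, dosages, snps, manifest


class TestQTLModel:
    def test_effect_matches_normal_equations_oracle(self):
        samples, matrix, dosages, snps, manifest = make_qtl_inputs(
            seed=3, effect=0.07)
        model = QTLModel({"5hmC": matrix}, dosages, snps, manifest,
                         samples, window_bp=None)
        res = model.fit()
        row = res.tested().query(
            "snp == 'rs0000' and probe == 'cg0000'").iloc[0]
        cov = model._covariates().to_numpy()
        X = np.column_stack([np.ones(len(samples)),
                             dosages.loc["rs0000"].to_numpy(), cov])
        y = matrix.loc["cg0000"].to_numpy()
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - X.shape[1])
        se = np.sqrt(XtX_inv[1, 1] * s2)
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), len(y) - X.shape[1])
        assert row["effect"] == pytest.approx(beta[1], abs=1e-10)
        assert row["se"] == pytest.approx(se, abs=1e-10)
        assert row["p"] == pytest.approx(p, abs=1e-10)

    def test_planted_effect_recovered(self):
        effects = []
        for s in range(60):
            samples, matrix, dosages, snps, manifest = make_qtl_inputs(
                seed=100 + s, effect=0.07)
            res = QTLModel({"5hmC": matrix}, dosages, snps, manifest,
                           samples, window_bp=None).fit()
            row = res.tested().query(
                "snp == 'rs0000' and probe == 'cg0000'").iloc[0]
            effects.append(row["effect"])
        assert abs(np.mean(effects) - 0.07) < 0.1 * 0.07

    def test_null_p_uniform(self):
        # independent null pairs: fresh phenotype and genotype each time
        rng = np.random.default_rng(5)
        samples = sheet(64, 5)
        cov_rng = np.random.default_rng(55)
        ps = []
        for _ in range(400):
            dose = rng.binomial(2, 0.3, 64).astype(float)
            y = rng.normal(0.06, 0.02, 64)
            pcs = pd.DataFrame(cov_rng.normal(0, 1, (64, 2)),
                               index=samples["sample_id"],
                               columns=["PC1", "PC2"])
            from oxbstools.qtl import _fit_pair
            covs = np.column_stack([
                samples["dpc"], (samples["sex"] == "M").astype(float),
                pcs.to_numpy()])
            out = _fit_pair(y, dose, covs)
            ps.append(out[3])
        assert stats.kstest(ps, "uniform").statistic < 0.08

    def test_cis_window_restricts_pairs(self):
        samples, matrix, dosages, snps, manifest = make_qtl_inputs(seed=6)
        model = QTLModel({"5hmC": matrix}, dosages, snps, manifest,
                         samples, window_bp=10_000)
        pairs = model.pairs()
        assert all(s == "rs0000" for s, _ in pairs)

    def test_constant_dosage_skipped_with_flag(self):
        samples, matrix, dosages, snps, manifest = make_qtl_inputs(seed=7)
        dosages.loc["rs0001"] = 1.0
        res = QTLModel({"5hmC": matrix}, dosages, snps, manifest,
                       samples, window_bp=None).fit()
        sub = res.table.query("snp == 'rs0001'")
        assert sub["skipped"].all()

    def test_too_few_genotyped_samples_rejected(self):
        samples, matrix, dosages, snps, manifest = make_qtl_inputs(n=64)
        with pytest.raises(ValueError):
            QTLModel({"5hmC": matrix}, dosages[dosages.columns[:10]],
                     snps, manifest, samples)


class TestHeterogeneity:
    def run_one(self, seed, effect_mc, effect_hmc, n=64):
        rng = np.random.default_rng(seed)
        samples = sheet(n, seed)
        dose = rng.binomial(2, 0.3, n).astype(float)
        b = rng.normal(0, 0.03, n)
        y_mc = 0.5 + effect_mc * dose + b + rng.normal(0, 0.02, n)
        y_hmc = 0.06 + effect_hmc * dose + b + rng.normal(0, 0.02, n)
        pcs = pd.DataFrame(rng.normal(0, 1, (n, 2)),
                           index=samples["sample_id"],
                           columns=["PC1", "PC2"])
        return heterogeneity_fit("rs1", "cg1", y_mc, y_hmc, dose,
                                  samples, pcs)

    def test_shared_effect_is_null_calibrated(self):
        n_runs = 300
        sig = sum(self.run_one(1000 + s, 0.07, 0.07).p_heterogeneity < 0.05
                  for s in range(n_runs))
        mc_sd = np.sqrt(0.05 * 0.95 / n_runs)
        assert abs(sig / n_runs - 0.05) < 3 * mc_sd

    def test_power_for_differential_effect(self):
        n_runs = 100
        sig = sum(self.run_one(2000 + s, 0.07, 0.0).p_heterogeneity < 0.05
                  for s in range(n_runs))
        assert sig / n_runs > 0.8

    def test_interaction_recovers_effect_difference(self):
        ests = [self.run_one(3000 + s, 0.07, 0.0).interaction
                for s in range(60)]
        assert abs(np.mean(ests) - (-0.07)) < 0.015

    def test_sign_concordance_under_shared_truth(self):
        results = [self.run_one(4000 + s, 0.07, 0.07) for s in range(60)]
        concordant = [np.sign(r.effect_5mc) == np.sign(r.effect_5hmc)
                      for r in results]
        assert np.mean(concordant) > 0.95

    def test_indicator_swap_symmetry(self):
        r1 = self.run_one(5, 0.07, 0.02)
        rng = np.random.default_rng(5)
        samples = sheet(64, 5)
        dose = rng.binomial(2, 0.3, 64).astype(float)
        b = rng.normal(0, 0.03, 64)
        y_mc = 0.5 + 0.07 * dose + b + rng.normal(0, 0.02, 64)
        y_hmc = 0.06 + 0.02 * dose + b + rng.normal(0, 0.02, 64)
        pcs = pd.DataFrame(rng.normal(0, 1, (64, 2)),
                           index=samples["sample_id"],
                           columns=["PC1", "PC2"])
        r2 = heterogeneity_fit("rs1", "cg1", y_hmc, y_mc, dose,
                                samples, pcs)
        assert r1.p_heterogeneity == pytest.approx(r2.p_heterogeneity,
                                                   abs=1e-12)

    def test_scan_over_significant_pairs(self):
        samples, matrix, dosages, snps, manifest = make_qtl_inputs(
            seed=8, effect=0.15, noise=0.01)
        oxbs = matrix + 0.4
        model = QTLModel({"5mC": oxbs, "5hmC": matrix}, dosages, snps,
                         manifest, samples, window_bp=None)
        res = model.fit()
        het = heterogeneity_scan(res, oxbs, matrix)
        if not het.empty:
            assert {"snp", "probe", "p_heterogeneity"} <= set(het.columns)
            assert het["p_heterogeneity"].between(0, 1).all()
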