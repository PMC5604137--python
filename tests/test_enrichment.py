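"""Feature enrichment, group summaries and pathway analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from oxbstools.containers import DetectionCalibration, HydroxyMatrix
from oxbstools.enrichment import (
    GenePathwayMap,
    feature_enrichment,
    go_enrichment,
    refine_pathways,
    summarize_by_feature,
)


def hypergeom_two_sided_oracle(sig_in, sig_out, nonsig_in, nonsig_out):
    """Exact two-sided p by enumerating the hypergeometric support.

    Sums the probabilities of every table (with the same margins) whose
    point probability does not exceed the observed table's.
    """
    n_in = sig_in + nonsig_in
    n_total = sig_in + sig_out + nonsig_in + nonsig_out
    n_sig = sig_in + sig_out

    def pmf(k):
        return (comb(n_in, k, exact=True)
                * comb(n_total - n_in, n_sig - k, exact=True)
                / comb(n_total, n_sig, exact=True))

    p_obs = pmf(sig_in)
    lo = max(0, n_sig - (n_total - n_in))
    hi = min(n_in, n_sig)
    return sum(pmf(k) for k in range(lo, hi + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


def manifest_with_features(n_in, n_out):
    probes = [f"cg{i:05d}" for i in range(n_in + n_out)]
    return pd.DataFrame({
        "probe": probes, "chrom": "chr1",
        "pos": np.arange(len(probes)) * 100 + 1, "strand": "+",
        "feature": ["island"] * n_in + ["open-sea"] * n_out,
        "cgi": ["island"] * n_in + ["open-sea"] * n_out,
        "genes": "GENEX"})


class TestFeatureEnrichment:
    def test_derived_example_table(self):
        # sig-in=8, sig-out=2, nonsig-in=92, nonsig-out=898
        m = manifest_with_features(100, 900)
        sig = set(m["probe"][:8]) | set(m["probe"][100:102])
        out = feature_enrichment(sig, m, "cgi")
        row = out.set_index("cgi").loc["island"]
        assert row["relative_enrichment"] == pytest.approx(8.0)
        oracle = hypergeom_two_sided_oracle(8, 2, 92, 898)
        assert row["p"] == pytest.approx(oracle, rel=1e-6)

    def test_balanced_toy_no_enrichment(self):
        m = manifest_with_features(100, 100)
        sig = set(m["probe"][:10]) | set(m["probe"][100:110])
        out = feature_enrichment(sig, m, "cgi").set_index("cgi")
        assert out.loc["island", "relative_enrichment"] == pytest.approx(1.0)
        assert out.loc["island", "p"] == pytest.approx(1.0)

    def test_all_significant_inside_feature(self):
        m = manifest_with_features(10, 90)
        sig = set(m["probe"][:10])
        out = feature_enrichment(sig, m, "cgi").set_index("cgi")
        # p equals the point mass of drawing all 10 from the feature
        point = (comb(10, 10, exact=True) * comb(90, 0, exact=True)
                 / comb(100, 10, exact=True))
        assert out.loc["island", "p"] == pytest.approx(point, rel=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_in = int(rng.integers(5, 60))
        n_out = int(rng.integers(5, 120))
        m = manifest_with_features(n_in, n_out)
        n_sig = int(rng.integers(1, n_in + n_out))
        sig = set(rng.choice(m["probe"], size=n_sig, replace=False))
        out = feature_enrichment(sig, m, "cgi").set_index("cgi")
        sig_in = len(sig & set(m["probe"][:n_in]))
        oracle = hypergeom_two_sided_oracle(
            sig_in, n_sig - sig_in, n_in - sig_in,
            n_out - (n_sig - sig_in))
        assert out.loc["island", "p"] == pytest.approx(oracle, rel=1e-6)

    def test_significant_outside_tested_rejected(self):
        m = manifest_with_features(5, 5)
        with pytest.raises(ValueError):
            feature_enrichment({"not_a_probe"}, m, "cgi")


class TestSummarizeByFeature:
    def make_hydroxy(self, values, probes):
        delta = pd.DataFrame(values, index=probes)
        return HydroxyMatrix(delta=delta,
                             calibration=DetectionCalibration(
                                 tau=0.036, n_negative=10))

    def test_identical_probes_no_difference(self):
        m = manifest_with_features(5, 5)
        h = self.make_hydroxy(np.full((10, 6), 0.05), m["probe"])
        out = summarize_by_feature(h, m, "cgi")
        np.testing.assert_allclose(out["mean_5hmc"], 0.05)
        assert out["p"].isna().all()  # zero variance -> test skipped

    def test_planted_offset_detected(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0.04, 0.01, size=(200, 20))
        base[:100] += 0.02  # island probes shifted up
        m = manifest_with_features(100, 100)
        out = summarize_by_feature(self.make_hydroxy(base, m["probe"]),
                                   m, "cgi").set_index("cgi")
        diff = out.loc["island", "mean_5hmc"] - out.loc["open-sea",
                                                        "mean_5hmc"]
        assert abs(diff - 0.02) < 0.2 * 0.02
        assert out.loc["island", "p"] < 1e-10

    def test_null_split_centred_at_zero(self):
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(40):
            vals = rng.normal(0.04, 0.01, size=(60, 10))
            m = manifest_with_features(30, 30)
            out = summarize_by_feature(self.make_hydroxy(vals, m["probe"]),
                                       m, "cgi").set_index("cgi")
            diffs.append(out.loc["island", "mean_5hmc"]
                         - out.loc["open-sea", "mean_5hmc"])
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs))


def build_map(pathways: dict, n_probes: dict | None = None):
    genes = sorted({g for gs in pathways.values() for g in gs})
    gene_to = {g: {pw for pw, gs in pathways.items() if g in gs}
               for g in genes}
    counts = pd.Series(n_probes or {g: 5.0 for g in genes}, dtype=float)
    return GenePathwayMap(gene_to_pathways=gene_to, gene_n_probes=counts)


class TestGoEnrichment:
    def random_universe(self, rng, n_genes=400, n_pathways=40,
                        sizes=(20, 120)):
        genes = [f"G{i:04d}" for i in range(n_genes)]
        pathways = {f"PW{k:03d}": set(rng.choice(
            genes, int(rng.integers(*sizes)), replace=False))
            for k in range(n_pathways)}
        # make sure every gene is mapped somewhere
        pathways["PWALL"] = set(genes[:2000])
        return genes, pathways

    def test_size_filter_applied(self):
        pathways = {"tiny": {f"G{i}" for i in range(5)},
                    "ok": {f"G{i}" for i in range(30)}}
        pw_map = build_map(pathways)
        out = go_enrichment([f"G{i}" for i in range(10)], pw_map)
        assert set(out["pathway"]) == {"ok"}

    def test_rank_agreement_with_exact_test_when_covariate_constant(self):
        # with a constant probes-per-gene covariate the logistic test
        # reduces to the 2x2 problem; its one-sided p should rank the
        # pathways like the exact hypergeometric (mid-p) oracle
        rng = np.random.default_rng(2)
        genes, pathways = self.random_universe(rng, n_pathways=50)
        pw_map = build_map(pathways, {g: 7.0 for g in genes})
        test_genes = set(rng.choice(genes, 60, replace=False))
        out = go_enrichment(test_genes, pw_map, size_max=5000)
        midp = []
        for pw in out["pathway"]:
            members = pathways[pw]
            a = len(test_genes & members)
            hg = stats.hypergeom(len(genes), len(members), len(test_genes))
            midp.append(hg.sf(a) + 0.5 * hg.pmf(a))
        rho = stats.spearmanr(out["p_enrichment"], midp).statistic
        assert rho > 0.99

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        genes, pathways = self.random_universe(rng, n_pathways=200)
        pw_map = build_map(pathways)
        test_genes = set(rng.choice(genes, 50, replace=False))
        out = go_enrichment(test_genes, pw_map, size_max=5000)
        ks = stats.kstest(out["p_enrichment"], "uniform").statistic
        assert ks < 0.1

    def test_probe_count_confounding_controlled(self):
        # list membership driven purely by probes-per-gene: the corrected
        # test stays calibrated while raw Fisher is anti-conservative
        rng = np.random.default_rng(4)
        genes = [f"G{i:04d}" for i in range(600)]
        n_probes = {g: float(rng.integers(1, 60)) for g in genes}
        # pathways preferentially contain probe-rich genes
        weights = np.array([n_probes[g] for g in genes], float)
        weights /= weights.sum()
        pathways = {f"PW{k:03d}":
                    set(rng.choice(genes, 50, replace=False, p=weights))
                    for k in range(60)}
        pathways["PWALL"] = set(genes)
        pw_map = build_map(pathways, n_probes)
        # test list also driven by probe count, independent of pathways
        probs = weights
        test_genes = set(rng.choice(genes, 80, replace=False, p=probs))
        out = go_enrichment(test_genes, pw_map, size_max=500)
        frac_corrected = (out["p_enrichment"] < 0.05).mean()
        fisher_p = []
        for pw in out["pathway"]:
            members = pathways[pw]
            a = len(test_genes & members)
            b = len(test_genes) - a
            c = len(members) - a
            d = len(genes) - a - b - c
            fisher_p.append(stats.fisher_exact(
                [[a, b], [c, d]], alternative="greater")[1])
        frac_fisher = np.mean(np.array(fisher_p) < 0.05)
        mc_sd = np.sqrt(0.05 * 0.95 / len(out))
        assert frac_corrected < frac_fisher
        assert frac_corrected <= 0.05 + 3 * mc_sd

    def test_planted_pathway_recovered(self):
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(100 + seed)
            genes = [f"G{i:04d}" for i in range(300)]
            test_genes = set(rng.choice(genes, 50, replace=False))
            # enriched pathway: odds multiplied by 5 for test genes
            members = set()
            for g in genes:
                p0 = 0.1
                if g in test_genes:
                    odds = p0 / (1 - p0) * 5
                    p0 = odds / (1 + odds)
                if rng.random() < p0:
                    members.add(g)
            pathways = {"planted": members,
                        "null": set(rng.choice(genes, 40, replace=False)),
                        "all": set(genes)}
            pw_map = build_map(pathways)
            out = go_enrichment(test_genes, pw_map, size_max=5000)
            p = out.set_index("pathway").loc["planted", "p_enrichment"]
            hits += p < 0.05
        assert hits / n_runs >= 0.9

    def test_no_test_genes_in_map_rejected(self):
        pw_map = build_map({"pw": {"G1", "G2"} | {f"G{i}" for i in
                                                  range(3, 20)}})
        with pytest.raises(ValueError):
            go_enrichment(["ZZZ"], pw_map)


class TestRefinement:
    def test_single_pathway_is_lead(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(100)]
        test_genes = set(genes[:30])
        pathways = {"A": set(genes[:40]), "all": set(genes)}
        pw_map = build_map(pathways)
        out = go_enrichment(test_genes, pw_map, size_max=5000)
        refined = refine_pathways(out, test_genes, pw_map)
        roles = refined.set_index("pathway")["role"]
        assert roles.get("A") == "lead"

    def test_duplicate_pathway_grouped_under_lead(self):
        genes = [f"G{i}" for i in range(200)]
        test_genes = set(genes[:40])
        shared = set(genes[:60])
        pathways = {"A": shared, "B": set(shared), "all": set(genes)}
        pw_map = build_map(pathways)
        out = go_enrichment(test_genes, pw_map, size_max=5000)
        refined = refine_pathways(out, test_genes, pw_map)
        roles = refined.set_index("pathway")
        leads = set(roles[roles["role"] == "lead"].index) & {"A", "B"}
        grouped = roles[roles["role"] == "grouped"]
        assert len(leads) == 1
        dup = ({"A", "B"} - leads).pop()
        assert roles.loc[dup, "role"] == "grouped"
        assert roles.loc[dup, "grouped_under"] == leads.pop()

    def test_disjoint_true_signals_both_lead(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(400)]
        test_genes = set(genes[:50]) | set(genes[200:250])
        pathways = {"first": set(genes[:70]),
                    "second": set(genes[200:270]),
                    "all": set(genes)}
        pw_map = build_map(pathways)
        out = go_enrichment(test_genes, pw_map, size_max=5000)
        refined = refine_pathways(out, test_genes, pw_map)
        roles = refined.set_index("pathway")["role"]
        assert roles.get("first") == "lead"
        assert roles.get("second") == "lead"

    def test_every_pathway_labelled_once(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(300)]
        test_genes = set(rng.choice(genes, 60, replace=False))
        pathways = {f"PW{k}": set(rng.choice(genes, 50, replace=False))
                    for k in range(20)}
        pathways["all"] = set(genes)
        pw_map = build_map(pathways)
        out = go_enrichment(test_genes, pw_map, size_max=5000)
        refined = refine_pathways(out, test_genes, pw_map)
        assert refined["pathway"].is_unique
        assert set(refined["role"]) <= {"lead", "grouped"}
        n_sig = (out["p_enrichment"] < 0.05).sum()
        assert len(refined) == n_sig
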