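"""Genomic-feature and gene-ontology enrichment of significant probes.

Feature enrichment uses the exact two-sided hypergeometric (Fisher) test
on the 2x2 table of feature membership against significance, reporting a
relative enrichment: the fraction of feature probes that are significant
over the genome-wide fraction.  Pathway enrichment uses logistic
regression over genes (membership ~ in-test-list + probes-per-gene) so
that genes carrying many array probes, which enter significant lists more
easily by chance, do not inflate the result; an iterative refinement pass
groups significant pathways explained by a stronger overlapping pathway
under that lead term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def feature_enrichment(significant, manifest: pd.DataFrame,
                       feature_col: str = "feature",
                       tested=None) -> pd.DataFrame:
    """Per-feature 2x2 enrichment of a significant probe set.

    ``relative_enrichment`` is (significant-in-feature / feature size)
    divided by (significant total / tested total); the p-value is the
    two-sided Fisher exact test.  Feature levels with no probes are
    skipped.
    """
    m = manifest if tested is None else \
        manifest[manifest["probe"].isin(set(tested))]
    significant = set(significant)
    if not significant <= set(m["probe"]):
        raise ValueError("significant probes must be a subset of tested")
    n_total = len(m)
    n_sig = len(significant)
    is_sig = m["probe"].isin(significant)
    rows = []
    for level, grp in m.groupby(feature_col):
        n_feat = len(grp)
        if n_feat == 0:
            continue
        sig_in = int(is_sig[grp.index].sum())
        table = [[sig_in, n_sig - sig_in],
                 [n_feat - sig_in, (n_total - n_feat) - (n_sig - sig_in)]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        frac_in = sig_in / n_feat
        overall = n_sig / n_total
        rows.append({
            feature_col: level,
            "n_feature_probes": n_feat,
            "n_significant_in_feature": sig_in,
            "percent_significant": 100 * frac_in,
            "relative_enrichment": frac_in / overall if overall else np.nan,
            "p": float(p),
        })
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def summarize_by_feature(hydroxy, manifest: pd.DataFrame,
                         group_col: str = "cgi") -> pd.DataFrame:
    """Mean 5hmC by annotation group with a Welch test against the rest.

    The summary statistic is the per-probe mean delta-beta across samples;
    each group's probe-level means are compared with the complement by
    Welch's two-sample t-test.  Groups with fewer than 2 probes are
    reported without a test.
    """
    delta = hydroxy.delta if hasattr(hydroxy, "delta") else hydroxy
    probe_means = delta.mean(axis=1)
    ann = manifest.set_index("probe")[group_col].reindex(probe_means.index)
    rows = []
    for level in ann.dropna().unique():
        in_group = probe_means[ann == level]
        out_group = probe_means[ann != level]
        row = {group_col: level, "n_probes": len(in_group),
               "mean_5hmc": float(in_group.mean()),
               "sd_5hmc": float(in_group.std())}
        if len(in_group) >= 2 and len(out_group) >= 2 and \
                (in_group.std() > 0 or out_group.std() > 0):
            t, p = stats.ttest_ind(in_group, out_group, equal_var=False)
            row.update(t=float(t), p=float(p))
        else:
            row.update(t=np.nan, p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GenePathwayMap:
    """Gene -> pathway mapping plus probes-per-gene counts."""

    gene_to_pathways: dict[str, set[str]]
    gene_n_probes: pd.Series

    @classmethod
    def from_manifest(cls, gene_to_pathways: dict[str, set[str]],
                      manifest: pd.DataFrame,
                      tested=None) -> "GenePathwayMap":
        """Count QC-passing probes per gene from the manifest.

        Probes annotated to several genes count toward each; intergenic
        probes (no gene) are dropped.  Only genes with at least one probe
        and at least one pathway are eligible.
        """
        m = manifest if tested is None else \
            manifest[manifest["probe"].isin(set(tested))]
        counts: dict[str, int] = {}
        for cell in m["genes"]:
            for g in str(cell).split(","):
                if g:
                    counts[g] = counts.get(g, 0) + 1
        eligible = {g: pws for g, pws in gene_to_pathways.items()
                    if pws and counts.get(g)}
        return cls(gene_to_pathways=eligible,
                   gene_n_probes=pd.Series({g: counts[g] for g in eligible},
                                           dtype=float))

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_to_pathways)

    def pathway_sizes(self) -> pd.Series:
        sizes: dict[str, int] = {}
        for pws in self.gene_to_pathways.values():
            for pw in pws:
                sizes[pw] = sizes.get(pw, 0) + 1
        return pd.Series(sizes, dtype=int)


def _logit_pathway(member: np.ndarray, in_list: np.ndarray,
                   covariates: np.ndarray) -> tuple[float, float, bool]:
    """Coefficient and two-sided LRT p for the in-list indicator.

    Pathway membership is regressed on the indicator plus the covariates;
    the p-value is the 1-df likelihood-ratio test against the covariate-
    only model (better calibrated than the Wald test at the small overlap
    counts typical of pathway tables).  When the covariates alone predict
    membership perfectly (e.g. a duplicated pathway used as covariate)
    the indicator can add nothing: coefficient 0, p 1.  A Fisher-exact
    fallback (flagged) covers separation in the indicator itself.
    """
    member = np.asarray(member, float)
    cov = np.atleast_2d(np.asarray(covariates, float).T).T
    cov = cov[:, cov.std(axis=0) > 1e-12]  # constants duplicate the intercept
    X_red = np.column_stack([np.ones(len(member)), cov])
    X = np.column_stack([X_red[:, :1], in_list[:, None], X_red[:, 1:]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            red = sm.GLM(member, X_red,
                         family=sm.families.Binomial()).fit()
            if red.deviance < 1e-8:
                return 0.0, 1.0, False
            fit = sm.GLM(member, X, family=sm.families.Binomial()).fit()
        coef = float(fit.params[1])
        lr = max(float(red.deviance - fit.deviance), 0.0)
        p = float(stats.chi2.sf(lr, df=1))
        if not np.isfinite(p) or abs(coef) > 30:
            raise ValueError("separation")
        return coef, p, False
    except Exception:
        memb = member.astype(bool)
        table = [[int((memb & (in_list > 0)).sum()),
                  int((memb & (in_list == 0)).sum())],
                 [int((~memb & (in_list > 0)).sum()),
                  int((~memb & (in_list == 0)).sum())]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        coef = np.log(odds) if 0 < odds < np.inf else np.sign(odds - 1) * 30.0
        return float(coef), float(p), True


def go_enrichment(test_genes, pathway_map: GenePathwayMap,
                  size_min: int = 10, size_max: int = 2000) -> pd.DataFrame:
    """Probe-count-corrected pathway enrichment of a gene list.

    For each pathway within the size window a logistic regression of
    pathway membership on the in-list indicator and the number of
    QC-passing probes per gene is fitted over all eligible genes.  The
    one-sided enrichment p (indicator > 0) and the two-sided p are both
    reported.
    """
    genes = pathway_map.genes
    test = set(test_genes) & set(genes)
    if not test:
        raise ValueError("no test gene appears in the pathway map")
    in_list = np.array([g in test for g in genes], dtype=float)
    n_probes = np.log1p(pathway_map.gene_n_probes.loc[genes].to_numpy())
    sizes = pathway_map.pathway_sizes()
    rows = []
    for pw, size in sizes.items():
        if not size_min <= size <= size_max:
            continue
        member = np.array([pw in pathway_map.gene_to_pathways[g]
                           for g in genes])
        coef, p_two, fallback = _logit_pathway(member, in_list, n_probes)
        p_one = p_two / 2 if coef > 0 else 1 - p_two / 2
        rows.append({"pathway": pw, "size": int(size),
                     "n_test_in_pathway": int((member & (in_list > 0)).sum()),
                     "coef": coef, "p_enrichment": float(p_one),
                     "p_two_sided": float(p_two), "exact_fallback": fallback})
    return (pd.DataFrame(rows)
            .sort_values("p_enrichment").reset_index(drop=True))


def refine_pathways(enrichment: pd.DataFrame, test_genes,
                    pathway_map: GenePathwayMap,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Group significant pathways explained by a stronger overlapping term.

    Repeatedly takes the most significant remaining pathway as a lead and
    refits every other remaining significant pathway with lead membership
    as an extra covariate; pathways whose in-list indicator is no longer
    significant (p >= alpha) are grouped under the lead.  Every pathway
    ends up labelled exactly once, as a lead or as grouped.
    """
    sig = enrichment[enrichment["p_enrichment"] < alpha] \
        .sort_values("p_enrichment")
    genes = pathway_map.genes
    test = set(test_genes) & set(genes)
    in_list = np.array([g in test for g in genes], dtype=float)
    n_probes = np.log1p(pathway_map.gene_n_probes.loc[genes].to_numpy())
    membership = {pw: np.array([pw in pathway_map.gene_to_pathways[g]
                                for g in genes])
                  for pw in sig["pathway"]}
    remaining = list(sig["pathway"])
    label_rows = []
    while remaining:
        lead = remaining.pop(0)
        label_rows.append({"pathway": lead, "role": "lead",
                           "grouped_under": ""})
        still = []
        for pw in remaining:
            covs = np.column_stack([n_probes,
                                    membership[lead].astype(float)])
            coef, p_two, _ = _logit_pathway(membership[pw], in_list, covs)
            p_one = p_two / 2 if coef > 0 else 1 - p_two / 2
            if p_one >= alpha:
                label_rows.append({"pathway": pw, "role": "grouped",
                                   "grouped_under": lead})
            else:
                still.append(pw)
        remaining = still
    labels = pd.DataFrame(label_rows)
    return sig.merge(labels, on="pathway", how="left")
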