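"""Per-probe linear models for developmental age and sex differences.

For each probe an ordinary least-squares model

    signal ~ intercept + DPC + sex

is fitted, where the signal is delta-beta (5hmC), the oxBS beta (5mC) or
the BS beta (total modification).  Developmental results are reported for
autosomal probes only; sex results for autosomal plus X-linked probes;
Y-linked probes are excluded throughout.  Sex is coded 0 = female,
1 = male, so a positive sex coefficient means higher in males.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TERMS = ("dpc", "sex")
_TERM_COL = {"dpc": 1, "sex": 2}


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


@dataclass
class ThresholdSet:
    n_tests: int
    bonferroni_alpha: float = 0.05
    discovery_p: float = 5e-05

    @property
    def bonferroni_p(self) -> float:
        return bonferroni_threshold(self.n_tests, self.bonferroni_alpha)


def _ols_stats(X: np.ndarray, Y: np.ndarray):
    """Vectorised OLS of every column of Y on the shared design X.

    Returns coefficients (p x m), standard errors, t statistics and
    two-sided p-values with n - p residual degrees of freedom.  Probes
    with (numerically) zero residual variance get se = 0, t = nan, p = 1
    and are flagged degenerate by the caller.
    """
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    rss = (resid ** 2).sum(axis=0)
    scale = np.max(np.abs(Y), axis=0) ** 2 + 1.0
    degenerate = rss <= 1e-24 * n * scale
    sigma2 = np.where(degenerate, np.nan, rss / df)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pval = 2 * stats.t.sf(np.abs(t), df)
    se = np.where(degenerate, 0.0, se)
    pval = np.where(degenerate, 1.0, pval)
    return beta, se, t, pval, degenerate


class SiteDifferentialModel:
    """Joint DPC + sex OLS per probe for one signal matrix.

    Parameters
    ----------
    matrix : DataFrame
        Signal values, probes x samples (delta-beta, oxBS or BS betas).
    samples : DataFrame
        Sample sheet with ``sample_id``, ``dpc`` and ``sex`` columns.
    signal : str
        Label stored in the results ('5hmC', '5mC' or 'total').
    manifest : DataFrame, optional
        Probe manifest; required for the chromosome-aware term subsets.
    """

    def __init__(self, matrix: pd.DataFrame, samples: pd.DataFrame,
                 signal: str = "5hmC", manifest: pd.DataFrame | None = None):
        if matrix.shape[1] != len(samples):
            raise ValueError("matrix columns and sample sheet differ")
        if matrix.shape[1] < 4:
            raise ValueError("at least 4 samples required")
        self.matrix = matrix
        self.samples = samples
        self.signal = signal
        self.manifest = manifest
        sex = (samples["sex"] == "M").to_numpy(float)
        if sex.min() == sex.max():
            raise ValueError("both sexes must be present (constant covariate)")
        dpc = samples["dpc"].to_numpy(float)
        self.design = np.column_stack([np.ones(len(samples)), dpc, sex])

    @classmethod
    def from_dataset(cls, dataset, signal: str = "5mC"):
        """Build from a PairedBetaDataset ('5mC' = oxBS, 'total' = BS)."""
        matrix = dataset.oxbs if signal == "5mC" else dataset.bs
        return cls(matrix, dataset.samples, signal=signal,
                   manifest=dataset.manifest)

    def fit(self) -> "SiteDifferentialResults":
        Y = self.matrix.to_numpy(float).T  # samples x probes
        complete = np.isfinite(Y).all(axis=0)
        n, _ = self.design.shape
        n_probes = Y.shape[1]
        out = {k: np.full((3, n_probes), np.nan) for k in
               ("coef", "se", "t", "p")}
        n_used = np.full(n_probes, n)
        degenerate = np.zeros(n_probes, bool)
        skipped = np.zeros(n_probes, bool)
        if complete.any():
            b, se, t, p, dg = _ols_stats(self.design, Y[:, complete])
            for k, v in zip(("coef", "se", "t", "p"), (b, se, t, p)):
                out[k][:, complete] = v
            degenerate[complete] = dg
        for j in np.nonzero(~complete)[0]:  # per-probe complete cases
            mask = np.isfinite(Y[:, j])
            n_used[j] = mask.sum()
            if n_used[j] < 4:
                skipped[j] = True
                continue
            b, se, t, p, dg = _ols_stats(self.design[mask],
                                         Y[mask, j][:, None])
            for k, v in zip(("coef", "se", "t", "p"), (b, se, t, p)):
                out[k][:, j] = v[:, 0]
            degenerate[j] = dg[0]
        return SiteDifferentialResults(self, out, n_used, degenerate, skipped)


class SiteDifferentialResults:
    """Per-probe estimates from :class:`SiteDifferentialModel`."""

    def __init__(self, model, stats_dict, n_used, degenerate, skipped):
        self.model = model
        self._stats = stats_dict
        self.n_used = n_used
        self.degenerate = degenerate
        self.skipped = skipped

    def _frame(self, term: str) -> pd.DataFrame:
        j = _TERM_COL[term]
        m = self.model
        df = pd.DataFrame({
            "probe": m.matrix.index,
            "signal": m.signal,
            "term": term,
            "coefficient": self._stats["coef"][j],
            "se": self._stats["se"][j],
            "t": self._stats["t"][j],
            "p": self._stats["p"][j],
            "n": self.n_used,
            "degenerate": self.degenerate,
            "skipped": self.skipped,
        })
        if m.manifest is not None:
            ann = m.manifest.set_index("probe")[["chrom", "pos"]]
            df = df.join(ann, on="probe")
        return df[~df["skipped"]].drop(columns="skipped").reset_index(drop=True)

    def for_term(self, term: str, chrom_filter: bool = True) -> pd.DataFrame:
        """Result table for one term with the chromosome policy applied.

        DPC results cover autosomes only; sex results cover autosomes plus
        the X chromosome; Y probes never appear.  Pass
        ``chrom_filter=False`` to get every probe instead.
        """
        if term not in TERMS:
            raise ValueError(f"term must be one of {TERMS}")
        df = self._frame(term)
        if self.model.manifest is None or not chrom_filter:
            return df
        if term == "dpc":
            df = df[~df["chrom"].isin(["chrX", "chrY"])]
        else:
            df = df[df["chrom"] != "chrY"]
        return df.reset_index(drop=True)

    def with_thresholds(self, term: str, alpha: float = 0.05,
                        discovery_p: float = 5e-05) -> pd.DataFrame:
        """Term table plus Bonferroni/discovery significance flags."""
        df = self.for_term(term)
        cut = bonferroni_threshold(len(df), alpha)
        df = df.copy()
        df["significant_bonferroni"] = df["p"] < cut
        df["significant_discovery"] = df["p"] < discovery_p
        df.attrs["bonferroni_p"] = cut
        return df

    def summary(self, term: str = "dpc") -> str:
        df = self.with_thresholds(term)
        lines = [
            f"Site differential model: {self.model.signal} ~ DPC + sex",
            f"term: {term}   probes tested: {len(df)}   "
            f"samples: {self.model.matrix.shape[1]}",
            f"Bonferroni p < {df.attrs['bonferroni_p']:.3g}: "
            f"{int(df['significant_bonferroni'].sum())} probes",
            f"discovery p < 5e-05: "
            f"{int(df['significant_discovery'].sum())} probes",
        ]
        return "\n".join(lines)


def fit_site_models(matrix: pd.DataFrame, samples: pd.DataFrame,
                    signal: str = "5hmC",
                    manifest: pd.DataFrame | None = None,
                    terms=TERMS) -> pd.DataFrame:
    """Functional wrapper: fitted per-probe results stacked over terms."""
    res = SiteDifferentialModel(matrix, samples, signal, manifest).fit()
    return pd.concat([res.for_term(t) for t in terms], ignore_index=True)


def direction_enrichment(results: pd.DataFrame, p_cut: float) -> dict:
    """Sign balance among significant probes.

    Counts probes with positive ('up', increasing with the term) and
    negative coefficients among those with p < p_cut; the odds ratio is
    n_up / n_down and the p-value is the exact two-sided binomial test
    against equal proportions.
    """
    sig = results[results["p"] < p_cut]
    n_up = int((sig["coefficient"] > 0).sum())
    n_down = int((sig["coefficient"] < 0).sum())
    total = n_up + n_down
    if total == 0:
        return {"n_up": 0, "n_down": 0, "odds": np.nan, "binomial_p": np.nan}
    odds = np.inf if n_down == 0 else n_up / n_down
    p = stats.binomtest(n_up, total, 0.5, alternative="two-sided").pvalue
    return {"n_up": n_up, "n_down": n_down, "odds": odds, "binomial_p": p}


def correlate_effect_sizes(results_a: pd.DataFrame, results_b: pd.DataFrame,
                           on: str = "coefficient") -> dict:
    """Pearson correlation of effect sizes over the shared probes."""
    a = results_a.set_index("probe")[on]
    b = results_b.set_index("probe")[on]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared probes")
    r, p = stats.pearsonr(a.loc[shared], b.loc[shared])
    return {"r": float(r), "p": float(p), "n": int(len(shared))}
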