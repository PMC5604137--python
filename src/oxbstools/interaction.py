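"""Tests for divergent developmental trajectories of 5mC and 5hmC.

At each probe the oxBS betas (5mC) and the delta betas (5hmC) from the
same individuals are stacked, with a modification indicator and its
interaction with developmental age among the fixed effects and a random
intercept per individual absorbing the within-person correlation:

    value ~ DPC + sex + modification + DPC:modification + (1 | individual)

A significant DPC-by-modification interaction means the two marks change
at different rates across development; the interaction coefficient equals
the 5hmC slope minus the 5mC slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import paired_lrt

# design columns: intercept, dpc, sex, indicator(5hmC), dpc x indicator
_COL_INTERCEPT, _COL_DPC, _COL_SEX, _COL_IND, _COL_INTER = range(5)


def _designs(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    dpc = samples["dpc"].to_numpy(float)
    sex = (samples["sex"] == "M").to_numpy(float)
    n = len(samples)
    ones = np.ones(n)
    zeros = np.zeros(n)
    X_mc = np.column_stack([ones, dpc, sex, zeros, zeros])
    X_hmc = np.column_stack([ones, dpc, sex, ones, dpc])
    return X_mc, X_hmc


@dataclass
class InteractionResult:
    probe: str
    slope_5mc: float
    slope_5hmc: float
    interaction: float          # slope_5hmc - slope_5mc
    se_interaction: float
    se_slope_5mc: float
    se_slope_5hmc: float
    p_lrt: float
    p_wald: float
    lrt_stat: float
    boundary: bool
    degenerate: bool


def fit_interaction(probe: str, oxbs_row, delta_row,
                    samples: pd.DataFrame) -> InteractionResult:
    """Mixed-model slope-heterogeneity test for one probe.

    Fits the random-intercept model by maximum likelihood on the complete
    cases present in both modifications and tests the DPC-by-modification
    interaction with a 1-df likelihood-ratio test (the Wald p is also
    reported).
    """
    y_mc = np.asarray(oxbs_row, float)
    y_hmc = np.asarray(delta_row, float)
    mask = np.isfinite(y_mc) & np.isfinite(y_hmc)
    if mask.sum() < 8:
        raise ValueError("need at least 8 individuals with both measurements")
    if not mask.all():
        samples = samples.loc[mask].reset_index(drop=True)
    X_mc, X_hmc = _designs(samples)
    full, _, lrt_stat, p_lrt = paired_lrt(
        y_mc[mask], y_hmc[mask], X_mc, X_hmc, drop=_COL_INTER)
    slope_mc = float(full.beta[_COL_DPC])
    inter = float(full.beta[_COL_INTER])
    cov = full.cov_beta
    var_hmc_slope = (cov[_COL_DPC, _COL_DPC] + cov[_COL_INTER, _COL_INTER]
                     + 2 * cov[_COL_DPC, _COL_INTER])
    return InteractionResult(
        probe=probe, slope_5mc=slope_mc, slope_5hmc=slope_mc + inter,
        interaction=inter, se_interaction=float(full.se[_COL_INTER]),
        se_slope_5mc=float(full.se[_COL_DPC]),
        se_slope_5hmc=float(np.sqrt(max(var_hmc_slope, 0.0))),
        p_lrt=p_lrt, p_wald=full.wald_p(_COL_INTER), lrt_stat=lrt_stat,
        boundary=full.boundary, degenerate=full.degenerate)


class ModificationInteractionModel:
    """Slope-interaction tests over a set of probes.

    Parameters
    ----------
    oxbs, delta : DataFrame
        5mC betas and delta betas, probes x samples, identically indexed.
    samples : DataFrame
        Sample sheet (``sample_id``, ``dpc``, ``sex``).
    probes : sequence, optional
        Probes to test (e.g. the developmental discovery set); defaults to
        every shared probe.
    """

    def __init__(self, oxbs: pd.DataFrame, delta: pd.DataFrame,
                 samples: pd.DataFrame, probes=None):
        shared = oxbs.index.intersection(delta.index)
        if probes is not None:
            shared = shared.intersection(pd.Index(probes))
        if shared.empty:
            raise ValueError("no shared probes to test")
        self.oxbs = oxbs.loc[shared]
        self.delta = delta.loc[shared]
        self.samples = samples

    def fit(self) -> "ModificationInteractionResults":
        rows = []
        for probe in self.oxbs.index:
            r = fit_interaction(probe, self.oxbs.loc[probe].to_numpy(),
                                self.delta.loc[probe].to_numpy(),
                                self.samples)
            rows.append(r.__dict__)
        return ModificationInteractionResults(self, pd.DataFrame(rows))


class ModificationInteractionResults:
    def __init__(self, model, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def bonferroni_p(self) -> float:
        return interaction_bonferroni(len(self.table))

    def significant(self, p_cut: float | None = None) -> pd.DataFrame:
        cut = self.bonferroni_p if p_cut is None else p_cut
        return self.table[self.table["p_lrt"] < cut]

    def summary(self) -> str:
        cut = self.bonferroni_p
        n_sig = int((self.table["p_lrt"] < cut).sum())
        return "\n".join([
            "Modification interaction model: "
            "value ~ DPC + sex + mod + DPC:mod + (1 | individual)",
            f"probes tested: {len(self.table)}",
            f"significant interactions (p < {cut:.3g}): {n_sig} "
            f"({100 * n_sig / len(self.table):.2f}%)",
        ])


def interaction_bonferroni(n_tested: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold over the probes carried into the test."""
    if n_tested < 1:
        raise ValueError("n_tested must be at least 1")
    return alpha / n_tested


def classify_trajectories(results: pd.DataFrame,
                          p_cut: float = 0.05) -> pd.DataFrame:
    """Label each probe's joint 5mC/5hmC developmental behaviour.

    'parallel': both slopes nominally significant with the same sign;
    'opposed': both significant with opposite signs; 'hmc-only': only the
    5hmC slope significant; 'none' otherwise.  Significance of each slope
    uses the Wald test from the mixed fit at ``p_cut``.
    """
    out = results.copy()
    z_mc = out["slope_5mc"] / out["se_slope_5mc"].replace(0, np.nan)
    z_hmc = out["slope_5hmc"] / out["se_slope_5hmc"].replace(0, np.nan)
    p_mc = 2 * stats.norm.sf(np.abs(z_mc))
    p_hmc = 2 * stats.norm.sf(np.abs(z_hmc))
    same_sign = np.sign(out["slope_5mc"]) == np.sign(out["slope_5hmc"])
    sig_mc = p_mc < p_cut
    sig_hmc = p_hmc < p_cut
    labels = np.where(
        sig_mc & sig_hmc & same_sign, "parallel",
        np.where(sig_mc & sig_hmc, "opposed",
                 np.where(sig_hmc & ~sig_mc, "hmc-only", "none")))
    out["classification"] = labels
    return out
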