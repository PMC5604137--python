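"""Exact ML for the balanced two-measurements-per-individual mixed model.

Both the 5mC-vs-5hmC slope-interaction test and the QTL heterogeneity test
fit the same random-intercept model: every individual contributes exactly
one row per modification,

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sb^2),  e_ij ~ N(0, se^2)

with j indexing the modification.  For this balanced design the
per-individual sum and difference contrasts

    u_i = (y_i1 + y_i2) / sqrt(2),    v_i = (y_i1 - y_i2) / sqrt(2)

are independent with variances l1 = se^2 + 2 sb^2 and l2 = se^2, turning
the marginal likelihood into two heteroscedastic least-squares blocks that
share the fixed-effect vector.  Maximum likelihood is then an exact
coordinate ascent: GLS for beta given (l1, l2), closed-form variance
updates given beta, with the boundary sb^2 = 0 handled as pooled OLS.
This is faster and far more robust near the variance boundary than a
generic mixed-model optimiser, which matters for the large null-
calibration suites these tests require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PairedMixedFit:
    """ML fit of the balanced random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_e2: float
    sigma_b2: float
    loglik: float
    n_individuals: int
    boundary: bool          # sb^2 estimated at 0
    degenerate: bool        # within-pair residual variance ~ 0
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def wald_p(self, index: int) -> float:
        """Two-sided Wald p-value for one fixed effect (normal reference)."""
        se = self.se[index]
        if not np.isfinite(se) or se == 0:
            return 1.0
        return float(2 * stats.norm.sf(abs(self.beta[index]) / se))


def fit_paired_mixed(y1: np.ndarray, y2: np.ndarray,
                     X1: np.ndarray, X2: np.ndarray,
                     max_iter: int = 200, tol: float = 1e-10,
                     ) -> PairedMixedFit:
    """Fit the balanced paired random-intercept model by exact ML.

    ``y1``/``X1`` are the outcome and design rows for modification 1,
    ``y2``/``X2`` for modification 2, aligned on individuals; the fixed-
    effect vector is shared.
    """
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n = len(y1)
    if len(y2) != n or X1.shape[0] != n or X2.shape[0] != n:
        raise ValueError("rows must align on individuals")
    s2 = np.sqrt(2.0)
    u, v = (y1 + y2) / s2, (y1 - y2) / s2
    Xu, Xv = (X1 + X2) / s2, (X1 - X2) / s2

    scale = max(float(np.var(y1) + np.var(y2)), 1e-30)
    floor = 1e-12 * scale

    # init from unweighted stacked OLS
    Xs = np.vstack([Xu, Xv])
    ys = np.concatenate([u, v])
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    l1 = max(float(np.mean((u - Xu @ beta) ** 2)), floor)
    l2 = max(float(np.mean((v - Xv @ beta) ** 2)), floor)

    degenerate = False
    ll_old = -np.inf
    converged = False
    boundary = False
    for _ in range(max_iter):
        if l1 < l2:  # sb^2 would be negative: boundary, pooled variance
            boundary = True
            l1 = l2 = max((l1 + l2) / 2, floor)
        else:
            boundary = False
        A = Xu.T @ Xu / l1 + Xv.T @ Xv / l2
        b = Xu.T @ u / l1 + Xv.T @ v / l2
        beta = np.linalg.solve(A, b)
        ru = u - Xu @ beta
        rv = v - Xv @ beta
        if boundary:
            l1 = l2 = max(float((ru @ ru + rv @ rv) / (2 * n)), floor)
        else:
            l1 = max(float(ru @ ru / n), floor)
            l2 = max(float(rv @ rv / n), floor)
            if l1 < l2:
                continue  # revisit with the boundary constraint active
        ll = -0.5 * (n * np.log(l1) + (ru @ ru) / l1
                     + n * np.log(l2) + (rv @ rv) / l2) \
            - n * np.log(2 * np.pi)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_old = ll
    if l2 <= floor * 1.01:
        degenerate = True
    A = Xu.T @ Xu / l1 + Xv.T @ Xv / l2
    cov = np.linalg.inv(A)
    return PairedMixedFit(
        beta=beta, cov_beta=cov, sigma_e2=l2, sigma_b2=max((l1 - l2) / 2, 0.0),
        loglik=float(ll), n_individuals=n, boundary=boundary,
        degenerate=degenerate, converged=converged)


def paired_lrt(y1, y2, X1_full, X2_full, drop: int,
               ) -> tuple[PairedMixedFit, PairedMixedFit, float, float]:
    """Likelihood-ratio test for one fixed effect in the paired model.

    Fits the full model and the model with column ``drop`` removed from
    both designs; returns (full fit, reduced fit, LRT statistic, p) with
    the p-value from the chi-square distribution on 1 df.  Degenerate
    within-pair variance (e.g. the two modifications are numerically
    identical) yields p = 1.
    """
    keep = [j for j in range(X1_full.shape[1]) if j != drop]
    full = fit_paired_mixed(y1, y2, X1_full, X2_full)
    reduced = fit_paired_mixed(y1, y2, X1_full[:, keep], X2_full[:, keep])
    if full.degenerate or reduced.degenerate:
        return full, reduced, 0.0, 1.0
    stat = max(2 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(stat, df=1))
    return full, reduced, stat, p
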