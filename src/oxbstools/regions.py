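"""Spatially-correlated p-value combination and region calling.

Implements the two-pass region procedure popularised for methylation
arrays: estimate the distance-binned autocorrelation of probit-transformed
p-values, smooth each site's p by a Stouffer-Liptak combination over its
neighbourhood, seed and extend candidate regions from the smoothed track,
then score each region with a Stouffer-Liptak combination of the original
p-values and a Sidak correction scaled by n_a / n_r (total probes tested
over probes in the region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-300
P_CEIL = 1 - 1e-16


@dataclass
class PValueTrack:
    """Sorted per-probe p-values with genomic coordinates (1-based)."""

    data: pd.DataFrame  # columns: chrom, pos, probe, p

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "p"}
        if not required <= set(self.data.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if "probe" not in self.data.columns:
            self.data = self.data.assign(probe=[f"site{i}" for i in
                                                range(len(self.data))])
        d = self.data.sort_values(["chrom", "pos"]).reset_index(drop=True)
        if (d.groupby("chrom")["pos"].apply(lambda s: s.duplicated().any())
                .any()):
            raise ValueError("duplicate positions within a chromosome")
        p = d["p"].to_numpy(float)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        self.data = d

    @classmethod
    def from_results(cls, results: pd.DataFrame) -> "PValueTrack":
        return cls(results[["chrom", "pos", "probe", "p"]].copy())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class AcfEstimate:
    """Distance-binned autocorrelation of probit-transformed p-values."""

    bin_edges: np.ndarray      # half-open [lo, hi) in bp, increasing
    correlations: np.ndarray   # one per bin
    n_pairs: np.ndarray
    inherited: np.ndarray = field(default=None)  # bins below the pair floor

    def corr_at(self, dist: float) -> float:
        """Correlation for a pair at the given distance (0 beyond range)."""
        if dist <= 0:
            return 1.0
        idx = np.searchsorted(self.bin_edges[1:], dist, side="left")
        if idx >= len(self.correlations):
            return 0.0
        return float(self.correlations[idx])


def _probit(p: np.ndarray) -> np.ndarray:
    """z = Phi^-1(1 - p), large for small p."""
    return stats.norm.isf(np.clip(p, P_FLOOR, P_CEIL))


def estimate_acf(track: PValueTrack, max_dist: int = 500,
                 bin_width: int = 50, min_pairs: int = 10) -> AcfEstimate:
    """Estimate distance-binned correlation of neighbouring test statistics.

    For every intra-chromosome probe pair closer than ``max_dist``, the
    Pearson correlation of the probit-transformed p-values is computed
    within half-open distance bins of ``bin_width``.  Bins with fewer than
    ``min_pairs`` pairs inherit the nearest estimated bin (identity/zero
    if none exists).
    """
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    pairs: list[list[tuple[float, float]]] = [[] for _ in range(n_bins)]
    d = track.data
    z = _probit(d["p"].to_numpy())
    for _, grp in d.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        for i in range(len(grp)):
            j = i + 1
            while j < len(grp) and pos[j] - pos[i] <= max_dist:
                dist = pos[j] - pos[i]
                b = int(np.searchsorted(edges[1:], dist, side="left"))
                pairs[b].append((z[idx[i]], z[idx[j]]))
                j += 1

    cors = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        n_pairs[b] = len(pairs[b])
        if n_pairs[b] >= min_pairs:
            a = np.array(pairs[b])
            # symmetrise: a pair contributes in both orders
            x = np.concatenate([a[:, 0], a[:, 1]])
            y = np.concatenate([a[:, 1], a[:, 0]])
            if np.std(x) > 0:
                cors[b] = np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0)
    inherited = ~np.isfinite(cors)
    if inherited.all():
        warnings.warn("no distance bin had enough pairs; assuming "
                      "independence between neighbouring sites")
        cors[:] = 0.0
    elif inherited.any():
        known = np.nonzero(~inherited)[0]
        for b in np.nonzero(inherited)[0]:
            cors[b] = cors[known[np.argmin(np.abs(known - b))]]
    return AcfEstimate(bin_edges=edges, correlations=cors, n_pairs=n_pairs,
                       inherited=inherited)


def _make_psd(C: np.ndarray, max_lambda: float = 1.0) -> np.ndarray:
    """Shrink toward the identity until positive semi-definite."""
    lam = 0.0
    step = 1e-6
    while True:
        Cs = (1 - lam) * C + lam * np.eye(len(C)) if lam else C
        if np.linalg.eigvalsh(Cs).min() >= -1e-12:
            return Cs
        lam = step if lam == 0 else min(lam * 2, max_lambda)
        if lam >= max_lambda:
            raise np.linalg.LinAlgError(
                "correlation matrix cannot be regularised to PSD")
        step = lam


def stouffer_liptak(p_values, correlation_matrix=None) -> float:
    """Combine p-values allowing for correlation between the tests.

    Each p is transformed to z = Phi^-1(1 - p); the combined statistic is
    sum(z) / sqrt(sum of all correlation entries) and the combined p is its
    upper-tail normal probability.  With the identity matrix this is the
    classical equally-weighted Stouffer combination.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    k = len(p)
    if correlation_matrix is None:
        C = np.eye(k)
    else:
        C = np.atleast_2d(np.asarray(correlation_matrix, dtype=float))
        if C.shape != (k, k):
            raise ValueError("correlation matrix does not match p length")
        C = _make_psd(C)
    z = _probit(p)
    denom = C.sum()
    if denom <= 0:
        raise ValueError("correlation matrix sums to a non-positive value")
    return float(stats.norm.sf(z.sum() / np.sqrt(denom)))


def _neighbourhood_corr(positions: np.ndarray, acf: AcfEstimate) -> np.ndarray:
    k = len(positions)
    C = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            C[i, j] = C[j, i] = acf.corr_at(abs(positions[j] - positions[i]))
    return C


def slk_adjust(track: PValueTrack, acf: AcfEstimate,
               window: int = 500) -> PValueTrack:
    """Smooth each site's p by combining it with its neighbours.

    Every site's p-value is replaced by the Stouffer-Liptak combination of
    the site and all sites within ``window`` bp on the same chromosome,
    with pairwise correlations taken from the distance-binned estimate.
    Isolated sites are unchanged.
    """
    d = track.data
    adjusted = d["p"].to_numpy(float).copy()
    for _, grp in d.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        pv = grp["p"].to_numpy()
        idx = grp.index.to_numpy()
        lo = np.searchsorted(pos, pos - window, side="left")
        hi = np.searchsorted(pos, pos + window, side="right")
        for i in range(len(grp)):
            if hi[i] - lo[i] <= 1:
                continue
            sel = slice(lo[i], hi[i])
            C = _neighbourhood_corr(pos[sel], acf)
            adjusted[idx[i]] = stouffer_liptak(pv[sel], C)
    out = d.copy()
    out["p"] = np.clip(adjusted, P_FLOOR, 1.0)
    return PValueTrack(out)


@dataclass
class RegionResult:
    """A called region with combined and Sidak-corrected p-values."""

    chrom: str
    start: int           # 1-based inclusive
    end: int             # 1-based inclusive
    n_probes: int
    combined_p: float
    sidak_p: float
    probes: list[str]
    n_a: int
    n_r: int


def find_regions(track: PValueTrack, seed_p: float = 1e-4,
                 max_gap: int = 500, min_probes: int = 3) -> list[dict]:
    """Candidate intervals of consecutive sub-threshold sites.

    A region is a maximal run of sites with (smoothed) p < ``seed_p``
    whose consecutive gaps are at most ``max_gap`` bp; runs with fewer
    than ``min_probes`` members are discarded.
    """
    candidates = []
    d = track.data
    for chrom, grp in d.groupby("chrom", sort=False):
        sub = grp[grp["p"] < seed_p]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        probes = sub["probe"].to_numpy()
        run_start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or pos[i] - pos[i - 1] > max_gap:
                if i - run_start >= min_probes:
                    candidates.append({
                        "chrom": chrom,
                        "start": int(pos[run_start]),
                        "end": int(pos[i - 1]),
                        "probes": list(probes[run_start:i]),
                        "positions": pos[run_start:i].tolist(),
                    })
                run_start = i
    return candidates


def score_regions(candidates: list[dict], original: PValueTrack,
                  acf: AcfEstimate, n_a: int) -> list[RegionResult]:
    """Score candidates on the original (unsmoothed) p-values.

    The combined p uses the Stouffer-Liptak statistic with ACF-derived
    correlations; the Sidak-corrected p is 1 - (1 - p)^(n_a / n_r) where
    n_a is the total number of probes tested and n_r the region size.
    Results come back sorted by corrected p.
    """
    lookup = original.data.set_index(["chrom", "pos"])["p"]
    results = []
    for cand in candidates:
        pos = np.asarray(cand["positions"])
        p = lookup.loc[[(cand["chrom"], int(x)) for x in pos]].to_numpy()
        C = _neighbourhood_corr(pos, acf)
        combined = stouffer_liptak(p, C)
        n_r = len(pos)
        sidak = sidak_correction(combined, n_a, n_r)
        results.append(RegionResult(
            chrom=cand["chrom"], start=cand["start"], end=cand["end"],
            n_probes=n_r, combined_p=combined, sidak_p=sidak,
            probes=cand["probes"], n_a=n_a, n_r=n_r))
    results.sort(key=lambda r: (r.sidak_p, r.combined_p))
    return results


def sidak_correction(p: float, n_a: int, n_r: int) -> float:
    """Sidak adjustment for n_a / n_r effective tests."""
    if p <= 0:
        return 0.0
    ratio = n_a / n_r
    return float(-np.expm1(ratio * np.log1p(-min(p, 1.0))))


def call_regions(results: pd.DataFrame, seed_p: float = 1e-4,
                 max_gap: int = 500, min_probes: int = 3,
                 sidak_cut: float = 0.05, bin_width: int = 50,
                 ) -> tuple[list[RegionResult], AcfEstimate]:
    """End-to-end region calling from a per-probe association table.

    ``results`` needs columns chrom, pos, probe, p (as produced by the
    association stage).  Returns regions passing the Sidak cut plus the
    ACF estimate used.
    """
    track = PValueTrack.from_results(results)
    acf = estimate_acf(track, max_dist=max_gap, bin_width=bin_width)
    adjusted = slk_adjust(track, acf, window=max_gap)
    candidates = find_regions(adjusted, seed_p=seed_p, max_gap=max_gap,
                              min_probes=min_probes)
    scored = score_regions(candidates, track, acf, n_a=len(track))
    return [r for r in scored if r.sidak_p < sidak_cut], acf


def regions_to_frame(regions: list[RegionResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_probes": r.n_probes, "combined_p": r.combined_p,
        "sidak_p": r.sidak_p, "probes": ",".join(r.probes)}
        for r in regions])
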