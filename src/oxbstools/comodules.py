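"""Signed weighted co-hydroxymethylation networks and module detection.

The workflow mirrors weighted correlation network analysis: a signed
adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^power, optional topological
overlap, average-linkage hierarchical clustering with a static height
cut and a minimum module size, iterative merging of modules whose
eigengenes (first principal components) correlate above 1 - merge
threshold, and the usual module diagnostics: module membership MM
(|cor(probe, eigengene)|), probe significance PS (|cor(probe, trait)|),
and module-trait correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

_COLORS = ["turquoise", "blue", "brown", "yellow", "green", "red", "black",
           "pink", "magenta", "purple", "greenyellow", "tan", "salmon",
           "cyan", "midnightblue", "lightcyan", "grey60", "lightgreen",
           "lightyellow", "royalblue", "darkred", "darkgreen", "darkturquoise",
           "darkgrey", "orange", "darkorange", "white", "skyblue",
           "saddlebrown", "steelblue", "paleturquoise", "violet"]
GREY = "grey"


@dataclass
class NetworkConfig:
    """Tunables of the signed network build.

    ``min_module_size`` defaults to the array-scale value of 1000 probes
    only for inputs of at least 100,000 probes; below that it scales as
    max(20, n_probes / 100).
    """

    soft_power: int = 5
    signed: bool = True
    merge_threshold: float = 0.30
    min_module_size: int | None = None
    tom: bool = True
    cut_height_quantile: float = 0.99
    cut_height_max: float = 0.90  # ceiling; background joins sit above it
    kme_min: float = 0.30  # probes below this |cor(probe, ME)| go grey

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must lie in (0, 1)")

    def resolve_min_size(self, n_probes: int) -> int:
        if self.min_module_size is not None:
            return self.min_module_size
        if n_probes >= 100_000:
            return 1000
        return max(20, n_probes // 100)


def build_adjacency(delta: pd.DataFrame,
                    config: NetworkConfig) -> pd.DataFrame:
    """Signed soft-thresholded adjacency from probe-probe correlations.

    Zero-variance probes are excluded with a warning (their correlation is
    undefined).
    """
    if delta.shape[0] < 3 or delta.shape[1] < 3:
        raise ValueError("need at least 3 probes and 3 samples")
    x = delta.to_numpy(float)
    keep = x.std(axis=1) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance probes")
        x = x[keep]
    idx = delta.index[keep]
    cor = np.corrcoef(x)
    if config.signed:
        adj = ((1 + cor) / 2) ** config.soft_power
    else:
        adj = np.abs(cor) ** config.soft_power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=idx, columns=idx)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap of the adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj over u != i, j and k the connectivity.
    """
    a = adjacency.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def module_eigengene(delta: pd.DataFrame, probes,
                     ) -> tuple[pd.Series, float, bool]:
    """First principal component of the probe-standardised module block.

    Returns the unit-variance eigengene (per sample), the fraction of
    variance it explains, and a flag marking a degenerate sign
    orientation.  The sign is chosen so the eigengene correlates
    positively with the module's mean standardised profile; when that
    mean is numerically zero (e.g. perfectly anti-correlated probes) the
    first probe's profile breaks the tie and the flag is set.
    """
    probes = pd.Index(probes)
    if probes.empty:
        raise ValueError("module is empty")
    sub = delta.loc[probes].to_numpy(float)
    sd = sub.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    if len(probes) == 1:
        me = z[0]
        var_explained = 1.0
        flagged = False
    else:
        u_, s_, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        var_explained = float(s_[0] ** 2 / (s_ ** 2).sum())
        mean_profile = z.mean(axis=0)
        flagged = False
        orient = float(me @ mean_profile)
        if abs(orient) < 1e-10:
            orient = float(me @ z[0])
            flagged = True
        if orient < 0:
            me = -me
    sd_me = me.std(ddof=0)
    me = me / sd_me if sd_me > 0 else me
    return pd.Series(me, index=delta.columns, name="ME"), var_explained, flagged


def detect_modules(adjacency: pd.DataFrame, config: NetworkConfig,
                   delta: pd.DataFrame | None = None) -> pd.Series:
    """Cluster the network and assign probes to pre-merge modules.

    Average-linkage hierarchical clustering runs on the TOM dissimilarity
    (or 1 - adjacency when ``tom`` is off); the tree is cut at a fixed
    height (a quantile of the merge heights) and clusters below the
    minimum size become 'grey' (unassigned).  When the data matrix is
    supplied, cluster members whose eigengene membership falls below
    ``config.kme_min`` are returned to grey: a static height cut is
    greedy and otherwise absorbs uncorrelated probes into large clusters.
    """
    n = len(adjacency)
    min_size = config.resolve_min_size(n)
    if config.tom:
        diss = 1 - topological_overlap(adjacency).to_numpy()
    else:
        diss = 1 - adjacency.to_numpy()
    diss = np.clip((diss + diss.T) / 2, 0, None)
    np.fill_diagonal(diss, 0.0)
    Z = hierarchy.average(squareform(diss, checks=False))
    height = min(float(np.quantile(Z[:, 2], config.cut_height_quantile)),
                 config.cut_height_max)
    raw = hierarchy.fcluster(Z, t=height, criterion="distance")
    labels = pd.Series(raw, index=adjacency.index)
    if delta is not None:
        labels = _prune_low_membership(labels, delta, config.kme_min,
                                       min_size)
    sizes = labels.value_counts()
    keep = sizes.index[(sizes >= min_size) & (sizes.index != 0)]
    # deterministic colour order: biggest cluster first
    keep = sorted(keep, key=lambda c: (-sizes[c], c))
    mapping = {c: _COLORS[i % len(_COLORS)] for i, c in enumerate(keep)}
    out = labels.map(lambda c: mapping.get(c, GREY))
    if (out == GREY).all():
        warnings.warn("no module met the minimum size; everything is grey")
    return out.rename("module")


def _prune_low_membership(labels: pd.Series, delta: pd.DataFrame,
                          kme_min: float, min_size: int,
                          max_rounds: int = 10) -> pd.Series:
    """Move probes with weak eigengene membership to the 0 (grey) label."""
    labels = labels.copy()
    for _ in range(max_rounds):
        changed = False
        for c in [c for c in labels.unique() if c != 0]:
            members = labels.index[labels == c]
            if len(members) < max(2, min_size):
                continue
            me, _, _ = module_eigengene(delta, members)
            sub = delta.loc[members].to_numpy(float)
            subc = sub - sub.mean(axis=1, keepdims=True)
            norms = np.sqrt((subc ** 2).sum(axis=1))
            norms[norms == 0] = np.nan
            mec = me.to_numpy() - me.to_numpy().mean()
            kme = np.abs((subc @ mec) / (norms * np.sqrt((mec ** 2).sum())))
            weak = members[kme < kme_min]
            if len(weak):
                labels[weak] = 0
                changed = True
        if not changed:
            break
    return labels


def merge_similar_modules(assignment: pd.Series, delta: pd.DataFrame,
                          merge_threshold: float = 0.30) -> pd.Series:
    """Iteratively merge modules with near-identical eigengenes.

    While any pair of module eigengenes has dissimilarity
    1 - cor(ME_a, ME_b) below the threshold, the closest pair is merged
    (keeping the larger module's label) and eigengenes are recomputed.
    The fixed point is independent of merge order.
    """
    labels = assignment.copy()
    while True:
        modules = [m for m in labels.unique() if m != GREY]
        if len(modules) < 2:
            return labels
        mes = {m: module_eigengene(delta, labels.index[labels == m])[0]
               for m in modules}
        best = None
        for i, a in enumerate(modules):
            for b in modules[i + 1:]:
                d = 1 - float(np.corrcoef(mes[a], mes[b])[0, 1])
                if d < merge_threshold and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            return labels
        _, a, b = best
        if (labels == b).sum() > (labels == a).sum():
            a, b = b, a
        labels[labels == b] = a


class CoHydroxyNetwork:
    """Signed co-hydroxymethylation network model.

    Parameters
    ----------
    delta : DataFrame
        Delta-beta matrix, probes x samples.
    samples : DataFrame
        Sample sheet with ``dpc`` and ``sex`` columns (traits).
    config : NetworkConfig, optional
    """

    def __init__(self, delta: pd.DataFrame, samples: pd.DataFrame,
                 config: NetworkConfig | None = None):
        self.delta = delta
        self.samples = samples
        self.config = config or NetworkConfig()

    def fit(self) -> "CoHydroxyNetworkResults":
        adjacency = build_adjacency(self.delta, self.config)
        delta = self.delta.loc[adjacency.index]
        pre = detect_modules(adjacency, self.config, delta=delta)
        merged = merge_similar_modules(pre, delta,
                                       self.config.merge_threshold)
        return CoHydroxyNetworkResults(self, delta, pre, merged)


class CoHydroxyNetworkResults:
    def __init__(self, model, delta, pre_merge: pd.Series,
                 assignment: pd.Series):
        self.model = model
        self.delta = delta
        self.pre_merge = pre_merge
        self.assignment = assignment
        self.modules = [m for m in assignment.unique() if m != GREY]
        self._eigengenes = None

    @property
    def eigengenes(self) -> pd.DataFrame:
        """Module x sample eigengene matrix (unit variance per row)."""
        if self._eigengenes is None:
            rows = {m: module_eigengene(
                self.delta, self.assignment.index[self.assignment == m])[0]
                for m in self.modules}
            self._eigengenes = pd.DataFrame(rows).T
        return self._eigengenes

    def module_membership(self) -> pd.DataFrame:
        """MM = |cor(probe, module eigengene)| for every probe x module."""
        z = self.delta.to_numpy(float)
        z = z - z.mean(axis=1, keepdims=True)
        norms = np.sqrt((z ** 2).sum(axis=1))
        norms[norms == 0] = np.nan
        out = {}
        for m in self.modules:
            me = self.eigengenes.loc[m].to_numpy()
            mec = me - me.mean()
            cor = (z @ mec) / (norms * np.sqrt((mec ** 2).sum()))
            out[m] = np.abs(cor)
        return pd.DataFrame(out, index=self.delta.index)

    def probe_significance(self, trait: str = "dpc") -> pd.Series:
        """PS = |cor(probe, trait)| per probe."""
        t = self._trait_vector(trait)
        z = self.delta.to_numpy(float)
        z = z - z.mean(axis=1, keepdims=True)
        norms = np.sqrt((z ** 2).sum(axis=1))
        norms[norms == 0] = np.nan
        tc = t - t.mean()
        cor = (z @ tc) / (norms * np.sqrt((tc ** 2).sum()))
        return pd.Series(np.abs(cor), index=self.delta.index,
                         name=f"PS_{trait}")

    def _trait_vector(self, trait: str) -> np.ndarray:
        if trait == "sex":
            v = (self.model.samples["sex"] == "M").to_numpy(float)
        else:
            v = self.model.samples[trait].to_numpy(float)
        if v.std() == 0:
            raise ValueError(f"trait {trait} is constant")
        return v

    def module_trait_association(self, traits=("dpc", "sex")) -> pd.DataFrame:
        """Pearson correlation of each eigengene with each trait.

        Sex is coded 0 = female, 1 = male (point-biserial correlation).
        The Bonferroni threshold 0.05 / n_modules is stored in
        ``DataFrame.attrs['bonferroni_p']``.
        """
        rows = []
        for m in self.modules:
            me = self.eigengenes.loc[m].to_numpy()
            for trait in traits:
                t = self._trait_vector(trait)
                r, p = stats.pearsonr(me, t)
                rows.append({"module": m, "trait": trait,
                             "n_probes": int((self.assignment == m).sum()),
                             "cor": float(r), "p": float(p)})
        df = pd.DataFrame(rows)
        if self.modules:
            df.attrs["bonferroni_p"] = 0.05 / len(self.modules)
        return df

    def summary(self) -> str:
        sizes = self.assignment.value_counts()
        lines = [
            f"Co-hydroxymethylation network: signed adjacency, "
            f"power {self.model.config.soft_power}, merge threshold "
            f"{self.model.config.merge_threshold}",
            f"probes: {len(self.assignment)}   modules: {len(self.modules)}"
            f"   unassigned (grey): {int(sizes.get(GREY, 0))}",
        ]
        assoc = self.module_trait_association()
        for m in self.modules:
            sub = assoc[assoc["module"] == m]
            parts = ", ".join(f"{t['trait']}: r={t['cor']:+.2f} "
                              f"(p={t['p']:.2g})" for _, t in sub.iterrows())
            lines.append(f"  {m} ({int(sizes[m])} probes)  {parts}")
        return "\n".join(lines)
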