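"""QC filtering, normalization, delta-beta and detection-threshold calibration.

The stages run in a fixed order: probe/sample QC filtering, blacklist
removal, between-sample quantile normalization (applied to the BS and oxBS
matrices separately), delta-beta computation, threshold calibration from
the negative delta values, and the detectability filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DetectionCalibration,
    HydroxyMatrix,
    PairedBetaDataset,
    QCMetrics,
)

PIPELINE_ORDER = ("pfilter", "blacklist", "normalize", "delta",
                  "calibrate", "detectability")


@dataclass
class RemovalReport:
    """Counts of probes/samples removed by each QC rule."""

    n_probes_beadcount: int = 0
    n_probes_detection_p: int = 0
    n_samples_detection_p: int = 0
    n_probes_blacklist: int = 0
    n_probes_undetectable: int = 0
    removed_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def pfilter(dataset: PairedBetaDataset, qc: QCMetrics,
            beadcount_min: int = 3, beadcount_sample_frac: float = 0.05,
            detp_cut: float = 0.05, detp_probe_frac: float = 0.01,
            detp_sample_frac: float = 0.05,
            ) -> tuple[PairedBetaDataset, RemovalReport]:
    """Remove probes and samples failing array QC.

    Probes are dropped when the bead count is below ``beadcount_min`` in at
    least ``beadcount_sample_frac`` of samples, or when the detection
    p-value exceeds ``detp_cut`` in at least ``detp_probe_frac`` of
    samples.  Samples are dropped when more than ``detp_sample_frac`` of
    their sites have detection p above the cut.
    """
    if not qc.beadcount.index.equals(dataset.bs.index) or \
            not qc.beadcount.columns.equals(dataset.bs.columns):
        raise ValueError("QC matrices are not aligned to the dataset")
    report = RemovalReport()
    bead = qc.beadcount.to_numpy()
    detp = qc.detection_p.to_numpy()
    n_samples = dataset.n_samples

    bad_bead = (bead < beadcount_min).sum(axis=1) >= \
        beadcount_sample_frac * n_samples
    bad_detp = (detp > detp_cut).sum(axis=1) >= detp_probe_frac * n_samples
    report.n_probes_beadcount = int(bad_bead.sum())
    report.n_probes_detection_p = int((bad_detp & ~bad_bead).sum())
    keep_probes = dataset.bs.index[~(bad_bead | bad_detp)]

    frac_bad = (detp > detp_cut).mean(axis=0)
    bad_sample = frac_bad >= detp_sample_frac
    report.n_samples_detection_p = int(bad_sample.sum())
    report.removed_samples = list(dataset.bs.columns[bad_sample])
    keep_samples = dataset.bs.columns[~bad_sample]
    if keep_samples.empty:
        raise ValueError("pfilter removed every sample")
    if keep_probes.empty:
        raise ValueError("pfilter removed every probe")

    out = dataset.subset_probes(keep_probes)
    if report.removed_samples:
        out = out.subset_samples(keep_samples)
    return out, report


def remove_blacklisted(dataset: PairedBetaDataset, blacklist,
                       ) -> tuple[PairedBetaDataset, int]:
    """Drop cross-reactive/polymorphic probes listed in ``blacklist``."""
    blacklist = set(blacklist)
    unknown = blacklist - set(dataset.bs.index)
    if unknown:
        warnings.warn(f"{len(unknown)} blacklisted ids not in dataset")
    keep = dataset.bs.index[~dataset.bs.index.isin(blacklist)]
    n_removed = dataset.n_probes - len(keep)
    if keep.empty:
        raise ValueError("blacklist removes every probe")
    if n_removed == 0:
        return dataset, 0
    return dataset.subset_probes(keep), n_removed


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Between-sample quantile normalization (rank-wise column means)."""
    x = matrix.to_numpy(float)
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])[:, None]
    np.put_along_axis(ranks, order, rows, axis=0)
    mean_sorted = np.take_along_axis(x, order, axis=0).mean(axis=1)
    return pd.DataFrame(mean_sorted[ranks], index=matrix.index,
                        columns=matrix.columns)


def normalize(dataset: PairedBetaDataset, method: str = "quantile",
              ) -> PairedBetaDataset:
    """Normalize the BS and oxBS matrices separately.

    ``"quantile"`` forces every sample within an array type onto the
    rank-wise mean distribution; ``"none"`` passes the data through.  The
    two array types are never mixed, preserving the BS-vs-oxBS shift that
    carries the 5hmC signal.
    """
    if method == "none":
        return dataset
    if method not in ("quantile", "quantile-by-stratum"):
        raise ValueError(f"unknown normalization method: {method}")
    if dataset.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    return PairedBetaDataset(
        bs=quantile_normalize(dataset.bs),
        oxbs=quantile_normalize(dataset.oxbs),
        samples=dataset.samples, manifest=dataset.manifest)


def compute_delta(dataset: PairedBetaDataset) -> HydroxyMatrix:
    """Delta-beta = BS - oxBS per cell; negative values are retained."""
    return HydroxyMatrix(delta=dataset.bs - dataset.oxbs)


def calibrate_threshold(delta: pd.DataFrame | HydroxyMatrix,
                        percentile: float = 95.0) -> DetectionCalibration:
    """Calibrate the detection threshold from negative delta values.

    Negative cells arise from technical noise alone, so the chosen
    percentile of their magnitudes (pooled over all probes and samples)
    bounds the noise excursion; delta values strictly above it are called
    detectable 5hmC.  Quantiles use linear interpolation between order
    statistics (the "type 7" rule).
    """
    if isinstance(delta, HydroxyMatrix):
        delta = delta.delta
    values = delta.to_numpy(float).ravel()
    neg = -values[values < 0]
    if neg.size == 0:
        raise ValueError(
            "no negative delta values: cannot calibrate, set tau manually")
    tau = float(np.quantile(neg, percentile / 100.0, method="linear"))
    return DetectionCalibration(tau=tau, n_negative=int(neg.size),
                                percentile=percentile)


def detectability_filter(hydroxy: HydroxyMatrix,
                         min_detected: int = 1,
                         ) -> tuple[HydroxyMatrix, pd.Index]:
    """Drop probes with no sample above the detection threshold.

    Detection is strict (delta > tau); a probe at exactly tau in its best
    sample is removed.  Returns the retained matrix and the removed ids.
    """
    if hydroxy.calibration is None:
        raise ValueError("calibrate_threshold must run first")
    counts = hydroxy.detection_counts()
    keep = counts.index[counts >= min_detected]
    removed = counts.index.difference(keep)
    retained = HydroxyMatrix(delta=hydroxy.delta.loc[keep],
                             calibration=hydroxy.calibration)
    return retained, removed


def preprocess_pipeline(dataset: PairedBetaDataset,
                        qc: QCMetrics | None = None,
                        blacklist=None, norm_method: str = "quantile",
                        percentile: float = 95.0,
                        ) -> tuple[PairedBetaDataset, HydroxyMatrix,
                                   RemovalReport]:
    """Run the full fixed-order preprocessing chain."""
    report = RemovalReport()
    if qc is not None:
        dataset, report = pfilter(dataset, qc)
    if blacklist:
        dataset, n = remove_blacklisted(dataset, blacklist)
        report.n_probes_blacklist = n
    dataset = normalize(dataset, norm_method)
    hydroxy = compute_delta(dataset)
    calibration = calibrate_threshold(hydroxy.delta, percentile=percentile)
    hydroxy = HydroxyMatrix(delta=hydroxy.delta, calibration=calibration)
    hydroxy, removed = detectability_filter(hydroxy)
    report.n_probes_undetectable = len(removed)
    dataset = dataset.subset_probes(hydroxy.delta.index)
    return dataset, hydroxy, report
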