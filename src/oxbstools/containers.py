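"""Core in-memory containers shared across the pipeline.

Matrices are pandas DataFrames with probe ids on the rows and sample ids on
the columns; the sample sheet and probe manifest are plain DataFrames so
that every stage can use ordinary pandas indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("sample_id", "dpc", "sex")
MANIFEST_COLUMNS = ("probe", "chrom", "pos", "strand", "feature", "cgi", "genes")


def _check_aligned(bs: pd.DataFrame, oxbs: pd.DataFrame) -> None:
    if not bs.index.equals(oxbs.index) or not bs.columns.equals(oxbs.columns):
        raise ValueError("BS and oxBS matrices must share probe and sample axes")


@dataclass
class PairedBetaDataset:
    """Paired BS and oxBS beta matrices with sample sheet and probe manifest.

    Parameters
    ----------
    bs, oxbs : DataFrame
        Beta values in [0, 1], probes x samples, identically indexed.
    samples : DataFrame
        One row per sample with columns ``sample_id`` (matching the matrix
        columns), ``dpc`` (days post-conception) and ``sex`` ('M' or 'F').
    manifest : DataFrame
        One row per probe with columns ``probe``, ``chrom``, ``pos``
        (1-based), ``strand``, ``feature``, ``cgi`` and ``genes``
        (comma-separated symbols, empty for intergenic probes).
    """

    bs: pd.DataFrame
    oxbs: pd.DataFrame
    samples: pd.DataFrame
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        _check_aligned(self.bs, self.oxbs)
        if self.bs.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.bs.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if list(self.samples["sample_id"]) != list(self.bs.columns):
            raise ValueError("sample sheet does not match matrix columns")
        missing = self.bs.index.difference(self.manifest["probe"])
        if len(missing):
            raise ValueError(f"{len(missing)} probes absent from manifest")

    @property
    def n_probes(self) -> int:
        return self.bs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.bs.shape[1]

    def probe_manifest(self) -> pd.DataFrame:
        """Manifest rows for the probes currently in the matrices, in order."""
        m = self.manifest.set_index("probe", drop=False)
        return m.loc[self.bs.index]

    def subset_probes(self, probes) -> "PairedBetaDataset":
        probes = pd.Index(probes)
        if probes.empty:
            raise ValueError("probe subset is empty")
        return PairedBetaDataset(
            bs=self.bs.loc[probes],
            oxbs=self.oxbs.loc[probes],
            samples=self.samples,
            manifest=self.manifest[self.manifest["probe"].isin(probes)],
        )

    def subset_samples(self, sample_ids) -> "PairedBetaDataset":
        sample_ids = list(sample_ids)
        if not sample_ids:
            raise ValueError("sample subset is empty")
        sheet = self.samples[self.samples["sample_id"].isin(sample_ids)]
        order = list(sheet["sample_id"])
        return PairedBetaDataset(
            bs=self.bs[order], oxbs=self.oxbs[order],
            samples=sheet.reset_index(drop=True), manifest=self.manifest,
        )


@dataclass
class QCMetrics:
    """Per-cell array QC: bead counts and detection p-values."""

    beadcount: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beadcount.shape != self.detection_p.shape:
            raise ValueError("QC matrices must share a shape")
        dp = self.detection_p.to_numpy(float)
        if np.nanmin(dp) < 0 or np.nanmax(dp) > 1:
            raise ValueError("detection p-values outside [0, 1]")


@dataclass
class DetectionCalibration:
    """Empirically calibrated 5hmC detection threshold.

    ``tau`` is the 95th percentile of the magnitudes of negative delta-beta
    values (which arise from technical noise alone); delta-beta values
    strictly above ``tau`` are called detectable 5hmC.
    """

    tau: float
    n_negative: int
    percentile: float = 95.0
    quantile_rule: str = "linear"  # type-7: interpolate between order stats

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.n_negative <= 0:
            raise ValueError("calibration requires negative delta values")


@dataclass
class HydroxyMatrix:
    """Delta-beta (BS - oxBS) matrix with detection mask and calibration.

    Negative values are retained: downstream regressions see exactly the
    values the detection threshold was calibrated on, and only the mask
    encodes detectability.
    """

    delta: pd.DataFrame
    calibration: DetectionCalibration | None = None
    detected: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        if self.calibration is not None and self.detected is None:
            self.detected = self.delta > self.calibration.tau

    @property
    def tau(self) -> float:
        if self.calibration is None:
            raise ValueError("no calibration attached")
        return self.calibration.tau

    def detection_counts(self) -> pd.Series:
        """Number of samples with detectable 5hmC, per probe."""
        if self.detected is None:
            raise ValueError("no calibration attached")
        return self.detected.sum(axis=1)
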