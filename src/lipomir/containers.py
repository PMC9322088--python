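"""Shared in-memory containers for the quantification/analysis pipeline.

Plate-level data (Ct wells, dilution series, spike-in wells) are plain
pandas DataFrames with documented column schemas; the classes here wrap the
matrix-shaped results that flow between pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column schema of a Ct plate table (one row per well).
PLATE_COLUMNS = ["sample_id", "assay_id", "replicate", "ct", "detected"]

#: Column schema of a dilution-series table (one row per dilution point).
DILUTION_COLUMNS = ["assay_id", "copies", "ct"]

#: Column schema of a spike-in well table.
SPIKE_COLUMNS = ["control_id", "expected_copies", "sample_id", "replicate", "ct", "detected"]


@dataclass(frozen=True)
class StandardCurve:
    """Linear Ct-vs-log10(copies) calibration for one qPCR assay.

    ``slope`` is in cycles per log10 copies (negative for any working
    assay), ``intercept`` is the Ct expected at a single template copy, and
    ``efficiency`` is the fractional per-cycle amplification gain derived
    from the slope, ``10**(-1/slope) - 1`` (1.0 for perfect doubling).
    """

    assay_id: str
    slope: float
    intercept: float
    efficiency: float
    r2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope >= 0:
            raise ValueError(
                f"assay {self.assay_id!r}: standard-curve slope must be negative, "
                f"got {self.slope}"
            )
        if not (0.0 < self.efficiency <= 1.5):
            raise ValueError(
                f"assay {self.assay_id!r}: efficiency {self.efficiency:.3f} outside (0, 1.5]"
            )


@dataclass
class SpikeInSet:
    """Observed spike-in control copies per sample.

    ``expected``: Series indexed by control_id with known input copies.
    ``observed``: DataFrame samples x controls of measured absolute copies.
    """

    expected: pd.Series
    observed: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.expected <= 0).any():
            raise ValueError("expected spike-in copies must be positive")
        missing = set(self.expected.index) - set(self.observed.columns)
        if missing:
            raise ValueError(f"observed table lacks spike-in controls: {sorted(missing)}")


@dataclass
class CopyMatrix:
    """Samples x assays absolute copy numbers with a detection mask.

    ``values`` holds copies (NaN where non-detect); ``detected`` is the
    boolean mask of the same shape; ``factors`` records the per-sample
    normalization factor once spike-in normalization has been applied.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detection mask must share shape")
        det = self.detected.to_numpy(dtype=bool)
        vals = self.values.to_numpy(dtype=float)
        if np.any(det & ~(vals > 0)):
            raise ValueError("detected entries must hold positive copy numbers")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def assays(self) -> pd.Index:
        return self.values.columns

    def detection_rate(self) -> pd.Series:
        """Per-assay fraction of samples in which the assay was detected."""
        return self.detected.mean(axis=0)


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs log2 normalized expression with class labels.

    ``detected`` carries the pre-imputation detection mask so downstream
    stages can distinguish measured values from imputed ones.
    ``provenance`` accumulates the processing steps applied (filter
    threshold, normalization method, imputation rule).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    labels: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detection mask must share shape")
        if not self.values.index.equals(pd.Index(self.labels.index)):
            raise ValueError("labels must be indexed by the matrix samples")
        if np.isinf(self.values.to_numpy()).any():
            raise ValueError("expression matrix contains infinities")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def mirnas(self) -> pd.Index:
        return self.values.columns


@dataclass
class ExplorationSummary:
    """PCA scores and sample dendrogram for exploratory QC.

    ``variance_fractions`` are the per-component shares of total variance,
    non-increasing; ``linkage`` is a scipy-format merge matrix over samples.
    """

    scores: pd.DataFrame
    variance_fractions: np.ndarray
    linkage: np.ndarray
    distance_metric: str
    linkage_method: str

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fractions, dtype=float)
        if (vf < -1e-12).any() or np.any(np.diff(vf) > 1e-9):
            raise ValueError("variance fractions must be non-negative and non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions must sum to at most 1")


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Validate a Ct plate table against the well schema.

    Raises ValueError naming the offending rows for duplicate well keys or
    non-positive detected Ct values.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"Ct plate missing required columns: {missing}")
    key = ["sample_id", "assay_id", "replicate"]
    dup = plate.duplicated(subset=key)
    if dup.any():
        rows = (plate.index[dup] + 1).tolist()[:5]
        raise ValueError(f"duplicate (sample, assay, replicate) keys at rows {rows}")
    det = plate["detected"].astype(bool)
    bad = det & ~(plate["ct"] > 0)
    if bad.any():
        rows = (plate.index[bad] + 1).tolist()[:5]
        raise ValueError(f"detected wells with non-positive or missing Ct at rows {rows}")
    return plate
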