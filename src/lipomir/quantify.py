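"""Absolute quantification of qPCR Ct values via standard curves.

Converts raw per-well threshold-cycle measurements into spike-in-normalized
absolute copy numbers.  Each assay is calibrated against a serial dilution
of synthetic template (6 logs by default); interpolation on the fitted
Ct-vs-log10(copies) line adjusts for the assay's amplification efficiency,
which is encoded entirely by the slope.  Technical replicates are averaged
in Ct space before interpolation; a well is non-detect only when every
replicate failed.  Per-sample technical variation (RNA isolation, RT,
qPCR) is removed by dividing by the geometric mean of the observed/expected
ratios of the spike-in controls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from lipomir.containers import CopyMatrix, SpikeInSet, StandardCurve, validate_plate


def fit_standard_curve(series: pd.DataFrame) -> StandardCurve:
    """Least-squares fit of Ct on log10(copies) for one assay's dilutions.

    ``series`` has columns ``assay_id, copies, ct`` for a single assay.
    Raises ValueError for fewer than two distinct dilution points or a
    non-negative fitted slope (an unusable assay).
    """
    assay_ids = series["assay_id"].unique()
    if len(assay_ids) != 1:
        raise ValueError("fit_standard_curve expects a single assay's series")
    assay_id = str(assay_ids[0])
    pts = series.dropna(subset=["ct"])
    if (pts["copies"] <= 0).any():
        raise ValueError(f"assay {assay_id!r}: template copies must be positive")
    x = np.log10(pts["copies"].to_numpy(dtype=float))
    y = pts["ct"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError(f"assay {assay_id!r}: need >= 2 distinct dilution points")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError(f"assay {assay_id!r}: non-negative slope {fit.slope:.3f}")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        assay_id=assay_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r2=float(fit.rvalue**2),
    )


def fit_standard_curves(dilutions: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per assay present in a dilution table."""
    return {
        str(aid): fit_standard_curve(group)
        for aid, group in dilutions.groupby("assay_id", sort=True)
    }


def collapse_replicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates in Ct space.

    Returns one row per (sample_id, assay_id) with the arithmetic mean of
    the *detected* replicate Ct values; the well is non-detect only when
    all replicates are non-detect.  Partially detected wells keep the
    detected mean so that missingness reflects true assay dropout rather
    than replicate-level noise.
    """
    if plate.empty:
        raise ValueError("empty Ct plate")
    validate_plate(plate)
    grp = plate.groupby(["sample_id", "assay_id"], sort=True)
    out = grp.agg(ct=("ct", "mean"), detected=("detected", "any")).reset_index()
    return out


def ct_to_copies(ct: float | np.ndarray, curve: StandardCurve) -> float | np.ndarray:
    """Interpolate Ct on the standard curve: copies = 10**((ct - b) / m).

    Strictly decreasing in Ct for any valid (negative-slope) curve; Ct at
    the intercept maps to a single copy.
    """
    return 10.0 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)


def quantify_plate(
    plate: pd.DataFrame, curves: dict[str, StandardCurve]
) -> CopyMatrix:
    """Collapse replicates and interpolate every well to absolute copies."""
    wells = collapse_replicates(plate)
    missing = sorted(set(wells["assay_id"]) - set(curves))
    if missing:
        raise ValueError(f"no standard curve for assays: {missing[:5]}")
    copies = np.full(len(wells), np.nan)
    for aid, idx in wells.groupby("assay_id").groups.items():
        sub = wells.loc[idx]
        det = sub["detected"].to_numpy(dtype=bool)
        vals = np.full(len(sub), np.nan)
        vals[det] = ct_to_copies(sub.loc[det, "ct"].to_numpy(), curves[str(aid)])
        copies[wells.index.get_indexer(idx)] = vals
    wells = wells.assign(copies=copies)
    values = wells.pivot(index="sample_id", columns="assay_id", values="copies")
    detected = wells.pivot(index="sample_id", columns="assay_id", values="detected")
    return CopyMatrix(values=values, detected=detected.astype(bool))


def quantify_spike_ins(
    spikes: pd.DataFrame, curves: dict[str, StandardCurve]
) -> SpikeInSet:
    """Convert spike-in control wells to observed absolute copies.

    Spike-in controls are calibrated like any other assay; replicates are
    averaged in Ct space.  Every profiled sample must have a detected
    measurement for every control.
    """
    expected = (
        spikes.drop_duplicates("control_id").set_index("control_id")["expected_copies"]
    )
    wells = spikes.rename(columns={"control_id": "assay_id"})[
        ["sample_id", "assay_id", "replicate", "ct", "detected"]
    ]
    cm = quantify_plate(wells, curves)
    if not cm.detected.to_numpy().all():
        bad = cm.detected.stack()
        bad = bad[~bad].index.tolist()[:5]
        raise ValueError(f"missing spike-in observations for {bad}")
    return SpikeInSet(expected=expected.astype(float), observed=cm.values)


def spike_in_normalize(copies: CopyMatrix, spikes: SpikeInSet) -> CopyMatrix:
    """Remove per-sample technical scaling using the spike-in controls.

    The per-sample factor is the geometric mean over controls of
    observed/expected copies; every copy number in the sample is divided by
    it.  The factor is recorded on the returned matrix.
    """
    obs = spikes.observed.reindex(index=copies.samples)
    if obs.isna().any().any():
        missing = obs.index[obs.isna().any(axis=1)].tolist()[:5]
        raise ValueError(f"samples lacking spike-in observations: {missing}")
    if (obs <= 0).any().any():
        raise ValueError("non-positive spike-in observation")
    ratios = obs / spikes.expected.reindex(obs.columns)
    factors = np.exp(np.log(ratios).mean(axis=1)).rename("factor")
    values = copies.values.div(factors, axis=0)
    return CopyMatrix(values=values, detected=copies.detected.copy(), factors=factors)
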