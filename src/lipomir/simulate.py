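"""Synthetic qPCR study generator with planted ground truth.

Emulates the FFPE profiling design this pipeline targets: five tumor
classes (benign lipoma and four sarcoma subtypes, 34/24/20/16/18 samples by
default), 350 stem-loop RT-qPCR miRNA assays measured with technical
replicates, a 6-log synthetic-template dilution series per assay, three
spike-in control RNAs that carry only per-sample technical variation, and a
hard limit-of-detection Ct above which wells are non-detects.

Biological variation is lognormal (normal on the log2-copies scale), the
scale on which the downstream analysis operates.  Planted differential
markers are offset by +/- a configured log2 fold change in every
non-baseline class relative to the first class listed in ``class_sizes``,
split evenly between up- and down-regulation.  Pathway resources (a
miRNA-to-gene target map and a GMT-style pathway collection) are generated
with a configurable number of planted pathways whose gene sets are built
from the planted markers' target genes, so set-enrichment recovery can be
tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from lipomir.containers import (
    DILUTION_COLUMNS,
    PLATE_COLUMNS,
    SPIKE_COLUMNS,
)

#: Class sizes of the study design being emulated (benign lipoma baseline,
#: then the four malignant classes).
DEFAULT_CLASS_SIZES = {"lipoma": 34, "WDLPS": 24, "DDLPS": 20, "MFS": 16, "UPS": 18}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic profiling study.

    Noise magnitudes default to plausible values for an FFPE qPCR workflow
    (the emulated platform publishes none): 0.25 Ct between technical
    replicates, 1.0 log2 units of biological spread per miRNA, 0.5 log2
    units of per-sample technical scaling, and a limit of detection at
    Ct 35.
    """

    class_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    n_assays: int = 350
    n_planted_markers: int = 6
    planted_log2fc: float = 2.0
    biological_sd: float = 1.0
    replicate_sd: float = 0.25
    technical_factor_sd: float = 0.5
    lod_ct: float = 35.0
    n_replicates: int = 2
    n_spikeins: int = 3
    curve_slope_range: tuple[float, float] = (-3.6, -3.2)
    curve_intercept_range: tuple[float, float] = (36.0, 40.0)
    base_log2_range: tuple[float, float] = (6.0, 15.0)
    dilution_points: int = 6
    dilution_top_copies: float = 1e6
    # pathway-resource parameters
    n_genes: int = 4000
    targets_per_mirna: tuple[int, int] = (20, 50)
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (30, 100)
    n_planted_pathways: int = 3
    planted_overlap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_assays,
            self.n_replicates,
            self.n_spikeins,
            self.dilution_points,
            self.n_genes,
            self.n_pathways,
            *self.class_sizes.values(),
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not self.class_sizes:
            raise ValueError("at least one class is required")
        if self.n_planted_markers < 0 or self.n_planted_markers > self.n_assays:
            raise ValueError("n_planted_markers must lie in [0, n_assays]")
        if self.n_planted_pathways < 0 or self.n_planted_pathways > self.n_pathways:
            raise ValueError("n_planted_pathways must lie in [0, n_pathways]")
        sds = (self.biological_sd, self.replicate_sd, self.technical_factor_sd)
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        if self.curve_slope_range[0] >= 0 or self.curve_slope_range[1] >= 0:
            raise ValueError("curve slopes must be negative")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ValueError("pathway_size_range incompatible with gene universe")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth of one synthetic study, for recovery-based testing."""

    marker_ids: list[str]
    #: +1 if the marker is up-regulated in the non-baseline classes, -1 if down.
    marker_directions: dict[str, int]
    #: per-sample log2 technical scaling factor
    technical_factors: pd.Series
    #: assays x classes true mean log2 copies
    class_means: pd.DataFrame
    #: per-assay true standard-curve parameters, assay_id -> (slope, intercept)
    curve_params: dict[str, tuple[float, float]]
    planted_pathway_ids: list[str] = field(default_factory=list)
    #: +1 for pathways built from up-regulated markers, -1 for down
    planted_pathway_directions: dict[str, int] = field(default_factory=dict)


def _assay_ids(n: int) -> list[str]:
    return [f"mir-{i + 1:04d}" for i in range(n)]


def _sample_ids(class_sizes: dict[str, int]) -> tuple[list[str], pd.Series]:
    ids, labels = [], []
    for cls, n in class_sizes.items():
        for i in range(n):
            ids.append(f"{cls}-{i + 1:03d}")
            labels.append(cls)
    return ids, pd.Series(labels, index=ids, name="label")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series, GroundTruth]:
    """Generate one synthetic study.

    Returns ``(plate, dilutions, spikes, labels, truth)`` where ``plate``,
    ``dilutions`` and ``spikes`` are DataFrames in the documented well
    schemas, ``labels`` maps sample_id to class, and ``truth`` records the
    planted parameters.

    The generative model per (sample s, assay a): true log2 copies are
    drawn N(mu_{class(s),a}, biological_sd), multiplied by the sample's
    technical factor 2**t_s, converted to Ct through the assay's standard
    curve, and measured ``n_replicates`` times with N(0, replicate_sd) Ct
    noise; wells with Ct above ``lod_ct`` become non-detects.  Spike-in
    wells carry the same t_s but no biological variation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    assays = _assay_ids(config.n_assays)
    samples, labels = _sample_ids(config.class_sizes)
    classes = list(config.class_sizes)
    baseline = classes[0]

    # planted markers: evenly split between up/down in the non-baseline classes
    marker_ids = list(rng.choice(assays, size=config.n_planted_markers, replace=False))
    directions = {
        m: (1 if i < (config.n_planted_markers + 1) // 2 else -1)
        for i, m in enumerate(marker_ids)
    }

    base = rng.uniform(*config.base_log2_range, size=config.n_assays)
    class_means = pd.DataFrame(
        np.tile(base[:, None], (1, len(classes))), index=assays, columns=classes
    )
    for m in marker_ids:
        for cls in classes:
            if cls != baseline:
                class_means.loc[m, cls] += directions[m] * config.planted_log2fc

    tech = pd.Series(
        rng.normal(0.0, config.technical_factor_sd, size=len(samples)),
        index=samples,
        name="log2_factor",
    )

    # per-assay standard curves; spike-in controls are calibrated assays too
    control_ids = [f"spikein-{i + 1:02d}" for i in range(config.n_spikeins)]
    all_curve_ids = assays + control_ids
    slopes = rng.uniform(*config.curve_slope_range, size=len(all_curve_ids))
    intercepts = rng.uniform(*config.curve_intercept_range, size=len(all_curve_ids))
    curve_params = {
        aid: (float(s), float(b)) for aid, s, b in zip(all_curve_ids, slopes, intercepts)
    }

    # sample wells
    mu = class_means[labels.to_numpy()].to_numpy().T  # samples x assays
    true_log2 = mu + rng.normal(0.0, config.biological_sd, size=mu.shape)
    scaled_log2 = true_log2 + tech.to_numpy()[:, None]
    if not np.all(np.isfinite(scaled_log2)):
        raise ValueError("non-finite simulated copy numbers")
    slope_v = slopes[: config.n_assays]
    inter_v = intercepts[: config.n_assays]
    # Ct from log10 copies: ct = intercept + slope * log10(copies)
    ct_mean = inter_v[None, :] + slope_v[None, :] * (scaled_log2 * np.log10(2.0))

    rows = []
    for r in range(1, config.n_replicates + 1):
        noise = rng.normal(0.0, config.replicate_sd, size=ct_mean.shape)
        ct = ct_mean + noise
        detected = ct <= config.lod_ct
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(samples, config.n_assays),
                    "assay_id": np.tile(assays, len(samples)),
                    "replicate": r,
                    "ct": np.where(detected, ct, np.nan).ravel(),
                    "detected": detected.ravel(),
                }
            )
        )
    plate = pd.concat(rows, ignore_index=True)[PLATE_COLUMNS]
    plate = plate.sort_values(["sample_id", "assay_id", "replicate"], ignore_index=True)

    # dilution series: 6-log span, one well per point, for assays and controls
    n_pts = config.dilution_points
    copies_series = config.dilution_top_copies / np.power(10.0, np.arange(n_pts))
    drows = []
    for aid in all_curve_ids:
        s, b = curve_params[aid]
        ct = b + s * np.log10(copies_series)
        ct = ct + rng.normal(0.0, config.replicate_sd, size=n_pts)
        drows.append(pd.DataFrame({"assay_id": aid, "copies": copies_series, "ct": ct}))
    dilutions = pd.concat(drows, ignore_index=True)[DILUTION_COLUMNS]

    # spike-in wells: expected copies per control, scaled only by the
    # technical factor (no biological variation)
    expected = {cid: 10.0 ** (3 + i % 3) for i, cid in enumerate(control_ids)}
    srows = []
    for cid in control_ids:
        s, b = curve_params[cid]
        obs_log10 = np.log10(expected[cid]) + tech.to_numpy() * np.log10(2.0)
        ct_mean_c = b + s * obs_log10
        for r in range(1, config.n_replicates + 1):
            ct = ct_mean_c + rng.normal(0.0, config.replicate_sd, size=len(samples))
            detected = ct <= config.lod_ct
            srows.append(
                pd.DataFrame(
                    {
                        "control_id": cid,
                        "expected_copies": expected[cid],
                        "sample_id": samples,
                        "replicate": r,
                        "ct": np.where(detected, ct, np.nan),
                        "detected": detected,
                    }
                )
            )
    spikes = pd.concat(srows, ignore_index=True)[SPIKE_COLUMNS]
    spikes = spikes.sort_values(["control_id", "sample_id", "replicate"], ignore_index=True)

    truth = GroundTruth(
        marker_ids=marker_ids,
        marker_directions=directions,
        technical_factors=tech,
        class_means=class_means,
        curve_params=curve_params,
    )
    return plate, dilutions, spikes, labels, truth


def simulate_pathway_resources(
    config: SimulationConfig,
) -> tuple[dict[str, set[str]], dict[str, set[str]], GroundTruth]:
    """Generate a miRNA-to-gene target map and pathway database with truth.

    A regulated pathway concentrates its strong targeting miRNAs at one
    extreme of the fold-change ranking, so each planted pathway is built
    from the planted markers of a single regulation direction (alternating
    up/down across planted pathways): every same-direction marker
    contributes ``planted_overlap`` of its target genes to the pathway's
    gene set, giving those miRNAs strong (low hypergeometric p) targeting of
    the pathway; the remainder of the gene set is random filler up to a size
    drawn from ``pathway_size_range``.  Non-planted pathways are uniform
    random gene sets and are enriched for planted markers only by chance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    assays = _assay_ids(config.n_assays)
    genes = np.array([f"g{i + 1:05d}" for i in range(config.n_genes)])

    lo_t, hi_t = config.targets_per_mirna
    target_map: dict[str, set[str]] = {}
    for aid in assays:
        size = int(rng.integers(lo_t, hi_t + 1))
        target_map[aid] = set(rng.choice(genes, size=size, replace=False))

    # planted markers match simulate_dataset's choice for the same seed
    marker_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    marker_ids = list(marker_rng.choice(assays, size=config.n_planted_markers, replace=False))
    directions = {
        m: (1 if i < (config.n_planted_markers + 1) // 2 else -1)
        for i, m in enumerate(marker_ids)
    }

    lo_p, hi_p = config.pathway_size_range
    pathways: dict[str, set[str]] = {}
    planted_names = []
    planted_directions: dict[str, int] = {}
    for j in range(config.n_pathways):
        name = f"pathway_{j + 1:03d}"
        size = int(rng.integers(lo_p, hi_p + 1))
        if j < config.n_planted_pathways and marker_ids:
            direction = 1 if j % 2 == 0 else -1
            contributors = [m for m in marker_ids if directions[m] == direction]
            if not contributors:
                contributors = marker_ids
            gene_set: set[str] = set()
            for m in contributors:
                k = min(config.planted_overlap, len(target_map[m]))
                gene_set |= set(rng.choice(sorted(target_map[m]), size=k, replace=False))
            n_fill = max(size - len(gene_set), 0)
            filler = rng.choice(genes, size=n_fill, replace=False)
            gene_set |= set(filler)
            planted_names.append(name)
            planted_directions[name] = direction
        else:
            gene_set = set(rng.choice(genes, size=size, replace=False))
        pathways[name] = gene_set

    truth = GroundTruth(
        marker_ids=marker_ids,
        marker_directions=directions,
        technical_factors=pd.Series(dtype=float),
        class_means=pd.DataFrame(),
        curve_params={},
        planted_pathway_ids=planted_names,
        planted_pathway_directions=planted_directions,
    )
    return target_map, pathways, truth
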