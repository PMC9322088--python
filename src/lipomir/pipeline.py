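"""End-to-end pipeline driver: quantify -> preprocess -> panels -> enrichment.

``PipelineConfig`` gathers every stage parameter plus the input paths and a
single global seed; ``run_pipeline`` executes the configured comparisons
and writes all result tables together with a manifest (seed, parameters,
package versions, input checksums) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lipomir import enrich, io, panel, preprocess, quantify


@dataclass
class PipelineConfig:
    """Paths and parameters for one full analysis run."""

    plate_path: str = ""
    dilution_path: str = ""
    spike_path: str = ""
    labels_path: str = ""
    target_pairs_path: str = ""
    gmt_path: str = ""
    out_dir: str = "results"
    #: list of (positive_class, negative_classes) binary comparisons;
    #: samples of several negative classes are pooled (e.g. DDLPS vs MFS+UPS)
    comparisons: list[tuple[str, list[str]]] = field(default_factory=list)
    min_rate: float = 0.90
    folds: int = 4
    repeats: int = 100
    k_max: int = 12
    delta: float = 0.01
    n_perm: int = 5000
    p_max: float = 0.01
    q_max: float = 0.05
    lod_ct: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_rate <= 1):
            raise ValueError("min_rate must lie in (0, 1]")
        if self.folds < 2 or self.repeats < 1 or self.k_max < 1 or self.n_perm < 1:
            raise ValueError("folds/repeats/k_max/n_perm out of range")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["comparisons"] = [(p, list(n)) for p, n in raw.get("comparisons", [])]
        return cls(**raw)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_seeds(seed: int, n: int) -> list[int]:
    # one deterministic sub-seed per stage, all below 2**31
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis; returns the manifest dict.

    Stages: standard-curve quantification with spike-in normalization;
    detection filter + global-mean normalization + imputation; per
    comparison, cross-validated panel selection with the AUC-increment
    stopping rule; miRNA-set enrichment on the first comparison's contrast
    if pathway resources are configured.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        "plate": config.plate_path,
        "dilutions": config.dilution_path,
        "spikes": config.spike_path,
        "labels": config.labels_path,
    }
    for name, p in inputs.items():
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"missing required input {name!r}: {p!r}")

    plate = io.read_ct_plate(config.plate_path)
    dilutions = io.read_dilution_series(config.dilution_path)
    spikes = io.read_spike_ins(config.spike_path)
    labels = io.read_labels(config.labels_path)

    curves = quantify.fit_standard_curves(dilutions)
    copies = quantify.quantify_plate(plate, curves)
    spike_set = quantify.quantify_spike_ins(spikes, curves)
    normed = quantify.spike_in_normalize(copies, spike_set)
    io.write_copy_matrix(normed, out / "copy_matrix.tsv", out / "sample_factors.tsv")

    expr = preprocess.preprocess(normed, labels, min_rate=config.min_rate)
    io.write_expression_matrix(expr, out / "expression_matrix.tsv")

    seeds = _stage_seeds(config.seed, 2 + len(config.comparisons))
    panel_summaries = {}
    for i, (pos, negs) in enumerate(config.comparisons):
        mask = expr.labels.isin([pos, *negs])
        sub_labels = expr.labels[mask].where(expr.labels[mask] == pos, other="|".join(negs))
        sub = pd.DataFrame(expr.values.loc[mask])
        curve = panel.cv_panel_evaluation(
            sub,
            sub_labels,
            positive_class=pos,
            folds=config.folds,
            repeats=config.repeats,
            k_max=config.k_max,
            seed=seeds[2 + i],
        )
        k = panel.select_optimal_k(curve, delta=config.delta)
        result = panel.finalize_panel(
            sub,
            sub_labels,
            k,
            positive_class=pos,
            curve=curve,
            parameters={
                "folds": config.folds,
                "repeats": config.repeats,
                "k_max": config.k_max,
                "delta": config.delta,
                "seed": seeds[2 + i],
            },
        )
        tag = f"{pos}_vs_{'_'.join(negs)}"
        curve.table.to_csv(out / f"panel_curve_{tag}.tsv", sep="\t")
        curve.mean_roc.to_csv(out / f"roc_points_{tag}.tsv", sep="\t")
        io.write_json(
            {
                "optimal_k": result.optimal_k,
                "markers": result.markers,
                "directions": result.directions,
                "mean_auc": float(curve.table.loc[k, "mean_auc"]),
                "ci": [
                    float(curve.table.loc[k, "ci_lower"]),
                    float(curve.table.loc[k, "ci_upper"]),
                ],
                "positive_class": pos,
                "parameters": result.parameters,
            },
            out / f"panel_{tag}.json",
        )
        panel_summaries[tag] = {
            "optimal_k": result.optimal_k,
            "markers": result.markers,
            "mean_auc": float(curve.table.loc[k, "mean_auc"]),
        }

    enrichment_summary = None
    if config.target_pairs_path and config.gmt_path and config.comparisons:
        target_map = io.read_target_pairs(config.target_pairs_path)
        pathways = io.read_gmt(config.gmt_path)
        pos, negs = config.comparisons[0]
        mask = expr.labels.isin([pos, *negs])
        sub_labels = expr.labels[mask].where(expr.labels[mask] == pos, other="|".join(negs))
        results = enrich.enrichment_analysis(
            pd.DataFrame(expr.values.loc[mask]),
            sub_labels,
            positive_class=pos,
            target_map=target_map,
            pathways=pathways,
            n_perm=config.n_perm,
            seed=seeds[1],
        )
        results.rename_axis("pathway").to_csv(out / "enrichment.tsv", sep="\t")
        sig = enrich.significant_pathways(results, p_max=config.p_max, q_max=config.q_max)
        sig.rename_axis("pathway").to_csv(out / "enrichment_significant.tsv", sep="\t")
        enrichment_summary = {
            "n_pathways_tested": int(len(results)),
            "n_significant": int(len(sig)),
        }

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": asdict(config),
        "inputs": {k: {"path": v, "sha256": _checksum(v)} for k, v in inputs.items() if v},
        "versions": _versions(),
        "panels": panel_summaries,
        "enrichment": enrichment_summary,
        "n_mirnas_retained": int(expr.values.shape[1]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _versions() -> dict:
    import sklearn
    import scipy

    import lipomir

    return {
        "lipomir": lipomir.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
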