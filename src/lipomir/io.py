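"""Readers and writers for the pipeline's plain-text formats.

Formats are deliberately diff-able: CSV for plate-level tables (Ct wells,
dilution series, spike-in wells, labels), TSV for matrices and result
tables, GMT (tab-separated name, description, genes...) for pathway
collections, two-column TSV for miRNA-target pairs, and JSON for ground
truth and run manifests.  Readers validate against the documented schemas
and report offending rows by line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from lipomir.containers import (
    CopyMatrix,
    DILUTION_COLUMNS,
    ExpressionMatrix,
    PLATE_COLUMNS,
    SPIKE_COLUMNS,
    validate_plate,
)
from lipomir.simulate import GroundTruth


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path | str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------- plate CSVs

def read_ct_plate(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, path)
    df["detected"] = df["detected"].astype(bool)
    try:
        return validate_plate(df)
    except ValueError as err:  # add file context; row numbers are 1-based data rows
        raise ValueError(f"{path}: {err}") from None


def write_ct_plate(plate: pd.DataFrame, path: str | Path) -> None:
    plate[PLATE_COLUMNS].to_csv(path, index=False)


def read_dilution_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, DILUTION_COLUMNS, path)
    if (df["copies"] <= 0).any():
        rows = (df.index[df["copies"] <= 0] + 1).tolist()[:5]
        raise ValueError(f"{path}: non-positive template copies at rows {rows}")
    return df


def write_dilution_series(dilutions: pd.DataFrame, path: str | Path) -> None:
    dilutions[DILUTION_COLUMNS].to_csv(path, index=False)


def read_spike_ins(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SPIKE_COLUMNS, path)
    df["detected"] = df["detected"].astype(bool)
    return df


def write_spike_ins(spikes: pd.DataFrame, path: str | Path) -> None:
    spikes[SPIKE_COLUMNS].to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "label"], path)
    dup = df.duplicated("sample_id")
    if dup.any():
        rows = (df.index[dup] + 1).tolist()[:5]
        raise ValueError(f"{path}: duplicate sample_id at rows {rows}")
    return df.set_index("sample_id")["label"].rename_axis(None)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").rename_axis("sample_id").reset_index().to_csv(path, index=False)


# ------------------------------------------------------------- matrix TSVs

def write_copy_matrix(cm: CopyMatrix, path: str | Path, factors_path: str | Path | None = None) -> None:
    """Samples x assays copies TSV; non-detects are empty cells."""
    cm.values.rename_axis("sample_id").to_csv(path, sep="\t")
    if factors_path is not None and cm.factors is not None:
        cm.factors.rename("factor").rename_axis("sample_id").reset_index().to_csv(
            factors_path, sep="\t", index=False
        )


def read_copy_matrix(path: str | Path) -> CopyMatrix:
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    values = values.rename_axis("sample_id", axis=0).rename_axis("assay_id", axis=1)
    detected = values.notna()
    return CopyMatrix(values=values, detected=detected)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.rename_axis("sample_id").to_csv(path, sep="\t")


def read_expression_matrix(path: str | Path, labels: pd.Series) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(
        values=values,
        detected=values.notna(),
        labels=labels.reindex(values.index),
    )


# ------------------------------------------------------ pathway resources

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: tab-separated name, description, gene symbols."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i}: GMT rows need name, description, >= 1 gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}: line {i}: empty gene set for {name!r}")
            if name in pathways:
                raise ValueError(f"{path}: line {i}: duplicate pathway name {name!r}")
            pathways[name] = set(genes)
    return pathways


def write_gmt(pathways: dict[str, set[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_target_pairs(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["mirna_id", "gene_symbol"], path)
    out: dict[str, set[str]] = {}
    for m, g in zip(df["mirna_id"], df["gene_symbol"]):
        out.setdefault(str(m), set()).add(str(g))
    return out


def write_target_pairs(target_map: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"mirna_id": m, "gene_symbol": g}
        for m in sorted(target_map)
        for g in sorted(target_map[m])
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene_symbol"]).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ ground truth

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "marker_ids": truth.marker_ids,
        "marker_directions": truth.marker_directions,
        "technical_factors": truth.technical_factors.to_dict(),
        "class_means": truth.class_means.to_dict(),
        "curve_params": {k: list(v) for k, v in truth.curve_params.items()},
        "planted_pathway_ids": truth.planted_pathway_ids,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        marker_ids=payload["marker_ids"],
        marker_directions={k: int(v) for k, v in payload["marker_directions"].items()},
        technical_factors=pd.Series(payload["technical_factors"], dtype=float),
        class_means=pd.DataFrame(payload["class_means"]),
        curve_params={k: (float(a), float(b)) for k, (a, b) in payload["curve_params"].items()},
        planted_pathway_ids=payload.get("planted_pathway_ids", []),
    )


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_default))
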