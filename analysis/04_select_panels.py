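"""Cross-validated marker-panel selection for the three tumor comparisons.

For each binary contrast (WDLPS vs lipoma, DDLPS vs WDLPS, DDLPS vs
MFS/UPS) the script runs 100 repeats of stratified 4-fold CV, evaluating
RBF-SVM panels of the top 1-12 logistic-ranked miRNAs, applies the
AUC-increment < 0.01 stopping rule, and finalizes the panel on all samples
pooled.  The synthetic truth plants its differential markers between
lipoma and every malignant class, so only the first contrast carries
signal; recovery against the planted markers is reported for it, and the
other two behave as matched-malignant null comparisons.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from lipomir import io, panel

COMPARISONS = [
    ("WDLPS", ["lipoma"]),
    ("DDLPS", ["WDLPS"]),
    ("DDLPS", ["MFS", "UPS"]),
]


def main(seed: int = 0) -> None:
    data_dir = ROOT / "scratch" / "study"
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    labels = io.read_labels(data_dir / "labels.csv")
    expr = io.read_expression_matrix(data_dir / "expression_matrix.tsv", labels)
    truth = io.read_ground_truth(data_dir / "ground_truth.json")

    for pos, negs in COMPARISONS:
        mask = labels.isin([pos, *negs])
        sub_labels = labels[mask].where(labels[mask] == pos, other="/".join(negs))
        X = expr.values.loc[mask]
        curve = panel.cv_panel_evaluation(
            X, sub_labels, positive_class=pos, folds=4, repeats=100, k_max=12, seed=seed
        )
        k = panel.select_optimal_k(curve, delta=0.01)
        result = panel.finalize_panel(X, sub_labels, k, positive_class=pos, curve=curve)
        tag = f"{pos}_vs_{'_'.join(negs)}"
        curve.table.round(4).to_csv(results / f"panel_curve_{tag}.tsv", sep="\t")
        curve.mean_roc.round(4).to_csv(results / f"roc_{tag}.tsv", sep="\t")
        io.write_json(
            {
                "optimal_k": result.optimal_k,
                "markers": result.markers,
                "directions": result.directions,
                "mean_auc": float(curve.table.loc[k, "mean_auc"]),
                "ci": [float(curve.table.loc[k, "ci_lower"]), float(curve.table.loc[k, "ci_upper"])],
                "seed": seed,
            },
            results / f"panel_{tag}.json",
        )
        auc, lo, hi = curve.table.loc[k, ["mean_auc", "ci_lower", "ci_upper"]]
        print(f"{pos} vs {'/'.join(negs)}: optimal k = {k}, "
              f"AUC = {auc:.3f} (95% CI {lo:.3f}-{hi:.3f})")
        print(f"  panel: {result.markers} ({result.directions})")
        if negs == ["lipoma"]:
            hit = set(result.markers) & set(truth.marker_ids)
            print(f"  planted-marker recovery: {len(hit)}/{min(k, len(truth.marker_ids))} "
                  f"of the top-{k} panel are planted markers")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--seed", type=int, default=0)
    main(seed=ap.parse_args().seed)
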