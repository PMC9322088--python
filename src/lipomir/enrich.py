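"""miRNA-set pathway enrichment with a weighted KS running statistic.

The procedure links differential miRNA expression to pathways through the
genes the miRNAs target:

1.  For every (miRNA, pathway) pair, the overlap of the miRNA's target-gene
    set with the pathway's genes is scored by an upper-tail hypergeometric
    p-value over the measured gene universe; a miRNA "targets" a pathway
    when the overlap is at least one gene, and the targeting weight is
    -log10(p).
2.  Pathways targeted by fewer than 10 or more than 200 miRNAs, or whose
    targeting miRNAs are less than 50% measured, are dropped.
3.  miRNAs are ranked by log2 fold change between the two sample classes;
    walking down the ranked list, a pathway's running sum rises by a
    normalized hit weight (|log2fc| x targeting weight) at each targeting
    miRNA and falls by 1/(N - n_hits) otherwise.  The signed extremum of
    the running sum is the enrichment score (ES); hits at or before the
    extremum (after it, for negative ES) form the leading edge.
4.  Significance comes from permuting sample labels (5000 rounds by
    default), two-sided on |ES| with add-one smoothing; the FDR q-value
    compares each pathway's |ES| against the null scores pooled over all
    pathways, normalized by the observed tail fraction and monotonized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lipomir.containers import ExpressionMatrix


@dataclass
class TargetingProfile:
    """Per-(miRNA, pathway) targeting strengths over a gene universe.

    ``weights``: DataFrame pathways x miRNAs of -log10 hypergeometric p
    (0 where the miRNA does not target the pathway).
    ``hits``: boolean DataFrame, overlap >= 1.
    ``pvalues``: DataFrame of the hypergeometric p-values themselves.
    ``summary``: per-pathway targeting-miRNA count (over the full target
    map) and measured fraction.
    """

    weights: pd.DataFrame
    hits: pd.DataFrame
    pvalues: pd.DataFrame
    summary: pd.DataFrame
    universe_size: int


def hypergeometric_p(overlap: int, universe: int, pathway_size: int, targets: int) -> float:
    """P(X >= overlap) when drawing ``targets`` genes from a universe
    containing ``pathway_size`` pathway genes."""
    return float(stats.hypergeom.sf(overlap - 1, universe, pathway_size, targets))


def pathway_targeting(
    target_map: dict[str, set[str]],
    pathways: dict[str, set[str]],
    measured_mirnas: list[str] | pd.Index,
) -> TargetingProfile:
    """Score how strongly each miRNA targets each pathway.

    The gene universe is the union of all target sets in ``target_map``;
    pathway gene sets are intersected with it.  Pathways with no gene in
    the universe are excluded.  Targeting counts in ``summary`` cover all
    miRNAs in the map; the measured fraction is the share of those that
    appear in ``measured_mirnas``.
    """
    if not target_map or not pathways:
        raise ValueError("empty target map or pathway database")
    universe = set().union(*target_map.values())
    M = len(universe)
    mirnas = sorted(target_map)
    measured = set(map(str, measured_mirnas))

    names, weights, hits, pvals, counts, fracs = [], [], [], [], [], []
    for name in sorted(pathways):
        genes = pathways[name] & universe
        if not genes:
            continue
        K = len(genes)
        w_row, h_row, p_row = [], [], []
        for m in mirnas:
            tset = target_map[m]
            ov = len(tset & genes)
            if ov >= 1:
                p = hypergeometric_p(ov, M, K, len(tset))
                h_row.append(True)
            else:
                p = 1.0
                h_row.append(False)
            p_row.append(p)
            w_row.append(-np.log10(p) if h_row[-1] else 0.0)
        names.append(name)
        weights.append(w_row)
        hits.append(h_row)
        pvals.append(p_row)
        targeting = [m for m, h in zip(mirnas, h_row) if h]
        counts.append(len(targeting))
        fracs.append(
            len([m for m in targeting if m in measured]) / len(targeting)
            if targeting
            else 0.0
        )
    idx = pd.Index(names, name="pathway")
    return TargetingProfile(
        weights=pd.DataFrame(weights, index=idx, columns=mirnas),
        hits=pd.DataFrame(hits, index=idx, columns=mirnas),
        pvalues=pd.DataFrame(pvals, index=idx, columns=mirnas),
        summary=pd.DataFrame(
            {"n_targeting": counts, "measured_fraction": fracs}, index=idx
        ),
        universe_size=M,
    )


def filter_pathways(
    profile: TargetingProfile,
    min_targeting: int = 10,
    max_targeting: int = 200,
    min_measured_fraction: float = 0.5,
) -> TargetingProfile:
    """Keep pathways targeted by 10-200 miRNAs with >= 50% measured.

    Boundaries are inclusive: exactly 10 or exactly 200 targeting miRNAs
    are retained, as is exactly half measured.
    """
    s = profile.summary
    keep = s.index[
        (s["n_targeting"] >= min_targeting)
        & (s["n_targeting"] <= max_targeting)
        & (s["measured_fraction"] >= min_measured_fraction)
    ]
    return TargetingProfile(
        weights=profile.weights.loc[keep],
        hits=profile.hits.loc[keep],
        pvalues=profile.pvalues.loc[keep],
        summary=s.loc[keep],
        universe_size=profile.universe_size,
    )


def rank_mirnas(
    expr: ExpressionMatrix | pd.DataFrame, labels: pd.Series, positive_class: str
) -> pd.Series:
    """log2 fold change per miRNA, ordered descending.

    The returned Series maps miRNA id -> log2fc in ranking order; the
    differential weight used in the KS walk is its absolute value.  Ties
    break lexicographically by id for determinism.
    """
    X = expr.values if isinstance(expr, ExpressionMatrix) else expr
    lab = labels.reindex(X.index)
    if lab.nunique() != 2:
        raise ValueError("rank_mirnas requires exactly two classes")
    if positive_class not in set(lab):
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    fc = X.loc[lab == positive_class].mean() - X.loc[lab != positive_class].mean()
    order = sorted(fc.index, key=lambda m: (-fc[m], m))
    return fc.loc[order]


def compute_es(
    ranked_fc: pd.Series, hit_mirnas: set[str], targeting_weights: pd.Series
) -> tuple[float, list[str]]:
    """Weighted KS enrichment score and leading edge for one pathway.

    Walking the ranked list, a hit increments the running sum by its weight
    w = |log2fc| x targeting weight divided by the summed hit weights; a
    miss decrements by 1/(N - n_hits).  ES is the running-sum value of
    maximal absolute deviation (signed).  With all hit weights zero the ES
    is 0 by convention.
    """
    ids = list(ranked_fc.index)
    hit_mask = np.array([m in hit_mirnas for m in ids])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("empty hit set after intersection with the ranked list")
    w = np.abs(ranked_fc.to_numpy()) * targeting_weights.reindex(ids).fillna(0.0).to_numpy()
    w = np.where(hit_mask, w, 0.0)
    total = w.sum()
    if total == 0:
        return 0.0, []
    N = len(ids)
    steps = np.where(
        hit_mask, w / total, -1.0 / (N - n_hits) if N > n_hits else 0.0
    )
    running = np.cumsum(steps)
    # extremum of maximal |deviation|; exact ties resolve to the positive side
    i_pos, i_neg = int(np.argmax(running)), int(np.argmin(running))
    if running[i_pos] >= -running[i_neg]:
        idx, es = i_pos, float(running[i_pos])
    else:
        idx, es = i_neg, float(running[i_neg])
    if es >= 0:
        leading = [m for i, m in enumerate(ids) if hit_mask[i] and i <= idx]
    else:
        leading = [m for i, m in enumerate(ids) if hit_mask[i] and i > idx]
    return es, leading


def _es_all_pathways(
    fc: np.ndarray,
    mirna_ids: np.ndarray,
    hit_matrix: np.ndarray,
    weight_matrix: np.ndarray,
) -> np.ndarray:
    """Vectorized ES over all pathways for one fold-change vector."""
    order = np.lexsort((mirna_ids, -fc))
    dw = np.abs(fc[order])
    hits = hit_matrix[:, order]
    W = weight_matrix[:, order] * dw[None, :]
    W = np.where(hits, W, 0.0)
    total = W.sum(axis=1)
    n_hits = hits.sum(axis=1)
    N = hit_matrix.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = W / total[:, None]
        miss = np.where(N > n_hits, 1.0 / (N - n_hits), 0.0)
    steps = np.where(hits, inc, -miss[:, None])
    running = np.cumsum(steps, axis=1)
    pos = running.max(axis=1)
    neg = running.min(axis=1)
    es = np.where(pos >= -neg, pos, neg)
    return np.where(total > 0, es, 0.0)


def permutation_test(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    positive_class: str,
    profile: TargetingProfile,
    n_perm: int = 5000,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, np.ndarray]:
    """Sample-permutation null for every pathway's ES.

    Returns ``(observed_es, p_values, null_es)`` where ``null_es`` is the
    pathways x n_perm matrix of permutation scores retained for the pooled
    FDR.  p = (1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1), two-sided.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = expr.values if isinstance(expr, ExpressionMatrix) else expr
    lab = labels.reindex(X.index)
    if (lab == positive_class).sum() < 2 or (lab != positive_class).sum() < 2:
        raise ValueError("need >= 2 samples per class for permutation")
    mirnas = [m for m in profile.hits.columns if m in X.columns]
    if not mirnas:
        raise ValueError("no measured miRNA appears in the targeting profile")
    hit_m = profile.hits[mirnas].to_numpy(dtype=bool)
    w_m = profile.weights[mirnas].to_numpy(dtype=float)
    ids = np.array(mirnas)
    Xv = X[mirnas].to_numpy(dtype=float)
    y = (lab.to_numpy() == positive_class)
    n_pos = int(y.sum())

    def fold_changes(mask: np.ndarray) -> np.ndarray:
        return Xv[mask].mean(axis=0) - Xv[~mask].mean(axis=0)

    obs = _es_all_pathways(fold_changes(y), ids, hit_m, w_m)
    rng = np.random.default_rng(seed)
    null = np.empty((hit_m.shape[0], n_perm))
    n = len(y)
    for b in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_pos, replace=False)] = True
        null[:, b] = _es_all_pathways(fold_changes(perm), ids, hit_m, w_m)
    exceed = (np.abs(null) >= np.abs(obs)[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    idx = profile.hits.index
    return pd.Series(obs, index=idx), pd.Series(p, index=idx), null


def fdr_correct(observed_es: pd.Series, null_es: np.ndarray) -> pd.Series:
    """Pooled-null FDR q-values on |ES|.

    q(P) = [fraction of pooled null |ES| >= |ES_P|] / [fraction of observed
    |ES| >= |ES_P|], clipped to [0, 1] and monotonized so that a larger
    |ES| never carries a larger q.
    """
    if observed_es.empty:
        raise ValueError("no pathways to correct")
    null_abs = np.abs(np.asarray(null_es).ravel())
    if null_abs.size == 0:
        raise ValueError("empty null store")
    obs_abs = observed_es.abs().to_numpy()
    q = np.empty(len(obs_abs))
    for i, e in enumerate(obs_abs):
        null_frac = (null_abs >= e).mean()
        obs_frac = (obs_abs >= e).mean()  # >= 1/n: the pathway itself counts
        q[i] = min(null_frac / obs_frac, 1.0)
    # monotonize from the weakest pathway upward (BH-style cumulative min),
    # so a larger |ES| never carries a larger q
    order = np.argsort(obs_abs, kind="stable")  # ascending |ES|
    running = np.inf
    mono = q.copy()
    for pos in order:
        running = min(running, q[pos])
        mono[pos] = running
    return pd.Series(mono, index=observed_es.index, name="q")


def enrichment_analysis(
    expr: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    positive_class: str,
    target_map: dict[str, set[str]],
    pathways: dict[str, set[str]],
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full enrichment pipeline; one row per retained pathway.

    Columns: es, p, q, n_targeting, leading_edge (comma-joined ids).
    """
    X = expr.values if isinstance(expr, ExpressionMatrix) else expr
    profile = filter_pathways(pathway_targeting(target_map, pathways, list(X.columns)))
    if profile.summary.empty:
        import warnings

        warnings.warn("no pathway passes the targeting filters", stacklevel=2)
        return pd.DataFrame(columns=["es", "p", "q", "n_targeting", "leading_edge"])
    obs, p, null = permutation_test(
        expr, labels, positive_class, profile, n_perm=n_perm, seed=seed
    )
    q = fdr_correct(obs, null)
    ranked = rank_mirnas(expr, labels, positive_class)
    leading = {}
    for name in profile.hits.index:
        hit_set = set(profile.hits.columns[profile.hits.loc[name]]) & set(ranked.index)
        if hit_set:
            _, le = compute_es(ranked, hit_set, profile.weights.loc[name])
        else:
            le = []
        leading[name] = ",".join(le)
    out = pd.DataFrame(
        {
            "es": obs,
            "p": p,
            "q": q,
            "n_targeting": profile.summary["n_targeting"],
            "leading_edge": pd.Series(leading),
        }
    )
    return out.sort_values(["p", "q"])


def significant_pathways(
    results: pd.DataFrame, p_max: float = 0.01, q_max: float = 0.05
) -> pd.DataFrame:
    """Rows with p < p_max and q < q_max, sorted by p then q."""
    if results.empty:
        return results.copy()
    keep = (results["p"] < p_max) & (results["q"] < q_max)
    return results.loc[keep].sort_values(["p", "q"])
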