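"""Quantitative assessment of integration quality.

Partition agreement (adjusted mutual information, homogeneity /
completeness / V-measure), neighborhood mixing (local inverse Simpson's
index, LISI), and a cell-type recovery pipeline: Wilcoxon rank-sum marker
detection on a held-out split, preranked GSEA of each cell type's
fold-change ranking against every type's marker set, and a weighted
accuracy computed from the resulting confusion matrix of normalized
enrichment scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import (adjusted_mutual_info_score,
                             homogeneity_completeness_v_measure)
from sklearn.neighbors import NearestNeighbors

from .datamodel import ModalityView


# ---------------------------------------------------------------------
# partition agreement
# ---------------------------------------------------------------------

def _entropy(labels) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def adjusted_mutual_information(a, b) -> float:
    """AMI with permutation-model expectation and arithmetic normalization.

    1 for identical partitions; around 0 for independent ones.  A
    zero-entropy (constant) labeling scores 0 by convention.
    """
    a, b = np.asarray(a), np.asarray(b)
    if len(a) != len(b):
        raise ValueError(f"label lengths differ: {len(a)} vs {len(b)}")
    if _entropy(a) == 0.0 or _entropy(b) == 0.0:
        return 0.0
    return float(adjusted_mutual_info_score(a, b, average_method="arithmetic"))


def clustering_scores(truth, pred):
    """(homogeneity, completeness, V-measure) of pred against truth."""
    truth, pred = np.asarray(truth), np.asarray(pred)
    if len(truth) != len(pred):
        raise ValueError(f"label lengths differ: {len(truth)} vs {len(pred)}")
    h, c, v = homogeneity_completeness_v_measure(truth, pred)
    return float(h), float(c), float(v)


# ---------------------------------------------------------------------
# LISI
# ---------------------------------------------------------------------

def lisi(embedding: np.ndarray, labels, perplexity: int = 30,
         tol: float = 1e-5, max_iter: int = 50):
    """Local inverse Simpson's index per cell, plus its mean.

    For each cell the 3*perplexity nearest neighbors (self excluded) are
    weighted by a Gaussian kernel whose bandwidth is tuned by binary
    search so the weight distribution's perplexity matches the target;
    the index is 1 / sum_b p_b^2 over label probabilities p_b.  Values
    range from 1 (all neighbors share one label) to the number of
    distinct labels (perfect mixing).
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    labels = np.asarray(labels)
    n = embedding.shape[0]
    if len(labels) != n:
        raise ValueError("labels must match embedding rows")
    cats, codes = np.unique(labels, return_inverse=True)
    n_labels = len(cats)
    if n_labels == 1:
        return np.ones(n), 1.0

    k = 3 * perplexity
    if k > n - 1:
        warnings.warn(f"only {n - 1} neighbors available; using all")
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    d2 = dist ** 2
    log_u = np.log(perplexity)

    out = np.empty(n)
    for i in range(n):
        p = _perplexity_kernel(d2[i], log_u, tol, max_iter)
        probs = np.bincount(codes[idx[i]], weights=p, minlength=n_labels)
        out[i] = 1.0 / np.sum(probs ** 2)
    return out, float(out.mean())


def _perplexity_kernel(d2: np.ndarray, log_u: float, tol: float,
                       max_iter: int) -> np.ndarray:
    """Gaussian kernel weights with entropy matched to log_u by bisection."""
    beta, beta_min, beta_max = 1.0, -np.inf, np.inf
    d2 = d2 - d2.min()  # numerical shift; softmax-invariant
    for _ in range(max_iter):
        w = np.exp(-beta * d2)
        s = w.sum()
        if s == 0:
            h, p = 0.0, np.zeros_like(w)
        else:
            p = w / s
            nz = p > 0
            h = float(-(p[nz] * np.log(p[nz])).sum())
        diff = h - log_u
        if abs(diff) < tol:
            break
        if diff > 0:  # entropy too high -> sharpen
            beta_min = beta
            beta = beta * 2 if np.isinf(beta_max) else (beta + beta_max) / 2
        else:
            beta_max = beta
            beta = beta / 2 if np.isinf(beta_min) else (beta + beta_min) / 2
    if p.sum() == 0:
        p = np.full_like(d2, 1.0 / len(d2))
    return p


# ---------------------------------------------------------------------
# marker detection (Wilcoxon rank-sum, group vs rest)
# ---------------------------------------------------------------------

def rank_features(view_or_features, labels=None, pseudocount: float = 1e-9,
                  feature_ids=None) -> pd.DataFrame:
    """Per-group feature ranking by two-sided Wilcoxon rank-sum vs rest.

    Returns a long-format table with columns group, feature, statistic
    (the rank-sum U of the group), lfc (log2 fold change of group mean
    over rest mean, pseudocounted), pval and padj (Benjamini-Hochberg
    within group).  Groups with fewer than 2 cells are skipped.
    """
    if isinstance(view_or_features, ModalityView):
        if view_or_features.features is None:
            raise ValueError("modality carries no features")
        X = view_or_features.features
        feature_ids = view_or_features.feature_ids
        if labels is None:
            labels = view_or_features.cell_labels
    else:
        X = np.asarray(view_or_features, dtype=np.float64)
    if feature_ids is None:
        feature_ids = np.array([f"feature_{j}" for j in range(X.shape[1])])
    feature_ids = np.asarray(feature_ids)
    labels = np.asarray(labels)
    n, F = X.shape
    if len(labels) != n:
        raise ValueError("labels must match feature rows")

    ranks = scipy.stats.rankdata(X, axis=0)
    # tie correction term per feature: sum(t^3 - t) over tied groups
    tie_term = np.empty(F)
    for j in range(F):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = float(np.sum(counts ** 3 - counts))

    frames = []
    for g in np.unique(labels):
        mask = labels == g
        n1 = int(mask.sum())
        n2 = n - n1
        if n1 < 2:
            warnings.warn(f"group {g!r} has fewer than 2 cells; skipped")
            continue
        r1 = ranks[mask].sum(axis=0)
        U = r1 - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, (U - mu) / np.sqrt(var), 0.0)
        pval = 2.0 * scipy.stats.norm.sf(np.abs(z))
        pval = np.clip(pval, 0.0, 1.0)
        padj = scipy.stats.false_discovery_control(pval, method="bh")
        m1 = X[mask].mean(axis=0)
        m2 = X[~mask].mean(axis=0) if n2 else np.zeros(F)
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2((m1 + pseudocount) / (m2 + pseudocount))
        # negative means (non-expression-like data) have no defined ratio
        lfc = np.where(np.isfinite(lfc), lfc, 0.0)
        lfc = np.where(m1 == m2, 0.0, lfc)
        frames.append(pd.DataFrame({
            "group": g, "feature": feature_ids, "statistic": U,
            "lfc": lfc, "pval": pval, "padj": padj}))
    if not frames:
        raise ValueError("no group had at least 2 cells")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------
# marker sets and preranked GSEA
# ---------------------------------------------------------------------

@dataclass
class MarkerSetCollection:
    """Cell type -> ordered marker feature list."""

    sets: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, feats in self.sets.items():
            feats = list(feats)
            if len(set(feats)) != len(feats):
                raise ValueError(f"duplicate features in marker set {name!r}")
            self.sets[name] = feats

    def __iter__(self):
        return iter(self.sets.items())


#: conventional marker-set sizes per modality role
ROLE_TOP_K = {"expression": 100, "regions": 500}


def build_marker_sets(test_table: pd.DataFrame, adjusted_p_max: float = 5e-3,
                      top_k: int | str = 100, provenance=None
                      ) -> MarkerSetCollection:
    """Top-``top_k`` significant features per cell type, by fold change.

    ``top_k`` may be a number or a modality role tag: ``'expression'``
    (100 features) or ``'regions'`` (500 features).  Features with
    adjusted p below the threshold are sorted by decreasing fold change;
    a type with no surviving features is recorded as an empty set with a
    warning (and later excluded from the confusion matrix).
    """
    if isinstance(top_k, str):
        if top_k not in ROLE_TOP_K:
            raise ValueError(f"unknown modality role {top_k!r}; "
                             f"expected one of {sorted(ROLE_TOP_K)}")
        top_k = ROLE_TOP_K[top_k]
    sets = {}
    for g, sub in test_table.groupby("group", sort=True):
        surv = sub[sub["padj"] < adjusted_p_max].sort_values(
            ["lfc", "feature"], ascending=[False, True])
        if surv.empty:
            warnings.warn(f"cell type {g!r}: no significant markers")
            sets[g] = []
        else:
            sets[g] = list(surv["feature"].head(top_k))
    return MarkerSetCollection(sets=sets, provenance=provenance or {})


def preranked_gsea(ranking: pd.Series, gene_set, n_perm: int = 1000,
                   rng=None, weight: float = 1.0):
    """Classic weighted Kolmogorov-Smirnov enrichment of a feature set.

    ``ranking`` maps feature -> ranking metric (e.g. log fold change).
    Hits advance the running sum by |metric|^weight (normalized), misses
    retreat by 1/(N - N_hits); ES is the extremum of the running sum.
    The null is ``n_perm`` random same-size feature sets; NES divides ES
    by the mean |null ES| of matching sign, and p is the one-sided
    frequency of a same-sign null at least as extreme.

    Returns (ES, NES, p); NES is NaN when the set misses the ranking
    entirely (downstream imputes 0).
    """
    rng = np.random.default_rng(rng)
    ranking = ranking.sort_values(ascending=False)
    features = np.asarray(ranking.index)
    metric = ranking.to_numpy(dtype=np.float64)
    N = len(features)
    hit_mask = np.isin(features, list(gene_set))
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == N:
        return np.nan, np.nan, np.nan

    es = _enrichment_score(metric, hit_mask, weight)

    null = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(N, dtype=bool)
        mask[rng.choice(N, size=n_hits, replace=False)] = True
        null[i] = _enrichment_score(metric, mask, weight)
    same_sign = null[null * es > 0] if es != 0 else null
    if len(same_sign) == 0:
        return es, np.nan, np.nan
    nes = es / np.mean(np.abs(same_sign))
    p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + len(same_sign))
    return float(es), float(nes), float(p)


def _enrichment_score(metric: np.ndarray, hit_mask: np.ndarray,
                      weight: float) -> float:
    """Extremum of the weighted KS running sum over a descending ranking."""
    w = np.abs(metric) ** weight
    hit_sum = w[hit_mask].sum()
    steps = np.where(
        hit_mask,
        w / hit_sum if hit_sum > 0 else 1.0 / hit_mask.sum(),
        -1.0 / (len(metric) - hit_mask.sum()))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


@dataclass
class NESConfusionMatrix:
    """Rows: marker sets (true types); columns: evaluated cell types."""

    matrix: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.matrix, pd.DataFrame):
            self.matrix = pd.DataFrame(self.matrix)
        if self.matrix.isna().any().any():
            raise ValueError("confusion matrix must be NaN-free (impute 0 upstream)")


def nes_confusion_matrix(train_table: pd.DataFrame,
                         marker_sets: MarkerSetCollection,
                         n_perm: int = 1000, rng=None) -> NESConfusionMatrix:
    """NES of every marker set against every cell type's ranking.

    Rankings come from the train-split feature table (log fold change);
    NaN enrichment scores are imputed as 0; types with empty marker sets
    are excluded with a warning.
    """
    rng = np.random.default_rng(rng)
    kept = [name for name, feats in marker_sets if feats]
    for name, feats in marker_sets:
        if not feats:
            warnings.warn(f"cell type {name!r} has an empty marker set; excluded")
    types = [g for g in sorted(train_table["group"].unique()) if g in kept]
    mat = pd.DataFrame(0.0, index=types, columns=types)
    for t in types:
        sub = train_table[train_table["group"] == t]
        ranking = pd.Series(sub["lfc"].to_numpy(), index=sub["feature"].to_numpy())
        for s in types:
            _, nes, _ = preranked_gsea(ranking, marker_sets.sets[s],
                                       n_perm=n_perm, rng=rng)
            mat.loc[s, t] = 0.0 if np.isnan(nes) else nes
    return NESConfusionMatrix(matrix=mat)


def accuracy_from_confusion(m: NESConfusionMatrix):
    """(weighted, unweighted) accuracy of a NES confusion matrix.

    Columns are scaled by their absolute maxima (all-zero columns stay
    zero).  Positive diagonal mass counts as TP, |negative diagonal| as
    FN, positive off-diagonal as FP, |negative off-diagonal| as TN;
    accuracy is (TP + TN) / (TP + TN + FP + FN).  The unweighted variant
    replaces each scaled value by its sign first.
    """
    A = m.matrix.to_numpy(dtype=np.float64)
    if A.size == 0 or A.shape[0] != A.shape[1]:
        raise ValueError("confusion matrix must be square and non-empty")
    colmax = np.abs(A).max(axis=0)
    scale = np.where(colmax > 0, colmax, 1.0)
    S = A / scale

    def _acc(S):
        diag = np.diag(S)
        off = S[~np.eye(len(S), dtype=bool)]
        tp = diag[diag > 0].sum()
        fn = -diag[diag < 0].sum()
        fp = off[off > 0].sum()
        tn = -off[off < 0].sum()
        denom = tp + tn + fp + fn
        return float((tp + tn) / denom) if denom > 0 else 0.0

    return _acc(S), _acc(np.sign(S))


# ---------------------------------------------------------------------
# graph clustering for label-free evaluation
# ---------------------------------------------------------------------

def leiden_clusters(view: ModalityView, resolution: float = 1.0,
                    seed: int = 0) -> np.ndarray:
    """Leiden partition of the weighted neighbor graph.

    A generic modularity-based clustering stage for pipelines whose
    inputs carry no ground-truth labels; partitions feed the AMI /
    V-measure comparisons.
    """
    import igraph as ig
    import leidenalg

    coo = view.neighbor_graph.tocoo()
    mask = coo.row < coo.col
    g = ig.Graph(n=view.n_cells,
                 edges=list(zip(coo.row[mask], coo.col[mask])),
                 edge_attrs={"weight": coo.data[mask]})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights="weight",
        resolution_parameter=resolution, seed=seed)
    return np.asarray(part.membership)


# ---------------------------------------------------------------------
# split helper for the GSEA pipeline
# ---------------------------------------------------------------------

def stratified_split(labels, test_fraction: float = 0.3, rng=None):
    """Seeded 70:30 split of cell indices, stratified by label.

    Returns (train_idx, test_idx).
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    train, test = [], []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        idx = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))
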