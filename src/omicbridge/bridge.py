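"""Using synthetic multimodal cells as a bridge between real modalities.

Three operations: kNN regression to give synthetic cells feature values
(k = 2, unweighted mean), two-stage kNN majority label transfer
source -> synthetic -> target, and consistency filtering of synthetic
cells against their model (batch-of-origin) label.

All neighbor queries are Euclidean in the given embeddings; majority
votes break ties toward the lexicographically lowest label, so every
operation is deterministic given its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import KNeighborsRegressor, NearestNeighbors

from .datamodel import ModalityView, MultiomicStudy, SyntheticMultiomicOutput


@dataclass
class FeatureRegressor:
    """kNN regression of features on embedding coordinates."""

    embedding: np.ndarray
    features: np.ndarray
    k: int = 2
    _reg: KNeighborsRegressor | None = None

    def __post_init__(self):
        n = self.embedding.shape[0]
        if not 1 <= self.k <= n:
            raise ValueError(f"k={self.k} must be in [1, {n}]")
        self._reg = KNeighborsRegressor(n_neighbors=self.k, weights="uniform")
        self._reg.fit(self.embedding, self.features)

    def predict(self, query: np.ndarray) -> np.ndarray:
        query = np.asarray(query, dtype=np.float64)
        if query.shape[0] == 0:
            return np.zeros((0, self.features.shape[1]))
        if query.shape[1] != self.embedding.shape[1]:
            raise ValueError(
                f"query has {query.shape[1]} components, regressor expects "
                f"{self.embedding.shape[1]}")
        return self._reg.predict(query)


def fit_feature_regressor(view: ModalityView, k: int = 2) -> FeatureRegressor:
    if view.features is None:
        raise ValueError(f"modality {view.name!r} carries no features")
    return FeatureRegressor(embedding=view.embedding, features=view.features, k=k)


def reconstruct_features(reg: FeatureRegressor, out: SyntheticMultiomicOutput,
                         modality_index: int, modality_name: str | None = None
                         ) -> np.ndarray:
    """Impute features for synthetic cells of one modality; attaches them."""
    pred = reg.predict(out.modality_embedding(modality_index))
    key = modality_name or out.modality_names[modality_index]
    out.reconstructed_features[key] = pred
    return pred


def _majority_vote(neighbor_labels: np.ndarray):
    """Row-wise plurality with lexicographic tie-break.

    Returns (labels, agreement fraction).
    """
    n, k = neighbor_labels.shape
    cats, codes = np.unique(neighbor_labels, return_inverse=True)
    codes = codes.reshape(n, k)
    counts = np.zeros((n, len(cats)), dtype=np.intp)
    for j in range(k):
        np.add.at(counts, (np.arange(n), codes[:, j]), 1)
    win = counts.argmax(axis=1)  # first max = lexicographically lowest label
    conf = counts[np.arange(n), win] / k
    return cats[win], conf


@dataclass
class LabelTransferResult:
    transferred: np.ndarray
    confidence: np.ndarray
    path: str
    stage1_labels: np.ndarray | None = None
    stage1_confidence: np.ndarray | None = None


def transfer_labels(source: ModalityView, bridge_out: SyntheticMultiomicOutput,
                    target: ModalityView, k: int = 15,
                    source_index: int = 0, target_index: int = 1
                    ) -> LabelTransferResult:
    """Propagate labels source -> synthetic -> target.

    Stage 1: each synthetic cell takes the majority label of its k nearest
    source cells in the source-modality embedding.  Stage 2: each target
    cell takes the majority label of its k nearest synthetic cells in the
    target-modality slice.  The reported per-cell confidence is the stage-2
    agreement fraction times the mean stage-1 confidence of the voting
    synthetic neighbors.
    """
    if source.cell_labels is None:
        raise ValueError("source modality carries no labels")
    if bridge_out.n_syn == 0:
        raise ValueError("empty bridge: no synthetic cells")

    k1 = min(k, source.n_cells)
    nn1 = NearestNeighbors(n_neighbors=k1).fit(source.embedding)
    _, idx1 = nn1.kneighbors(bridge_out.modality_embedding(source_index))
    syn_labels, syn_conf = _majority_vote(
        np.asarray(source.cell_labels, dtype=object)[idx1])

    k2 = min(k, bridge_out.n_syn)
    nn2 = NearestNeighbors(n_neighbors=k2).fit(
        bridge_out.modality_embedding(target_index))
    _, idx2 = nn2.kneighbors(target.embedding)
    labels, conf2 = _majority_vote(syn_labels[idx2])
    confidence = conf2 * syn_conf[idx2].mean(axis=1)

    return LabelTransferResult(
        transferred=labels,
        confidence=confidence,
        path=f"{source.name}->synthetic->{target.name}",
        stage1_labels=syn_labels,
        stage1_confidence=syn_conf,
    )


def filter_by_model_label(out: SyntheticMultiomicOutput, study: MultiomicStudy,
                          k: int = 15) -> SyntheticMultiomicOutput:
    """Keep synthetic cells whose transferred batch equals their model label.

    Batch identity is transferred from real reference-modality cells to
    synthetic cells by kNN majority vote in the reference slice.
    """
    ref = study.reference
    if ref.batch_labels is None:
        raise ValueError("reference modality carries no batch labels")
    if out.model_label is None:
        raise ValueError("synthetic output carries no model labels")
    if out.n_syn == 0:
        return out

    k_eff = min(k, ref.n_cells)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(ref.embedding)
    _, idx = nn.kneighbors(out.modality_embedding(study.reference_index))
    transferred, _ = _majority_vote(
        np.asarray(ref.batch_labels, dtype=object)[idx])
    keep = transferred.astype(str) == out.model_label.astype(str)
    filtered = out.subset(keep)
    filtered.provenance = {**out.provenance,
                           "model_label_filter_retained": float(keep.mean())}
    return filtered
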