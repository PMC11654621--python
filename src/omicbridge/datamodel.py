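"""Core containers: per-modality views, multi-omic studies, synthetic output.

A :class:`ModalityView` holds one molecular layer (RNA, ATAC, a histone
mark, ...) as its cells' low-dimensional embedding plus a weighted kNN
graph over the cells.  A :class:`MultiomicStudy` is an ordered collection
of such views, paired (shared barcodes) or unpaired, harmonized to a
common embedding width C.  :class:`SyntheticMultiomicOutput` is what the
generative model emits: jointly embedded synthetic cells, one C-dimensional
slice per modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

SYMMETRY_TOL = 1e-8


def knn_affinity_graph(embedding: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Weighted kNN affinity graph from an embedding.

    Edge weights are Gaussian affinities exp(-(d/sigma_i)^2) with a per-cell
    bandwidth sigma_i equal to the distance to the k-th neighbor; the graph
    is symmetrized by the elementwise maximum of the two directions.
    """
    n = embedding.shape[0]
    k_eff = min(k, n - 1)
    if k_eff < 1:
        raise ValueError("need at least 2 cells to build a neighbor graph")
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    sigma = dist[:, -1].copy()
    sigma[sigma == 0] = 1.0
    w = np.exp(-((dist / sigma[:, None]) ** 2))
    rows = np.repeat(np.arange(n), k_eff)
    graph = sp.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
    graph = graph.maximum(graph.T)
    graph.setdiag(0)
    graph.eliminate_zeros()
    return graph


def symmetrize_max(graph: sp.spmatrix) -> sp.csr_matrix:
    g = sp.csr_matrix(graph)
    g = g.maximum(g.T)
    g.setdiag(0)
    g.eliminate_zeros()
    return g


@dataclass
class ModalityView:
    """One modality's cells: embedding, neighbor graph, optional extras."""

    name: str
    cell_ids: np.ndarray
    embedding: np.ndarray
    neighbor_graph: sp.csr_matrix
    eigenmap: np.ndarray | None = None
    eigenmap_order: np.ndarray | None = None
    features: np.ndarray | None = None
    feature_ids: np.ndarray | None = None
    cell_labels: np.ndarray | None = None
    batch_labels: np.ndarray | None = None

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids)
        self.embedding = np.asarray(self.embedding, dtype=np.float64)
        if self.embedding.ndim != 2:
            raise ValueError("embedding must be 2-D (cells x components)")
        n = self.embedding.shape[0]
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids but {n} embedding rows")
        g = sp.csr_matrix(self.neighbor_graph)
        if g.shape != (n, n):
            raise ValueError(f"neighbor graph shape {g.shape} != ({n}, {n})")
        asym = abs(g - g.T)
        if asym.nnz and asym.max() > SYMMETRY_TOL:
            warnings.warn("neighbor graph not symmetric; symmetrizing by max")
            g = symmetrize_max(g)
        if g.diagonal().any():
            g = g.copy()
            g.setdiag(0)
            g.eliminate_zeros()
        if g.nnz and g.data.min() < 0:
            raise ValueError("neighbor graph weights must be nonnegative")
        self.neighbor_graph = g
        if self.eigenmap is not None:
            self.eigenmap = np.asarray(self.eigenmap, dtype=np.float64)
            if self.eigenmap.shape != (n,) or not np.all(np.isfinite(self.eigenmap)):
                raise ValueError("eigenmap must be a finite length-n vector")
        for attr in ("cell_labels", "batch_labels"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v)
                if len(v) != n:
                    raise ValueError(f"{attr} length {len(v)} != {n}")
                setattr(self, attr, v)
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.shape[0] != n:
                raise ValueError("features row count must match cells")
            if self.feature_ids is None:
                self.feature_ids = np.array(
                    [f"feature_{j}" for j in range(self.features.shape[1])])

    @property
    def n_cells(self) -> int:
        return self.embedding.shape[0]

    @property
    def n_components(self) -> int:
        return self.embedding.shape[1]

    def subset(self, mask_or_idx) -> "ModalityView":
        """View restricted to a subset of cells; the kNN graph is rebuilt."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        emb = self.embedding[idx]
        return ModalityView(
            name=self.name,
            cell_ids=self.cell_ids[idx],
            embedding=emb,
            neighbor_graph=knn_affinity_graph(emb),
            features=None if self.features is None else self.features[idx],
            feature_ids=self.feature_ids,
            cell_labels=None if self.cell_labels is None else self.cell_labels[idx],
            batch_labels=None if self.batch_labels is None else self.batch_labels[idx],
        )


@dataclass
class MultiomicStudy:
    """Ordered modalities harmonized to a common embedding width C."""

    modalities: list
    paired: bool = False
    reference_index: int = 0
    C: int | None = None
    standardize: bool = False  # per-column z-scoring; off by default

    def __post_init__(self):
        if len(self.modalities) < 2:
            raise ValueError("a multi-omic study needs at least 2 modalities")
        if not 0 <= self.reference_index < len(self.modalities):
            raise ValueError("reference_index out of range")
        if self.standardize:
            for v in self.modalities:
                mu = v.embedding.mean(axis=0)
                sd = v.embedding.std(axis=0)
                sd[sd == 0] = 1.0
                v.embedding = (v.embedding - mu) / sd
        if self.paired:
            ref_ids = self.modalities[0].cell_ids
            for v in self.modalities:
                if len(np.unique(v.cell_ids)) != len(v.cell_ids):
                    raise ValueError(
                        f"paired study: duplicate barcodes in modality {v.name!r}")
                if set(v.cell_ids) != set(ref_ids):
                    raise ValueError("paired study: modalities must share barcodes")
        self.harmonize(self.C)

    def harmonize(self, C: int | None = None):
        """Truncate all embeddings to a common width.

        C never exceeds the smallest embedding width nor the smallest
        numerical matrix rank across modalities.
        """
        min_width = min(v.n_components for v in self.modalities)
        min_rank = min(np.linalg.matrix_rank(v.embedding) for v in self.modalities)
        bound = int(min(min_width, min_rank))
        self.C = bound if C is None else int(min(C, bound))
        for v in self.modalities:
            if v.n_components > self.C:
                v.embedding = v.embedding[:, : self.C].copy()
        return self

    @property
    def M(self) -> int:
        return len(self.modalities)

    @property
    def reference(self) -> ModalityView:
        return self.modalities[self.reference_index]


@dataclass
class SyntheticMultiomicOutput:
    """Generated cells: an (n_syn, M, C) embedding tensor plus annotations."""

    embeddings: np.ndarray
    modality_names: list
    reconstructed_features: dict = field(default_factory=dict)
    model_label: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.embeddings.ndim != 3:
            raise ValueError("embeddings must be (n_syn, M, C)")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("synthetic embeddings contain non-finite values")
        if self.embeddings.shape[1] != len(self.modality_names):
            raise ValueError("modality_names length must equal M")
        if self.model_label is None:
            self.model_label = np.full(self.embeddings.shape[0], "model_0", dtype=object)
        self.model_label = np.asarray(self.model_label, dtype=object)
        if len(self.model_label) != self.embeddings.shape[0]:
            raise ValueError("model_label length must equal n_syn")

    @property
    def n_syn(self) -> int:
        return self.embeddings.shape[0]

    @property
    def M(self) -> int:
        return self.embeddings.shape[1]

    @property
    def C(self) -> int:
        return self.embeddings.shape[2]

    def modality_embedding(self, m: int) -> np.ndarray:
        """The (n_syn, C) slice for modality m."""
        return self.embeddings[:, m, :]

    def subset(self, mask_or_idx) -> "SyntheticMultiomicOutput":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SyntheticMultiomicOutput(
            embeddings=self.embeddings[idx],
            modality_names=list(self.modality_names),
            reconstructed_features={k: v[idx] for k, v in self.reconstructed_features.items()},
            model_label=self.model_label[idx],
            provenance=dict(self.provenance),
        )


def concatenate_outputs(outputs) -> SyntheticMultiomicOutput:
    outputs = list(outputs)
    if not outputs:
        raise ValueError("nothing to concatenate")
    names = outputs[0].modality_names
    for o in outputs:
        if o.modality_names != names:
            raise ValueError("outputs have mismatched modalities")
    feats = {}
    if all(o.reconstructed_features.keys() == outputs[0].reconstructed_features.keys()
           for o in outputs):
        for k in outputs[0].reconstructed_features:
            feats[k] = np.concatenate([o.reconstructed_features[k] for o in outputs])
    return SyntheticMultiomicOutput(
        embeddings=np.concatenate([o.embeddings for o in outputs]),
        modality_names=list(names),
        reconstructed_features=feats,
        model_label=np.concatenate([o.model_label for o in outputs]),
        provenance={"concatenated": [o.provenance for o in outputs]},
    )
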