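"""Readers and writers for the containers the tool touches.

h5ad files go through :mod:`anndata`; a directory of delimited-text
matrices (embedding.csv, features.csv, labels.csv, ...) is accepted as a
lighter-weight alternative.  Matrices are cells-by-features throughout.
"""

from __future__ import annotations

import pathlib

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import (ModalityView, SyntheticMultiomicOutput,
                        knn_affinity_graph, symmetrize_max)


def load_modality(path, embedding_key: str = "X_pca", graph_key: str = "connectivities",
                  name: str | None = None, n_components: int | None = None,
                  label_key: str | None = None, batch_key: str | None = None,
                  k: int = 15) -> ModalityView:
    """Load one modality from an h5ad file or a delimited-text directory.

    When the container carries no cell graph, a weighted kNN graph
    (``k`` = 15 by default) is computed from the embedding.
    """
    path = pathlib.Path(path)
    if path.is_dir():
        return _load_directory(path, name=name, n_components=n_components, k=k)
    if path.suffix != ".h5ad":
        raise ValueError(f"unsupported container {path} (expected .h5ad or directory)")

    adata = ad.read_h5ad(path)
    if embedding_key not in adata.obsm:
        raise KeyError(
            f"embedding slot {embedding_key!r} not found in {path.name}; "
            f"available slots: {sorted(adata.obsm.keys())}")
    emb = np.asarray(adata.obsm[embedding_key], dtype=np.float64)
    if n_components is not None:
        emb = emb[:, :n_components]

    if graph_key in adata.obsp:
        graph = symmetrize_max(sp.csr_matrix(adata.obsp[graph_key]))
    else:
        graph = knn_affinity_graph(emb, k=k)

    features = feature_ids = None
    if adata.X is not None and adata.n_vars > 0:
        features = np.asarray(
            adata.X.toarray() if sp.issparse(adata.X) else adata.X, dtype=np.float64)
        feature_ids = np.asarray(adata.var_names)

    def _obs(key):
        return np.asarray(adata.obs[key]) if key and key in adata.obs else None

    return ModalityView(
        name=name or path.stem,
        cell_ids=np.asarray(adata.obs_names),
        embedding=emb,
        neighbor_graph=graph,
        features=features,
        feature_ids=feature_ids,
        cell_labels=_obs(label_key or "cell_type"),
        batch_labels=_obs(batch_key or "batch"),
    )


def _load_directory(path: pathlib.Path, name=None, n_components=None, k=15) -> ModalityView:
    emb_file = path / "embedding.csv"
    if not emb_file.exists():
        raise FileNotFoundError(
            f"no embedding.csv in {path}; available files: "
            f"{sorted(p.name for p in path.iterdir())}")
    emb_df = pd.read_csv(emb_file, index_col=0)
    emb = emb_df.to_numpy(dtype=np.float64)
    if n_components is not None:
        emb = emb[:, :n_components]
    cell_ids = np.asarray(emb_df.index.astype(str))

    graph_file = path / "graph.csv"
    if graph_file.exists():
        graph = symmetrize_max(
            sp.csr_matrix(pd.read_csv(graph_file, index_col=0).to_numpy(dtype=np.float64)))
    else:
        graph = knn_affinity_graph(emb, k=k)

    features = feature_ids = None
    feat_file = path / "features.csv"
    if feat_file.exists():
        fdf = pd.read_csv(feat_file, index_col=0)
        features = fdf.to_numpy(dtype=np.float64)
        feature_ids = np.asarray(fdf.columns)

    labels = batches = None
    lab_file = path / "labels.csv"
    if lab_file.exists():
        ldf = pd.read_csv(lab_file, index_col=0)
        if "cell_type" in ldf:
            labels = np.asarray(ldf["cell_type"])
        if "batch" in ldf:
            batches = np.asarray(ldf["batch"])

    return ModalityView(
        name=name or path.name, cell_ids=cell_ids, embedding=emb,
        neighbor_graph=graph, features=features, feature_ids=feature_ids,
        cell_labels=labels, batch_labels=batches)


def save_modality(view: ModalityView, path):
    """Write a ModalityView to h5ad (embedding in obsm, graph in obsp)."""
    n = view.n_cells
    adata = ad.AnnData(
        X=view.features if view.features is not None else np.zeros((n, 0)),
        obs=pd.DataFrame(index=pd.Index(view.cell_ids.astype(str), name="cell_id")),
    )
    if view.feature_ids is not None and view.features is not None:
        adata.var_names = pd.Index(view.feature_ids.astype(str))
    adata.obsm["X_pca"] = view.embedding
    adata.obsp["connectivities"] = view.neighbor_graph
    if view.cell_labels is not None:
        adata.obs["cell_type"] = pd.Categorical(view.cell_labels.astype(str))
    if view.batch_labels is not None:
        adata.obs["batch"] = pd.Categorical(view.batch_labels.astype(str))
    adata.uns["modality_name"] = view.name
    adata.write_h5ad(path)


def save_output(out: SyntheticMultiomicOutput, path):
    """Write synthetic cells, one h5ad per modality, into directory ``path``.

    Embeddings round-trip losslessly (float64); the main matrix is the
    reconstructed feature matrix when present, otherwise it is omitted and
    ``uns['has_features']`` records the flag.
    """
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    obs_index = pd.Index([f"syn_{i}" for i in range(out.n_syn)], name="cell_id")
    for m, mod_name in enumerate(out.modality_names):
        feats = out.reconstructed_features.get(mod_name)
        adata = ad.AnnData(
            X=feats if feats is not None else np.zeros((out.n_syn, 0)),
            obs=pd.DataFrame(index=obs_index),
        )
        adata.obsm["X_synthetic"] = out.modality_embedding(m).copy()
        adata.obs["model_label"] = pd.Categorical(out.model_label.astype(str)) \
            if out.n_syn else pd.Categorical([])
        adata.uns["provenance"] = _provenance_strs(out.provenance)
        adata.uns["has_features"] = feats is not None
        adata.write_h5ad(path / f"{mod_name}.h5ad")


def load_output(path, modality_names) -> SyntheticMultiomicOutput:
    path = pathlib.Path(path)
    slices, feats, model_label, prov = [], {}, None, {}
    for mod_name in modality_names:
        adata = ad.read_h5ad(path / f"{mod_name}.h5ad")
        slices.append(np.asarray(adata.obsm["X_synthetic"], dtype=np.float64))
        if bool(adata.uns.get("has_features", False)):
            feats[mod_name] = np.asarray(adata.X, dtype=np.float64)
        model_label = np.asarray(adata.obs["model_label"]).astype(object)
        prov = dict(adata.uns.get("provenance", {}))
    return SyntheticMultiomicOutput(
        embeddings=np.stack(slices, axis=1) if slices[0].shape[0] else
        np.zeros((0, len(modality_names), slices[0].shape[1])),
        modality_names=list(modality_names),
        reconstructed_features=feats,
        model_label=model_label,
        provenance=prov,
    )


def _provenance_strs(prov: dict) -> dict:
    return {str(k): str(v) for k, v in prov.items()}
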