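"""Synthetic multi-omic studies with known ground truth.

The generator emulates the situation the integration method assumes:
K latent cell populations living in a shared low-dimensional state space,
observed through M modality-specific linear maps plus Gaussian noise.
Paired studies reuse one latent draw for every modality (shared barcodes);
unpaired studies draw independent cells per modality from the same
population.  Optional batch structure adds a latent offset per batch.

Feature matrices are rendered through a nonnegative linear map followed by
a softplus, mimicking normalized expression values; a raw linear option
exists for exactness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datamodel import ModalityView, MultiomicStudy, knn_affinity_graph


@dataclass
class LatentPopulationSpec:
    """K Gaussian populations on shared latent coordinates."""

    K: int
    proportions: np.ndarray
    centers: np.ndarray  # (K, d_latent)
    within_sd: float = 1.0

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=np.float64)
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.proportions.shape != (self.K,):
            raise ValueError("proportions must have length K")
        if abs(self.proportions.sum() - 1.0) > 1e-9 or (self.proportions <= 0).any():
            raise ValueError("proportions must be positive and sum to 1")
        if self.centers.shape[0] != self.K:
            raise ValueError("centers must have K rows")
        if not self.within_sd >= 0:
            raise ValueError("within_sd must be nonnegative")

    @property
    def d_latent(self) -> int:
        return self.centers.shape[1]


@dataclass
class ModalityRenderSpec:
    """How one modality observes the latent space."""

    load_matrix: np.ndarray  # (d_latent, C)
    embed_noise_sd: float = 0.1
    n_features: int = 0
    feature_map: np.ndarray | None = None  # (C, n_features), nonnegative
    feature_noise_sd: float = 0.05
    feature_nonlinearity: str = "softplus"  # or "linear"
    name: str = "modality"
    knn_k: int = 15

    def __post_init__(self):
        self.load_matrix = np.asarray(self.load_matrix, dtype=np.float64)
        if self.load_matrix.ndim != 2:
            raise ValueError("load_matrix must be 2-D (d_latent x C)")
        if self.n_features:
            if self.feature_map is None:
                raise ValueError("n_features > 0 requires a feature_map")
            self.feature_map = np.asarray(self.feature_map, dtype=np.float64)
            if self.feature_map.shape != (self.load_matrix.shape[1], self.n_features):
                raise ValueError("feature_map must be (C x n_features)")
        if self.feature_nonlinearity not in ("softplus", "linear"):
            raise ValueError("feature_nonlinearity must be 'softplus' or 'linear'")

    @property
    def C(self) -> int:
        return self.load_matrix.shape[1]


@dataclass
class StudySpec:
    """Study-level design: cell counts, pairing, batches, seed."""

    n_cells: tuple  # per-modality cell counts
    paired: bool = False
    batches: list = field(default_factory=list)  # [(label, latent offset vector)]
    seed: int = 0

    def __post_init__(self):
        self.n_cells = tuple(int(n) for n in self.n_cells)
        if self.paired and len(set(self.n_cells)) > 1:
            raise ValueError("paired study requires equal cell counts per modality")


def sample_latent(spec: LatentPopulationSpec, n: int, rng: np.random.Generator):
    """Draw n latent cells; returns (latent (n, d), cluster labels (n,))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = rng.choice(spec.K, size=n, p=spec.proportions)
    latent = spec.centers[labels] + spec.within_sd * rng.standard_normal(
        (n, spec.d_latent))
    return latent, labels


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def render_modality(latent: np.ndarray, labels: np.ndarray, spec: ModalityRenderSpec,
                    rng: np.random.Generator, cell_ids=None,
                    batch_labels=None) -> ModalityView:
    """Project latent cells into one modality's embedding (and features)."""
    n = latent.shape[0]
    if latent.shape[1] != spec.load_matrix.shape[0]:
        raise ValueError("latent dimensionality does not match load_matrix")
    emb = latent @ spec.load_matrix
    if spec.embed_noise_sd > 0:
        emb = emb + spec.embed_noise_sd * rng.standard_normal(emb.shape)

    features = feature_ids = None
    if spec.n_features:
        raw = emb @ spec.feature_map
        if spec.feature_nonlinearity == "softplus":
            raw = _softplus(raw)
        if spec.feature_noise_sd > 0:
            raw = raw + spec.feature_noise_sd * rng.standard_normal(raw.shape)
        features = raw
        feature_ids = np.array([f"{spec.name}_f{j}" for j in range(spec.n_features)])

    if cell_ids is None:
        cell_ids = np.array([f"{spec.name}_cell_{i}" for i in range(n)])
    return ModalityView(
        name=spec.name,
        cell_ids=cell_ids,
        embedding=emb,
        neighbor_graph=knn_affinity_graph(emb, k=spec.knn_k),
        features=features,
        feature_ids=feature_ids,
        cell_labels=np.array([f"type_{k}" for k in labels], dtype=object),
        batch_labels=batch_labels,
    )


def _apply_batches(latent, batches, rng):
    """Assign cells to batches uniformly and add the latent offsets."""
    n = latent.shape[0]
    if not batches:
        return latent, None
    assign = rng.integers(0, len(batches), size=n)
    shifted = latent.copy()
    names = np.empty(n, dtype=object)
    for b, (label, offset) in enumerate(batches):
        mask = assign == b
        shifted[mask] += np.asarray(offset, dtype=np.float64)
        names[mask] = str(label)
    return shifted, names


def generate_study(pop: LatentPopulationSpec, renders, study: StudySpec) -> MultiomicStudy:
    """Materialize a paired or unpaired multi-omic study."""
    renders = list(renders)
    if len(renders) < 2:
        raise ValueError("need at least 2 modality render specs")
    if len(study.n_cells) != len(renders):
        raise ValueError("n_cells must give one count per modality")
    rng = np.random.default_rng(study.seed)

    views = []
    if study.paired:
        n = study.n_cells[0]
        latent, labels = sample_latent(pop, n, rng)
        latent, batch_names = _apply_batches(latent, study.batches, rng)
        cell_ids = np.array([f"cell_{i:06d}" for i in range(n)])
        for spec in renders:
            views.append(render_modality(latent, labels, spec, rng,
                                         cell_ids=cell_ids, batch_labels=batch_names))
    else:
        for spec, n in zip(renders, study.n_cells):
            latent, labels = sample_latent(pop, n, rng)
            latent, batch_names = _apply_batches(latent, study.batches, rng)
            views.append(render_modality(latent, labels, spec, rng,
                                         batch_labels=batch_names))

    return MultiomicStudy(modalities=views, paired=study.paired)


def planted_marker_features(labels, n_markers_per_type: int = 40,
                            n_background: int = 180, effect: float = 3.0,
                            noise_sd: float = 1.0, rng=None):
    """Feature matrix with a disjoint block of elevated markers per type.

    Emulates cell-type marker structure: every cell type gets
    ``n_markers_per_type`` features shifted up by ``effect`` in that type
    only, on top of nonnegative lognormal-like background noise shared by
    ``n_background`` unspecific features.  Returns (features, feature_ids,
    marker_map) where marker_map names each type's planted features.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    types = sorted(set(labels))
    n = len(labels)
    F = n_markers_per_type * len(types) + n_background
    X = np.abs(noise_sd * rng.standard_normal((n, F)))
    feature_ids = np.array([f"f{j:04d}" for j in range(F)])
    marker_map = {}
    for k, t in enumerate(types):
        cols = slice(k * n_markers_per_type, (k + 1) * n_markers_per_type)
        X[labels == t, cols] += effect
        marker_map[t] = list(feature_ids[cols])
    return X, feature_ids, marker_map


# ---------------------------------------------------------------------
# the standard desk-scale fixture
# ---------------------------------------------------------------------

def _small_rotation(C: int, angle_scale: float, rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((C, C))
    skew = angle_scale * (a - a.T) / 2.0
    return scipy.linalg.expm(skew)


def default_population(seed: int = 0, K: int = 3, d_latent: int = 8,
                       center_scale: float = 1.6, within_sd: float = 1.0,
                       proportions=(0.5, 0.3, 0.2)) -> LatentPopulationSpec:
    rng = np.random.default_rng(seed)
    centers = center_scale * rng.standard_normal((K, d_latent))
    props = np.asarray(proportions, dtype=np.float64)
    if props.shape != (K,):
        props = np.full(K, 1.0 / K)
    return LatentPopulationSpec(K=K, proportions=props, centers=centers,
                                within_sd=within_sd)


def default_renders(seed: int = 0, d_latent: int = 8, C: int = 10, M: int = 2,
                    n_features: int = 50, rotation: float = 0.2,
                    embed_noise_sd: float = 0.1):
    """Modality render specs sharing one variance-ordered latent basis.

    Each modality applies the shared orthonormal basis followed by a small
    modality-specific rotation, emulating harmonized embeddings (e.g. PCA
    scores) that capture the same latent geometry with modality-specific
    distortion.
    """
    rng = np.random.default_rng(seed + 1)
    basis, _ = np.linalg.qr(rng.standard_normal((d_latent, max(C, d_latent))))
    basis = basis[:, :C] if C <= d_latent else np.hstack(
        [basis, np.zeros((d_latent, C - d_latent))])
    specs = []
    for m in range(M):
        rot = _small_rotation(C, rotation, rng)
        fmap = rng.uniform(0, 1, size=(C, n_features)) * \
            (rng.uniform(size=(C, n_features)) < 0.3)
        specs.append(ModalityRenderSpec(
            load_matrix=basis @ rot,
            embed_noise_sd=embed_noise_sd,
            n_features=n_features,
            feature_map=fmap,
            name=f"modality_{m}",
        ))
    return specs


def default_study(seed: int = 0, n_cells: int = 3000, paired: bool = False,
                  K: int = 3, d_latent: int = 8, C: int = 10, M: int = 2,
                  n_features: int = 50, batches=None,
                  within_sd: float = 1.0) -> MultiomicStudy:
    """The standard fixture: K=3 populations, M=2 modalities, C=10."""
    pop = default_population(seed=seed, K=K, d_latent=d_latent, within_sd=within_sd)
    renders = default_renders(seed=seed, d_latent=d_latent, C=C, M=M,
                              n_features=n_features)
    spec = StudySpec(n_cells=(n_cells,) * M, paired=paired,
                     batches=batches or [], seed=seed + 2)
    return generate_study(pop, renders, spec)
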