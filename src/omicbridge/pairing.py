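"""Mini-batch pre-matching across unpaired modalities.

Cells in each modality are ordered by the first nontrivial eigenvector of
the symmetric-normalized graph Laplacian of their weighted kNN graph (the
Fiedler vector of the affinity graph).  A mini-batch sampled from the
reference modality is then matched to the best of ``n_candidates``
candidate mini-batches from each other modality, scored by a Bayesian
ridge regressor fit on the reference batch's (embedding, eigenmap) pair.
Matched batches are stacked into the (N, M, C) training tensor.

Paired studies skip the pre-match: cells are sorted lexicographically by
barcode and one shared random index set is used for every modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.linear_model import BayesianRidge

from .datamodel import ModalityView, MultiomicStudy

_DENSE_EIG_MAX = 500


class DisconnectedGraphError(ValueError):
    pass


def eigenmap_order(view: ModalityView, regularize: bool = False,
                   seed: int = 0):
    """First nontrivial Laplacian eigenvector and the cell ordering it induces.

    Uses the symmetric-normalized Laplacian L = I - D^{-1/2} W D^{-1/2}.
    The sign is canonicalized by the first robustly nonzero of: third
    central moment (skewness) >= 0, plain sum >= 0, first nonzero entry
    positive.  The eigenvector is defined only up to sign, and the plain
    sum is near zero by construction (the Fiedler vector is
    D^{1/2}-orthogonal to the trivial eigenvector), so the data-driven
    skewness rule is what keeps orderings comparable across modalities
    that share latent geometry.  The vector and the ascending ordering
    are stored on the view and returned.
    """
    W = sp.csr_matrix(view.neighbor_graph, dtype=np.float64)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")

    n_comp, _ = connected_components(W, directed=False)
    regularized = False
    if n_comp > 1:
        if not regularize:
            raise DisconnectedGraphError(
                f"neighbor graph of {view.name!r} has {n_comp} connected "
                "components; pass regularize=True to add a small uniform "
                "affinity and proceed")
        regularized = True

    if regularized or n <= _DENSE_EIG_MAX:
        Wd = W.toarray()
        if regularized:
            Wd = Wd + 1e-8 * (1 - np.eye(n))
        deg = Wd.sum(axis=1)
        d_inv_sqrt = 1.0 / np.sqrt(deg)
        L = np.eye(n) - (d_inv_sqrt[:, None] * Wd * d_inv_sqrt[None, :])
        _, eigvecs = scipy.linalg.eigh(L, subset_by_index=[0, 1], driver="evr")
        vec = eigvecs[:, 1]
    else:
        deg = np.asarray(W.sum(axis=1)).ravel()
        if (deg <= 0).any():
            raise DisconnectedGraphError(
                f"isolated cells in the neighbor graph of {view.name!r}")
        d_inv_sqrt = 1.0 / np.sqrt(deg)
        Wn = sp.diags(d_inv_sqrt) @ W @ sp.diags(d_inv_sqrt)
        L = sp.eye(n, format="csr") - Wn
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(n)
        # shift-invert around a point below the spectrum for the two
        # smallest eigenpairs; the first is the trivial (near-zero) one
        eigvals, eigvecs = scipy.sparse.linalg.eigsh(
            L, k=2, sigma=-1e-2, which="LM", v0=v0)
        order_ev = np.argsort(eigvals)
        vec = eigvecs[:, order_ev[1]]

    if _canonical_flip(vec):
        vec = -vec
    ordering = np.argsort(vec, kind="stable")
    view.eigenmap = vec
    view.eigenmap_order = ordering
    return vec, ordering


_SIGN_TOL = 1e-12


def _canonical_flip(vec: np.ndarray) -> bool:
    """Whether the eigenvector should be negated for the canonical sign."""
    skew = float(np.mean((vec - vec.mean()) ** 3))
    if abs(skew) > _SIGN_TOL * max(1.0, np.abs(vec).max() ** 3):
        return skew < 0
    s = float(vec.sum())
    if abs(s) > _SIGN_TOL * max(1.0, np.abs(vec).max()):
        return s < 0
    nz = np.flatnonzero(np.abs(vec) > _SIGN_TOL)
    return bool(len(nz)) and vec[nz[0]] < 0


@dataclass
class RidgeModel:
    """Evidence-maximized Bayesian ridge fit of eigenmap values on embeddings."""

    weights: np.ndarray
    intercept: float
    alpha: float  # noise precision
    lam: float    # weight precision

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept


def fit_minibatch_regressor(Xb: np.ndarray, yb: np.ndarray) -> RidgeModel:
    """Bayesian ridge of y on X with conjugate Gamma hyperpriors.

    Hyperparameters are set by iterative evidence maximization
    (tolerance 1e-3, at most 300 iterations).
    """
    Xb = np.asarray(Xb, dtype=np.float64)
    yb = np.asarray(yb, dtype=np.float64)
    if not (np.all(np.isfinite(Xb)) and np.all(np.isfinite(yb))):
        raise ValueError("non-finite values in regression inputs")
    if Xb.shape[0] <= Xb.shape[1]:
        warnings.warn("mini-batch smaller than embedding width; evidence "
                      "maximization may be ill-conditioned")
    br = BayesianRidge(tol=1e-3, max_iter=300)
    br.fit(Xb, yb)
    return RidgeModel(weights=br.coef_.copy(), intercept=float(br.intercept_),
                      alpha=float(br.alpha_), lam=float(br.lambda_))


def score_candidate(model: RidgeModel, Xc: np.ndarray, yc: np.ndarray) -> float:
    """Coefficient of determination of the model's predictions on (Xc, yc).

    1 is a perfect match; the score is unbounded below.  A zero-variance
    target is scored 0 by convention.
    """
    yc = np.asarray(yc, dtype=np.float64)
    ss_tot = float(np.sum((yc - yc.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    pred = model.predict(np.asarray(Xc, dtype=np.float64))
    ss_res = float(np.sum((yc - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _require_eigenmap(view: ModalityView, seed: int = 0, regularize: bool = False):
    if view.eigenmap is None or view.eigenmap_order is None:
        eigenmap_order(view, regularize=regularize, seed=seed)


def harmonize_eigenmap_signs(study: MultiomicStudy, N: int | None = None,
                             n_probes: int = 10, n_candidates: int = 20):
    """Orient each non-reference eigenmap for cross-modality matching.

    The Fiedler vector is defined only up to sign, and no per-modality
    rule can guarantee that two modalities sharing latent geometry end up
    oriented consistently.  This step probes both orientations of each
    non-reference modality with the same ridge scoring used for
    mini-batch matching — evenly spaced source windows against evenly
    spaced candidate windows — and keeps the orientation with the higher
    total best-candidate score.  Fully deterministic.
    """
    ref = study.reference
    _require_eigenmap(ref)
    if N is None:
        N = min(256, min(v.n_cells for v in study.modalities) // 2)
    n_ref = ref.n_cells
    starts = np.unique(np.linspace(0, n_ref - N, n_probes).astype(int))
    models = []
    for s in starts:
        idx = ref.eigenmap_order[s:s + N]
        models.append(fit_minibatch_regressor(ref.embedding[idx], ref.eigenmap[idx]))

    for m, view in enumerate(study.modalities):
        if m == study.reference_index:
            continue
        _require_eigenmap(view)
        cand_starts = np.unique(
            np.linspace(0, view.n_cells - N, n_candidates).astype(int))
        totals = {}
        for sign in (1.0, -1.0):
            y = sign * view.eigenmap
            order = np.argsort(y, kind="stable")
            total = 0.0
            for model in models:
                best = -np.inf
                for cs in cand_starts:
                    idx = order[cs:cs + N]
                    best = max(best, score_candidate(
                        model, view.embedding[idx], y[idx]))
                total += best
            totals[sign] = total
        if totals[-1.0] > totals[1.0]:
            view.eigenmap = -view.eigenmap
            view.eigenmap_order = np.argsort(view.eigenmap, kind="stable")
    return study


def _candidate_indices(view: ModalityView, N: int, n_candidates: int,
                       rng: np.random.Generator, strategy: str) -> np.ndarray:
    """(n_candidates, N) index array; rows ordered by ascending eigenmap."""
    n = view.n_cells
    order = view.eigenmap_order
    if strategy == "window":
        starts = rng.integers(0, n - N + 1, size=n_candidates)
        return np.stack([order[s:s + N] for s in starts])
    if strategy == "random":
        out = np.empty((n_candidates, N), dtype=np.intp)
        for i in range(n_candidates):
            idx = rng.choice(n, size=N, replace=False)
            out[i] = idx[np.argsort(view.eigenmap[idx], kind="stable")]
        return out
    raise ValueError(f"unknown candidate strategy {strategy!r}")


def select_matching_minibatch(source_X: np.ndarray, source_y: np.ndarray,
                              target: ModalityView, n_candidates: int = 50,
                              N: int = 256, rng=None,
                              strategy: str = "window",
                              model: RidgeModel | None = None) -> np.ndarray:
    """Indices of the best-scoring candidate mini-batch in ``target``.

    Fits the ridge regressor on the source (X, eigenmap) pair (unless a
    prefit ``model`` is passed), draws ``n_candidates`` candidate batches
    from the target and returns the argmax-scoring one; ties go to the
    first occurrence.
    """
    if target.n_cells < N:
        raise ValueError(
            f"target modality {target.name!r} has {target.n_cells} cells, "
            f"fewer than the mini-batch size N={N}; use a smaller N")
    rng = np.random.default_rng(rng)
    _require_eigenmap(target)
    if model is None:
        model = fit_minibatch_regressor(source_X, source_y)
    candidates = _candidate_indices(target, N, n_candidates, rng, strategy)
    scores = [score_candidate(model, target.embedding[idx], target.eigenmap[idx])
              for idx in candidates]
    return candidates[int(np.argmax(scores))]


@dataclass
class MiniBatchTensor:
    """An (N, M, C) stack of matched mini-batches."""

    data: np.ndarray
    source_indices: list  # per-modality index arrays into each view

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("tensor must be (N, M, C)")
        if len(self.source_indices) != self.data.shape[1]:
            raise ValueError("one index list per modality required")

    @property
    def N(self):
        return self.data.shape[0]

    @property
    def M(self):
        return self.data.shape[1]

    @property
    def C(self):
        return self.data.shape[2]


def assemble_minibatch_tensor(study: MultiomicStudy, N: int = 256,
                              n_candidates: int = 50, rng=None,
                              strategy: str = "window") -> MiniBatchTensor:
    """One (N, M, C) training tensor from a study.

    Unpaired: a contiguous eigenmap-ordered window is drawn from the
    reference modality; every other modality contributes its best-scoring
    candidate batch.  Rows of every slice are ordered by ascending
    eigenmap value.  Paired: cells are sorted lexicographically by barcode
    and one shared random index set indexes all modalities.
    """
    rng = np.random.default_rng(rng)
    for v in study.modalities:
        if v.n_cells < N:
            raise ValueError(
                f"modality {v.name!r} has {v.n_cells} cells < N={N}")

    if study.paired:
        ref_sorted = np.sort(study.reference.cell_ids.astype(str))
        pick = np.sort(rng.choice(study.reference.n_cells, size=N, replace=False))
        barcodes = ref_sorted[pick]
        slices, indices = [], []
        for v in study.modalities:
            lookup = {cid: i for i, cid in enumerate(v.cell_ids.astype(str))}
            idx = np.array([lookup[b] for b in barcodes], dtype=np.intp)
            slices.append(v.embedding[idx])
            indices.append(idx)
        return MiniBatchTensor(data=np.stack(slices, axis=1), source_indices=indices)

    ref = study.reference
    _require_eigenmap(ref)
    start = int(rng.integers(0, ref.n_cells - N + 1))
    src_idx = ref.eigenmap_order[start:start + N]
    model = fit_minibatch_regressor(ref.embedding[src_idx], ref.eigenmap[src_idx])

    slices, indices = [None] * study.M, [None] * study.M
    slices[study.reference_index] = ref.embedding[src_idx]
    indices[study.reference_index] = src_idx
    for m, v in enumerate(study.modalities):
        if m == study.reference_index:
            continue
        idx = select_matching_minibatch(
            ref.embedding[src_idx], ref.eigenmap[src_idx], v,
            n_candidates=n_candidates, N=N, rng=rng, strategy=strategy,
            model=model)
        slices[m] = v.embedding[idx]
        indices[m] = idx
    return MiniBatchTensor(data=np.stack(slices, axis=1), source_indices=indices)


def random_minibatch_tensor(study: MultiomicStudy, N: int = 256, rng=None,
                            strategy: str = "window") -> MiniBatchTensor:
    """Ablation control: same sampling scheme, no regressor selection."""
    rng = np.random.default_rng(rng)
    slices, indices = [], []
    for v in study.modalities:
        _require_eigenmap(v)
        idx = _candidate_indices(v, N, 1, rng, strategy)[0]
        slices.append(v.embedding[idx])
        indices.append(idx)
    return MiniBatchTensor(data=np.stack(slices, axis=1), source_indices=indices)
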