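"""Wasserstein GAN with gradient penalty over matched mini-batch tensors.

The generator maps per-cell Gaussian noise to an (M, C) block — one
C-dimensional embedding per modality, jointly — through three 1-D
convolutions along the modality axis (kernel 2, stride 1, same padding)
with batch normalization after the first two.  The critic applies two
convolutions and a single affine unit and carries no normalization
layers, as the gradient penalty requires.  Default optimizers: Adam
(lr 0.001, beta1 0.5, beta2 0.9, eps 1e-7) for the generator, RMSprop
(lr 0.0005) for the critic.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, grad, tmean, tsum, no_grad
from ._nn import Adam, Critic, Generator, RMSprop
from .datamodel import (MultiomicStudy, SyntheticMultiomicOutput,
                        concatenate_outputs)
from .pairing import assemble_minibatch_tensor


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class GeneratorSpec:
    latent_dim: int = 64
    conv_filters: tuple = (512, 128, None)  # None -> C at build time
    kernel_size: int = 2
    stride: int = 1
    bn_momentum: float = 0.99
    bn_eps: float = 1e-3


@dataclass
class CriticSpec:
    conv_filters: tuple = (128, 512)
    kernel_size: int = 2
    stride: int = 1


@dataclass
class TrainConfig:
    N: int = 256
    n_candidates: int = 50
    steps: int = 1000
    critic_updates_per_generator: int = 5
    gp_weight: float = 10.0
    generator_lr: float = 0.001
    generator_beta1: float = 0.5
    generator_beta2: float = 0.9
    generator_eps: float = 1e-7
    critic_lr: float = 0.0005
    latent_dim: int = 64
    generator_filters: tuple = (512, 128, None)
    critic_filters: tuple = (128, 512)
    candidate_strategy: str = "window"
    regularize_graph: bool = False
    seed: int = 0
    nan_policy: str = "abort"  # or "restart"

    def __post_init__(self):
        for name in ("gp_weight", "generator_lr", "critic_lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nan_policy not in ("abort", "restart"):
            raise ValueError("nan_policy must be 'abort' or 'restart'")

    def digest(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def build_generator(spec: GeneratorSpec, M: int, C: int,
                    rng: np.random.Generator) -> Generator:
    if M < 2 or C < 1:
        raise ValueError("need M >= 2 and C >= 1")
    if M < spec.kernel_size:
        raise ValueError("M smaller than the kernel size; same padding "
                         "cannot recover the modality axis")
    filters = tuple(C if f is None else f for f in spec.conv_filters)
    return Generator(spec.latent_dim, M, C, filters, rng,
                     bn_momentum=spec.bn_momentum, bn_eps=spec.bn_eps)


def build_critic(spec: CriticSpec, M: int, C: int,
                 rng: np.random.Generator) -> Critic:
    if M < 2 or C < 1:
        raise ValueError("need M >= 2 and C >= 1")
    if M < spec.kernel_size:
        raise ValueError("M smaller than the kernel size")
    return Critic(M, C, spec.conv_filters, rng)


def gradient_penalty(critic, real: np.ndarray, fake: np.ndarray,
                     rng: np.random.Generator) -> Tensor:
    """Mean squared deviation of the critic's input-gradient norm from 1.

    Evaluated at per-sample random interpolates x_hat = e*real +
    (1-e)*fake with e ~ Uniform(0, 1); the norm is the Euclidean norm
    over the whole (M, C) sample.
    """
    real = np.asarray(real, dtype=np.float64)
    fake = np.asarray(fake, dtype=np.float64)
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share a shape")
    e = rng.uniform(size=(real.shape[0],) + (1,) * (real.ndim - 1))
    xhat = Tensor(e * real + (1 - e) * fake, requires_grad=True)
    scores = critic(xhat)
    gx, = grad(tsum(scores), [xhat], create_graph=True)
    sq_norm = tsum(gx * gx, axis=tuple(range(1, real.ndim)))
    return tmean((sq_norm ** 0.5 - 1.0) ** 2)


def critic_loss(real_scores, fake_scores, gp, gp_weight: float):
    """Wasserstein critic objective: mean(fake) - mean(real) + lambda*gp."""
    return tmean(fake_scores) - tmean(real_scores) + gp_weight * gp


def generator_loss(fake_scores):
    return -tmean(fake_scores)


@dataclass
class TrainedModel:
    generator: Generator
    critic: Critic
    loss_history: dict
    config: TrainConfig
    study_fingerprint: str = ""
    modality_names: list = field(default_factory=list)
    n_reference_cells: int = 0

    def provenance(self) -> dict:
        return {
            "config_digest": self.config.digest(),
            "seed": self.config.seed,
            "steps": len(self.loss_history["generator"]),
            "study_fingerprint": self.study_fingerprint,
        }


def _study_fingerprint(study: MultiomicStudy) -> str:
    h = hashlib.sha256()
    for v in study.modalities:
        h.update(v.name.encode())
        h.update(np.ascontiguousarray(v.embedding).tobytes()[:4096])
    return h.hexdigest()[:16]


def _train_once(study: MultiomicStudy, config: TrainConfig, seed: int):
    rng = np.random.default_rng(seed)
    gen_spec = GeneratorSpec(latent_dim=config.latent_dim,
                             conv_filters=config.generator_filters)
    gen = build_generator(gen_spec, study.M, study.C, rng)
    critic = build_critic(CriticSpec(conv_filters=config.critic_filters),
                          study.M, study.C, rng)
    g_opt = Adam(config.generator_lr, config.generator_beta1,
                 config.generator_beta2, config.generator_eps)
    c_opt = RMSprop(config.critic_lr)
    g_params, c_params = gen.params(), critic.params()
    history = {"generator": [], "critic": []}

    for _ in range(config.steps):
        for _ in range(config.critic_updates_per_generator):
            batch = assemble_minibatch_tensor(
                study, N=config.N, n_candidates=config.n_candidates,
                rng=rng, strategy=config.candidate_strategy)
            z = rng.standard_normal((config.N, config.latent_dim))
            with no_grad():
                fake = gen(Tensor(z), training=True).data
            real_scores = critic(Tensor(batch.data))
            fake_scores = critic(Tensor(fake))
            gp = gradient_penalty(critic, batch.data, fake, rng)
            loss_c = critic_loss(real_scores, fake_scores, gp, config.gp_weight)
            grads = grad(loss_c, c_params)
            c_opt.step(c_params, grads)
            history["critic"].append(loss_c.item())

        z = rng.standard_normal((config.N, config.latent_dim))
        fake = gen(Tensor(z), training=True)
        loss_g = generator_loss(critic(fake))
        grads = grad(loss_g, g_params)
        g_opt.step(g_params, grads)
        history["generator"].append(loss_g.item())

        recent = history["critic"][-config.critic_updates_per_generator:]
        if not (np.isfinite(history["generator"][-1]) and np.all(np.isfinite(recent))):
            raise TrainingDivergedError("NaN in loss history")

    return TrainedModel(generator=gen, critic=critic, loss_history=history,
                        config=config, study_fingerprint=_study_fingerprint(study),
                        modality_names=[v.name for v in study.modalities],
                        n_reference_cells=study.reference.n_cells)


def train(study: MultiomicStudy, config: TrainConfig) -> TrainedModel:
    """Train the WGAN-GP on a harmonized study.

    Each generator step performs ``critic_updates_per_generator`` critic
    updates, each on a freshly matched mini-batch tensor, then one
    generator update.  A NaN in the loss raises under ``nan_policy
    'abort'``; ``'restart'`` re-seeds and retries up to 3 times.
    """
    for v in study.modalities:
        if v.n_cells < config.N:
            raise ValueError(f"modality {v.name!r} has fewer than N={config.N} cells")
    if not study.paired:
        from .pairing import _require_eigenmap, harmonize_eigenmap_signs
        for v in study.modalities:
            _require_eigenmap(v, seed=config.seed,
                              regularize=config.regularize_graph)
        harmonize_eigenmap_signs(study)

    attempts = 1 if config.nan_policy == "abort" else 4
    last_err = None
    for attempt in range(attempts):
        try:
            return _train_once(study, config, seed=config.seed + 1000 * attempt)
        except TrainingDivergedError as err:
            last_err = err
            if config.nan_policy == "abort":
                raise TrainingDivergedError(
                    "training diverged (NaN loss); lower the learning rates, "
                    "reduce filters, or rerun with nan_policy='restart'") from err
            warnings.warn(f"NaN loss on attempt {attempt + 1}; restarting")
    raise TrainingDivergedError("training diverged after 3 restarts") from last_err


def generate(model: TrainedModel, n_syn: int | None = None,
             rng=None) -> SyntheticMultiomicOutput:
    """Sample synthetic multimodal cells from a trained generator.

    Defaults to as many cells as the reference modality had.  Batch
    normalization runs in inference mode (running statistics), so output
    is deterministic given the noise draw.
    """
    if n_syn is None:
        n_syn = model.n_reference_cells
    if n_syn < 0:
        raise ValueError("n_syn must be nonnegative")
    rng = np.random.default_rng(rng)
    if n_syn == 0:
        emb = np.zeros((0, len(model.modality_names), model.generator.C))
    else:
        z = rng.standard_normal((n_syn, model.config.latent_dim))
        with no_grad():
            emb = model.generator(Tensor(z), training=False).data
    return SyntheticMultiomicOutput(
        embeddings=emb,
        modality_names=list(model.modality_names),
        model_label=np.full(n_syn, "model_0", dtype=object),
        provenance=model.provenance(),
    )


def save_model(model: TrainedModel, path):
    """Checkpoint a trained model (parameters + config) to HDF5."""
    import h5py
    import json as _json
    with h5py.File(path, "w") as f:
        for group, net in (("generator", model.generator),
                           ("critic", model.critic)):
            g = f.create_group(group)
            for i, p in enumerate(net.params()):
                g.create_dataset(f"param_{i:03d}", data=p.data)
        bn = f.create_group("batchnorm")
        for name, layer in (("bn1", model.generator.bn1),
                            ("bn2", model.generator.bn2)):
            bn.create_dataset(f"{name}_mean", data=layer.running_mean)
            bn.create_dataset(f"{name}_var", data=layer.running_var)
        f.create_dataset("loss_critic", data=np.asarray(model.loss_history["critic"]))
        f.create_dataset("loss_generator",
                         data=np.asarray(model.loss_history["generator"]))
        f.attrs["config"] = _json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in asdict(model.config).items()})
        f.attrs["study_fingerprint"] = model.study_fingerprint
        f.attrs["modality_names"] = _json.dumps(list(model.modality_names))
        f.attrs["n_reference_cells"] = model.n_reference_cells
        f.attrs["M"] = model.critic.M
        f.attrs["C"] = model.generator.C


def load_model(path) -> TrainedModel:
    """Restore a checkpointed model; exact inverse of :func:`save_model`."""
    import h5py
    import json as _json
    with h5py.File(path, "r") as f:
        raw = _json.loads(f.attrs["config"])
        cfg = TrainConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                             for k, v in raw.items()})
        M, C = int(f.attrs["M"]), int(f.attrs["C"])
        rng = np.random.default_rng(0)
        gen = build_generator(GeneratorSpec(latent_dim=cfg.latent_dim,
                                            conv_filters=cfg.generator_filters),
                              M, C, rng)
        critic = build_critic(CriticSpec(conv_filters=cfg.critic_filters),
                              M, C, rng)
        for group, net in (("generator", gen), ("critic", critic)):
            for i, p in enumerate(net.params()):
                p.data = np.asarray(f[group][f"param_{i:03d}"])
        for name, layer in (("bn1", gen.bn1), ("bn2", gen.bn2)):
            layer.running_mean = np.asarray(f["batchnorm"][f"{name}_mean"])
            layer.running_var = np.asarray(f["batchnorm"][f"{name}_var"])
        return TrainedModel(
            generator=gen, critic=critic,
            loss_history={"critic": list(f["loss_critic"][...]),
                          "generator": list(f["loss_generator"][...])},
            config=cfg,
            study_fingerprint=str(f.attrs["study_fingerprint"]),
            modality_names=_json.loads(f.attrs["modality_names"]),
            n_reference_cells=int(f.attrs["n_reference_cells"]))


def train_semisupervised(study: MultiomicStudy, config: TrainConfig,
                         n_syn_per_batch: int | None = None) -> SyntheticMultiomicOutput:
    """One model per batch label; outputs concatenated with model labels.

    Batches with fewer than N cells in any modality are skipped with a
    warning.
    """
    for v in study.modalities:
        if v.batch_labels is None:
            raise ValueError(f"modality {v.name!r} carries no batch labels")
    labels = sorted(set().union(*(set(v.batch_labels) for v in study.modalities)))

    outputs = []
    for b, label in enumerate(labels):
        masks = [v.batch_labels == label for v in study.modalities]
        if any(m.sum() < config.N for m in masks):
            warnings.warn(f"batch {label!r} has fewer than N={config.N} cells "
                          "in some modality; skipped")
            continue
        sub = MultiomicStudy(
            modalities=[v.subset(m) for v, m in zip(study.modalities, masks)],
            paired=study.paired, reference_index=study.reference_index,
            C=study.C)
        cfg = TrainConfig(**{**asdict(config),
                             "generator_filters": tuple(config.generator_filters),
                             "critic_filters": tuple(config.critic_filters),
                             "seed": config.seed + 7919 * (b + 1)})
        model = train(sub, cfg)
        out = generate(model, n_syn=n_syn_per_batch,
                       rng=np.random.default_rng(cfg.seed + 1))
        out.model_label = np.full(out.n_syn, str(label), dtype=object)
        outputs.append(out)
    if not outputs:
        raise ValueError("no batch had enough cells to train on")
    return concatenate_outputs(outputs)
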