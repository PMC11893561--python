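"""Synthetic multimodal embedding-bag generator.

Emulates the statistical structure the abnormality-aware pipeline assumes
about foundation-model patch embeddings, without any images:

* **Normal instances** are drawn from a K-component Gaussian mixture in a
  low-dimensional latent space (distinct normal tissue morphologies) and
  pushed through a fixed linear map per modality (patch / cell / text),
  plus isotropic Gaussian noise.  All three modalities are maps of the
  *same* latent draw, mimicking that they describe one tissue region.
* **Abnormal instances** are drawn from the same mixture *shifted* by a
  fixed-length displacement along a dataset-level random direction (drawn
  once from ``map_seed``, like the modality maps).  Tumor instances thus
  form a coherent off-manifold cluster — as tumor morphology does — and a
  single scalar, ``abnormal_shift``, controls the effect size;
  reconstruction error under a normal-tissue autoencoder is monotone in it.
* **Bags**: a negative bag (label 0) contains only normal instances; a
  positive bag (label 1) contains ``ceil(rho * m)`` abnormal instances at
  random positions (so every positive bag has at least one), with hidden
  instance labels kept as synthetic ground truth.

Randomness is hierarchical: the dataset seed keys a master stream, and
each bag index keys an independent sub-stream, so datasets are bitwise
reproducible regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .bags import BagDataset, EmbeddingBag

MODALITY_NAMES = ("p", "c", "t")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic embedding-bag distribution.

    Defaults are the package's reference study conditions: 16-d latent,
    3 mixture components, native modality dims 512/1280/512 matching
    patch/cell/text foundation-model embeddings, 10% abnormal instances
    per positive bag, latent displacement 4, bag sizes 30-80.
    """

    latent_dim: int = 16
    n_components: int = 3
    component_means: Optional[np.ndarray] = None   # (K, latent_dim)
    component_scales: Optional[np.ndarray] = None  # (K,)
    mixture_weights: Optional[np.ndarray] = None   # (K,) simplex
    component_spread: float = 3.0                  # used for default means
    modality_dims: tuple[int, int, int] = (512, 1280, 512)
    modality_maps: Optional[tuple] = None          # three (latent_dim, d) matrices
    modality_noise_sd: tuple[float, float, float] = (0.25, 0.25, 0.25)
    map_seed: int = 0                              # keys maps + shift direction
    abnormal_direction: Optional[np.ndarray] = None  # unit vector, latent space
    abnormal_shift: float = 4.0
    tumor_instance_fraction: float = 0.1
    bag_size_range: tuple[int, int] = (30, 80)
    seed: int = 17

    def __post_init__(self):
        K, D = self.n_components, self.latent_dim
        if K < 1 or D < 1:
            raise ValueError("n_components and latent_dim must be positive")
        if self.component_means is None:
            if K > D:
                raise ValueError(
                    "default component means need n_components <= latent_dim; "
                    "pass component_means explicitly"
                )
            self.component_means = self.component_spread * np.eye(K, D)
        self.component_means = np.asarray(self.component_means, dtype=float)
        if self.component_means.shape != (K, D):
            raise ValueError(f"component_means must have shape {(K, D)}")
        if self.component_scales is None:
            self.component_scales = np.ones(K)
        self.component_scales = np.asarray(self.component_scales, dtype=float)
        if np.any(self.component_scales < 0):
            raise ValueError("component_scales must be nonnegative")
        if self.mixture_weights is None:
            self.mixture_weights = np.full(K, 1.0 / K)
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        if self.mixture_weights.shape != (K,) or np.any(self.mixture_weights < 0) \
                or not math.isclose(self.mixture_weights.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("mixture_weights must be a nonnegative K-simplex")
        if self.modality_maps is None:
            map_rng = np.random.default_rng(self.map_seed)
            self.modality_maps = tuple(
                map_rng.normal(0.0, 1.0 / np.sqrt(D), (D, d))
                for d in self.modality_dims
            )
        for m, d in zip(self.modality_maps, self.modality_dims):
            if m.shape != (D, d):
                raise ValueError("modality_maps shapes must match "
                                 "(latent_dim, modality_dim)")
        if self.abnormal_direction is None:
            dir_rng = np.random.default_rng(
                np.random.SeedSequence(self.map_seed, spawn_key=(1,)))
            v = dir_rng.standard_normal(D)
            self.abnormal_direction = v / np.linalg.norm(v)
        self.abnormal_direction = np.asarray(self.abnormal_direction, dtype=float)
        if self.abnormal_direction.shape != (D,):
            raise ValueError("abnormal_direction must be a latent-dim vector")
        norm = np.linalg.norm(self.abnormal_direction)
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ValueError("abnormal_direction must be a unit vector")
        if any(sd < 0 for sd in self.modality_noise_sd):
            raise ValueError("modality_noise_sd must be nonnegative")
        if self.abnormal_shift < 0:
            raise ValueError("abnormal_shift must be nonnegative")
        if not (0.0 < self.tumor_instance_fraction <= 1.0):
            raise ValueError("tumor_instance_fraction must be in (0, 1]")
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise ValueError("bag_size_range must be a valid positive interval")

    def manifest_dict(self) -> dict:
        """Scalar provenance record; fixed maps are recoverable from map_seed."""
        return {
            "latent_dim": self.latent_dim,
            "n_components": self.n_components,
            "component_spread": self.component_spread,
            "modality_dims": list(self.modality_dims),
            "modality_noise_sd": list(self.modality_noise_sd),
            "map_seed": self.map_seed,
            "abnormal_shift": self.abnormal_shift,
            "tumor_instance_fraction": self.tumor_instance_fraction,
            "bag_size_range": list(self.bag_size_range),
            "seed": self.seed,
        }


def _map_to_modalities(latents: np.ndarray, config: GeneratorConfig,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    n = latents.shape[0]
    feats = {}
    for name, mat, d, sd in zip(MODALITY_NAMES, config.modality_maps,
                                config.modality_dims, config.modality_noise_sd):
        noise = rng.normal(0.0, sd, (n, d)) if sd > 0 else 0.0
        feats[name] = latents @ mat + noise
    return feats


def _sample_mixture_latents(n: int, config: GeneratorConfig,
                            rng: np.random.Generator) -> np.ndarray:
    comps = rng.choice(config.n_components, size=n, p=config.mixture_weights)
    eps = rng.standard_normal((n, config.latent_dim))
    return config.component_means[comps] + config.component_scales[comps, None] * eps


def sample_normal_instances(n: int, config: GeneratorConfig,
                            rng: np.random.Generator):
    """Draw ``n`` normal instances; returns ``(latents, features_by_modality)``."""
    if n < 1:
        raise ValueError("n must be positive")
    latents = _sample_mixture_latents(n, config, rng)
    return latents, _map_to_modalities(latents, config, rng)


def sample_abnormal_instances(n: int, config: GeneratorConfig,
                              rng: np.random.Generator):
    """Draw ``n`` abnormal instances from the shifted latent distribution.

    Abnormal latents are mixture draws displaced by
    ``abnormal_shift * abnormal_direction`` — the direction is a fixed
    dataset-level unit vector, so abnormal instances cluster off the normal
    manifold the way a distinct tissue morphology would.
    """
    if n < 1:
        raise ValueError("n must be positive")
    latents = _sample_mixture_latents(n, config, rng)
    latents = latents + config.abnormal_shift * config.abnormal_direction
    return latents, _map_to_modalities(latents, config, rng)


def generate_bag(label: int, config: GeneratorConfig,
                 rng: np.random.Generator, bag_id: str = "bag") -> EmbeddingBag:
    """Generate one bag; positive bags get ``ceil(rho*m)`` abnormal instances."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    lo, hi = config.bag_size_range
    m = int(rng.integers(lo, hi + 1))
    inst_labels = np.zeros(m, dtype=np.int8)
    if label == 1:
        n_ab = math.ceil(config.tumor_instance_fraction * m)
        positions = rng.choice(m, size=n_ab, replace=False)
        inst_labels[positions] = 1
    n_ab = int(inst_labels.sum())
    n_norm = m - n_ab
    feats = {name: np.empty((m, d))
             for name, d in zip(MODALITY_NAMES, config.modality_dims)}
    if n_norm > 0:
        _, normal = sample_normal_instances(n_norm, config, rng)
        for name in MODALITY_NAMES:
            feats[name][inst_labels == 0] = normal[name]
    if n_ab > 0:
        _, abnormal = sample_abnormal_instances(n_ab, config, rng)
        for name in MODALITY_NAMES:
            feats[name][inst_labels == 1] = abnormal[name]
    return EmbeddingBag(bag_id=bag_id, F_p=feats["p"], F_c=feats["c"],
                        F_t=feats["t"], label=label, instance_labels=inst_labels)


def _class_counts(n_bags: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder rounding of ``proportions * n_bags``."""
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("class_proportions must be a nonnegative simplex")
    if n_bags < len(p):
        raise ValueError("need at least one bag per class")
    raw = p * n_bags
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder, kind="stable")[: n_bags - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_dataset(n_bags: int, class_proportions: Sequence[float],
                     config: GeneratorConfig,
                     seed: Optional[int] = None) -> BagDataset:
    """Generate a dataset of independently seeded bags.

    Bag ``i`` draws from the sub-stream ``SeedSequence(seed, spawn_key=(i,))``,
    so the result is bitwise reproducible for a given ``(config, seed)``.
    """
    seed = config.seed if seed is None else seed
    counts = _class_counts(n_bags, class_proportions)
    labels = np.concatenate([np.full(c, lab, dtype=int)
                             for lab, c in enumerate(counts)])
    master = np.random.default_rng(np.random.SeedSequence(seed))
    labels = labels[master.permutation(n_bags)]
    bags = []
    for i, lab in enumerate(labels):
        sub = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        bags.append(generate_bag(int(lab), config, sub, bag_id=f"bag{i:05d}"))
    manifest = {"generator": config.manifest_dict(), "seed": seed,
                "n_bags": n_bags, "class_proportions": list(class_proportions)}
    return BagDataset(bags, manifest=manifest)
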