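"""Anomaly detection on patch embeddings via a (Gaussian-mixture) VAE.

The detector is an autoencoder with a probabilistic latent space, trained
**only on instances from normal bags**.  Its approximate posterior is a
diagonal Gaussian ``q(z|x) = N(mu(x), sigma^2(x) I)``; its prior is either
a standard normal (``mode="vae"``) or a learnable K-component Gaussian
mixture (``mode="gmvae"``), which lets the latent space cluster around
multiple modes of normal tissue morphology.  The likelihood is
``N(x; x_hat, I)``, so the reconstruction term of the negative ELBO is a
mean squared error.

The Gaussian-prior KL has the usual closed form; the mixture-prior KL does
not, and is estimated by Monte Carlo as ``E_q[log q(z|x) - log p(z)]``
with the mixture density evaluated through a log-sum-exp.

After training the model is frozen and used as a pure function: each patch
embedding ``f_p`` is mapped to a reconstruction embedding
``f_r = Dec(Enc(f_p))`` (deterministically, using the posterior mean — no
sampling), and the squared Euclidean reconstruction error
``e_i = ||f_p,i - f_r,i||^2`` is the instance anomaly score driving
downstream top-k selection.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor, exp, log_softmax, logsumexp, sum_
from .bags import BagDataset
from .nn import MLP, Adam, Linear

logger = logging.getLogger(__name__)

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Core densities and losses (generic: numpy arrays or autodiff Tensors)
# ---------------------------------------------------------------------------

def reparameterize(mu, sigma, epsilon):
    """Gaussian reparameterization ``z = mu + sigma * epsilon``."""
    return mu + sigma * epsilon


def mse_loss(x_batch, xhat_batch):
    """Mean over the batch of squared Euclidean reconstruction errors."""
    if not isinstance(x_batch, Tensor):
        x_batch = np.asarray(x_batch, dtype=float)
        xhat_batch = np.asarray(xhat_batch, dtype=float)
        if x_batch.shape != xhat_batch.shape:
            raise ValueError("shape mismatch")
    shape = x_batch.shape if not isinstance(x_batch, Tensor) else x_batch.data.shape
    if shape[0] == 0:
        raise ValueError("empty batch")
    diff = x_batch - xhat_batch
    return sum_(diff * diff) * (1.0 / shape[0])


def kld_gaussian(mu, sigma2):
    """Closed-form KL( N(mu, sigma2 I) || N(0, I) ), batch-averaged.

    Accepts a single latent vector or a batch (rows = samples); the KL is
    summed over latent coordinates and averaged over samples.
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("variances must be positive")
    per = -0.5 * np.sum(1.0 + np.log(sigma2) - mu**2 - sigma2, axis=-1)
    return float(np.mean(per))


def log_q(z, mu, sigma2):
    """Log-density of a diagonal Gaussian, summed over latent coordinates.

    Returns a scalar for vector input or a per-sample array for a batch.
    Works on numpy arrays and on autodiff Tensors.
    """
    vals = sigma2.data if isinstance(sigma2, Tensor) else np.asarray(sigma2)
    if np.any(vals <= 0):
        raise ValueError("variances must be positive")
    d = (z.shape if not isinstance(z, Tensor) else z.data.shape)[-1]
    diff = z - mu
    quad = sum_(diff * diff / sigma2 + _log(sigma2), axis=-1)
    return -0.5 * d * LOG2PI - 0.5 * quad


def _log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


class MixturePrior:
    """K-component Gaussian mixture prior with learnable parameters.

    Weights are parameterized by logits (normalized through a softmax),
    variances by log-variances, so all parameters are unconstrained.
    """

    def __init__(self, n_components: int, latent_dim: int,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.K = n_components
        self.latent_dim = latent_dim
        rng = rng or np.random.default_rng(0)
        self.logits = Tensor(np.zeros(n_components, dtype=dtype), requires_grad=True)
        self.mu = Tensor(rng.normal(0.0, 1.0, (n_components, latent_dim)).astype(dtype),
                         requires_grad=True)
        self.log_var = Tensor(np.zeros((n_components, latent_dim), dtype=dtype),
                              requires_grad=True)

    @classmethod
    def standard_normal(cls, latent_dim: int) -> "MixturePrior":
        prior = cls(1, latent_dim)
        prior.mu.data[:] = 0.0
        return prior

    @classmethod
    def from_arrays(cls, weights, mu, sigma2) -> "MixturePrior":
        mu = np.atleast_2d(np.asarray(mu, dtype=float))
        K, D = mu.shape
        prior = cls(K, D, dtype=np.float64)
        prior.logits.data = np.log(np.asarray(weights, dtype=float))
        prior.mu.data = mu
        s2 = np.asarray(sigma2, dtype=float)
        if s2.ndim == 1 and s2.shape == (K,):
            s2 = s2[:, None]
        prior.log_var.data = np.log(np.broadcast_to(s2, mu.shape).copy())
        return prior

    @property
    def weights(self) -> np.ndarray:
        e = np.exp(self.logits.data - self.logits.data.max())
        return e / e.sum()

    def parameters(self):
        return [self.logits, self.mu, self.log_var]


def _mixture_log_density(z, logits, mu, log_var):
    """log sum_k pi_k N(z; mu_k, sigma_k^2 I) for a batch z (B, D) -> (B,).

    Computed via log-sum-exp over components; generic over numpy/Tensor.
    """
    B = (z.shape if not isinstance(z, Tensor) else z.data.shape)[0]
    K, D = (mu.shape if not isinstance(mu, Tensor) else mu.data.shape)
    z3 = z.reshape(B, 1, D)
    mu3 = mu.reshape(1, K, D)
    lv3 = log_var.reshape(1, K, D)
    diff = z3 - mu3
    comp = -0.5 * (D * LOG2PI) - 0.5 * sum_(diff * diff * exp(-lv3) + lv3, axis=2)
    logw = log_softmax(logits, axis=-1).reshape(1, K)
    return logsumexp(comp + logw, axis=1)


def log_prior_mixture(z, prior: MixturePrior):
    """Log-density of the mixture prior at ``z`` (vector -> scalar, batch -> array)."""
    z_arr = np.asarray(z, dtype=float)
    single = z_arr.ndim == 1
    zb = np.atleast_2d(z_arr)
    out = _mixture_log_density(zb, prior.logits.data.astype(float),
                               prior.mu.data.astype(float),
                               prior.log_var.data.astype(float))
    return float(out[0]) if single else out


def mc_kl_estimate(mu, sigma2, prior: MixturePrior, n_mc: int,
                   rng: np.random.Generator) -> float:
    """Monte-Carlo estimate of KL( N(mu, sigma2 I) || mixture prior ).

    Averages ``log q(z) - log p(z)`` over ``n_mc`` reparameterized draws.
    With K=1 and a standard-normal prior this converges to the closed form
    of :func:`kld_gaussian`.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    mu = np.asarray(mu, dtype=float)
    sigma = np.sqrt(np.asarray(sigma2, dtype=float))
    eps = rng.standard_normal((n_mc, mu.shape[-1]))
    z = reparameterize(mu, sigma, eps)
    lq = log_q(z, mu, sigma**2)
    lp = log_prior_mixture(z, prior)
    return float(np.mean(lq - lp))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class ADTrainConfig:
    """Training hyperparameters for the anomaly detector."""

    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 128
    n_components: int = 5
    latent_dim: int = 16
    hidden_dims: tuple[int, ...] = (256, 128)
    activation: str = "tanh"
    n_mc: int = 1          # Monte-Carlo samples per step for the mixture KL
    kl_weight: float = 1.0
    mode: str = "gmvae"    # "gmvae" or "vae"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs and learning_rate must be positive")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        if self.mode not in ("vae", "gmvae"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ReconstructionResult:
    """Row-aligned reconstruction embeddings and squared-error scores."""

    F_r: np.ndarray
    errors: np.ndarray


class GMVAEModel:
    """Encoder/decoder pair with a Gaussian or Gaussian-mixture prior.

    The encoder is a symmetric MLP with twin linear heads for the posterior
    mean and log-variance; the decoder mirrors it with a linear output
    layer (the likelihood is ``N(x; x_hat, I)``).
    """

    def __init__(self, input_dim: int, latent_dim: int = 16,
                 n_components: int = 5,
                 hidden_dims: tuple[int, ...] = (256, 128),
                 mode: str = "gmvae", seed: int = 0,
                 activation: str = "tanh"):
        if mode not in ("vae", "gmvae"):
            raise ValueError(f"unknown mode {mode!r}")
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        self.mode = mode
        self.hidden_dims = tuple(hidden_dims)
        self.activation = activation
        self.seed = seed
        self.frozen = False
        self.loss_history: list[float] = []
        rng = np.random.default_rng(seed)
        dims = [input_dim, *hidden_dims]
        self.encoder = MLP(dims, rng, activation=activation)
        self.mu_head = Linear(dims[-1], latent_dim, rng)
        self.logvar_head = Linear(dims[-1], latent_dim, rng)
        self.decoder = MLP([latent_dim, *reversed(hidden_dims), input_dim],
                           rng, activation=activation)
        if mode == "gmvae":
            self.prior = MixturePrior(n_components, latent_dim, rng)
        else:
            self.prior = MixturePrior.standard_normal(latent_dim)
        self.n_components = self.prior.K

    # -- forward -------------------------------------------------------------
    def encode(self, x):
        from .nn import _ACTIVATIONS
        h = _ACTIVATIONS[self.activation](self.encoder(x))
        return self.mu_head(h), self.logvar_head(h)

    def decode(self, z):
        return self.decoder(z)

    def parameters(self):
        params = (self.encoder.parameters() + self.mu_head.parameters()
                  + self.logvar_head.parameters() + self.decoder.parameters())
        if self.mode == "gmvae":
            params += self.prior.parameters()
        return params

    def freeze(self) -> "GMVAEModel":
        self.frozen = True
        return self

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        with open(path, "wb") as f:
            np.savez(f, **arrays)
        meta = {
            "input_dim": self.input_dim, "latent_dim": self.latent_dim,
            "n_components": self.n_components, "hidden_dims": list(self.hidden_dims),
            "mode": self.mode, "seed": self.seed, "frozen": self.frozen,
            "activation": self.activation, "loss_history": self.loss_history,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "GMVAEModel":
        path = Path(path)
        meta = json.loads(Path(str(path) + ".json").read_text())
        model = cls(meta["input_dim"], meta["latent_dim"], meta["n_components"],
                    tuple(meta["hidden_dims"]), meta["mode"], meta["seed"],
                    activation=meta.get("activation", "tanh"))
        with np.load(path) as data:
            for i, p in enumerate(model.parameters()):
                p.data = data[f"param_{i}"]
        model.loss_history = list(meta["loss_history"])
        if meta["frozen"]:
            model.freeze()
        return model


# ---------------------------------------------------------------------------
# Losses and training
# ---------------------------------------------------------------------------

def _loss_graph(x: Tensor, model: GMVAEModel, config: ADTrainConfig,
                rng: np.random.Generator) -> Tensor:
    """Negative-ELBO graph for one minibatch (reconstruction + weighted KL)."""
    B = x.data.shape[0]
    mu, log_var = model.encode(x)
    sigma = exp(0.5 * log_var)
    if model.mode == "vae":
        eps = rng.standard_normal((B, model.latent_dim)).astype(x.data.dtype)
        z = reparameterize(mu, sigma, Tensor(eps))
        xhat = model.decode(z)
        sigma2 = exp(log_var)
        kl = (-0.5 * sum_(1.0 + log_var - mu * mu - sigma2)) * (1.0 / B)
        return mse_loss(x, xhat) + config.kl_weight * kl
    # GMVAE: Monte-Carlo KL against the mixture prior
    kl_terms = []
    xhat = None
    for _ in range(config.n_mc):
        eps = rng.standard_normal((B, model.latent_dim)).astype(x.data.dtype)
        z = reparameterize(mu, sigma, Tensor(eps))
        if xhat is None:
            xhat = model.decode(z)
        lq = log_q(z, mu, exp(log_var))
        lp = _mixture_log_density(z, model.prior.logits, model.prior.mu,
                                  model.prior.log_var)
        kl_terms.append(sum_(lq - lp))
    kl = sum(kl_terms[1:], kl_terms[0]) * (1.0 / (B * config.n_mc))
    return mse_loss(x, xhat) + config.kl_weight * kl


def gmvae_loss(x_batch: np.ndarray, model: GMVAEModel, config: ADTrainConfig,
               rng: np.random.Generator) -> float:
    """Scalar negative-ELBO of a batch under the mixture prior (Monte-Carlo KL)."""
    if model.mode != "gmvae":
        raise ValueError("gmvae_loss requires a model in gmvae mode")
    x = Tensor(np.asarray(x_batch))
    return _loss_graph(x, model, config, rng).item()


def vae_loss(x_batch: np.ndarray, model: GMVAEModel, config: ADTrainConfig,
             rng: np.random.Generator) -> float:
    if model.mode != "vae":
        raise ValueError("vae_loss requires a model in vae mode")
    x = Tensor(np.asarray(x_batch))
    return _loss_graph(x, model, config, rng).item()


def train_ad(normal_bags: BagDataset, config: ADTrainConfig) -> GMVAEModel:
    """Train the anomaly detector on instances pooled from normal bags only.

    Raises if any positive bag is present: the detector's contract is that
    it models the *normal* embedding distribution, so a single tumor bag in
    the training pool is a protocol violation, not noise.
    """
    positives = [b.bag_id for b in normal_bags if b.label != 0]
    if positives:
        raise ValueError(
            f"train_ad received non-normal bags (label != 0): {positives[:5]}"
        )
    if len(normal_bags) == 0:
        raise ValueError("no bags to train on")
    X = np.concatenate([b.F_p for b in normal_bags], axis=0).astype(np.float32)
    input_dim = X.shape[1]
    model = GMVAEModel(input_dim, config.latent_dim, config.n_components,
                       config.hidden_dims, config.mode, seed=config.seed,
                       activation=config.activation)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    opt = Adam(model.parameters(), lr=config.learning_rate)
    n = X.shape[0]
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            x = Tensor(X[idx])
            loss = _loss_graph(x, model, config, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        epoch_loss = float(np.mean(losses))
        model.loss_history.append(epoch_loss)
        logger.info("AD epoch %d/%d loss=%.4f", epoch + 1, config.epochs, epoch_loss)
    return model.freeze()


def reconstruct(model: GMVAEModel, F_p: np.ndarray) -> ReconstructionResult:
    """Deterministic reconstruction embeddings and squared-error scores.

    Uses the posterior mean (``z = mu(x)``, no sampling) so that scores,
    and hence instance selection, are reproducible across runs.
    """
    if not model.frozen:
        raise ValueError("model must be frozen (trained) before scoring")
    F_p = np.asarray(F_p)
    if F_p.ndim != 2 or F_p.shape[1] != model.input_dim:
        raise ValueError(
            f"F_p must be (m, {model.input_dim}), got {F_p.shape}"
        )
    mu, _ = model.encode(F_p)
    F_r = model.decode(mu)
    errors = np.sum((F_p - F_r) ** 2, axis=1)
    return ReconstructionResult(F_r=F_r, errors=errors)
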