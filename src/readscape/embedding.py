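"""A beta-VAE that embeds canonical tetranucleotide counts in 2D.

The encoder maps each read's 136-dimensional composition vector to the
mean and log-variance of a 2D Gaussian posterior; the decoder maps
latent samples back to feature space. Training maximises the evidence
lower bound with the Kullback-Leibler term down-weighted by beta < 1 —
with the full KL penalty the posterior collapses onto the prior and
the latent space stops carrying information about the reads, so beta
below 1 is a functional requirement here, not a tuning nicety.

Reads are visualised and selected via the encoder means mu (never the
sampled z), which give sharper cluster boundaries.

The model is a pair of small mirrored fully-connected networks written
directly in NumPy (forward, backprop and Adam), sized for CPU training
on read sets in the hundreds of thousands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .kmer_features import KmerFeatureMatrix


@dataclass
class VAEConfig:
    latent_dim: int = 2
    hidden_sizes: tuple[int, ...] = (150, 150)
    beta: float = 0.1
    epochs: int = 15
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim != 2:
            raise ValueError("this artifact fixes latent_dim = 2")
        if self.beta >= 1:
            warnings.warn(
                f"beta={self.beta} >= 1 risks posterior collapse: the latent space "
                "may stop storing useful information about the reads",
                stacklevel=2,
            )


@dataclass
class Scaler:
    """Counts -> proportions -> per-column standardisation.

    Fitted on the training matrix and stored with the model so new
    reads are re-encoded on the same scale. Zero-variance columns are
    centred but not scaled.
    """

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, counts: np.ndarray) -> np.ndarray:
        counts = np.asarray(counts, dtype=np.float64)
        sums = counts.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("rows with zero valid k-mer windows must be excluded before embedding")
        props = counts / sums
        return (props - self.mean) / self.sd


def preprocess_features(matrix: KmerFeatureMatrix | np.ndarray) -> tuple[np.ndarray, Scaler]:
    """Fit the scaler on a count matrix and return standardised features."""
    counts = matrix.counts if isinstance(matrix, KmerFeatureMatrix) else np.asarray(matrix)
    counts = counts.astype(np.float64)
    sums = counts.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("rows with zero valid k-mer windows must be excluded before embedding")
    props = counts / sums
    mean = props.mean(axis=0)
    sd = props.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    scaler = Scaler(mean=mean, sd=sd)
    return (props - mean) / sd, scaler


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray | float:
    """KL(q || N(0, I)) in closed form: 0.5 * sum(mu^2 + sigma^2 - 1 - log sigma^2).

    Accepts single vectors (returns a scalar) or (n, d) arrays
    (returns one value per row). Always nonnegative.
    """
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=-1)
    return float(kl) if kl.ndim == 0 else kl


@dataclass
class EncoderOutput:
    mu: np.ndarray  # (n, 2)
    logvar: np.ndarray  # (n, 2)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class ReadVAE:
    """Mirrored fully-connected encoder/decoder with Gaussian likelihood.

    Reconstruction loss is the mean squared error per feature on the
    standardised proportions (a unit-variance Gaussian likelihood up to
    constants and a 1/n_features scale); total loss = reconstruction +
    beta * KL. On this scale the KL term is comparable to the
    reconstruction term at beta near 1, which is why beta must stay
    below 1 for the latents to keep information about the reads.
    """

    def __init__(self, n_features: int, config: VAEConfig, scaler: Scaler, rng: np.random.Generator):
        self.n_features = n_features
        self.config = config
        self.scaler = scaler
        sizes_enc = [n_features, *config.hidden_sizes]
        sizes_dec = [config.latent_dim, *reversed(config.hidden_sizes)]
        self.params: dict[str, np.ndarray] = {}

        def _init(name: str, n_in: int, n_out: int) -> None:
            scale = np.sqrt(2.0 / n_in)
            self.params[f"W{name}"] = rng.normal(0.0, scale, size=(n_in, n_out))
            self.params[f"b{name}"] = np.zeros(n_out)

        for i in range(len(sizes_enc) - 1):
            _init(f"e{i}", sizes_enc[i], sizes_enc[i + 1])
        _init("mu", sizes_enc[-1], config.latent_dim)
        _init("lv", sizes_enc[-1], config.latent_dim)
        for i in range(len(sizes_dec) - 1):
            _init(f"d{i}", sizes_dec[i], sizes_dec[i + 1])
        _init("out", sizes_dec[-1], n_features)
        self._n_hidden = len(config.hidden_sizes)

    # ---- forward pieces -------------------------------------------------
    def encode_batch(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
        h = x
        pre: list[np.ndarray] = []
        for i in range(self._n_hidden):
            a = h @ self.params[f"We{i}"] + self.params[f"be{i}"]
            pre.append(a)
            h = _relu(a)
        mu = h @ self.params["Wmu"] + self.params["bmu"]
        logvar = h @ self.params["Wlv"] + self.params["blv"]
        return mu, logvar, pre

    def decode_batch(self, z: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        h = z
        pre: list[np.ndarray] = []
        for i in range(self._n_hidden):
            a = h @ self.params[f"Wd{i}"] + self.params[f"bd{i}"]
            pre.append(a)
            h = _relu(a)
        xhat = h @ self.params["Wout"] + self.params["bout"]
        return xhat, pre

    # ---- training -------------------------------------------------------
    def _step_grads(self, x: np.ndarray, eps: np.ndarray) -> tuple[dict[str, np.ndarray], float, float]:
        B = x.shape[0]
        mu, logvar, enc_pre = self.encode_batch(x)
        logvar = np.clip(logvar, -10.0, 10.0)
        sigma = np.exp(0.5 * logvar)
        z = mu + eps * sigma
        xhat, dec_pre = self.decode_batch(z)

        recon = float(np.sum((xhat - x) ** 2) / (B * self.n_features))
        kl = float(np.mean(kl_gaussian(mu, logvar)))
        beta = self.config.beta
        g: dict[str, np.ndarray] = {}

        # decoder backprop
        d = 2.0 * (xhat - x) / (B * self.n_features)
        h_prev = _relu(dec_pre[-1]) if self._n_hidden else z
        g["Wout"] = h_prev.T @ d
        g["bout"] = d.sum(axis=0)
        d = d @ self.params["Wout"].T
        for i in range(self._n_hidden - 1, -1, -1):
            d = d * (dec_pre[i] > 0)
            h_prev = _relu(dec_pre[i - 1]) if i > 0 else z
            g[f"Wd{i}"] = h_prev.T @ d
            g[f"bd{i}"] = d.sum(axis=0)
            d = d @ self.params[f"Wd{i}"].T
        dz = d

        dmu = dz + beta * mu / B
        dlv = dz * eps * 0.5 * sigma + beta * 0.5 * (np.exp(logvar) - 1.0) / B

        # encoder backprop
        h_last = _relu(enc_pre[-1]) if self._n_hidden else x
        g["Wmu"] = h_last.T @ dmu
        g["bmu"] = dmu.sum(axis=0)
        g["Wlv"] = h_last.T @ dlv
        g["blv"] = dlv.sum(axis=0)
        d = dmu @ self.params["Wmu"].T + dlv @ self.params["Wlv"].T
        for i in range(self._n_hidden - 1, -1, -1):
            d = d * (enc_pre[i] > 0)
            h_prev = _relu(enc_pre[i - 1]) if i > 0 else x
            g[f"W{'e'}{i}"] = h_prev.T @ d
            g[f"b{'e'}{i}"] = d.sum(axis=0)
            d = d @ self.params[f"We{i}"].T
        return g, recon, kl

    # ---- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {"n_features": self.n_features, "config": asdict(self.config)}
        with open(path, "wb") as fh:
            np.savez(
                fh,
                __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                scaler_mean=self.scaler.mean,
                scaler_sd=self.scaler.sd,
                **self.params,
            )

    @classmethod
    def load(cls, path: str | Path) -> "ReadVAE":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        config = VAEConfig(**cfg)
        model = cls.__new__(cls)
        model.n_features = meta["n_features"]
        model.config = config
        model.scaler = Scaler(mean=data["scaler_mean"], sd=data["scaler_sd"])
        model.params = {k: data[k] for k in data.files if k not in ("__meta__", "scaler_mean", "scaler_sd")}
        model._n_hidden = len(config.hidden_sizes)
        return model


class _Adam:
    """Adam with cosine learning-rate decay over the training run.

    The decay matters beyond polish: with a constant step size the
    normalised updates keep near-zero weights oscillating at the step
    scale, which leaves a spurious variance floor in the latent means;
    annealing the rate lets converged weights actually settle.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float, total_steps: int):
        self.lr0 = lr
        self.total_steps = max(total_steps, 1)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr = self.lr0 * 0.5 * (1.0 + np.cos(np.pi * min(self.t, self.total_steps) / self.total_steps))
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, gradient in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * gradient
            self.v[k] = b2 * self.v[k] + (1 - b2) * gradient**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def train_vae(
    features: np.ndarray,
    config: VAEConfig = VAEConfig(),
    scaler: Scaler | None = None,
) -> tuple[ReadVAE, pd.DataFrame]:
    """Train the beta-VAE on preprocessed features.

    Deterministic for a given config seed: initialisation, epoch
    shuffles and reparameterisation noise all derive from one
    generator. Returns the model plus a per-epoch loss breakdown
    (reconstruction, KL, total = reconstruction + beta*KL).
    """
    X = np.asarray(features, dtype=np.float64)
    n, n_features = X.shape
    if n < 2 * config.batch_size:
        warnings.warn(f"only {n} rows for batch size {config.batch_size}; expected at least two batches", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    if scaler is None:
        scaler = Scaler(mean=np.zeros(n_features), sd=np.ones(n_features))
    model = ReadVAE(n_features, config, scaler, rng)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    opt = _Adam(model.params, config.learning_rate, total_steps=config.epochs * steps_per_epoch)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        recon_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            eps = rng.standard_normal((batch.shape[0], config.latent_dim))
            grads, recon, kl = model._step_grads(batch, eps)
            total = recon + config.beta * kl
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: reconstruction={recon}, kl={kl}; "
                    "try a smaller learning rate"
                )
            opt.step(model.params, grads)
            recon_sum += recon
            kl_sum += kl
            n_batches += 1
        history.append(
            {
                "epoch": epoch,
                "reconstruction": recon_sum / n_batches,
                "kl": kl_sum / n_batches,
                "total": (recon_sum + config.beta * kl_sum) / n_batches,
            }
        )
    return model, pd.DataFrame(history).set_index("epoch")


def encode(features: np.ndarray, model: ReadVAE, batch_size: int = 8192) -> EncoderOutput:
    """Deterministic encoder pass: per-read mu and logvar, no sampling.

    Batched so arbitrarily large feature matrices stream through;
    batching does not change the result.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"expected (n, {model.n_features}) features, got {X.shape}")
    mus, lvs = [], []
    for start in range(0, X.shape[0], batch_size):
        mu, logvar, _ = model.encode_batch(X[start : start + batch_size])
        mus.append(mu)
        lvs.append(logvar)
    return EncoderOutput(
        mu=np.vstack(mus) if mus else np.zeros((0, model.config.latent_dim)),
        logvar=np.vstack(lvs) if lvs else np.zeros((0, model.config.latent_dim)),
    )


def embedding_frame(ids: list[str], enc: EncoderOutput) -> pd.DataFrame:
    """LatentEmbedding table: read id -> (mu1, mu2)."""
    df = pd.DataFrame({"mu1": enc.mu[:, 0], "mu2": enc.mu[:, 1]}, index=ids)
    df.index.name = "read_id"
    return df
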