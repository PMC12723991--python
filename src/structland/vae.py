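"""Variational autoencoder over one-hot encoded MSAs.

Architecture: one ReLU hidden layer of ``hidden_multiplier * L`` units on
each side; a 2-D Gaussian latent by default.  The encoder outputs the mean
mu and (through a log-sigma head) the standard deviation sigma of the
approximate posterior q(z|x); sampling uses the reparameterization
z = mu + sigma * eps with eps ~ N(0, I).  The decoder emits per-position
logits psi over the q states, turned into probabilities by a position-wise
softmax.

The minimized objective is the negative evidence lower bound: categorical
cross-entropy of the input states under the decoder (summed over positions,
averaged over the batch) plus the closed-form Gaussian KL divergence of
q(z|x) from the standard-normal prior.  Optimization is Adam with L2 weight
regularization; training stops early when the loss has not improved for
``patience`` consecutive epochs, and the best-loss parameters are restored.

The network is small (one hidden layer per side), so forward and backward
passes are written directly with numpy matrix algebra; given a fixed seed
and config, training is bit-reproducible on the same numpy build.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np


class VaeError(RuntimeError):
    pass


@dataclass
class VaeConfig:
    hidden_multiplier: int = 3
    latent_dim: int = 2
    learning_rate: float = 1e-4
    l2_penalty: float = 1e-4
    patience: int = 50
    max_epochs: int = 2000
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1 or self.patience < 1 or self.learning_rate <= 0:
            raise ValueError("invalid VaeConfig")


@dataclass
class TrainingReport:
    """Per-epoch loss trace; total = reconstruction + kl at every epoch."""

    total: list = field(default_factory=list)
    reconstruction: list = field(default_factory=list)
    kl: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_loss: float = float("inf")


class VaeModel:
    """Encoder/decoder parameter container with deterministic forward passes."""

    PARAM_NAMES = ["We", "be", "Wmu", "bmu", "Wls", "bls", "Wd", "bd", "Wo", "bo"]

    def __init__(self, L: int, q: int, config: VaeConfig):
        self.L = L
        self.q = q
        self.config = config
        rng = np.random.default_rng(config.seed)
        D = q * L
        H = config.hidden_multiplier * L
        Z = config.latent_dim

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        self.We, self.be = glorot(D, H), np.zeros(H)
        self.Wmu, self.bmu = glorot(H, Z), np.zeros(Z)
        self.Wls, self.bls = glorot(H, Z), np.zeros(Z)
        self.Wd, self.bd = glorot(Z, H), np.zeros(H)
        self.Wo, self.bo = glorot(H, D), np.zeros(D)

    # -- forward passes ----------------------------------------------------

    def encode(self, x: np.ndarray):
        """(mu, sigma) of q(z|x) for one-hot input of shape (q, L) or (B, q, L)."""
        single = x.ndim == 2
        xb = x[None] if single else x
        if xb.shape[1:] != (self.q, self.L):
            raise VaeError(f"input shape {x.shape} does not match (q={self.q}, L={self.L})")
        flat = xb.reshape(xb.shape[0], -1)
        h = np.maximum(flat @ self.We + self.be, 0.0)
        mu = h @ self.Wmu + self.bmu
        logsig = np.clip(h @ self.Wls + self.bls, -10.0, 10.0)
        sigma = np.exp(logsig)
        return (mu[0], sigma[0]) if single else (mu, sigma)

    def decode_logits(self, z: np.ndarray) -> np.ndarray:
        single = z.ndim == 1
        zb = z[None] if single else z
        h = np.maximum(zb @ self.Wd + self.bd, 0.0)
        logits = (h @ self.Wo + self.bo).reshape(-1, self.q, self.L)
        return logits[0] if single else logits

    def decode_probabilities(self, z: np.ndarray) -> np.ndarray:
        """Per-position softmax distributions, shape (q, L) (or batched)."""
        logits = self.decode_logits(z)
        m = logits.max(axis=-2, keepdims=True)
        p = np.exp(logits - m)
        return p / p.sum(axis=-2, keepdims=True)

    # -- persistence -------------------------------------------------------

    def save(self, path, alphabet_name: str = ""):
        with h5py.File(path, "w") as f:
            for name in self.PARAM_NAMES:
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["L"] = self.L
            f.attrs["q"] = self.q
            f.attrs["alphabet"] = alphabet_name
            for k, v in asdict(self.config).items():
                f.attrs[f"cfg_{k}"] = v
        return path

    @classmethod
    def load(cls, path) -> "VaeModel":
        with h5py.File(path, "r") as f:
            cfg = VaeConfig(
                **{k[4:]: f.attrs[k].item() for k in f.attrs if k.startswith("cfg_")}
            )
            model = cls(int(f.attrs["L"]), int(f.attrs["q"]), cfg)
            for name in cls.PARAM_NAMES:
                setattr(model, name, f[name][...])
        return model


def build(L: int, q: int, config: VaeConfig = None) -> VaeModel:
    """Construct a VAE with hidden width hidden_multiplier*L on both sides."""
    if L < 1 or q < 2:
        raise ValueError("need L >= 1 and q >= 2")
    return VaeModel(L, q, config or VaeConfig())


def reparameterize(mu: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """z = mu + sigma * epsilon, componentwise."""
    mu, sigma, epsilon = np.broadcast_arrays(mu, sigma, epsilon)
    return mu + sigma * epsilon


def argmax_sequence(probabilities: np.ndarray) -> np.ndarray:
    """Per-position argmax of a (q, L) probability matrix; ties -> lowest index."""
    return np.argmax(probabilities, axis=-2)


def _forward_backward(model: VaeModel, xb: np.ndarray, eps: np.ndarray):
    """One training step's loss terms and parameter gradients.

    Reconstruction is summed over positions and averaged over the batch;
    the KL term is the closed-form Gaussian expression averaged over the
    batch.  Gradients are with respect to total = reconstruction + kl (the
    L2 penalty gradient is added by the optimizer).
    """
    B = xb.shape[0]
    flat = xb.reshape(B, -1)
    pre_e = flat @ model.We + model.be
    he = np.maximum(pre_e, 0.0)
    mu = he @ model.Wmu + model.bmu
    logsig = np.clip(he @ model.Wls + model.bls, -10.0, 10.0)
    sigma = np.exp(logsig)
    z = mu + sigma * eps
    pre_d = z @ model.Wd + model.bd
    hd = np.maximum(pre_d, 0.0)
    logits = (hd @ model.Wo + model.bo).reshape(B, model.q, model.L)

    m = logits.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(logits - m).sum(axis=1, keepdims=True))
    logp = logits - lse
    recon = float(-(xb * logp).sum() / B)
    kl = float(0.5 * (mu**2 + sigma**2 - 1.0 - 2.0 * logsig).sum() / B)
    if not np.isfinite(recon) or not np.isfinite(kl):
        raise VaeError("non-finite loss")

    # backward
    p = np.exp(logp)
    dlogits = (p - xb) / B  # (B, q, L)
    dflat_out = dlogits.reshape(B, -1)
    gWo = hd.T @ dflat_out
    gbo = dflat_out.sum(axis=0)
    dhd = (dflat_out @ model.Wo.T) * (pre_d > 0)
    gWd = z.T @ dhd
    gbd = dhd.sum(axis=0)
    dz = dhd @ model.Wd.T

    dmu = dz + mu / B
    dsigma = dz * eps + (sigma - 1.0 / sigma) / B
    dlogsig = dsigma * sigma
    gWmu = he.T @ dmu
    gbmu = dmu.sum(axis=0)
    gWls = he.T @ dlogsig
    gbls = dlogsig.sum(axis=0)
    dhe = (dmu @ model.Wmu.T + dlogsig @ model.Wls.T) * (pre_e > 0)
    gWe = flat.T @ dhe
    gbe = dhe.sum(axis=0)

    grads = dict(
        We=gWe, be=gbe, Wmu=gWmu, bmu=gbmu, Wls=gWls, bls=gbls,
        Wd=gWd, bd=gbd, Wo=gWo, bo=gbo,
    )
    return recon, kl, grads


def elbo_loss(model: VaeModel, batch: np.ndarray, epsilon: np.ndarray):
    """(total, reconstruction, kl) of the minimized objective on a batch."""
    xb = batch[None] if batch.ndim == 2 else batch
    eps = np.asarray(epsilon, dtype=float)
    if eps.ndim == 1:
        eps = np.broadcast_to(eps, (xb.shape[0], model.config.latent_dim))
    recon, kl, _ = _forward_backward(model, xb, eps)
    return recon + kl, recon, kl


def train(encoded, config: VaeConfig = None):
    """Train on an EncodedMsa; returns (VaeModel, TrainingReport).

    Early stopping monitors the epoch-mean training loss; when no
    improvement is seen for ``patience`` epochs training halts and the
    best-loss parameters are restored.
    """
    from .msa_io import one_hot

    config = config or VaeConfig()
    X = one_hot(encoded)
    N = X.shape[0]
    if N < 2:
        raise VaeError("training requires at least 2 sequences")
    model = VaeModel(encoded.L, encoded.q, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE1B0]))

    # Adam state
    mstate = {k: np.zeros_like(getattr(model, k)) for k in model.PARAM_NAMES}
    vstate = {k: np.zeros_like(getattr(model, k)) for k in model.PARAM_NAMES}
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    t = 0

    report = TrainingReport()
    best_params = {k: getattr(model, k).copy() for k in model.PARAM_NAMES}
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(N)
        ep_recon = ep_kl = 0.0
        for start in range(0, N, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = X[idx]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            try:
                recon, kl, grads = _forward_backward(model, xb, eps)
            except VaeError as exc:
                raise VaeError(f"{exc} at epoch {epoch}, batch {start // config.batch_size}")
            t += 1
            for k, g in grads.items():
                if k[0] == "W" and config.l2_penalty > 0:
                    g = g + 2.0 * config.l2_penalty * getattr(model, k)
                mstate[k] = beta1 * mstate[k] + (1 - beta1) * g
                vstate[k] = beta2 * vstate[k] + (1 - beta2) * g * g
                mhat = mstate[k] / (1 - beta1**t)
                vhat = vstate[k] / (1 - beta2**t)
                setattr(
                    model, k,
                    getattr(model, k) - config.learning_rate * mhat / (np.sqrt(vhat) + adam_eps),
                )
            ep_recon += recon * len(idx)
            ep_kl += kl * len(idx)
        ep_recon /= N
        ep_kl /= N
        total = ep_recon + ep_kl
        report.reconstruction.append(ep_recon)
        report.kl.append(ep_kl)
        report.total.append(total)
        if total < report.best_loss - 1e-12:
            report.best_loss = total
            best_params = {k: getattr(model, k).copy() for k in model.PARAM_NAMES}
            since_best = 0
        else:
            since_best += 1
        if since_best >= config.patience:
            break
    report.stopped_epoch = len(report.total)
    for k, v in best_params.items():
        setattr(model, k, v)
    return model, report


def encode_msa(model: VaeModel, encoded) -> tuple:
    """(mu, sigma) arrays of shape (N, latent_dim) for a whole EncodedMsa."""
    from .msa_io import one_hot

    return model.encode(one_hot(encoded))
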