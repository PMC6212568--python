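"""Conditional variational autoencoder over one-hot protein sequences.

The inference model q(z|x,a) and generative model p(x|z,a) are both
three-block MLPs (512/256/128 units by default, mirrored in the
decoder) built from linear blocks LB(x) = ReLU(BN(Wx + b)). The encoder
ends in two linear heads producing the Gaussian posterior mean and (via
softplus) variance over a 16-dimensional latent space; the decoder ends
in a linear layer with sigmoid activation producing the soft
reconstruction. Training maximizes the evidence lower bound with a
single reparameterized latent sample per datum, a summed Bernoulli
(binary cross-entropy) reconstruction term, and a KL term against the
standard-normal prior scaled by a linearly increasing burn-in factor to
avoid early posterior collapse. Optimization is Adam at learning rate
5e-4, batch size 512, with both moment-decay constants 0.9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import _nn
from ._nn import MLP, Adam, Dense, bce_sum, sigmoid, softplus
from .codec import DEFAULT_MAX_LENGTH, Alphabet

#: Floor added to the softplus variance to keep 1/sigma2 finite.
_SIGMA2_FLOOR = 1e-8


@dataclass(frozen=True)
class LatentPosterior:
    """Gaussian posterior parameters in latent space.

    ``mu`` and ``sigma2`` have shape ``(latent_dim,)`` for a single
    input or ``(n, latent_dim)`` for a batch; ``sigma2`` is strictly
    positive.
    """

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma2) <= 0):
            raise ValueError("sigma2 must be strictly positive")


def kl_divergence(posterior: LatentPosterior) -> float | np.ndarray:
    """KL(q || N(0, I)) in closed form.

    Per sample: sum_d 0.5 * (mu_d^2 + sigma2_d - 1 - ln sigma2_d).
    Returns a scalar for a single posterior, an array for a batch.
    Zero exactly when mu = 0 and sigma2 = 1.
    """
    mu = np.asarray(posterior.mu, dtype=np.float64)
    sigma2 = np.asarray(posterior.sigma2, dtype=np.float64)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be strictly positive")
    kl = 0.5 * (mu**2 + sigma2 - 1.0 - np.log(sigma2)).sum(axis=-1)
    return float(kl) if kl.ndim == 0 else kl


def reparameterize(
    posterior: LatentPosterior, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Draw z = mu + sigma * eps with eps ~ N(0, I), deterministic per seed."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    mu = np.asarray(posterior.mu, dtype=np.float64)
    sigma = np.sqrt(np.asarray(posterior.sigma2, dtype=np.float64))
    return mu + sigma * rng.standard_normal(mu.shape)


class ConditionalVAE(BaseEstimator):
    """Attribute-conditioned VAE for fixed-length one-hot sequences.

    Parameters
    ----------
    latent_dim : int, default 16
        Dimension of the Gaussian latent space.
    hidden_dims : tuple of int, default (512, 256, 128)
        Encoder MLP block widths; the decoder uses them reversed.
    max_length : int, default 140
        Residue slots per sequence; the input width is ``22 * max_length``.
    learning_rate, batch_size, beta1, beta2 :
        Adam settings (defaults 5e-4, 512, 0.9, 0.9).
    kl_burnin_epochs : int, default 100
        The KL weight ramps linearly from 0 to 1, per optimizer step,
        over this many epochs' worth of steps, then stays at 1.
    max_epochs : int, default 300
    tol : float, default 1e-4
        Convergence: stop once no epoch improves the best mean loss by
        more than ``tol * |best|`` within ``patience`` epochs.
    patience : int, default 10
    random_state : int, default 0
        Seeds initialization, shuffling and the reparameterization noise.

    Attributes
    ----------
    encoder_, decoder_ : internal MLP stacks (set by :meth:`fit`).
    loss_trace_ : list of per-epoch dicts with keys
        ``epoch, total, reconstruction, kl, burnin``.
    n_features_in_, attr_dim_ : input widths seen at fit time.
    """

    def __init__(
        self,
        latent_dim: int = 16,
        hidden_dims: tuple[int, ...] = (512, 256, 128),
        max_length: int = DEFAULT_MAX_LENGTH,
        alphabet: Alphabet | None = None,
        learning_rate: float = 5e-4,
        batch_size: int = 512,
        beta1: float = 0.9,
        beta2: float = 0.9,
        kl_burnin_epochs: int = 100,
        max_epochs: int = 300,
        tol: float = 1e-4,
        patience: int = 10,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden_dims = hidden_dims
        self.max_length = max_length
        self.alphabet = alphabet
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.kl_burnin_epochs = kl_burnin_epochs
        self.max_epochs = max_epochs
        self.tol = tol
        self.patience = patience
        self.random_state = random_state

    # -- construction ------------------------------------------------------

    def _alphabet(self) -> Alphabet:
        return self.alphabet if self.alphabet is not None else Alphabet()

    def _build(self, n_features: int, attr_dim: int, rng: np.random.Generator):
        hid = list(self.hidden_dims)
        self.encoder_ = MLP([n_features + attr_dim] + hid, rng)
        self.mu_head_ = Dense(hid[-1], self.latent_dim, rng)
        self.sigma_head_ = Dense(hid[-1], self.latent_dim, rng)
        self.decoder_ = MLP([self.latent_dim + attr_dim] + hid[::-1], rng)
        self.out_head_ = Dense(hid[0], n_features, rng)
        self.n_features_in_ = n_features
        self.attr_dim_ = attr_dim

    def _modules(self):
        return {
            "enc": self.encoder_,
            "mu": self.mu_head_,
            "sigma": self.sigma_head_,
            "dec": self.decoder_,
            "out": self.out_head_,
        }

    def _all_params(self):
        out = {}
        for name, mod in self._modules().items():
            out.update(_nn.collect(mod, name + "."))
        return out

    def _all_grads(self):
        out = {}
        for name, mod in self._modules().items():
            out.update(_nn.collect_grads(mod, name + "."))
        return out

    # -- inference-mode passes --------------------------------------------

    def _validate_xa(self, X, A):
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        A = np.atleast_2d(np.asarray(A, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        if A.shape[1] != self.attr_dim_:
            raise ValueError(
                f"attribute has {A.shape[1]} entries, model expects {self.attr_dim_}"
            )
        if X.shape[0] != A.shape[0]:
            raise ValueError("X and A must have the same number of rows")
        return X, A

    def encode(self, X, A) -> LatentPosterior:
        """Posterior parameters q(z|x,a), using running normalization stats."""
        check_is_fitted(self, "encoder_")
        X, A = self._validate_xa(X, A)
        h = self.encoder_.forward(np.hstack([X, A]), training=False)
        mu = self.mu_head_.forward(h, training=False)
        sigma2 = softplus(self.sigma_head_.forward(h, training=False)) + _SIGMA2_FLOOR
        return LatentPosterior(np.squeeze(mu), np.squeeze(sigma2))

    def transform(self, X, A) -> np.ndarray:
        """Latent posterior means — the sequence embedding."""
        post = self.encode(X, A)
        return np.atleast_2d(post.mu)

    def decode(self, Z, A) -> np.ndarray:
        """Soft reconstruction p(x|z,a); entries strictly in (0, 1)."""
        check_is_fitted(self, "decoder_")
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        A = np.atleast_2d(np.asarray(A, dtype=np.float64))
        if Z.shape[1] != self.latent_dim:
            raise ValueError(f"z has {Z.shape[1]} dims, expected {self.latent_dim}")
        if A.shape[1] != self.attr_dim_:
            raise ValueError(
                f"attribute has {A.shape[1]} entries, model expects {self.attr_dim_}"
            )
        g = self.decoder_.forward(np.hstack([Z, A]), training=False)
        return sigmoid(self.out_head_.forward(g, training=False))

    def reconstruct(self, X, A) -> np.ndarray:
        """Deterministic encode-decode (z = posterior mean)."""
        post = self.encode(X, A)
        return self.decode(np.atleast_2d(post.mu), A)

    def elbo_loss(
        self, X, A, burnin_factor: float = 1.0, rng_seed: int = 0
    ) -> tuple[float, float, float]:
        """(total, reconstruction, kl) per-sample means in inference mode.

        ``total = reconstruction + burnin_factor * kl``; at burn-in
        factor 1 minimizing the total maximizes the ELBO.
        """
        if not 0.0 <= burnin_factor <= 1.0:
            raise ValueError("burnin_factor must be in [0, 1]")
        X, A = self._validate_xa(X, A)
        post = self.encode(X, A)
        z = reparameterize(
            LatentPosterior(np.atleast_2d(post.mu), np.atleast_2d(post.sigma2)),
            rng_seed,
        )
        yhat = self.decode(z, A)
        n = X.shape[0]
        recon = bce_sum(yhat, X) / n
        kl = float(np.mean(kl_divergence(post)))
        return recon + burnin_factor * kl, recon, kl

    # -- training ----------------------------------------------------------

    def fit(self, X, A):
        """Train on one-hot sequences ``X`` (n, 22*max_length) and
        conditioning attributes ``A`` (n, 8 or 1265)."""
        X = np.asarray(X, dtype=np.float64)
        A = np.asarray(A, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty 2-D array")
        expected = self.max_length * len(self._alphabet())
        if X.shape[1] != expected:
            raise ValueError(
                f"X width {X.shape[1]} != max_length * alphabet = {expected}"
            )
        root = np.random.default_rng(self.random_state)
        init_rng, shuffle_rng, eps_rng = root.spawn(3)
        self._build(X.shape[1], A.shape[1], init_rng)

        n = X.shape[0]
        batch = min(self.batch_size, n)
        steps_per_epoch = int(np.ceil(n / batch))
        burnin_steps = max(1, self.kl_burnin_epochs * steps_per_epoch)
        opt = Adam(
            self._all_params(),
            lr=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
        )

        self.loss_trace_ = []
        best = np.inf
        best_epoch = -1
        step = 0
        for epoch in range(self.max_epochs):
            order = shuffle_rng.permutation(n)
            ep_tot = ep_rec = ep_kl = 0.0
            last_factor = 0.0
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                factor = min(1.0, step / burnin_steps)
                tot, rec, kl = self._train_step(X[idx], A[idx], factor, eps_rng, opt)
                if not np.isfinite(tot):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                w = len(idx) / n
                ep_tot += tot * w
                ep_rec += rec * w
                ep_kl += kl * w
                last_factor = factor
                step += 1
            self.loss_trace_.append(
                {
                    "epoch": epoch,
                    "total": ep_tot,
                    "reconstruction": ep_rec,
                    "kl": ep_kl,
                    "burnin": last_factor,
                }
            )
            # convergence bookkeeping only once the KL weight is fully on,
            # so the ramp-induced loss increase never triggers a stop
            if last_factor >= 1.0:
                if ep_tot < best - self.tol * abs(best):
                    best = ep_tot
                    best_epoch = epoch
                elif best_epoch >= 0 and epoch - best_epoch >= self.patience:
                    break
        return self

    def _train_step(self, Xb, Ab, burnin_factor, eps_rng, opt):
        B = Xb.shape[0]
        # forward
        h = self.encoder_.forward(np.hstack([Xb, Ab]), training=True)
        mu = self.mu_head_.forward(h, training=True)
        s = self.sigma_head_.forward(h, training=True)
        sigma2 = softplus(s) + _SIGMA2_FLOOR
        sigma = np.sqrt(sigma2)
        eps = eps_rng.standard_normal(mu.shape)
        z = mu + sigma * eps
        g = self.decoder_.forward(np.hstack([z, Ab]), training=True)
        logits = self.out_head_.forward(g, training=True)
        yhat = sigmoid(logits)
        recon = bce_sum(yhat, Xb) / B
        kl_terms = 0.5 * (mu**2 + sigma2 - 1.0 - np.log(sigma2))
        kl = float(kl_terms.sum()) / B
        total = recon + burnin_factor * kl
        # backward (all gradients of the per-sample-mean loss)
        dlogits = (yhat - Xb) / B
        dg = self.out_head_.backward(dlogits)
        d_dec_in = self.decoder_.backward(dg)
        dz = d_dec_in[:, : self.latent_dim]
        dmu = dz + burnin_factor * mu / B
        dsigma2 = dz * eps / (2.0 * sigma) + burnin_factor * 0.5 * (
            1.0 - 1.0 / sigma2
        ) / B
        ds = dsigma2 * sigmoid(s)  # d softplus
        dh = self.mu_head_.backward(dmu) + self.sigma_head_.backward(ds)
        self.encoder_.backward(dh)
        opt.step(self._all_grads())
        return total, recon, kl

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Self-describing checkpoint: hyperparameters, parameters and
        batch-norm running statistics in a single ``.npz`` file."""
        check_is_fitted(self, "encoder_")
        arrays = self._all_params().copy()
        for name, mod in self._modules().items():
            arrays.update(_nn.collect_state(mod, name + "."))
        meta = {
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
                if k != "alphabet"
            },
            "alphabet": self._alphabet().symbols,
            "n_features_in": self.n_features_in_,
            "attr_dim": self.attr_dim_,
        }
        np.savez(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "ConditionalVAE":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        params = meta["params"]
        params["hidden_dims"] = tuple(params["hidden_dims"])
        model = cls(alphabet=Alphabet(meta["alphabet"]), **params)
        model._build(
            meta["n_features_in"], meta["attr_dim"], np.random.default_rng(0)
        )
        arrays = {k: data[k] for k in data.files if k != "_meta"}
        for name, mod in model._modules().items():
            _nn.load_arrays(mod, arrays, name + ".")
        model.loss_trace_ = []
        return model
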