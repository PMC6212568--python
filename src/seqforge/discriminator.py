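"""Multi-label metal-binding discriminator.

A feed-forward classifier predicting the 8-metal binding vector from a
flattened one-hot sequence: six layers of 1024, 512, 256, 128, 64 and 8
units, the first five being linear blocks (affine + batch norm + ReLU)
and the last an affine layer with sigmoid activation. Training minimizes
binary cross-entropy with per-metal weights proportional to the inverse
of each metal's positive count (counterbalancing class imbalance), uses
the same Adam settings as the VAE, holds out a family-disjoint
validation split, and early-stops by keeping the epoch checkpoint with
the lowest validation loss. It ranks generated candidate sequences by
predicted binding probability for a requested metal.
"""

from __future__ import annotations

import copy
import json

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import _nn
from ._nn import MLP, Adam, Dense, sigmoid
from .data_prep import METALS, SequenceRecord

_EPS = 1e-7  # prediction clamp for BCE stability


def weighted_bce(
    pred: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
    eps: float = _EPS,
) -> float:
    """Per-class weighted binary cross-entropy, summed over classes.

    Each class's weight multiplies both the positive and negative terms
    of its BCE contribution. For batched input the mean over samples is
    returned. Predictions are clamped to ``[eps, 1-eps]``.
    """
    p = np.clip(np.atleast_2d(np.asarray(pred, dtype=np.float64)), eps, 1.0 - eps)
    t = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if p.shape != t.shape:
        raise ValueError(f"pred shape {p.shape} != target shape {t.shape}")
    w = np.ones(p.shape[1]) if weights is None else np.asarray(weights, dtype=np.float64)
    per_class = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    return float((per_class * w).sum(axis=1).mean())


def inverse_frequency_weights(Y: np.ndarray) -> np.ndarray:
    """Per-metal loss weights proportional to 1 / positive count.

    Normalized to average 1 so the overall loss scale is unchanged.
    Metals with no positive examples get the largest finite weight seen.
    """
    Y = np.asarray(Y, dtype=np.float64)
    counts = Y.sum(axis=0)
    with np.errstate(divide="ignore"):
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1e-12), np.inf)
    finite = inv[np.isfinite(inv)]
    fill = finite.max() if finite.size else 1.0
    inv = np.where(np.isfinite(inv), inv, fill)
    return inv / inv.mean()


def family_split(
    records: list[SequenceRecord],
    fraction: float = 0.1,
    rng_seed: int = 0,
    force_validation: tuple[str, ...] = (),
) -> tuple[list[str], list[str]]:
    """Family-disjoint train/validation split of record ids.

    Families are atomic: all members land on the same side, preventing
    homology leakage between the sets. Validation receives about
    ``fraction`` of the sequences via greedy packing (largest families
    first, order randomized within ties by seed). Ids in
    ``force_validation`` drag their whole family into validation — the
    treatment given to designated held-out design targets.
    """
    missing = [r.id for r in records if r.family is None]
    if missing:
        raise ValueError(f"records without family labels: {missing[:5]}")
    fam_members: dict[str, list[str]] = {}
    for r in records:
        fam_members.setdefault(r.family, []).append(r.id)
    forced_families = {
        r.family for r in records if r.id in set(force_validation)
    }
    unknown = set(force_validation) - {r.id for r in records}
    if unknown:
        raise ValueError(f"force_validation ids not in records: {sorted(unknown)}")

    rng = np.random.default_rng(rng_seed)
    families = sorted(fam_members)
    rng.shuffle(families)
    families.sort(key=lambda f: -len(fam_members[f]))  # stable: keeps shuffle in ties

    target = fraction * len(records)
    val_fams = set(forced_families)
    val_count = sum(len(fam_members[f]) for f in val_fams)
    for fam in families:
        if fam in val_fams:
            continue
        if val_count >= target:
            break
        val_fams.add(fam)
        val_count += len(fam_members[fam])
    train_ids = [r.id for r in records if r.family not in val_fams]
    val_ids = [r.id for r in records if r.family in val_fams]
    if not train_ids or not val_ids:
        raise ValueError("split left one side empty; adjust fraction or data")
    return train_ids, val_ids


class MetalBindingClassifier(BaseEstimator):
    """Multi-label sequence -> 8-metal-flag classifier.

    Parameters mirror the VAE's optimizer settings; ``class_weight``
    is either ``"inverse_frequency"`` (default) or ``None`` for
    unweighted BCE.

    Attributes set by :meth:`fit` include ``best_epoch_`` (the epoch
    whose checkpoint minimized validation loss and whose parameters the
    fitted model carries), ``validation_losses_`` and ``class_weights_``.
    """

    def __init__(
        self,
        hidden_dims: tuple[int, ...] = (1024, 512, 256, 128, 64),
        n_outputs: int = len(METALS),
        learning_rate: float = 5e-4,
        batch_size: int = 512,
        beta1: float = 0.9,
        beta2: float = 0.9,
        max_epochs: int = 100,
        class_weight: str | None = "inverse_frequency",
        random_state: int = 0,
    ):
        self.hidden_dims = hidden_dims
        self.n_outputs = n_outputs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.beta1 = beta1
        self.beta2 = beta2
        self.max_epochs = max_epochs
        self.class_weight = class_weight
        self.random_state = random_state

    def _build(self, n_features: int, rng: np.random.Generator) -> None:
        self.trunk_ = MLP([n_features] + list(self.hidden_dims), rng)
        self.head_ = Dense(self.hidden_dims[-1], self.n_outputs, rng)
        self.n_features_in_ = n_features

    def _arrays(self, grads: bool = False):
        fn = _nn.collect_grads if grads else _nn.collect
        out = fn(self.trunk_, "trunk.")
        out.update(fn(self.head_, "head."))
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Per-metal binding probabilities, shape ``(n, 8)``."""
        check_is_fitted(self, "trunk_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        h = self.trunk_.forward(X, training=False)
        return sigmoid(self.head_.forward(h, training=False))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Thresholded multi-label prediction."""
        return (self.predict_proba(X) >= threshold).astype(int)

    def fit(self, X, Y, validation: tuple[np.ndarray, np.ndarray] | None = None):
        """Train with early stopping on a validation set.

        ``validation`` is an ``(X_val, Y_val)`` pair, normally built from
        a :func:`family_split`; if omitted, a random 10% sample is held
        out (no family structure assumed).
        """
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if X.shape[0] != Y.shape[0] or X.shape[0] == 0:
            raise ValueError("X and Y must be nonempty with matching rows")
        root = np.random.default_rng(self.random_state)
        init_rng, shuffle_rng = root.spawn(2)
        if validation is None:
            n_val = max(1, int(0.1 * X.shape[0]))
            order = shuffle_rng.permutation(X.shape[0])
            X, Y, X_val, Y_val = (
                X[order[n_val:]],
                Y[order[n_val:]],
                X[order[:n_val]],
                Y[order[:n_val]],
            )
        else:
            X_val = np.asarray(validation[0], dtype=np.float64)
            Y_val = np.asarray(validation[1], dtype=np.float64)
        if X_val.shape[0] == 0:
            raise ValueError("validation set is empty")

        self._build(X.shape[1], init_rng)
        self.class_weights_ = (
            inverse_frequency_weights(Y)
            if self.class_weight == "inverse_frequency"
            else np.ones(self.n_outputs)
        )
        opt = Adam(
            self._arrays(),
            lr=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
        )
        n = X.shape[0]
        batch = min(self.batch_size, n)
        w = self.class_weights_
        self.validation_losses_ = []
        best_loss = np.inf
        best_arrays = None
        self.best_epoch_ = -1
        for epoch in range(self.max_epochs):
            order = shuffle_rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start : start + batch]
                Xb, Yb = X[idx], Y[idx]
                B = Xb.shape[0]
                h = self.trunk_.forward(Xb, training=True)
                logits = self.head_.forward(h, training=True)
                p = sigmoid(logits)
                dlogits = w * (p - Yb) / B
                self.trunk_.backward(self.head_.backward(dlogits))
                opt.step(self._arrays(grads=True))
            val_loss = weighted_bce(self.predict_proba(X_val), Y_val, w)
            if not np.isfinite(val_loss):
                raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
            self.validation_losses_.append(val_loss)
            if val_loss < best_loss:
                best_loss = val_loss
                self.best_epoch_ = epoch
                best_arrays = {
                    k: v.copy()
                    for k, v in {
                        **self._arrays(),
                        **_nn.collect_state(self.trunk_, "trunk."),
                    }.items()
                }
        # restore the checkpoint that minimized validation loss
        _nn.load_arrays(self.trunk_, best_arrays, "trunk.")
        self.head_.W[...] = best_arrays["head.W"]
        self.head_.b[...] = best_arrays["head.b"]
        return self

    # -- candidate ranking -------------------------------------------------

    def rank_candidates(
        self, sequences: list[str], metal: str, encode=None
    ) -> list[tuple[str, float]]:
        """Order candidate sequences by predicted probability for ``metal``.

        Descending by probability; ties (including duplicated sequences)
        keep input order. ``encode`` maps a string to the model's input
        vector; by default the canonical one-hot codec at the width the
        model was trained on.
        """
        if not sequences:
            raise ValueError("no candidate sequences given")
        if metal not in METALS:
            raise ValueError(f"unknown metal {metal!r}; choose from {METALS}")
        if encode is None:
            from .codec import DEFAULT_ALPHABET, encode_sequence

            n_len = self.n_features_in_ // len(DEFAULT_ALPHABET)
            encode = lambda s: encode_sequence(s, DEFAULT_ALPHABET, n_len)
        X = np.stack([encode(s) for s in sequences])
        probs = self.predict_proba(X)[:, METALS.index(metal)]
        order = np.argsort(-probs, kind="stable")
        return [(sequences[i], float(probs[i])) for i in order]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "trunk_")
        arrays = self._arrays().copy()
        arrays.update(_nn.collect_state(self.trunk_, "trunk."))
        arrays["class_weights"] = self.class_weights_
        meta = {
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "n_features_in": self.n_features_in_,
            "best_epoch": self.best_epoch_,
        }
        np.savez(path, _meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "MetalBindingClassifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        params = meta["params"]
        params["hidden_dims"] = tuple(params["hidden_dims"])
        model = cls(**params)
        model._build(meta["n_features_in"], np.random.default_rng(0))
        arrays = {k: data[k] for k in data.files if k != "_meta"}
        _nn.load_arrays(model.trunk_, arrays, "trunk.")
        model.head_.W[...] = arrays["head.W"]
        model.head_.b[...] = arrays["head.b"]
        model.class_weights_ = arrays["class_weights"]
        model.best_epoch_ = meta["best_epoch"]
        model.validation_losses_ = []
        return model
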