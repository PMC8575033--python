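"""VAE embedding network with an attached tumour-type classifier.

The encoder maps an expression profile x in [0,1]^G to a Gaussian
posterior N(mu, diag sigma^2) over a low-dimensional latent space; the
decoder reconstructs x from a sample z = mu + sigma * eps; a softmax
classifier reads the deterministic mu vector (never a sample), so
prediction and attribution are reproducible bit for bit.

Training runs in two phases: an unsupervised phase minimizing the negative
ELBO alone, then a joint phase minimizing alpha * L_vae + beta * L_class.
The reconstruction likelihood is elementwise Bernoulli (binary
cross-entropy), appropriate for unit-interval-normalized expression; MSE
is available behind ``recon_loss="mse"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .expr_io import ExpressionMatrix
from .nncore import Adam, FeedForward, Linear, ReLU

__all__ = [
    "XOmiHyperparams",
    "XOmiModel",
    "reparameterize",
    "kl_unit_gaussian",
    "vae_loss",
    "classification_loss",
    "total_loss",
    "softmax",
    "train",
    "accuracy",
]

_LOGVAR_CLIP = 8.0


@dataclass
class XOmiHyperparams:
    """Training configuration; defaults follow the reference setting
    (128-dimensional latent space, Adam at 1e-3, batch 32, 50 unsupervised
    + 100 supervised epochs, two classifier hidden layers of 128 and 64).

    ``kl_weight`` scales the KL term relative to the per-gene-summed
    reconstruction likelihood during training. With thousands of genes a
    unit KL weight lets the posterior noise drown weak single-gene
    factors (posterior collapse); 0.1 keeps the latent space informative
    while still regularizing it. ``weight_decay`` applies decoupled
    (AdamW-style) L2 decay to the weight matrices. With
    ``standardize_latent`` the latent space is canonicalized after
    training to zero mean and unit per-dimension variance over the
    training samples — a pure reparameterization (weights of the
    adjoining layers absorb the affine map, so every network output is
    bit-for-bit unchanged) that gives latent-space interventions such as
    the sign-flip ablation a well-defined scale."""

    latent_dim: int = 128
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs_unsupervised: int = 50
    epochs_supervised: int = 100
    alpha: float = 1.0
    beta: float = 1.0
    kl_weight: float = 0.1
    weight_decay: float = 0.0
    standardize_latent: bool = True
    encoder_hidden: tuple[int, ...] = (1024,)
    classifier_hidden: tuple[int, ...] = (128, 64)
    recon_loss: str = "bce"
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.encoder_hidden = tuple(self.encoder_hidden)
        self.classifier_hidden = tuple(self.classifier_hidden)
        for name in ("latent_dim", "learning_rate", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.recon_loss not in ("bce", "mse"):
            raise ValueError("recon_loss must be 'bce' or 'mse'")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def reparameterize(mu: np.ndarray, sigma: np.ndarray,
                   eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps, elementwise."""
    mu, sigma, eps = (np.asarray(a, dtype=float) for a in (mu, sigma, eps))
    if not (mu.shape == sigma.shape == eps.shape):
        raise ValueError(
            f"shape mismatch: mu {mu.shape}, sigma {sigma.shape}, eps {eps.shape}")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive elementwise")
    return mu + sigma * eps


def kl_unit_gaussian(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL( N(mu, diag sigma^2) || N(0, I) ) = sum_j 1/2 (sigma_j^2 + mu_j^2
    - 1 - 2 ln sigma_j). For batched input returns the per-sample mean."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive elementwise")
    per_sample = 0.5 * (sigma ** 2 + mu ** 2 - 1.0 - 2.0 * np.log(sigma)).sum(axis=1)
    return float(per_sample.mean())


def _bce(x: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float((-(x * np.log(p) + (1 - x) * np.log(1 - p))).sum(axis=1).mean())


def vae_loss(x: np.ndarray, x_recon: np.ndarray, mu: np.ndarray,
             sigma: np.ndarray, recon_weight: float = 1.0,
             recon_loss: str = "bce") -> float:
    """Negative ELBO: reconstruction term (summed over genes, averaged over
    the batch) plus the KL term."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    x_recon = np.atleast_2d(np.asarray(x_recon, dtype=float))
    if x.shape != x_recon.shape:
        raise ValueError("x and x_recon shapes differ")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    if recon_loss == "bce":
        rec = _bce(x, x_recon)
    elif recon_loss == "mse":
        rec = float(((x - x_recon) ** 2).sum(axis=1).mean())
    else:
        raise ValueError("recon_loss must be 'bce' or 'mse'")
    return recon_weight * rec + kl_unit_gaussian(mu, sigma)


def classification_loss(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy of softmax(logits) against integer
    class indices y."""
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    y = np.asarray(y)
    if y.dtype.kind not in "iu":
        raise ValueError("y must contain integer class indices")
    n_classes = logits.shape[1]
    if np.any((y < 0) | (y >= n_classes)):
        bad = int(y[(y < 0) | (y >= n_classes)][0])
        raise ValueError(f"label index {bad} outside vocabulary of {n_classes}")
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(y)), y].mean())


def total_loss(l_vae: float, l_class: float, alpha: float, beta: float) -> float:
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    return alpha * l_vae + beta * l_class


class XOmiModel:
    """Trained encoder/decoder/classifier triple.

    The pieces are stored as explicit layer stacks so the attribution
    engine can walk any sub-path (genes -> mu, genes -> logit,
    mu -> logit) with access to every pre-activation.
    """

    def __init__(self, enc_trunk: FeedForward, mu_head: Linear,
                 logvar_head: Linear, decoder: FeedForward,
                 classifier: FeedForward, classes: list[str],
                 gene_ids: list[str], hyperparams: XOmiHyperparams):
        self.enc_trunk = enc_trunk
        self.mu_head = mu_head
        self.logvar_head = logvar_head
        self.decoder = decoder
        self.classifier = classifier
        self.classes = list(classes)
        self.gene_ids = list(gene_ids)
        self.hyperparams = hyperparams
        self.training_log: list[dict] = []
        self.train_idx: np.ndarray | None = None
        self.val_idx: np.ndarray | None = None

    # ---- construction -------------------------------------------------
    @classmethod
    def build(cls, n_genes: int, classes: list[str], h: XOmiHyperparams,
              gene_ids: list[str] | None = None) -> "XOmiModel":
        rng = np.random.default_rng(h.seed)
        widths = [n_genes, *h.encoder_hidden]
        trunk_layers: list = []
        for a, b in zip(widths[:-1], widths[1:]):
            trunk_layers += [Linear(a, b, rng), ReLU()]
        mu_head = Linear(widths[-1], h.latent_dim, rng)
        logvar_head = Linear(widths[-1], h.latent_dim, rng)
        dec_widths = [h.latent_dim, *reversed(h.encoder_hidden)]
        dec_layers: list = []
        for a, b in zip(dec_widths[:-1], dec_widths[1:]):
            dec_layers += [Linear(a, b, rng), ReLU()]
        dec_layers.append(Linear(dec_widths[-1], n_genes, rng))  # logits
        clf_widths = [h.latent_dim, *h.classifier_hidden]
        clf_layers: list = []
        for a, b in zip(clf_widths[:-1], clf_widths[1:]):
            clf_layers += [Linear(a, b, rng), ReLU()]
        clf_layers.append(Linear(clf_widths[-1], len(classes), rng))
        if gene_ids is None:
            gene_ids = [f"G{j:05d}" for j in range(n_genes)]
        return cls(FeedForward(trunk_layers), mu_head, logvar_head,
                   FeedForward(dec_layers), FeedForward(clf_layers),
                   classes, gene_ids, h)

    # ---- deterministic forward passes ----------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def latent_dim(self) -> int:
        return self.mu_head.W.shape[1]

    def _check_width(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_genes:
            raise ValueError(
                f"input has {x.shape[1]} genes but the model expects {self.n_genes}")
        return x

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic (mu, sigma) of the posterior; no sampling."""
        x = self._check_width(x)
        t = self.enc_trunk.forward(x)
        mu = self.mu_head.forward(t)
        logvar = np.clip(self.logvar_head.forward(t), -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return mu, np.exp(0.5 * logvar)

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, logits); the classifier consumes mu directly."""
        mu, _ = self.encode(x)
        logits = self.classifier.forward(mu)
        return softmax(logits), logits

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        probs, _ = self.predict(x)
        return np.array([self.classes[i] for i in probs.argmax(axis=1)],
                        dtype=object)

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        mu, _ = self.encode(x)
        from .nncore import Sigmoid
        return Sigmoid().f(self.decoder.forward(mu))

    def class_index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise KeyError(f"unknown class label {label!r}") from None

    # ---- attribution paths ---------------------------------------------
    def path_genes_to_mu(self) -> FeedForward:
        return FeedForward([*self.enc_trunk.layers, self.mu_head])

    def path_mu_to_logits(self) -> FeedForward:
        return FeedForward(list(self.classifier.layers))

    def path_genes_to_logits(self) -> FeedForward:
        return FeedForward([*self.enc_trunk.layers, self.mu_head,
                            *self.classifier.layers])

    # ---- persistence ----------------------------------------------------
    def _stacks(self) -> dict[str, list[Linear]]:
        return {
            "trunk": self.enc_trunk.param_layers(),
            "mu": [self.mu_head],
            "logvar": [self.logvar_head],
            "dec": self.decoder.param_layers(),
            "clf": self.classifier.param_layers(),
        }

    def save(self, path: str | Path) -> None:
        arrays = {}
        for name, layers in self._stacks().items():
            for i, lyr in enumerate(layers):
                arrays[f"{name}_{i}_W"] = lyr.W
                arrays[f"{name}_{i}_b"] = lyr.b
        meta = {
            "classes": self.classes,
            "gene_ids": self.gene_ids,
            "hyperparams": asdict(self.hyperparams),
            "training_log": self.training_log,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "XOmiModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            h = XOmiHyperparams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in meta["hyperparams"].items()})
            model = cls.build(len(meta["gene_ids"]), meta["classes"], h,
                              gene_ids=meta["gene_ids"])
            for name, layers in model._stacks().items():
                for i, lyr in enumerate(layers):
                    lyr.W = data[f"{name}_{i}_W"]
                    lyr.b = data[f"{name}_{i}_b"]
            model.training_log = meta["training_log"]
        return model


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train, val = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * len(idx)))) if val_fraction > 0 else 0
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(val, dtype=int))


def train(m: ExpressionMatrix, h: XOmiHyperparams) -> XOmiModel:
    """Two-phase training, fully determined by ``h.seed``.

    Phase 1 optimizes the negative ELBO alone for ``epochs_unsupervised``
    epochs; phase 2 optimizes ``alpha * L_vae + beta * L_class`` for
    ``epochs_supervised`` epochs with the classifier reading mu. A
    stratified ``val_fraction`` of samples is held out before training and
    recorded on the model (``train_idx`` / ``val_idx``).
    """
    X = np.asarray(m.values, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix has missing values; impute first")
    if np.any((X < 0) | (X > 1)):
        raise ValueError("matrix must be normalized to [0, 1]")
    supervised = h.epochs_supervised > 0
    if supervised and m.class_labels is None:
        raise ValueError("class labels required for the supervised phase")

    rng = np.random.default_rng(h.seed)
    if m.class_labels is not None:
        classes = sorted(set(map(str, m.class_labels)))
        y_all = np.array([classes.index(str(c)) for c in m.class_labels])
        tr_idx, val_idx = _stratified_split(np.asarray(m.class_labels),
                                            h.val_fraction, rng)
    else:
        classes = []
        y_all = None
        perm = rng.permutation(len(X))
        n_val = int(round(h.val_fraction * len(X)))
        val_idx, tr_idx = np.sort(perm[:n_val]), np.sort(perm[n_val:])

    model = XOmiModel.build(X.shape[1], classes, h, gene_ids=m.gene_ids)
    model.train_idx, model.val_idx = tr_idx, val_idx
    Xtr = X[tr_idx]
    ytr = y_all[tr_idx] if y_all is not None else None

    vae_layers = (model.enc_trunk.param_layers() + [model.mu_head,
                  model.logvar_head] + model.decoder.param_layers())
    opt1 = Adam(vae_layers, lr=h.learning_rate, weight_decay=h.weight_decay)
    opt2 = Adam(vae_layers + model.classifier.param_layers(),
                lr=h.learning_rate, weight_decay=h.weight_decay)

    def run_phase(phase: int, n_epochs: int, opt: Adam,
                  alpha: float, beta: float) -> None:
        n = len(Xtr)
        for epoch in range(n_epochs):
            order = rng.permutation(n)
            ep_vae, ep_cls, n_batches = 0.0, 0.0, 0
            for start in range(0, n, h.batch_size):
                idx = order[start:start + h.batch_size]
                x = Xtr[idx]
                B = len(x)
                t = model.enc_trunk.forward(x)
                mu = model.mu_head.forward(t)
                raw_lv = model.logvar_head.forward(t)
                logvar = np.clip(raw_lv, -_LOGVAR_CLIP, _LOGVAR_CLIP)
                lv_mask = (np.abs(raw_lv) < _LOGVAR_CLIP).astype(float)
                sigma = np.exp(0.5 * logvar)
                eps = rng.standard_normal(mu.shape)
                z = mu + sigma * eps
                dec_logits = model.decoder.forward(z)
                p = 1.0 / (1.0 + np.exp(-dec_logits))

                if h.recon_loss == "bce":
                    rec = _bce(x, p)
                    g_dec = (p - x) / B
                else:
                    rec = float(((x - p) ** 2).sum(axis=1).mean())
                    g_dec = (-2.0 * (x - p) * p * (1 - p)) / B
                kl = 0.5 * float((sigma ** 2 + mu ** 2 - 1 - logvar).sum(axis=1).mean())
                klw = h.kl_weight
                l_vae = rec + klw * kl
                l_cls = 0.0

                g_z = model.decoder.backward(alpha * g_dec)
                g_mu = alpha * (g_z + klw * mu / B)
                g_lv = alpha * (g_z * eps * sigma * 0.5
                                + klw * 0.5 * (sigma ** 2 - 1.0) / B) * lv_mask
                if beta > 0 and ytr is not None:
                    logits = model.classifier.forward(mu)
                    yb = ytr[idx]
                    l_cls = classification_loss(logits, yb)
                    probs = softmax(logits)
                    probs[np.arange(B), yb] -= 1.0
                    g_mu = g_mu + beta * model.classifier.backward(probs / B)
                g_t = (model.mu_head.backward(g_mu)
                       + model.logvar_head.backward(g_lv))
                model.enc_trunk.backward(g_t)

                loss = alpha * l_vae + beta * l_cls
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at phase {phase}, epoch {epoch}, "
                        f"batch {start // h.batch_size}")
                opt.step()
                ep_vae += l_vae
                ep_cls += l_cls
                n_batches += 1
            model.training_log.append({
                "phase": phase, "epoch": epoch,
                "vae_loss": ep_vae / n_batches,
                "class_loss": ep_cls / n_batches,
            })

    run_phase(1, h.epochs_unsupervised, opt1, alpha=1.0, beta=0.0)
    if supervised:
        run_phase(2, h.epochs_supervised, opt2, alpha=h.alpha, beta=h.beta)
    if h.standardize_latent:
        standardize_latent_space(model, Xtr)
    return model


def standardize_latent_space(model: XOmiModel, X: np.ndarray) -> None:
    """Canonicalize mu to zero mean / unit variance over ``X`` in place.

    Latent units are arbitrary: any per-dimension affine map of mu can be
    absorbed by the adjoining layers. This folds mu' = (mu - c) / s into
    the mu head and compensates the classifier and decoder first layers
    and the logvar head bias, so every output of the network (logits,
    reconstructions, z samples) is exactly unchanged while latent-space
    statistics and interventions gain a fixed scale. Dimensions with
    (near-)zero variance are centred but not rescaled.
    """
    mu, _ = model.encode(X)
    c = mu.mean(axis=0)
    s = mu.std(axis=0)
    s = np.where(s > 1e-6, s, 1.0)
    model.mu_head.W = model.mu_head.W / s
    model.mu_head.b = (model.mu_head.b - c) / s
    model.logvar_head.b = model.logvar_head.b - 2.0 * np.log(s)
    for stack in (model.classifier, model.decoder):
        first = stack.param_layers()[0]
        first.b = first.b + c @ first.W
        first.W = first.W * s[:, np.newaxis]


def accuracy(model: XOmiModel, m: ExpressionMatrix,
             idx: np.ndarray | None = None) -> float:
    """Classification accuracy; ``idx=None`` uses every sample,
    ``idx="val"`` the recorded held-out split."""
    if isinstance(idx, str) and idx == "val":
        idx = model.val_idx
    X = m.values if idx is None else m.values[idx]
    y = m.class_labels if idx is None else m.class_labels[idx]
    pred = model.predict_labels(X)
    return float((pred == np.asarray(y, dtype=object)).mean())
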