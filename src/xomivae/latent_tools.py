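"""Unsupervised latent-space explanation and dimension ablation.

Two tools: Welch's t-test over the latent mu vectors ranks the dimensions
that separate two sample groups (no labels needed beyond the grouping
itself), and sign-flip ablation measures how much the classifier actually
depends on a dimension by replacing mu_j with -1 when positive and +1
when negative — a perturbation guaranteed to move the value regardless of
its sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .expr_io import ExpressionMatrix
from .model import XOmiModel, softmax

__all__ = [
    "LatentGroupStats",
    "AblationSpec",
    "AblatedModel",
    "welch_rank_dimensions",
    "ablate",
    "ablation_study",
    "DEFAULT_POSITIONS",
]


@dataclass
class LatentGroupStats:
    """Per-dimension Welch statistics between two sample groups."""

    mean_a: np.ndarray
    sd_a: np.ndarray
    n_a: int
    mean_b: np.ndarray
    sd_b: np.ndarray
    n_b: int
    t_statistic: np.ndarray
    welch_df: np.ndarray
    p_value: np.ndarray
    ranked_dims: list[int]
    degenerate: list[int]  # dims with zero variance in both groups

    @property
    def top_dim(self) -> int:
        return self.ranked_dims[0]

    def to_frame(self) -> pd.DataFrame:
        order = self.ranked_dims
        return pd.DataFrame({
            "dim": order,
            "t": self.t_statistic[order],
            "df": self.welch_df[order],
            "p": self.p_value[order],
            "mean_a": self.mean_a[order], "sd_a": self.sd_a[order],
            "mean_b": self.mean_b[order], "sd_b": self.sd_b[order],
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def welch_rank_dimensions(mu_a: np.ndarray, mu_b: np.ndarray) -> LatentGroupStats:
    """Welch's two-sample t-test per latent dimension.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    Dimensions are ranked by p ascending, ties by |t| descending then dim
    index. A dimension with zero variance in both groups has no defined t
    and is assigned p = 1 and flagged.
    """
    A = np.atleast_2d(np.asarray(mu_a, dtype=float))
    B = np.atleast_2d(np.asarray(mu_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups have different latent dimensionality")
    n_a, n_b = len(A), len(B)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two samples")
    m_a, m_b = A.mean(axis=0), B.mean(axis=0)
    s_a, s_b = A.std(axis=0, ddof=1), B.std(axis=0, ddof=1)
    va, vb = s_a ** 2 / n_a, s_b ** 2 / n_b
    denom2 = va + vb
    degenerate = np.flatnonzero(denom2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m_a - m_b) / np.sqrt(denom2)
        df = denom2 ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    p = np.ones_like(t)
    ok = denom2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    t[~ok] = np.nan
    df[~ok] = np.nan
    abs_t = np.where(np.isnan(t), 0.0, np.abs(t))
    order = sorted(range(A.shape[1]), key=lambda j: (p[j], -abs_t[j], j))
    return LatentGroupStats(m_a, s_a, n_a, m_b, s_b, n_b, t, df, p,
                            ranked_dims=order,
                            degenerate=[int(j) for j in degenerate])


@dataclass(frozen=True)
class AblationSpec:
    """Latent dimensions to knock out by the sign-flip rule."""

    dim_indices: tuple[int, ...]

    def __init__(self, dim_indices) -> None:
        object.__setattr__(self, "dim_indices",
                           tuple(int(j) for j in dim_indices))


class AblatedModel:
    """Forward pass with selected mu coordinates sign-flipped to -/+1.

    mu_j > 0 is fed to the classifier as -1, mu_j < 0 as +1, exactly 0 is
    left unchanged. The wrapped model is not modified.
    """

    def __init__(self, model: XOmiModel, spec: AblationSpec):
        for j in spec.dim_indices:
            if not 0 <= j < model.latent_dim:
                raise IndexError(f"latent index {j} out of range "
                                 f"({model.latent_dim} dims)")
        self.model = model
        self.spec = spec

    def ablate_mu(self, mu: np.ndarray) -> np.ndarray:
        mu = mu.copy()
        idx = list(self.spec.dim_indices)
        if idx:
            sub = mu[:, idx]
            mu[:, idx] = np.where(sub > 0, -1.0, np.where(sub < 0, 1.0, sub))
        return mu

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, _ = self.model.encode(x)
        logits = self.model.classifier.forward(self.ablate_mu(mu))
        return softmax(logits), logits

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        probs, _ = self.predict(x)
        return np.array([self.model.classes[i] for i in probs.argmax(axis=1)],
                        dtype=object)


def ablate(model: XOmiModel | AblatedModel, spec: AblationSpec) -> AblatedModel:
    """Wrap a model so the listed dims are sign-flipped during predict.

    The flip is always computed from the clean encoder output, so ablating
    an already-ablated model with the same spec changes nothing
    (idempotence); ablating with a different spec ablates the union.
    """
    if isinstance(model, AblatedModel):
        merged = AblationSpec(set(model.spec.dim_indices) | set(spec.dim_indices))
        return AblatedModel(model.model, merged)
    return AblatedModel(model, spec)


DEFAULT_POSITIONS: dict[str, tuple[int, ...]] = {
    "1st": (0,), "2nd": (1,), "3rd": (2,), "top3": (0, 1, 2),
    "3rd_last": (-3,), "2nd_last": (-2,), "last": (-1,),
    "bottom3": (-3, -2, -1), "none": (),
}


def _class_recall(pred: np.ndarray, y: np.ndarray, cls: str) -> float:
    mask = y == cls
    return float((pred[mask] == cls).mean())


def ablation_study(model: XOmiModel, m: ExpressionMatrix,
                   ranked_dims, positions: dict[str, tuple[int, ...]] | None = None,
                   sample_idx: np.ndarray | str | None = "val") -> pd.DataFrame:
    """Accuracy change per class when ranked dimensions are knocked out.

    ``ranked_dims`` is either one ordered dimension list applied to every
    class, or a mapping ``{class_label: ordered dims}`` so each class is
    ablated by its own ranking. ``positions`` maps a row name to index
    positions within the ranking (negative = from the least important
    end). Accuracy is one-vs-rest recall per class, evaluated on the
    recorded held-out split by default; the table carries per-class
    changes plus their mean and sd.
    """
    if positions is None:
        positions = DEFAULT_POSITIONS
    if isinstance(sample_idx, str) and sample_idx == "val":
        sample_idx = model.val_idx
    X = m.values if sample_idx is None else m.values[sample_idx]
    y = np.asarray(m.class_labels if sample_idx is None
                   else m.class_labels[sample_idx], dtype=object)
    if len(X) == 0:
        raise ValueError("empty evaluation set")
    classes = [c for c in model.classes if (y == c).any()]
    if not isinstance(ranked_dims, dict):
        seq = [int(d) for d in ranked_dims]
        ranked_dims = {c: seq for c in classes}
    base_pred = model.predict_labels(X)
    base = {c: _class_recall(base_pred, y, c) for c in classes}

    rows = {}
    for name, pos in positions.items():
        deltas = []
        for c in classes:
            ranking = ranked_dims[c]
            dims = [ranking[p] for p in pos]
            pred = ablate(model, AblationSpec(dims)).predict_labels(X)
            deltas.append(_class_recall(pred, y, c) - base[c])
        rows[name] = deltas
    df = pd.DataFrame.from_dict(rows, orient="index", columns=classes)
    df["mean"] = df[classes].mean(axis=1)
    df["sd"] = df[classes].std(axis=1, ddof=0)
    return df
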