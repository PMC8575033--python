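"""Difference-from-reference attribution with the DeepLIFT rescale rule.

Each explained sample x is compared against one or more reference profiles
r. Contributions are computed by propagating multipliers backward through
the network: linear layers propagate by the transposed weights; an
elementwise nonlinearity f contributes the finite-difference slope
(f(a) - f(a_ref)) / (a - a_ref), falling back to the local gradient when
the pre-activation difference underflows. The resulting per-feature scores
satisfy summation-to-delta exactly: for every (sample, reference) pair the
scores sum to f(x) - f(r) at the chosen output.

Targets are either a class logit (pre-activation — never the softmax
probability, which saturates) or a latent coordinate mu_j; the feature
space may be the input genes or the latent mu layer (for latent -> class
explanations of the classifier sub-network). With several references the
engine attributes against each reference separately and averages the
per-reference contributions — not the contribution against an averaged
reference, which differs for nonlinear networks.

Gradient-based baselines (saliency, input x gradient, gradient-SHAP) are
provided for comparison; they share the same interface but do not satisfy
summation-to-delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix
from .model import XOmiModel
from .nncore import Activation, FeedForward, Linear

__all__ = [
    "TargetSpec",
    "ReferenceSet",
    "AttributionResult",
    "RankedGeneList",
    "deeplift_rescale",
    "attribute",
    "aggregate_abs_mean",
    "explain_class_by_genes",
    "explain_class_by_latent",
    "explain_latent_by_genes",
    "baseline_attribution",
    "build_reference_set",
]

FALLBACK_EPS = 1e-7


@dataclass(frozen=True)
class TargetSpec:
    """What to explain: which scalar output, over which feature space."""

    kind: str  # "class_logit" | "latent_dim"
    index: int
    layer: str = "input_genes"  # "input_genes" | "latent_mu"

    def __post_init__(self) -> None:
        if self.kind not in ("class_logit", "latent_dim"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.layer not in ("input_genes", "latent_mu"):
            raise ValueError(f"unknown feature layer {self.layer!r}")
        if self.kind == "latent_dim" and self.layer == "latent_mu":
            raise ValueError("a latent dimension cannot be explained over "
                             "the latent layer itself")


@dataclass
class ReferenceSet:
    """Background profiles the explained samples are compared against."""

    profiles: np.ndarray
    strategy: str = "custom"  # "random_train" | "phenotype_matched" | "custom"
    seed: int | None = None
    feature_space: str = "input_genes"

    def __post_init__(self) -> None:
        self.profiles = np.atleast_2d(np.asarray(self.profiles, dtype=float))
        if self.profiles.shape[0] < 1:
            raise ValueError("reference set needs at least one profile")

    @property
    def k_refs(self) -> int:
        return self.profiles.shape[0]

    def summary(self) -> dict:
        return {"strategy": self.strategy, "k_refs": self.k_refs,
                "seed": self.seed, "feature_space": self.feature_space}


@dataclass
class AttributionResult:
    """Per-sample, per-feature contribution scores for one target.

    ``scores`` are averaged over references; ``delta_o`` is
    f(x) - mean_r f(r) per sample, which the averaged scores sum to.
    """

    scores: np.ndarray
    delta_o: np.ndarray
    feature_ids: list[str]
    target: TargetSpec
    reference: dict
    method: str = "deepshap"

    def summation_gap(self) -> np.ndarray:
        """Relative |sum(scores) - delta_o| per sample."""
        s = self.scores.sum(axis=1)
        return np.abs(s - self.delta_o) / (np.abs(self.delta_o) + 1e-6)

    def write_tsv(self, path: str | Path, sample_ids=None) -> None:
        idx = sample_ids if sample_ids is not None else range(len(self.scores))
        pd.DataFrame(self.scores, index=idx, columns=self.feature_ids).to_csv(
            path, sep="\t")


@dataclass
class RankedGeneList:
    """Features ordered by aggregated contribution, best first.

    Scores are non-negative (absolute-mean aggregation) and
    non-increasing; ties break deterministically by feature id.
    """

    gene_ids: list[str]
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_scores(cls, gene_ids, scores, provenance=None) -> "RankedGeneList":
        scores = np.asarray(scores, dtype=float)
        order = sorted(range(len(gene_ids)),
                       key=lambda i: (-scores[i], str(gene_ids[i])))
        return cls([str(gene_ids[i]) for i in order], scores[order],
                   provenance or {})

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]

    def bottom(self, k: int) -> list[str]:
        return self.gene_ids[-k:]

    def rank_of(self, gene_id: str) -> int:
        """1-based rank."""
        try:
            return self.gene_ids.index(str(gene_id)) + 1
        except ValueError:
            raise KeyError(f"{gene_id!r} not in ranking") from None

    def ranks(self) -> dict[str, int]:
        return {g: i + 1 for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rank": np.arange(1, len(self) + 1),
                             "gene_id": self.gene_ids, "score": self.scores})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RankedGeneList":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        return cls(list(df["gene_id"]), df["score"].to_numpy())


def _check_stack(stack: FeedForward) -> None:
    for lyr in stack.layers:
        if not isinstance(lyr, (Linear, Activation)):
            raise TypeError(
                f"unsupported layer type for attribution: {type(lyr).__name__}")


def deeplift_rescale(stack: FeedForward, samples: np.ndarray,
                     refs: np.ndarray, out_index: int,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Rescale-rule attribution of ``stack`` output ``out_index``.

    Returns ``(scores, delta_o)`` where scores (n_samples, n_features) are
    the contributions averaged over the reference rows and delta_o is
    f(x) - mean_r f(r). Summation-to-delta holds per (sample, reference)
    pair before averaging, hence also after.
    """
    _check_stack(stack)
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    R = np.atleast_2d(np.asarray(refs, dtype=float))
    if X.shape[1] != R.shape[1]:
        raise ValueError(
            f"feature mismatch: samples have {X.shape[1]}, refs {R.shape[1]}")
    n_out = stack.n_out
    if not 0 <= out_index < n_out:
        raise IndexError(f"output index {out_index} out of range ({n_out})")

    acts_x = stack.forward_all(X)
    # keep copies: layer caches are overwritten by the reference pass
    acts_x = [a.copy() for a in acts_x]
    total = np.zeros_like(X)
    f_x = acts_x[-1][:, out_index]
    f_r_sum = np.zeros(len(X))
    for r in R:
        acts_r = stack.forward_all(r[np.newaxis, :])
        m = np.zeros((len(X), n_out))
        m[:, out_index] = 1.0
        for i in range(len(stack.layers) - 1, -1, -1):
            lyr = stack.layers[i]
            if isinstance(lyr, Linear):
                m = m @ lyr.W.T
            else:
                a_x, a_r = acts_x[i], acts_r[i]
                out_x, out_r = acts_x[i + 1], acts_r[i + 1]
                da = a_x - a_r
                with np.errstate(divide="ignore", invalid="ignore"):
                    slope = (out_x - out_r) / da
                m = m * np.where(np.abs(da) < FALLBACK_EPS,
                                 lyr.fprime(a_x), slope)
        total += m * (X - r)
        f_r_sum += acts_r[-1][0, out_index]
    scores = total / len(R)
    delta_o = f_x - f_r_sum / len(R)
    return scores, delta_o


def _resolve(model, target: TargetSpec,
             ) -> tuple[FeedForward, int, list[str]]:
    """Map (model, target) to (layer stack, output index, feature ids)."""
    if isinstance(model, FeedForward):
        ids = [f"x{j}" for j in range(model.n_in)]
        return model, target.index, ids
    if not isinstance(model, XOmiModel):
        raise TypeError(f"cannot attribute over {type(model).__name__}")
    if target.kind == "class_logit":
        if not 0 <= target.index < len(model.classes):
            raise IndexError(f"class index {target.index} out of range "
                             f"({len(model.classes)} classes)")
        if target.layer == "input_genes":
            return model.path_genes_to_logits(), target.index, list(model.gene_ids)
        return (model.path_mu_to_logits(), target.index,
                [f"dim{j}" for j in range(model.latent_dim)])
    if not 0 <= target.index < model.latent_dim:
        raise IndexError(f"latent index {target.index} out of range "
                         f"({model.latent_dim} dims)")
    return model.path_genes_to_mu(), target.index, list(model.gene_ids)


def _as_array(samples) -> np.ndarray:
    if isinstance(samples, ExpressionMatrix):
        return samples.values
    return np.atleast_2d(np.asarray(samples, dtype=float))


def attribute(model, samples, refs: ReferenceSet,
              target: TargetSpec) -> AttributionResult:
    """Rescale-rule attribution of a model target over samples."""
    stack, out_index, ids = _resolve(model, target)
    X = _as_array(samples)
    if refs.feature_space != target.layer and not isinstance(model, FeedForward):
        raise ValueError(
            f"reference set lives in {refs.feature_space!r} but the target "
            f"is attributed over {target.layer!r}")
    scores, delta_o = deeplift_rescale(stack, X, refs.profiles, out_index)
    return AttributionResult(scores, delta_o, ids, target, refs.summary())


def aggregate_abs_mean(res: AttributionResult,
                       sample_mask: np.ndarray | None = None) -> RankedGeneList:
    """Mean absolute contribution per feature over (a subset of) samples,
    sorted descending. Taking |.| first keeps positive and negative
    contributions from cancelling across samples."""
    if sample_mask is None:
        sub = res.scores
    else:
        sample_mask = np.asarray(sample_mask)
        if sample_mask.dtype == bool:
            if not sample_mask.any():
                raise ValueError("empty sample mask")
            sub = res.scores[sample_mask]
        else:
            if len(sample_mask) == 0:
                raise ValueError("empty sample mask")
            sub = res.scores[sample_mask]
    agg = np.abs(sub).mean(axis=0)
    prov = {"target": (res.target.kind, res.target.index, res.target.layer),
            "reference": res.reference, "n_samples": int(len(sub)),
            "method": res.method}
    return RankedGeneList.from_scores(res.feature_ids, agg, prov)


def explain_class_by_genes(model: XOmiModel, class_label: str, samples,
                           refs: ReferenceSet) -> RankedGeneList:
    """Gene ranking for one class: attribute the class logit over the
    input genes for the given samples, then aggregate by absolute mean."""
    target = TargetSpec("class_logit", model.class_index(class_label),
                        "input_genes")
    res = attribute(model, samples, refs, target)
    out = aggregate_abs_mean(res)
    out.provenance["class_label"] = class_label
    return out


def explain_class_by_latent(model: XOmiModel, class_label: str, samples,
                            refs: ReferenceSet) -> RankedGeneList:
    """Latent-dimension ranking for one class: intercept the classifier's
    input (the mu layer) and attribute the class logit over it."""
    target = TargetSpec("class_logit", model.class_index(class_label),
                        "latent_mu")
    X = _as_array(samples)
    if X.shape[1] == model.n_genes:
        X, _ = model.encode(X)
    refs_mu = refs
    if refs.feature_space == "input_genes":
        mu_r, _ = model.encode(refs.profiles)
        refs_mu = ReferenceSet(mu_r, refs.strategy, refs.seed, "latent_mu")
    res = attribute(model, X, refs_mu, target)
    out = aggregate_abs_mean(res)
    out.provenance["class_label"] = class_label
    return out


def explain_latent_by_genes(model: XOmiModel, dim_index: int, samples,
                            refs: ReferenceSet) -> RankedGeneList:
    """Gene ranking for one latent dimension mu_j (deterministic head)."""
    target = TargetSpec("latent_dim", int(dim_index), "input_genes")
    res = attribute(model, samples, refs, target)
    return aggregate_abs_mean(res)


def baseline_attribution(method: str, model, samples, refs: ReferenceSet,
                         target: TargetSpec, n_draws: int = 50,
                         seed: int = 0) -> AttributionResult:
    """Gradient-based comparison methods.

    saliency:          |d f / d x_i|
    input_x_gradient:  x_i * d f / d x_i
    gradient_shap:     mean over draws of (x_i - r_i) * d f / d x at
                       r + u (x - r), u ~ U(0,1), r sampled from refs
    """
    stack, out_index, ids = _resolve(model, target)
    X = _as_array(samples)
    R = refs.profiles
    if method == "saliency":
        scores = np.abs(stack.gradient(X, out_index))
    elif method == "input_x_gradient":
        scores = X * stack.gradient(X, out_index)
    elif method == "gradient_shap":
        rng = np.random.default_rng(seed)
        acc = np.zeros_like(X)
        for _ in range(n_draws):
            r = R[rng.integers(0, len(R), size=len(X))]
            u = rng.random((len(X), 1))
            point = r + u * (X - r)
            acc += (X - r) * stack.gradient(point, out_index)
        scores = acc / n_draws
    else:
        raise ValueError(f"unknown attribution method {method!r}")
    f_x = stack.forward(X)[:, out_index]
    f_r = stack.forward(R)[:, out_index].mean()
    return AttributionResult(scores, f_x - f_r, ids, target, refs.summary(),
                             method=method)


def build_reference_set(m: ExpressionMatrix, strategy: str = "random_train",
                        k_refs: int = 100,
                        phenotype_filter: str | None = None,
                        seed: int = 0) -> ReferenceSet:
    """Draw reference profiles from a dataset.

    ``random_train`` samples ``k_refs`` rows uniformly without replacement
    (all rows if fewer). ``phenotype_matched`` restricts to rows matching
    a ``"name==value"`` filter, where name is ``class`` (the class label)
    or a phenotype column such as ``sex``.
    """
    rng = np.random.default_rng(seed)
    if strategy == "random_train":
        pool = np.arange(m.n_samples)
    elif strategy == "phenotype_matched":
        if not phenotype_filter or "==" not in phenotype_filter:
            raise ValueError("phenotype_matched needs a 'name==value' filter")
        name, value = (s.strip() for s in phenotype_filter.split("==", 1))
        if name == "class":
            if m.class_labels is None:
                raise ValueError("matrix has no class labels")
            mask = np.asarray(m.class_labels, dtype=object) == value
        else:
            if m.phenotypes is None or name not in m.phenotypes.columns:
                raise ValueError(f"unknown phenotype column {name!r}")
            mask = (m.phenotypes[name].astype(str) == value).to_numpy()
        pool = np.flatnonzero(mask)
        if len(pool) == 0:
            raise ValueError(f"filter {phenotype_filter!r} matches no sample")
    else:
        raise ValueError(f"unknown reference strategy {strategy!r}")
    take = min(k_refs, len(pool))
    rows = np.sort(rng.choice(pool, size=take, replace=False))
    return ReferenceSet(m.values[rows], strategy=strategy, seed=seed)
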