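"""Validation machinery for ranked gene lists.

Given a ranking produced by the attribution engine, these tools measure
whether the top of the list is enriched for a curated (or planted) gene
set — via a thresholded ROC curve — and whether the top genes carry real
signal, via retraining a fresh classifier on only those genes and
comparing it with random-gene controls. A rank-sum combiner aggregates
per-class rankings into an overall importance ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .attribution import (RankedGeneList, TargetSpec, aggregate_abs_mean,
                          baseline_attribution, build_reference_set,
                          explain_class_by_genes)
from .expr_io import ExpressionMatrix
from .model import XOmiHyperparams, XOmiModel, train
from .synthetic import GroundTruth

__all__ = [
    "EvalCurve",
    "RetrainReport",
    "roc_against_gene_set",
    "compare_methods",
    "retrain_top_k",
    "rank_sum_overall",
    "overlap_count",
    "one_vs_rest_metrics",
]


@dataclass
class EvalCurve:
    """ROC curve of a gene ranking against a truth gene set."""

    thresholds: list[int]
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "tpr": self.tpr, "fpr": self.fpr})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def roc_against_gene_set(ranked: RankedGeneList, truth_set,
                         n_thresholds: int = 100) -> EvalCurve:
    """TPR/FPR of top-k membership in ``truth_set`` over a grid of k.

    Thresholds are spaced evenly from 1 to the number of genes (both ends
    forced into the grid). At cutoff k,
    TPR = |top-k intersect truth| / |truth| and
    FPR = |top-k minus truth| / (n_genes - |truth|);
    AUC is the trapezoid area under (FPR, TPR) including the (0, 0) origin.
    """
    universe = list(ranked.gene_ids)
    truth = {str(g) for g in truth_set}
    if not truth:
        raise ValueError("truth gene set is empty")
    missing = truth - set(universe)
    if missing:
        raise ValueError(f"truth genes absent from ranking: {sorted(missing)[:5]}")
    n = len(universe)
    if len(truth) >= n:
        raise ValueError("truth set covers the whole gene universe")
    ks = np.unique(np.round(np.linspace(1, n, min(n_thresholds, n))).astype(int))
    ks[0], ks[-1] = 1, n
    is_true = np.array([g in truth for g in universe])
    cum_tp = np.cumsum(is_true)
    tp = cum_tp[ks - 1]
    fp = ks - tp
    tpr = tp / len(truth)
    fpr = fp / (n - len(truth))
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr, fpr))
    return EvalCurve([0, *ks.tolist()], tpr, fpr, auc)


def compare_methods(model: XOmiModel, m: ExpressionMatrix, truth: GroundTruth,
                    methods=("deepshap", "saliency", "input_x_gradient",
                             "gradient_shap", "random"),
                    k_refs: int = 50, samples_per_class: int | None = 30,
                    n_random_seeds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean planted-recovery ROC-AUC per attribution method.

    For each class, genes are ranked by the method and scored against the
    class's planted gene set; the table reports the mean and sd of the
    AUC across classes (the random arm averages fresh shuffles over
    ``n_random_seeds`` seeds).
    """
    labels = np.asarray(m.class_labels, dtype=object)
    refs = build_reference_set(m, "random_train", k_refs=k_refs, seed=seed)
    rows = []
    for method in methods:
        aucs = []
        for cls in model.classes:
            truth_ids = set(truth.planted_gene_ids(m, cls))
            idx = np.flatnonzero(labels == cls)
            if samples_per_class is not None:
                idx = idx[:samples_per_class]
            X = m.values[idx]
            if method == "random":
                rng = np.random.default_rng(seed)
                vals = []
                for _ in range(n_random_seeds):
                    order = rng.permutation(m.n_genes)
                    ranking = RankedGeneList(
                        [m.gene_ids[j] for j in order],
                        np.linspace(1, 0, m.n_genes))
                    vals.append(roc_against_gene_set(ranking, truth_ids).auc)
                aucs.append(float(np.mean(vals)))
                continue
            if method == "deepshap":
                ranking = explain_class_by_genes(model, cls, X, refs)
            else:
                target = TargetSpec("class_logit", model.class_index(cls),
                                    "input_genes")
                res = baseline_attribution(method, model, X, refs, target,
                                           seed=seed)
                ranking = aggregate_abs_mean(res)
            aucs.append(roc_against_gene_set(ranking, truth_ids).auc)
        rows.append({"method": method, "mean_auc": float(np.mean(aucs)),
                     "sd_auc": float(np.std(aucs))})
    return pd.DataFrame(rows).set_index("method")


def one_vs_rest_metrics(model: XOmiModel, m: ExpressionMatrix,
                        target_class: str,
                        idx: np.ndarray | str | None = "val") -> dict[str, float]:
    """F1 / PPV / TPR / AUC of one class against the rest."""
    if isinstance(idx, str) and idx == "val":
        idx = model.val_idx
    X = m.values if idx is None else m.values[idx]
    y = np.asarray(m.class_labels if idx is None else m.class_labels[idx],
                   dtype=object)
    probs, _ = model.predict(X)
    c = model.class_index(target_class)
    y_true = (y == target_class).astype(int)
    y_pred = (probs.argmax(axis=1) == c).astype(int)
    out = {
        "F1": float(skm.f1_score(y_true, y_pred, zero_division=0)),
        "PPV": float(skm.precision_score(y_true, y_pred, zero_division=0)),
        "TPR": float(skm.recall_score(y_true, y_pred, zero_division=0)),
    }
    if y_true.min() == y_true.max():
        out["AUC"] = float("nan")
    else:
        out["AUC"] = float(skm.roc_auc_score(y_true, probs[:, c]))
    return out


@dataclass
class RetrainReport:
    """Metrics of models retrained on selected vs random gene subsets."""

    target_class: str
    k: int
    n_random_seeds: int
    selected_target: dict[str, float]
    random_target_mean: dict[str, float]
    random_target_sd: dict[str, float]
    selected_others: dict[str, float]
    random_others_mean: dict[str, float]
    random_others_sd: dict[str, float]
    selected_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for metric in ("F1", "PPV", "TPR", "AUC"):
            rows[metric] = {
                "target_selected": self.selected_target[metric],
                "target_random_mean": self.random_target_mean[metric],
                "target_random_sd": self.random_target_sd[metric],
                "others_selected": self.selected_others[metric],
                "others_random_mean": self.random_others_mean[metric],
                "others_random_sd": self.random_others_sd[metric],
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _evaluate_arm(m: ExpressionMatrix, genes: list[str],
                  target_class: str, h: XOmiHyperparams,
                  ) -> tuple[dict[str, float], dict[str, float]]:
    sub = m.subset_genes(genes)
    model = train(sub, h)
    tgt = one_vs_rest_metrics(model, sub, target_class)
    others = [one_vs_rest_metrics(model, sub, c)
              for c in model.classes if c != target_class]
    macro = {k: float(np.nanmean([o[k] for o in others])) for k in tgt}
    return tgt, macro


def retrain_top_k(m: ExpressionMatrix, ranked: RankedGeneList,
                  target_class: str, k: int = 20, n_random_seeds: int = 10,
                  hyperparams: XOmiHyperparams | None = None,
                  seed: int = 0) -> RetrainReport:
    """Retrain fresh models on the top-k ranked genes and on k random
    genes (one model per random seed) and compare one-vs-rest metrics for
    the target class and the macro-average over the other classes.
    Hyperparameters are inherited except for the input width; each arm
    gets a fresh training seed.
    """
    if k >= m.n_genes:
        raise ValueError(f"k={k} must be smaller than n_genes={m.n_genes}")
    if m.class_labels is None or target_class not in set(map(str, m.class_labels)):
        raise ValueError(f"class {target_class!r} absent from labels")
    h = hyperparams or XOmiHyperparams()
    top_genes = ranked.top(k)
    h_sel = dc_replace(h, seed=seed + 1)
    sel_target, sel_others = _evaluate_arm(m, top_genes, target_class, h_sel)

    rng = np.random.default_rng(seed)
    rand_t, rand_o = [], []
    for s in range(n_random_seeds):
        genes = [m.gene_ids[j] for j in
                 rng.choice(m.n_genes, size=k, replace=False)]
        h_rand = dc_replace(h, seed=seed + 100 + s)
        t, o = _evaluate_arm(m, genes, target_class, h_rand)
        rand_t.append(t)
        rand_o.append(o)

    def agg(dicts, fn):
        return {k_: float(fn([d[k_] for d in dicts])) for k_ in dicts[0]}

    return RetrainReport(
        target_class=target_class, k=k, n_random_seeds=n_random_seeds,
        selected_target=sel_target,
        random_target_mean=agg(rand_t, np.nanmean),
        random_target_sd=agg(rand_t, np.nanstd),
        selected_others=sel_others,
        random_others_mean=agg(rand_o, np.nanmean),
        random_others_sd=agg(rand_o, np.nanstd),
        selected_genes=top_genes,
    )


def rank_sum_overall(per_class_rankings: list[RankedGeneList]) -> RankedGeneList:
    """Combine per-class rankings by summing each gene's rank.

    The output is ordered ascending by rank-sum (lowest = most important
    overall); ``bottom(k)`` gives the overall least important genes.
    """
    if not per_class_rankings:
        raise ValueError("no rankings given")
    universe = set(per_class_rankings[0].gene_ids)
    for r in per_class_rankings[1:]:
        diff = universe.symmetric_difference(r.gene_ids)
        if diff:
            raise ValueError(
                f"rankings cover different gene universes; symmetric "
                f"difference includes {sorted(diff)[:5]}")
    sums = {g: 0 for g in universe}
    for r in per_class_rankings:
        for g, rank in r.ranks().items():
            sums[g] += rank
    order = sorted(universe, key=lambda g: (sums[g], g))
    return RankedGeneList(order, np.array([float(sums[g]) for g in order]),
                          provenance={"order": "ascending_rank_sum",
                                      "n_rankings": len(per_class_rankings)})


def overlap_count(list_a, list_b) -> tuple[int, float]:
    """Exact intersection size and Jaccard index of two gene lists."""
    a, b = {str(g) for g in list_a}, {str(g) for g in list_b}
    inter = len(a & b)
    union = len(a | b)
    return inter, (inter / union) if union else 0.0
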