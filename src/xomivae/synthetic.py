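"""Synthetic expression datasets with known ground truth.

The generator emulates the shape of normalized bulk pan-cancer expression
data: values in [0, 1], far more genes than samples, a small planted subset
of genes carrying the class signal, an optional sex-analogue covariate
driven by a single designated gene (the way XIST marks sex in real
expression data), and missing values at a controlled rate. Every module in
the package is testable against these fixtures because the discriminative
genes are known by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, read_expression
from .nncore import FeedForward, Linear, ReLU

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_dataset",
    "write_fixture",
    "read_fixture",
    "SaturatedFixture",
    "saturated_relu_fixture",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-signal expression dataset.

    ``effect_size`` is the mean shift (in normalized units) added to a
    class's planted genes in that class's samples; ``noise_sd`` the
    standard deviation of the truncated-Gaussian background around 0.5.
    """

    n_samples: int = 600
    n_genes: int = 2000
    n_classes: int = 4
    planted_genes_per_class: int = 25
    effect_size: float = 0.4
    noise_sd: float = 0.1
    na_rate: float = 0.0
    sex_gene_index: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.na_rate <= 1.0:
            raise ValueError("na_rate must be in [0, 1]")
        if self.planted_genes_per_class * self.n_classes > self.n_genes:
            raise ValueError(
                f"{self.planted_genes_per_class} planted genes x "
                f"{self.n_classes} classes exceeds {self.n_genes} genes")


@dataclass
class GroundTruth:
    """What the generator planted: class signal genes and the sex driver."""

    planted: dict[str, list[int]]
    class_labels: list[str]
    sex_labels: list[str]
    sex_gene_index: int | None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[int] = set()
        for cls, idx in self.planted.items():
            s = set(idx)
            if seen & s:
                raise ValueError(
                    f"planted gene sets overlap (class {cls!r})")
            seen |= s
        if self.sex_gene_index is not None and self.sex_gene_index in seen:
            raise ValueError("sex gene collides with a planted gene")
        if len(self.class_labels) != len(self.sex_labels):
            raise ValueError("label vectors differ in length")

    def planted_union(self) -> set[int]:
        return set().union(*self.planted.values())

    def planted_gene_ids(self, m: ExpressionMatrix, cls: str) -> list[str]:
        return [m.gene_ids[j] for j in self.planted[cls]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "planted": self.planted,
            "class_labels": self.class_labels,
            "sex_labels": self.sex_labels,
            "sex_gene_index": self.sex_gene_index,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(planted={k: list(v) for k, v in d["planted"].items()},
                   class_labels=list(d["class_labels"]),
                   sex_labels=list(d["sex_labels"]),
                   sex_gene_index=d["sex_gene_index"])


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one dataset; fully determined by ``spec.seed``.

    Background values are Gaussian around 0.5 (sd ``noise_sd``) clipped to
    [0, 1]; each class's planted genes are shifted up by ``effect_size`` in
    that class's samples; the sex gene sits near 1 for one sex and near 0
    for the other; ``na_rate`` of cells are masked missing uniformly.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_genes
    class_names = [f"C{c}" for c in range(spec.n_classes)]
    labels = [class_names[i % spec.n_classes] for i in range(n)]

    # choose the sex gene first, then disjoint planted blocks from the rest
    if spec.sex_gene_index is not None:
        sex_idx = int(spec.sex_gene_index)
        if not 0 <= sex_idx < g:
            raise ValueError("sex_gene_index out of range")
    else:
        sex_idx = None
    pool = np.array([j for j in range(g) if j != sex_idx])
    perm = rng.permutation(pool)
    p = spec.planted_genes_per_class
    planted = {cls: sorted(int(j) for j in perm[c * p:(c + 1) * p])
               for c, cls in enumerate(class_names)}

    values = rng.normal(0.5, spec.noise_sd, size=(n, g))
    for c, cls in enumerate(class_names):
        rows = np.array([i for i, lb in enumerate(labels) if lb == cls])
        cols = np.array(planted[cls])
        values[np.ix_(rows, cols)] += spec.effect_size
    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    if sex_idx is not None:
        centre = np.where(sexes == "F", 0.95, 0.05)
        values[:, sex_idx] = centre + rng.normal(0.0, spec.noise_sd, size=n)
    values = np.clip(values, 0.0, 1.0)
    if spec.na_rate > 0:
        mask = rng.random(size=(n, g)) < spec.na_rate
        values[mask] = np.nan

    m = ExpressionMatrix(
        values,
        gene_ids=[f"G{j:05d}" for j in range(g)],
        sample_ids=[f"S{i:05d}" for i in range(n)],
        class_labels=np.array(labels, dtype=object),
        phenotypes=pd.DataFrame({"sex": sexes},
                                index=[f"S{i:05d}" for i in range(n)]),
    )
    truth = GroundTruth(planted=planted, class_labels=labels,
                        sex_labels=list(sexes), sex_gene_index=sex_idx)
    return m, truth


def write_fixture(m: ExpressionMatrix, truth: GroundTruth,
                  directory: str | Path) -> None:
    """Persist matrix.tsv / labels.tsv / phenotypes.tsv / truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    m.write_tsv(d / "matrix.tsv")
    pd.Series(m.class_labels, index=m.sample_ids, name="label").to_csv(
        d / "labels.tsv", sep="\t", header=True)
    if m.phenotypes is not None:
        m.phenotypes.to_csv(d / "phenotypes.tsv", sep="\t")
    truth.to_json(d / "truth.json")


def read_fixture(directory: str | Path) -> tuple[ExpressionMatrix, GroundTruth]:
    """Load a fixture written by :func:`write_fixture`; validates the truth
    invariants (disjoint planted sets, consistent labels) on read."""
    d = Path(directory)
    for name in ("matrix.tsv", "labels.tsv", "truth.json"):
        if not (d / name).exists():
            raise FileNotFoundError(d / name)
    m = read_expression(d / "matrix.tsv")
    labels = pd.read_csv(d / "labels.tsv", sep="\t", index_col=0)["label"]
    truth = GroundTruth.from_json(d / "truth.json")
    phen = None
    if (d / "phenotypes.tsv").exists():
        phen = pd.read_csv(d / "phenotypes.tsv", sep="\t", index_col=0)
    if list(labels.index) != m.sample_ids:
        raise ValueError("labels.tsv sample ids do not match matrix.tsv")
    if list(labels.values) != truth.class_labels:
        raise ValueError("labels.tsv disagrees with truth.json")
    m = ExpressionMatrix(m.values, m.gene_ids, m.sample_ids,
                         class_labels=labels.values, phenotypes=phen)
    return m, truth


@dataclass
class SaturatedFixture:
    """A hand-built ReLU network whose signal genes sit past the hinge.

    For the samples of interest every planted gene drives its dedicated
    ReLU unit into the flat region (zero gradient), while the references
    sit on the active side. Gradient-based saliency therefore sees nothing
    on the planted genes, whereas difference-from-reference attribution
    still credits them — the canonical saturation failure case.
    """

    network: FeedForward
    samples: np.ndarray
    refs: np.ndarray
    gene_ids: list[str]
    planted: set[str] = field(default_factory=set)


def saturated_relu_fixture(n_genes: int = 200, n_planted: int = 20,
                           n_samples: int = 40, seed: int = 0) -> SaturatedFixture:
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{j:05d}" for j in range(n_genes)]
    planted_idx = np.arange(n_planted)

    # unit k reads gene k with weight -1, bias 0.8: input 0.9 -> pre-act -0.1
    # (saturated at 0), reference 0.1 -> pre-act 0.7 (active).
    W1 = np.zeros((n_genes, n_planted + 1))
    b1 = np.zeros(n_planted + 1)
    W1[planted_idx, planted_idx] = -1.0
    b1[:n_planted] = 0.8
    # one always-active unit with small positive weights from every gene so
    # background genes carry a non-zero gradient
    W1[:, -1] = rng.uniform(0.01, 0.05, size=n_genes)
    W1[planted_idx, -1] = 0.005
    b1[-1] = 1.0
    W2 = np.ones((n_planted + 1, 1))
    net = FeedForward([Linear.from_weights(W1, b1), ReLU(),
                       Linear.from_weights(W2)])

    samples = rng.uniform(0.3, 0.7, size=(n_samples, n_genes))
    samples[:, planted_idx] = rng.uniform(0.88, 0.92, size=(n_samples, n_planted))
    refs = rng.uniform(0.3, 0.7, size=(n_samples, n_genes))
    refs[:, planted_idx] = rng.uniform(0.08, 0.12, size=(n_samples, n_planted))
    return SaturatedFixture(network=net, samples=samples, refs=refs,
                            gene_ids=gene_ids,
                            planted={gene_ids[j] for j in planted_idx})
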