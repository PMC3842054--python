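"""Synthetic two-class expression data with planted markers.

Emulates the statistical shape of small-sample microarray benchmarks:
tens of samples, thousands of genes, a binary phenotype, a handful of
truly informative genes, and (optionally) blocks of highly correlated
redundant markers.  The generative model is deliberately minimal —
Gaussian background, a mean shift of ``effect_size`` standard deviations
in the positive class for informative genes — because it is the least
structure to which all eight rankers respond, while correlated blocks
reproduce the redundancy-driven instability seen with recursive
elimination selectors.

Block construction: each block has one latent standard-normal signal
(shifted like an informative gene); block gene ``j`` is
``sqrt(rho)·latent + sqrt(1−rho)·noise_j``, giving within-class pairwise
correlation ≈ ``rho`` between block members, plus the full class shift.

Labels are assigned deterministically (the first ``ceil(balance·Z)``
samples positive) and rows then shuffled under the seed, so stratified
subsampling is always feasible and class proportions are exact.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .datasets import AnnotationMap, ExpressionDataset, OntologyDAG

__all__ = [
    "SyntheticSpec",
    "generate_dataset",
    "generate_toy_ontology",
    "redundancy_scenario",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic expression study.

    Defaults mirror a small two-class microarray screen: 60 samples,
    1000 genes of which 10 carry a 2-SD class shift, balanced classes.
    """

    z_samples: int = 60
    n_genes: int = 1000
    n_informative: int = 10
    effect_size: float = 2.0
    n_redundant_blocks: int = 0
    block_size: int = 5
    block_correlation: float = 0.8
    class_balance: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant_blocks * self.block_size > self.n_genes:
            raise ValueError("informative + block genes exceed n_genes")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0, 1)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        if self.z_samples < 4:
            raise ValueError("need at least 4 samples")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionDataset, list[str]]:
    """Draw one dataset; returns (dataset, ground-truth marker gene ids).

    The marker list contains the standalone informative genes and every
    member of every redundant block.
    """
    rng = np.random.default_rng(spec.seed)
    z, n = spec.z_samples, spec.n_genes
    n_pos = int(np.ceil(spec.class_balance * z))
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(z - n_pos, dtype=int)])

    x = rng.normal(0.0, spec.noise_sd, size=(z, n))
    markers: list[int] = []
    col = 0
    for _ in range(spec.n_informative):
        x[:, col] += spec.effect_size * spec.noise_sd * y
        markers.append(col)
        col += 1
    rho = spec.block_correlation
    for _ in range(spec.n_redundant_blocks):
        latent = rng.normal(0.0, spec.noise_sd, size=z)
        for _ in range(spec.block_size):
            noise = rng.normal(0.0, spec.noise_sd, size=z)
            x[:, col] = (
                np.sqrt(rho) * latent
                + np.sqrt(1.0 - rho) * noise
                + spec.effect_size * spec.noise_sd * y
            )
            markers.append(col)
            col += 1

    order = rng.permutation(z)
    gene_ids = [f"G{j:04d}" for j in range(n)]
    dataset = ExpressionDataset(
        sample_ids=[f"S{i:03d}" for i in range(z)],
        gene_ids=gene_ids,
        values=x[order],
        labels=np.where(y[order] == 1, "case", "control"),
        negative_class="control",
    )
    return dataset, [gene_ids[j] for j in markers]


def redundancy_scenario(seed: int = 0) -> SyntheticSpec:
    """Study conditions for the redundancy-driven instability phenomenon.

    All class signal sits in two blocks of 10 highly correlated markers
    (within-class correlation 0.8) — the situation of gene families or
    co-regulated modules where many genes carry interchangeable
    information.  Recursive elimination selectors then pick different
    block representatives on different subsamples (low stability) while
    any representative predicts well (high AUC).
    """
    return SyntheticSpec(
        z_samples=60,
        n_genes=1000,
        n_informative=0,
        n_redundant_blocks=2,
        block_size=10,
        block_correlation=0.8,
        effect_size=2.0,
        seed=seed,
    )


def generate_toy_ontology(
    n_terms: int = 7,
    depth: int = 2,
    genes: list[str] | None = None,
    seed: int = 0,
    namespace: str = "molecular_function",
) -> tuple[OntologyDAG, AnnotationMap]:
    """Random is_a tree of the stated depth plus gene annotations to leaves.

    Term 0 is the root; every other term attaches to a uniformly drawn
    node of the previous level (levels sized to reach ``depth``).  Each
    gene is annotated to 1–3 leaf terms.  Deterministic under ``seed``.
    """
    if n_terms < depth + 1:
        raise ValueError("need at least depth+1 terms for the stated depth")
    rng = np.random.default_rng(seed)
    terms = [f"TOY:{i:04d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    levels: list[list[str]] = [[terms[0]]]
    # guarantee one chain of the requested depth, then attach the rest randomly
    for d in range(1, depth + 1):
        t = terms[d]
        parents[t] = {levels[d - 1][0]}
        levels.append([t])
    for i in range(depth + 1, n_terms):
        lvl = int(rng.integers(1, depth + 1))
        parent = str(rng.choice(levels[lvl - 1]))
        parents[terms[i]] = {parent}
        levels[lvl].append(terms[i])
    dag = OntologyDAG(terms=set(terms), parents=parents, namespace=namespace)
    kids = dag.children_map()
    leaves = sorted(t for t in terms if not kids[t])
    gene_to_terms: dict[str, set[str]] = {}
    for g in genes or []:
        k = int(rng.integers(1, min(3, len(leaves)) + 1))
        chosen = rng.choice(len(leaves), size=k, replace=False)
        gene_to_terms[g] = {leaves[int(i)] for i in chosen}
    return dag, AnnotationMap(gene_to_terms=gene_to_terms)
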