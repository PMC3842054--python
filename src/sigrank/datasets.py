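"""Datasets, ontologies and annotations.

The central container is :class:`ExpressionDataset`: a ``Z × N`` matrix of
real-valued expression levels for ``Z`` samples and ``N`` genes, with a
binary class label per sample (e.g. tumor vs. normal tissue).  Loaders
validate rather than repair: files with missing values, duplicate gene
identifiers or more than two class symbols are rejected, because silent
imputation or symbol merging would change every downstream ranking.

For functional similarity the module also loads a Gene Ontology subgraph
(:class:`OntologyDAG`, ``is_a`` edges only) and a gene→term annotation
table (:class:`AnnotationMap`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GeneSet",
    "OntologyDAG",
    "AnnotationMap",
    "read_expression_table",
    "write_expression_table",
    "read_obo_subset",
    "read_annotations",
]


class DataError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionDataset:
    """Samples × genes expression matrix with a binary class label.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per sample (row).
    gene_ids : list of str
        Unique gene identifiers, one per column; file order is preserved.
    values : ndarray of shape (Z, N)
        Real expression levels; no missing values.
    labels : ndarray of shape (Z,)
        Class symbol per sample; exactly two distinct symbols, both present.
    negative_class : str, optional
        Symbol mapped to the negative class.  Defaults to the
        lexicographically smaller symbol so that AUC orientation is
        deterministic.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    negative_class: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        z, n = self.values.shape
        if z < 2 or n < 1:
            raise DataError(f"need Z >= 2 samples and N >= 1 genes, got Z={z}, N={n}")
        if len(self.sample_ids) != z or len(self.gene_ids) != n:
            raise DataError("id list lengths do not match matrix dimensions")
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DataError(f"duplicate gene ids: {dupes[:5]}")
        if np.isnan(self.values).any():
            rows = np.unique(np.where(np.isnan(self.values))[0])
            raise DataError(f"missing expression values in sample rows {rows.tolist()[:5]}")
        classes = sorted(set(map(str, self.labels)))
        if len(classes) != 2:
            raise DataError(f"need exactly 2 class symbols, got {classes}")
        if self.negative_class is None:
            self.negative_class = classes[0]
        elif str(self.negative_class) not in classes:
            raise DataError(f"negative_class {self.negative_class!r} not among {classes}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> tuple[str, str]:
        """(negative, positive) class symbols."""
        symbols = sorted(set(map(str, self.labels)))
        neg = str(self.negative_class)
        pos = symbols[0] if symbols[1] == neg else symbols[1]
        return neg, pos

    @property
    def y(self) -> np.ndarray:
        """Labels encoded 0 (negative class) / 1 (positive class)."""
        return (self.labels.astype(str) != str(self.negative_class)).astype(int)

    def subset_samples(self, indices: np.ndarray) -> "ExpressionDataset":
        indices = np.asarray(indices)
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in indices],
            gene_ids=list(self.gene_ids),
            values=self.values[indices],
            labels=self.labels[indices],
            negative_class=self.negative_class,
        )

    def subset_genes(self, genes: "GeneSet | list[str]") -> "ExpressionDataset":
        wanted = set(genes.genes) if isinstance(genes, GeneSet) else set(genes)
        missing = sorted(wanted - set(self.gene_ids))
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        # keep the dataset's gene order, so column order is deterministic
        idx = [j for j, g in enumerate(self.gene_ids) if g in wanted]
        names = [self.gene_ids[j] for j in idx]
        return ExpressionDataset(
            sample_ids=list(self.sample_ids),
            gene_ids=names,
            values=self.values[:, idx],
            labels=self.labels,
            negative_class=self.negative_class,
        )


@dataclass(frozen=True)
class GeneSet:
    """An unordered signature: the top-``t`` genes cut from a ranked list."""

    genes: frozenset[str]
    source_ranker: str = ""
    threshold_t: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if self.threshold_t and len(self.genes) != self.threshold_t:
            raise ValueError(
                f"|genes|={len(self.genes)} does not match threshold_t={self.threshold_t}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class OntologyDAG:
    """GO term graph restricted to one namespace and ``is_a`` edges."""

    terms: set[str]
    parents: dict[str, set[str]]
    namespace: str = "molecular_function"
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = nx.DiGraph((t, p) for t, ps in self.parents.items() for p in ps)
        g.add_nodes_from(self.terms)
        unknown = set(g.nodes) - set(self.terms)
        if unknown:
            raise DataError(f"is_a references to unknown terms: {sorted(unknown)[:5]}")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise DataError(f"cyclic is_a chain: {cycle}")
        self._graph = g

    @property
    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def ancestors(self, term: str) -> set[str]:
        """All ``is_a`` ancestors of ``term``, inclusive of ``term``."""
        return nx.descendants(self._graph, term) | {term}

    def descendants(self, term: str) -> set[str]:
        """All terms reachable downward from ``term``, inclusive."""
        return nx.ancestors(self._graph, term) | {term}

    def children_map(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {t: set() for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                kids[p].add(t)
        return kids


@dataclass
class AnnotationMap:
    """Gene → GO term assignments, restricted to a companion ontology."""

    gene_to_terms: dict[str, set[str]]
    unannotated: set[str] = field(default_factory=set)

    def terms_for(self, gene: str) -> set[str]:
        return set(self.gene_to_terms.get(gene, set()))

    @property
    def annotated_genes(self) -> set[str]:
        return {g for g, ts in self.gene_to_terms.items() if ts}


def read_expression_table(
    path,
    orientation: str = "rows-are-samples",
    label_column: str = "class",
    negative_class: str | None = None,
) -> ExpressionDataset:
    """Read a delimited samples×genes (or genes×samples) expression table.

    The file must be comma- or tab-delimited with a header row.  With
    ``orientation="rows-are-samples"`` the column ``label_column`` holds the
    class symbol of each sample; with ``"rows-are-genes"`` one row whose
    identifier equals ``label_column`` holds the symbols instead.
    """
    if orientation not in ("rows-are-samples", "rows-are-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    names = header.split(sep)[1:]
    if orientation == "rows-are-samples" and len(set(names)) != len(names):
        dupes = sorted({g for g in names if names.count(g) > 1})
        raise DataError(f"duplicate gene ids: {dupes[:5]}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, na_values=[""]
    )
    if orientation == "rows-are-genes":
        df = df.T
    if label_column not in df.columns:
        raise DataError(f"label column {label_column!r} not found in {list(df.columns)[:5]}...")
    labels = df[label_column].astype(str)
    symbols = sorted(labels.unique())
    if len(symbols) != 2:
        raise DataError(f"label column must hold exactly 2 symbols, got {symbols}")
    expr = df.drop(columns=[label_column])
    try:
        values = expr.astype(float).to_numpy()
    except ValueError:
        for j, c in enumerate(expr.columns):
            bad = pd.to_numeric(expr[c], errors="coerce").isna() & expr[c].notna()
            if bad.any():
                row = expr.index[bad.to_numpy().argmax()]
                raise DataError(
                    f"non-numeric expression value at row {row!r}, column {c!r}"
                ) from None
        raise
    if expr.isna().any().any():
        bad_rows = expr.index[expr.isna().any(axis=1)].tolist()
        raise DataError(f"missing expression values in rows {bad_rows[:5]}")
    return ExpressionDataset(
        sample_ids=[str(s) for s in expr.index],
        gene_ids=[str(g) for g in expr.columns],
        values=values,
        labels=labels.to_numpy(),
        negative_class=negative_class,
    )


def write_expression_table(dataset: ExpressionDataset, path, sep: str = ",") -> None:
    """Write a dataset in the rows-are-samples dialect ``read_expression_table`` reads.

    The round trip is exact: ``repr`` formatting preserves float values
    bit-for-bit and identifiers verbatim.
    """
    df = pd.DataFrame(dataset.values, index=dataset.sample_ids, columns=dataset.gene_ids)
    df.insert(0, "class", dataset.labels)
    df.index.name = "sample"
    df.to_csv(path, sep=sep, float_format=lambda v: repr(float(v)))


def read_obo_subset(path, namespace: str = "molecular_function") -> OntologyDAG:
    """Parse an OBO 1.2 file into an is_a DAG over one namespace.

    Obsolete terms are dropped; edges other than ``is_a`` are ignored.
    A term whose ``is_a`` parent is not defined in the file, or a cyclic
    ``is_a`` chain, is an error.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    # obonet materialises dangling is_a targets as attribute-less nodes
    defined = {n for n, d in graph.nodes(data=True) if d}
    for term, data in graph.nodes(data=True):
        for parent in data.get("is_a", []):
            if parent not in defined:
                raise DataError(f"term {term} has is_a parent {parent} not defined in file")
    keep = {n for n in defined if graph.nodes[n].get("namespace") == namespace}
    parents = {
        n: {p for p in graph.nodes[n].get("is_a", []) if p in keep} for n in keep
    }
    names = {n: graph.nodes[n].get("name", "") for n in keep}
    return OntologyDAG(terms=keep, parents=parents, namespace=namespace, names=names)


def read_annotations(path, ontology: OntologyDAG, gaf: bool = False) -> AnnotationMap:
    """Read gene→term annotations (two-column TSV, or minimal GAF 2.x).

    Terms absent from ``ontology`` are dropped; genes left without any
    surviving term are recorded as unannotated.  Malformed lines are
    skipped with a logged warning.
    """
    gene_terms: dict[str, set[str]] = {}
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if gaf:
                if len(fields) < 5:
                    skipped += 1
                    continue
                gene, term = fields[2], fields[4]
            else:
                if len(fields) == 1:
                    fields = line.split(",")
                if len(fields) < 2 or not fields[0] or not fields[1]:
                    skipped += 1
                    continue
                gene, term = fields[0].strip(), fields[1].strip()
            gene_terms.setdefault(gene, set()).add(term)
    if skipped:
        logger.warning("read_annotations: skipped %d malformed lines", skipped)
    kept = {g: {t for t in ts if t in ontology.terms} for g, ts in gene_terms.items()}
    unannotated = {g for g, ts in kept.items() if not ts}
    return AnnotationMap(
        gene_to_terms={g: ts for g, ts in kept.items() if ts},
        unannotated=unannotated,
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
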