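"""Functional similarity between gene signatures via GO term semantics.

Two signatures that share few or no genes can still capture the same
biology: their genes may be annotated to the same (or closely related)
molecular-function GO terms.  This module quantifies that with an
information-content (IC) approach:

* each signature is mapped to the union of the GO terms annotating its
  genes (:func:`annotate_gene_set`);
* a term's IC is −log2 of the fraction of annotated genes covered by the
  term or any of its descendants, computed from the supplied annotation
  corpus itself (:func:`term_information_content`);
* two terms are compared with the Lin measure,
  2·IC(MICA) / (IC(t1) + IC(t2)), where MICA is their common ``is_a``
  ancestor of maximal IC (:func:`term_pair_similarity`);
* two term sets are compared with the symmetric best-match average
  (:func:`termset_similarity`).

The term-pair measure is pluggable; Lin + best-match average is the
default because it is transparent, self-contained (no external frequency
tables) and bounded in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datasets import AnnotationMap, GeneSet, OntologyDAG
from .setsim import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TermSet",
    "annotate_gene_set",
    "InformationContent",
    "term_information_content",
    "term_pair_similarity",
    "termset_similarity",
    "functional_similarity_matrix",
]


@dataclass
class TermSet:
    """The GO terms annotating a gene signature."""

    terms: set[str]
    source_genes: GeneSet | None = None
    unannotated_genes: set[str] = field(default_factory=set)
    label: str = ""

    def __len__(self) -> int:
        return len(self.terms)


def annotate_gene_set(genes: GeneSet, annotations: AnnotationMap, label: str = "") -> TermSet:
    """Union of the terms of all annotated genes; unannotated genes flagged."""
    terms: set[str] = set()
    missing: set[str] = set()
    for g in sorted(genes.genes):
        ts = annotations.terms_for(g)
        if ts:
            terms |= ts
        else:
            missing.add(g)
    if missing:
        logger.info("annotate_gene_set: %d/%d genes unannotated", len(missing), len(genes))
    return TermSet(
        terms=terms,
        source_genes=genes,
        unannotated_genes=missing,
        label=label or genes.source_ranker,
    )


class InformationContent:
    """Per-term IC from descendant-propagated annotation counts.

    The corpus is the AnnotationMap itself: p(term) is the fraction of
    annotated genes annotated to the term or any descendant, and
    IC = −log2 p.  Terms covering no gene have undefined IC and are
    excluded from comparisons (with a warning at construction).
    """

    def __init__(self, ontology: OntologyDAG, annotations: AnnotationMap):
        self.ontology = ontology
        total = len(annotations.annotated_genes)
        if total == 0:
            raise ValueError("annotation corpus is empty; IC is undefined")
        covered: dict[str, set[str]] = {t: set() for t in ontology.terms}
        for gene, terms in annotations.gene_to_terms.items():
            for t in terms:
                for anc in ontology.ancestors(t):
                    covered[anc].add(gene)
        self._ic: dict[str, float] = {}
        empty = []
        for t in ontology.terms:
            if covered[t]:
                self._ic[t] = float(-np.log2(len(covered[t]) / total))
            else:
                empty.append(t)
        if empty:
            logger.warning(
                "InformationContent: %d terms annotate no gene and are excluded", len(empty)
            )

    def __contains__(self, term: str) -> bool:
        return term in self._ic

    def __getitem__(self, term: str) -> float:
        if term not in self._ic:
            raise KeyError(f"IC undefined for term {term} (annotates no gene)")
        return self._ic[term]

    def lin(self, t1: str, t2: str) -> float:
        """Lin similarity 2·IC(MICA)/(IC(t1)+IC(t2)) over is_a ancestors."""
        ic1, ic2 = self[t1], self[t2]
        if ic1 + ic2 == 0:
            return 0.0  # both are root-level terms carrying no information
        common = self.ontology.ancestors(t1) & self.ontology.ancestors(t2)
        mica = max((self._ic[t] for t in common if t in self._ic), default=0.0)
        return 2.0 * mica / (ic1 + ic2)


def term_information_content(
    term: str, annotations: AnnotationMap, ontology: OntologyDAG
) -> float:
    """IC(term) = −log2 p(term) with descendant-propagated gene counts."""
    return InformationContent(ontology, annotations)[term]


def term_pair_similarity(
    t1: str, t2: str, ontology: OntologyDAG, annotations: AnnotationMap
) -> float:
    """Lin similarity of two terms in [0, 1]."""
    return InformationContent(ontology, annotations).lin(t1, t2)


def _bma(
    a: Sequence[str], b: Sequence[str], pair_sim: Callable[[str, str], float]
) -> float:
    """Symmetric best-match average of a pairwise term similarity."""
    best_a = [max(pair_sim(x, y) for y in b) for x in a]
    best_b = [max(pair_sim(x, y) for x in a) for y in b]
    return (float(np.mean(best_a)) + float(np.mean(best_b))) / 2.0


def termset_similarity(
    a: TermSet,
    b: TermSet,
    ontology: OntologyDAG,
    annotations: AnnotationMap,
    ic: InformationContent | None = None,
    pair_measure: Callable[[str, str], float] | None = None,
) -> float:
    """Best-match-average similarity of two term sets in [0, 1].

    Returns NaN when either set is empty (after dropping terms with
    undefined IC): an unannotated signature has no functional profile,
    which is different from having a dissimilar one.
    """
    if ic is None and pair_measure is None:
        ic = InformationContent(ontology, annotations)
    sim = pair_measure if pair_measure is not None else ic.lin
    ta = sorted(t for t in a.terms if pair_measure is not None or t in ic)
    tb = sorted(t for t in b.terms if pair_measure is not None or t in ic)
    if not ta or not tb:
        return float("nan")
    return _bma(ta, tb, sim)


def functional_similarity_matrix(
    sets: Sequence[TermSet],
    ontology: OntologyDAG,
    annotations: AnnotationMap,
    labels: Sequence[str] | None = None,
    pair_measure: Callable[[str, str], float] | None = None,
) -> SimilarityMatrix:
    """Pairwise term-set similarity matrix (same contract as the overlap matrix)."""
    ic = None if pair_measure is not None else InformationContent(ontology, annotations)
    m = len(sets)
    if labels is None:
        labels = [s.label or f"set{i}" for i, s in enumerate(sets)]
    values = np.ones((m, m))
    for i in range(m):
        values[i, i] = termset_similarity(
            sets[i], sets[i], ontology, annotations, ic=ic, pair_measure=pair_measure
        )
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = termset_similarity(
                sets[i], sets[j], ontology, annotations, ic=ic, pair_measure=pair_measure
            )
    return SimilarityMatrix(labels=list(labels), values=values, index_name="I-functional")
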