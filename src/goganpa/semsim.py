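"""Resnik semantic similarity between GO terms and genes.

Term specificity is measured by information content,
``ic(t) = -ln(|genes annotated to t| / |annotated genes|)`` on the
ancestor-propagated annotation view. The Resnik similarity of two terms is
the maximal information content over their common ancestors (a term counts
as its own ancestor). Gene-gene similarity uses the *max* mixing strategy:
the maximum term similarity over all pairs of the two genes' directly
annotated terms. The genome-wide matrix is normalized by its maximal
off-diagonal entry so that downstream thresholding operates on [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import AnnotationSet, OntologyDAG

logger = logging.getLogger(__name__)


@dataclass
class ICTable:
    """Information content per term (natural log), with the number of
    annotated genes used as denominator."""

    ic: dict[str, float]
    total_genes: int

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


def information_content(
    anns: AnnotationSet, dag: OntologyDAG, namespace: str | None = "BP"
) -> ICTable:
    """IC for every term with at least one annotated gene (propagated view).

    Terms with zero annotated genes simply have no entry — they are
    excluded, not assigned an infinite value.
    """
    if anns.propagated is None:
        raise ValueError("information_content requires a propagated view")
    ns_terms = dag.traversable_terms(namespace) if namespace else None
    counts: dict[str, int] = {}
    genes_in_ns: set[str] = set()
    for gene, terms in anns.propagated.items():
        used = terms if ns_terms is None else terms & ns_terms
        if used:
            genes_in_ns.add(gene)
        for t in used:
            counts[t] = counts.get(t, 0) + 1
    total = len(genes_in_ns)
    if total == 0:
        raise ValueError(f"no annotated genes in namespace {namespace!r}")
    ic = {t: -math.log(c / total) for t, c in counts.items()}
    return ICTable(ic=ic, total_genes=total)


def term_similarity(
    t1: str, t2: str, dag: OntologyDAG, ic: ICTable
) -> float:
    """Resnik similarity: max IC over the common ancestors of t1 and t2.

    Returns 0 when the only common ancestry carries zero IC (e.g. the root),
    or — with a warning — when the terms live in different namespaces.
    """
    if dag.namespace_of(t1) != dag.namespace_of(t2):
        logger.warning(
            "terms %s and %s are in different namespaces; similarity 0", t1, t2
        )
        return 0.0
    common = dag.ancestors(t1) & dag.ancestors(t2)
    values = [ic[t] for t in common if t in ic]
    return max(values, default=0.0)


def gene_similarity(
    g1: str,
    g2: str,
    anns: AnnotationSet,
    dag: OntologyDAG,
    ic: ICTable,
) -> float:
    """Max-mixing gene similarity over all pairs of *direct* terms."""
    terms1 = [t for t in anns.direct.get(g1, ()) if t in ic]
    terms2 = [t for t in anns.direct.get(g2, ()) if t in ic]
    if not terms1 or not terms2:
        raise ValueError(
            f"gene similarity undefined: {g1!r} or {g2!r} has no term with "
            "defined information content"
        )
    return max(
        term_similarity(t1, t2, dag, ic) for t1 in terms1 for t2 in terms2
    )


class DegenerateSimilarityError(ValueError):
    pass


@dataclass
class GeneSimilarityMatrix:
    genes: list[str]
    values: np.ndarray  # symmetric, >= 0
    normalized: bool = False
    max_raw: float | None = None
    dropped_genes: list[str] = field(default_factory=list)

    def index_of(self, gene: str) -> int:
        return self.genes.index(gene)

    def offdiag_max(self) -> float:
        n = len(self.genes)
        if n < 2:
            return 0.0
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].max())


def similarity_matrix(
    genes: list[str],
    anns: AnnotationSet,
    dag: OntologyDAG,
    ic: ICTable,
) -> GeneSimilarityMatrix:
    """Pairwise gene similarity over ``genes``, normalized to a maximal
    off-diagonal entry of exactly 1.

    Genes without any direct term with defined IC are dropped from the
    matrix (they receive the basic weight downstream, not similarity 0).
    """
    usable: list[str] = []
    dropped: list[str] = []
    gene_terms: list[list[str]] = []
    for g in genes:
        ts = [t for t in anns.direct.get(g, ()) if t in ic]
        if ts:
            usable.append(g)
            gene_terms.append(ts)
        else:
            dropped.append(g)
    if len(usable) < 2:
        raise ValueError("need at least 2 genes with usable annotations")
    if dropped:
        logger.info("dropped %d genes without usable annotations", len(dropped))

    # precompute the term-level similarity matrix over the used terms
    used_terms = sorted({t for ts in gene_terms for t in ts})
    tidx = {t: i for i, t in enumerate(used_terms)}
    ancestors = {t: dag.ancestors(t) for t in used_terms}
    ns = {t: dag.namespace_of(t) for t in used_terms}
    T = len(used_terms)
    tsim = np.zeros((T, T))
    for i, ti in enumerate(used_terms):
        for j in range(i, T):
            tj = used_terms[j]
            if ns[ti] != ns[tj]:
                continue
            common = ancestors[ti] & ancestors[tj]
            val = max((ic[t] for t in common if t in ic), default=0.0)
            tsim[i, j] = tsim[j, i] = val

    n = len(usable)
    term_idx = [np.array([tidx[t] for t in ts]) for ts in gene_terms]
    values = np.zeros((n, n))
    for i in range(n):
        rows = tsim[term_idx[i]]
        for j in range(i, n):
            values[i, j] = values[j, i] = rows[:, term_idx[j]].max()

    mask = ~np.eye(n, dtype=bool)
    max_raw = float(values[mask].max())
    if max_raw <= 0.0:
        raise DegenerateSimilarityError("degenerate similarity matrix")
    values = values / max_raw
    return GeneSimilarityMatrix(
        genes=list(usable),
        values=values,
        normalized=True,
        max_raw=max_raw,
        dropped_genes=dropped,
    )


# ---------------------------------------------------------------------------
# I/O


def write_similarity_edges(sim: GeneSimilarityMatrix, path: str | Path) -> None:
    """3-column edge-style TSV (gene_a, gene_b, similarity), i < j pairs."""
    n = len(sim.genes)
    rows = [
        (sim.genes[i], sim.genes[j], sim.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"]).to_csv(
        path, sep="\t", index=False
    )


def write_similarity_dense(sim: GeneSimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.genes, columns=sim.genes).to_csv(
        path, sep="\t"
    )


def read_similarity_edges(path: str | Path) -> GeneSimilarityMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    genes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    idx = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(genes), len(genes)))
    ia = df["gene_a"].map(idx).to_numpy()
    ib = df["gene_b"].map(idx).to_numpy()
    values[ia, ib] = df["similarity"].to_numpy()
    values[ib, ia] = df["similarity"].to_numpy()
    return GeneSimilarityMatrix(genes=genes, values=values, normalized=True)


def read_similarity_dense(path: str | Path) -> GeneSimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return GeneSimilarityMatrix(
        genes=list(df.index), values=df.to_numpy(dtype=float), normalized=True
    )
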