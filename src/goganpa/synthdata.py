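"""Synthetic inputs for every stage of the pipeline.

Everything the pipeline consumes — ontologies, annotation sets, gene set
collections, expression matrices with binary phenotypes, and similarity
matrices with a planted scale-free structure — can be generated here as a
pure function of a configuration and a seed, so the whole package is
testable without any external download.

The expression generator draws independent unit-variance Gaussian noise
per gene and sample; differential expression, when requested, is a mean
shift of ``effect_size`` (in within-group standard deviations) applied to
the second phenotype group, either uniformly over designated sets or only
to the high-weight (hub) genes of a supplied weight table. Permutation
inference downstream is distribution-free, so Gaussian noise is the
simplest adequate null model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .gsa import ExpressionDataset
from .ontology import (
    NAMESPACE_CODES,
    AnnotationRecord,
    AnnotationSet,
    OntologyDAG,
    Term,
    filter_records,
)
from .semsim import GeneSimilarityMatrix
from .weighting import GeneSetCollection

logger = logging.getLogger(__name__)

_NAMESPACE_NAMES = {v: k for k, v in NAMESPACE_CODES.items()}


@dataclass
class SimulationConfig:
    """Study conditions for a simulated two-group expression experiment.

    Defaults describe a small calibration-scale experiment: 20 genes
    partitioned into 5 disjoint sets of 4, 6 samples per phenotype group,
    and no differential expression (a pure null).
    """

    n_terms: int = 30
    n_genes: int = 20
    n_sets: int = 5
    set_size: tuple[int, int] = (4, 4)
    n_samples: int = 6  # per group
    effect_size: float = 0.0
    de_mode: str = "none"  # none | uniform | hub_only
    n_de_sets: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_terms, self.n_genes, self.n_sets, self.n_samples) < 1:
            raise ValueError("all counts must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.de_mode not in ("none", "uniform", "hub_only"):
            raise ValueError(f"unknown de_mode {self.de_mode!r}")


def gene_names(n: int) -> list[str]:
    return [f"G{i+1:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# ontology + annotations


def toy5() -> OntologyDAG:
    """Fixed 5-term fixture: root R; T1, T2 is_a R; T3 is_a T1 and T2."""
    terms = {
        t: Term(id=t, name=t, namespace="BP")
        for t in ("R", "T1", "T2", "T3")
    }
    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    graph.add_edge("T1", "R", relation="is_a")
    graph.add_edge("T2", "R", relation="is_a")
    graph.add_edge("T3", "T1", relation="is_a")
    graph.add_edge("T3", "T2", relation="is_a")
    return OntologyDAG(terms=terms, graph=graph)


def make_dag(
    n_terms: int, max_parents: int = 3, seed: int = 0
) -> OntologyDAG:
    """Random single-root acyclic DAG: term i > 1 draws 1..max_parents
    parents among the earlier terms, so the topological order is the term
    order and the result is acyclic by construction."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"T{i+1:04d}" for i in range(n_terms)]
    terms = {t: Term(id=t, name=t, namespace="BP") for t in ids}
    graph = nx.DiGraph()
    graph.add_nodes_from(ids)
    for i in range(1, n_terms):
        n_par = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=n_par, replace=False)
        for p in parents:
            graph.add_edge(ids[i], ids[int(p)], relation="is_a")
    dag = OntologyDAG(terms=terms, graph=graph)
    dag.validate()
    return dag


def make_annotations(
    dag: OntologyDAG,
    n_genes: int,
    terms_per_gene: tuple[int, int] = (1, 3),
    evidence_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> AnnotationSet:
    """Random direct annotations over the non-root terms of ``dag``.

    Evidence codes are sampled from ``evidence_mix`` (default 60% EXP, 30%
    IEA, 10% ND) so downstream evidence filtering is exercised. The
    returned set is the default-filtered direct view (ND dropped, IEA
    kept); the raw records are attached as ``.records``.
    """
    evidence_mix = evidence_mix or {"EXP": 0.6, "IEA": 0.3, "ND": 0.1}
    codes = sorted(evidence_mix)
    probs = np.array([evidence_mix[c] for c in codes], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    roots = dag.roots("BP")
    pool = sorted(dag.traversable_terms("BP") - roots) or sorted(roots)
    lo, hi = terms_per_gene
    records: list[AnnotationRecord] = []
    for g in gene_names(n_genes):
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        for t in chosen:
            ev = codes[int(rng.choice(len(codes), p=probs))]
            records.append(AnnotationRecord(gene=g, term=pool[int(t)], evidence=ev))
    anns = filter_records(records, dag, namespace="BP")
    anns.records = records  # type: ignore[attr-defined]
    return anns


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    lines = ["format-version: 1.2", ""]
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines += [
            "[Term]",
            f"id: {term.id}",
            f"name: {term.name}",
            f"namespace: {_NAMESPACE_NAMES.get(term.namespace, term.namespace)}",
        ]
        if term.obsolete:
            lines.append("is_obsolete: true")
        elif tid in dag.graph:
            for _, parent, attrs in dag.graph.out_edges(tid, data=True):
                rel = attrs.get("relation", "is_a")
                if rel == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_annotations(records, path: str | Path) -> None:
    """Simplified 3-column dialect: gene, term, evidence."""
    lines = ["!gene\tterm\tevidence"] + [
        f"{r.gene}\t{r.term}\t{r.evidence}" for r in records
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# gene sets + expression


def make_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """Disjoint gene sets carved from a seeded shuffle of the gene list."""
    rng = np.random.default_rng(config.seed)
    genes = gene_names(config.n_genes)
    order = rng.permutation(config.n_genes)
    lo, hi = config.set_size
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_sets)]
    if sum(sizes) > config.n_genes:
        raise ValueError("gene sets do not fit into the gene list")
    sets: dict[str, frozenset[str]] = {}
    pos = 0
    for i, size in enumerate(sizes):
        members = frozenset(genes[j] for j in order[pos : pos + size])
        sets[f"SET{i+1:03d}"] = members
        pos += size
    return GeneSetCollection(sets=sets, min_size=lo, max_size=hi)


def make_expression(
    config: SimulationConfig,
    gene_sets: GeneSetCollection | None = None,
    weight_table: pd.DataFrame | None = None,
) -> ExpressionDataset:
    """Two-group expression matrix under the configured null/alternative.

    ``de_mode='none'``: labels independent of expression. ``'uniform'``:
    every gene of the first ``n_de_sets`` sets is shifted by
    ``effect_size`` in group 2. ``'hub_only'``: only genes with weight > 1
    in ``weight_table`` are shifted.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_names(config.n_genes)
    n = config.n_samples
    X = rng.standard_normal((config.n_genes, 2 * n))
    labels = np.array([0] * n + [1] * n)

    de_genes: set[str] = set()
    if config.de_mode == "uniform":
        if gene_sets is None:
            raise ValueError("uniform de_mode requires gene_sets")
        for name in gene_sets.names()[: config.n_de_sets]:
            de_genes |= set(gene_sets.sets[name])
    elif config.de_mode == "hub_only":
        if weight_table is None:
            raise ValueError("hub_only de_mode requires a weight table")
        hubs = weight_table.loc[weight_table["weight"] > 1, "gene"]
        de_genes = set(hubs)

    if de_genes and config.effect_size > 0:
        idx = [i for i, g in enumerate(genes) if g in de_genes]
        X[np.ix_(idx, np.where(labels == 1)[0])] += config.effect_size

    data = ExpressionDataset(genes=genes, matrix=X, labels=labels)
    data.de_genes = de_genes  # type: ignore[attr-defined]
    return data


# ---------------------------------------------------------------------------
# planted scale-free similarity


def _powerlaw_degrees(
    n: int, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    deg = rng.zipf(gamma, size=n)
    deg = np.minimum(deg, n - 1)
    if deg.sum() % 2:  # configuration model needs an even stub count
        deg[int(np.argmin(deg))] += 1
    return deg


def make_planted_similarity(
    n_genes: int,
    gamma: float = 2.5,
    tau_star: float = 0.4,
    seed: int = 0,
    max_retries: int = 5,
) -> GeneSimilarityMatrix:
    """Normalized similarity matrix whose thresholding at ``tau_star``
    recovers a configuration-model power-law graph.

    Planted edges carry similarities in [tau_star, tau_star + 0.04], so one
    grid step above tau_star almost all edges vanish; non-edges carry
    similarities uniform in [0, tau_star), so lower thresholds bury the
    power law under Erdos-Renyi noise. One planted edge is pinned to 1 to
    satisfy the normalization contract.
    """
    if not 1.0 < gamma:
        raise ValueError("gamma must exceed 1")
    if not 0.0 < tau_star < 0.95:
        raise ValueError("tau_star must lie strictly inside (0, 0.95)")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        deg = _powerlaw_degrees(n_genes, gamma, rng)
        g = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31)))
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        if g.number_of_edges() >= 3:
            break
        logger.info("degree sequence attempt %d infeasible; resampling", attempt)
    else:
        raise ValueError("could not realize a planted degree sequence")

    n = n_genes
    values = rng.uniform(0.0, tau_star, size=(n, n))
    values = np.triu(values, k=1)
    values = values + values.T
    edges = np.array(list(g.edges), dtype=int)
    hi = min(tau_star + 0.04, 0.999)
    edge_vals = rng.uniform(tau_star, hi, size=len(edges))
    values[edges[:, 0], edges[:, 1]] = edge_vals
    values[edges[:, 1], edges[:, 0]] = edge_vals
    pin = edges[int(rng.integers(len(edges)))]
    values[pin[0], pin[1]] = values[pin[1], pin[0]] = 1.0
    np.fill_diagonal(values, 1.0)
    return GeneSimilarityMatrix(
        genes=gene_names(n), values=values, normalized=True, max_raw=None
    )


# ---------------------------------------------------------------------------
# published-table fixtures


def table_fixtures() -> dict[str, pd.DataFrame]:
    """Packaged transcriptions of the published benchmark tables.

    ``p53_qvalues``: 17 pathways x 5 methods of q-values from the p53
    cell-line benchmark. ``breast_ranks``: 22 pathways x 4 methods, each
    with the three per-dataset Z ranks from the breast-cancer
    reproducibility benchmark. ``asthma_zscores``: 18 pathways x 4 methods
    of normalized Z scores (and published ranks) from the asthma benchmark.
    """
    base = resources.files("goganpa") / "data"
    return {
        "p53_qvalues": pd.read_csv(
            str(base / "p53_qvalues.tsv"), sep="\t"
        ),
        "breast_ranks": pd.read_csv(
            str(base / "breast_ranks.tsv"), sep="\t"
        ),
        "asthma_zscores": pd.read_csv(
            str(base / "asthma_zscores.tsv"), sep="\t"
        ),
    }
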