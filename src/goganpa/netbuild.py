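"""Functional network construction by similarity thresholding.

A normalized gene-gene similarity matrix is hard-thresholded into an
unweighted, self-edge-free network: genes i and j are connected iff
``s_ij >= tau``. The threshold is selected by the scale-free-topology
criterion: for each candidate tau, the degree distribution of the resulting
network is binned (equal-width bins over the positive degrees), and the
R-squared of the ordinary least-squares regression of log10(bin proportion)
on log10(bin mean degree) measures how well the degrees follow a power law.
The tau maximizing R-squared wins.

Zero-degree nodes are excluded before binning (log10 of a zero proportion
is undefined for them only in the sense that they carry no edges at all);
the exclusion count is reported. Log base 10 on both axes: R-squared is
base-invariant, the slope is the power-law exponent estimate (negated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .semsim import GeneSimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_GRID = [round(0.05 * i, 2) for i in range(1, 20)]  # 0.05 .. 0.95
DEFAULT_N_BINS = 10


class InsufficientDegreeSpreadError(ValueError):
    pass


@dataclass
class FunctionalNetwork:
    """Undirected, unweighted gene network (symmetric 0/1 adjacency with an
    empty diagonal)."""

    nodes: list[str]
    adjacency: np.ndarray  # bool, symmetric, zero diagonal
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node list")
        if a.dtype != bool:
            self.adjacency = a.astype(bool)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree_array(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def index_of(self, gene: str) -> int:
        return self.nodes.index(gene)


def threshold_network(
    sim: GeneSimilarityMatrix, tau: float
) -> FunctionalNetwork:
    """Edges where similarity >= tau (inclusive), diagonal forced empty.

    Isolated nodes are retained in the node list.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    adj = sim.values >= tau
    np.fill_diagonal(adj, False)
    adj = adj & adj.T  # guard against asymmetric input
    return FunctionalNetwork(
        nodes=list(sim.genes), adjacency=adj, threshold_used=tau
    )


def connectivity(net: FunctionalNetwork) -> dict[str, int]:
    """Whole-network degree per gene."""
    k = net.degree_array()
    return {g: int(k[i]) for i, g in enumerate(net.nodes)}


@dataclass
class ScaleFreeFit:
    n_bins: int
    bin_means: np.ndarray  # mean degree per nonempty bin
    bin_props: np.ndarray  # proportion of positive-degree nodes per bin
    r_squared: float
    slope: float
    n_excluded_zero_degree: int = 0


def scale_free_fit(
    k_values, n_bins: int = DEFAULT_N_BINS
) -> ScaleFreeFit:
    """Binned log-log power-law goodness of fit for a degree sequence.

    Equal-width bins over the range of the positive degrees; empty bins are
    skipped; requires at least 3 nonempty bins for the regression.
    """
    k = np.asarray(list(k_values), dtype=float)
    pos = k[k > 0]
    n_zero = int(k.size - pos.size)
    if pos.size == 0 or pos.min() == pos.max():
        raise InsufficientDegreeSpreadError("insufficient degree spread")
    kmin, kmax = float(pos.min()), float(pos.max())
    width = (kmax - kmin) / n_bins
    idx = np.minimum(((pos - kmin) / width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=pos, minlength=n_bins)
    nonempty = counts > 0
    if int(nonempty.sum()) < 3:
        raise InsufficientDegreeSpreadError("insufficient degree spread")
    bin_means = sums[nonempty] / counts[nonempty]
    bin_props = counts[nonempty] / pos.size
    res = stats.linregress(np.log10(bin_means), np.log10(bin_props))
    return ScaleFreeFit(
        n_bins=n_bins,
        bin_means=bin_means,
        bin_props=bin_props,
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        n_excluded_zero_degree=n_zero,
    )


@dataclass
class ThresholdReport:
    tau: float
    n_edges: int
    n_nonisolated: int
    fit: ScaleFreeFit | None
    error: str | None = None


def select_threshold(
    sim: GeneSimilarityMatrix,
    grid=None,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[float, list[ThresholdReport]]:
    """Scan the threshold grid, fit each degree distribution, return the tau
    with maximal R-squared (ties: lowest tau) plus the per-tau reports.

    Grid points whose network cannot be fitted (too little degree spread)
    are skipped and reported.
    """
    grid = DEFAULT_GRID if grid is None else list(grid)
    if any(not 0.0 <= t <= 1.0 for t in grid):
        raise ValueError("grid values must lie in [0, 1]")
    reports: list[ThresholdReport] = []
    for tau in grid:
        net = threshold_network(sim, tau)
        k = net.degree_array()
        n_noniso = int((k > 0).sum())
        try:
            fit = scale_free_fit(k, n_bins=n_bins)
            reports.append(ThresholdReport(tau, net.n_edges, n_noniso, fit))
        except InsufficientDegreeSpreadError as exc:
            reports.append(
                ThresholdReport(tau, net.n_edges, n_noniso, None, str(exc))
            )
    fitted = [r for r in reports if r.fit is not None]
    if not fitted:
        details = "; ".join(f"tau={r.tau}: {r.error}" for r in reports)
        raise InsufficientDegreeSpreadError(
            f"no grid point admits a scale-free fit ({details})"
        )
    best = max(fitted, key=lambda r: (r.fit.r_squared, -r.tau))
    return best.tau, reports


# ---------------------------------------------------------------------------
# I/O


def write_network(
    net: FunctionalNetwork,
    edges_path: str | Path,
    nodes_path: str | Path,
    header: str | None = None,
) -> None:
    """Edge list (2-column TSV) plus node list; threshold recorded in a
    comment header on the edge file."""
    lines = []
    if header:
        lines.append(f"# {header}")
    lines.append(f"# threshold={net.threshold_used}")
    lines.append("gene_a\tgene_b")
    idx_i, idx_j = np.nonzero(np.triu(net.adjacency, k=1))
    for i, j in zip(idx_i, idx_j):
        lines.append(f"{net.nodes[i]}\t{net.nodes[j]}")
    Path(edges_path).write_text("\n".join(lines) + "\n")
    node_lines = ([f"# {header}"] if header else []) + ["gene"] + list(net.nodes)
    Path(nodes_path).write_text("\n".join(node_lines) + "\n")


def read_network(
    edges_path: str | Path, nodes_path: str | Path
) -> FunctionalNetwork:
    threshold = None
    for line in Path(edges_path).read_text().splitlines():
        if line.startswith("# threshold="):
            raw = line.split("=", 1)[1]
            threshold = None if raw == "None" else float(raw)
        if not line.startswith("#"):
            break
    nodes = [
        ln
        for ln in Path(nodes_path).read_text().splitlines()
        if ln and not ln.startswith("#") and ln != "gene"
    ]
    idx = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    edges = pd.read_csv(edges_path, sep="\t", comment="#")
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    return FunctionalNetwork(nodes=nodes, adjacency=adj, threshold_used=threshold)


def write_fit_report(
    reports: list[ThresholdReport], path: str | Path, header: str | None = None
) -> None:
    rows = [
        {
            "tau": r.tau,
            "n_edges": r.n_edges,
            "n_nonisolated": r.n_nonisolated,
            "r_squared": r.fit.r_squared if r.fit else np.nan,
            "slope": r.fit.slope if r.fit else np.nan,
            "error": r.error or "",
        }
        for r in reports
    ]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
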