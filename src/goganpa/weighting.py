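"""Per-(gene set, gene) weights from network connectivity.

A gene that is preferentially connected, within the functional network, to
the other members of a gene set is functionally central to that set and is
up-weighted. Under the null of no specific association, the number of a
gene's edges landing inside the set follows a hypergeometric distribution:
the other N-1 network genes are the urn, the gene's k_net neighbours the
white balls, and the other n_s-1 set members the draws, giving the expected
in-set connectivity ``E = k_net * (n_s - 1) / (N - 1)``. The weight is

    w = 1 + max(0, log2(k_path / E))

so a gene whose in-set connectivity matches (or falls below) expectation
keeps the basic weight 1, and each doubling beyond expectation adds 1.
Genes absent from the network get the basic weight 1.

Multi-subunit-protein (MSP) correction collapses the genes encoding one
protein complex into a single network unit before connectivities are
counted, preventing complex subunits from inflating their neighbours'
weights; member genes inherit their unit's weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .netbuild import FunctionalNetwork

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 15
DEFAULT_MAX_SIZE = 500

WEIGHT_COLUMNS = [
    "set",
    "gene",
    "k_net",
    "k_path",
    "expected",
    "raw_log",
    "weight",
]


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    min_size: int = DEFAULT_MIN_SIZE
    max_size: int = DEFAULT_MAX_SIZE

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)


def load_collection(
    sets: dict[str, set[str] | frozenset[str]],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    restrict_to: set[str] | None = None,
) -> GeneSetCollection:
    """Apply the size filter at load. If ``restrict_to`` is given (e.g. the
    measured genes of an expression dataset), sets are intersected with it
    *before* the size filter is applied."""
    kept: dict[str, frozenset[str]] = {}
    for name, genes in sets.items():
        g = frozenset(genes)
        if restrict_to is not None:
            g = g & frozenset(restrict_to)
        if min_size <= len(g) <= max_size:
            kept[name] = g
    return GeneSetCollection(sets=kept, min_size=min_size, max_size=max_size)


def read_gmt(
    path: str | Path,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    restrict_to: set[str] | None = None,
) -> GeneSetCollection:
    """GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    raw: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        raw[fields[0]] = {g for g in fields[2:] if g}
    return load_collection(raw, min_size, max_size, restrict_to)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na"] + sorted(genes))
        for name, genes in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class MSPMap:
    """Partial map gene -> complex-unit id; unmapped genes are singletons."""

    units: dict[str, str] = field(default_factory=dict)

    def unit_of(self, gene: str) -> str:
        return self.units.get(gene, gene)


def read_msp_map(path: str | Path) -> MSPMap:
    units: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, unit = line.rstrip("\n").split("\t")[:2]
        units[gene] = unit
    return MSPMap(units=units)


def write_msp_map(msp: MSPMap, path: str | Path) -> None:
    lines = ["gene\tunit_id"] + [
        f"{g}\t{u}" for g, u in sorted(msp.units.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# connectivity and weights


def pathway_connectivity(
    net: FunctionalNetwork, s: set[str] | frozenset[str]
) -> dict[str, int]:
    """In-set degree for every gene of ``s``; genes absent from the network
    count 0."""
    if not s:
        raise ValueError("gene set is empty")
    idx = {g: i for i, g in enumerate(net.nodes)}
    members = [g for g in s if g in idx]
    member_idx = np.array([idx[g] for g in members], dtype=int)
    result = {g: 0 for g in s}
    if member_idx.size:
        sub = net.adjacency[np.ix_(member_idx, member_idx)]
        in_deg = sub.sum(axis=1)
        for g, d in zip(members, in_deg):
            result[g] = int(d)
    return result


def expected_pathway_connectivity(k_net: int, n_s: int, N: int) -> float:
    """Hypergeometric mean in-set connectivity: ``k_net * (n_s-1) / (N-1)``.

    Population N-1 (every network gene but the focal one), k_net successes,
    n_s-1 draws (the focal gene is itself a set member).
    """
    if N < 2:
        raise ValueError(f"network must contain at least 2 genes, got N={N}")
    if not 1 <= n_s <= N:
        raise ValueError(f"set size n_s={n_s} outside [1, N={N}]")
    if not 0 <= k_net <= N - 1:
        raise ValueError(f"connectivity k_net={k_net} outside [0, N-1]")
    return k_net * (n_s - 1) / (N - 1)


def gene_weight(k_path: int, expected: float) -> tuple[float, float]:
    """(raw_log, weight) for one gene: ``w = 1 + max(0, log2(k_path/E))``.

    Degenerate inputs (no in-set edges, or zero expectation) yield the basic
    weight 1 with a ``-inf`` raw log.
    """
    if expected < 0:
        raise ValueError("expected connectivity must be >= 0")
    if k_path > 0 and expected > 0:
        raw = math.log2(k_path / expected)
    else:
        raw = float("-inf")
    return raw, 1.0 + max(0.0, raw)


def collapse_msp(net: FunctionalNetwork, msp: MSPMap) -> FunctionalNetwork:
    """Unit-level network: units U != V are adjacent iff any member of U is
    adjacent to any member of V; intra-unit edges vanish."""
    missing = [g for g in msp.units if g not in set(net.nodes)]
    if missing:
        logger.info(
            "MSP map references %d genes absent from the network", len(missing)
        )
    unit_of = {g: msp.unit_of(g) for g in net.nodes}
    units = sorted(set(unit_of.values()))
    uidx = {u: i for i, u in enumerate(units)}
    # membership matrix: units x genes
    M = np.zeros((len(units), len(net.nodes)), dtype=bool)
    for j, g in enumerate(net.nodes):
        M[uidx[unit_of[g]], j] = True
    adj = (M.astype(np.uint8) @ net.adjacency.astype(np.uint8) @ M.T.astype(np.uint8)) > 0
    np.fill_diagonal(adj, False)
    return FunctionalNetwork(
        nodes=units, adjacency=adj, threshold_used=net.threshold_used
    )


def weight_gene_sets(
    net: FunctionalNetwork,
    collection: GeneSetCollection,
    msp: MSPMap | None = None,
) -> pd.DataFrame:
    """Weight table with one row per (set, gene) and provenance columns
    (k_net, k_path, expected, raw_log, weight).

    With an MSP map, connectivities and sizes are counted in units on the
    collapsed network (a unit belongs to a set iff any member gene does) and
    every member gene inherits its unit's weight. Genes absent from the
    network get weight exactly 1.
    """
    if msp is not None:
        cnet = collapse_msp(net, msp)
        unit_of = {g: msp.unit_of(g) for g in net.nodes}
    else:
        cnet = net
        unit_of = {g: g for g in net.nodes}

    node_set = set(cnet.nodes)
    N = len(cnet.nodes)
    k_net_all = dict(zip(cnet.nodes, cnet.degree_array().astype(int)))

    rows = []
    for name, genes in collection:
        units_in_set = {unit_of[g] for g in genes if g in unit_of}
        units_in_set &= node_set
        if not units_in_set:
            logger.warning(
                "gene set %r shares no genes with the network; weights 1", name
            )
        k_path = (
            pathway_connectivity(cnet, units_in_set) if units_in_set else {}
        )
        n_s = len(units_in_set)
        unit_rows: dict[str, tuple] = {}
        for u in units_in_set:
            kn = int(k_net_all[u])
            exp = expected_pathway_connectivity(kn, n_s, N) if N >= 2 else 0.0
            raw, w = gene_weight(k_path[u], exp)
            unit_rows[u] = (kn, int(k_path[u]), exp, raw, w)
        for g in sorted(genes):
            u = unit_of.get(g, g)
            if u in unit_rows:
                kn, kp, exp, raw, w = unit_rows[u]
            else:
                kn, kp, exp, raw, w = 0, 0, 0.0, float("-inf"), 1.0
            rows.append((name, g, kn, kp, exp, raw, w))
    return pd.DataFrame(rows, columns=WEIGHT_COLUMNS)


def weights_for_set(table: pd.DataFrame, name: str) -> dict[str, float]:
    sub = table[table["set"] == name]
    return dict(zip(sub["gene"], sub["weight"]))


def write_weight_table(
    table: pd.DataFrame, path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_weight_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
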