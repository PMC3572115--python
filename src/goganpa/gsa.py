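"""Weighted gene set analysis with phenotype permutation.

For each gene a two-sample (pooled-variance) t statistic d_i is computed
between the two phenotype groups. The set-level statistic is the weighted
mean absolute statistic

    T_s = sum_{i in s} w_i |d_i| / sum_{i in s} w_i

which reduces to the plain mean-absolute statistic when all weights are 1.
Significance comes from B random permutations of the phenotype labels
(weights held fixed): p_s is the fraction of permuted statistics >= the
observed one — the plain proportion with denominator B, so a statistic
exceeding every permuted value gets an exact p of 0 (an optional +1
smoothing flag exists). Multiple testing is handled by Benjamini-Hochberg
q-values (a Storey-style variant with lambda = 0.5 is available). The
normalized score Z_s centers the observed statistic by the median of the
set's own permuted values and scales by their standard deviation, making
effect sizes comparable across sets of different sizes; a pooled
normalization scope (all sets' permuted values together) is provided as an
alternative. Sets are ranked by descending Z with competition (minimum)
ranking for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .weighting import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    genes: list[str]
    matrix: np.ndarray  # genes x samples
    labels: np.ndarray  # per-sample 0/1 phenotype

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.matrix.shape != (len(self.genes), self.labels.size):
            raise ValueError("matrix shape does not match genes/labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        counts = np.bincount(self.labels, minlength=2)
        if len(np.unique(self.labels)) != 2 or counts.min() < 2:
            raise ValueError("both phenotype groups need at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.labels.size


def read_expression_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Expression TSV: first column gene id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


def write_expression_tsv(
    genes: list[str], matrix: np.ndarray, path: str | Path, samples=None
) -> None:
    samples = samples or [f"S{i+1}" for i in range(matrix.shape[1])]
    pd.DataFrame(matrix, index=genes, columns=samples).rename_axis("gene").to_csv(
        path, sep="\t"
    )


def read_cls(path: str | Path) -> np.ndarray:
    """Broad 3-line CLS dialect: counts line, '# name0 name1' line, labels."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln.strip()
    ]
    if len(lines) < 3:
        raise ValueError("CLS file needs 3 lines")
    tokens = lines[2].split()
    classes = []
    for t in tokens:
        if t not in classes:
            classes.append(t)
    if len(classes) != 2:
        raise ValueError(f"expected 2 phenotype classes, found {classes}")
    return np.array([classes.index(t) for t in tokens], dtype=int)


def write_cls(labels: np.ndarray, path: str | Path, names=("A", "B")) -> None:
    labels = np.asarray(labels, dtype=int)
    body = " ".join(names[v] for v in labels)
    Path(path).write_text(
        f"{labels.size} 2 1\n# {names[0]} {names[1]}\n{body}\n"
    )


# ---------------------------------------------------------------------------
# gene-level statistics


def _t_stats(
    X: np.ndarray, group1: np.ndarray, welch: bool = False
) -> np.ndarray:
    """Two-sample t statistics for every gene (row) of X, for one or many
    group assignments.

    ``group1``: boolean matrix (B x samples) — one row per labelling. The
    result is genes x B. Zero-variance genes get t = 0.
    """
    G1 = group1.astype(float).T  # samples x B
    n1 = group1[0].sum()
    n2 = group1.shape[1] - n1
    S1 = X @ G1
    Q1 = (X**2) @ G1
    tot = X.sum(axis=1, keepdims=True)
    qtot = (X**2).sum(axis=1, keepdims=True)
    m1 = S1 / n1
    m2 = (tot - S1) / n2
    ss1 = Q1 - n1 * m1**2
    ss2 = (qtot - Q1) - n2 * m2**2
    ss1 = np.maximum(ss1, 0.0)
    ss2 = np.maximum(ss2, 0.0)
    if welch:
        v1 = ss1 / (n1 - 1)
        v2 = ss2 / (n2 - 1)
        se2 = v1 / n1 + v2 / n2
    else:
        sp2 = (ss1 + ss2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    t[~np.isfinite(t)] = 0.0
    return t


def gene_statistics(
    data: ExpressionDataset, welch: bool = False
) -> dict[str, float]:
    """Per-gene two-sample t statistic (pooled variance by default).

    Constant genes get d = 0 (logged).
    """
    group1 = (data.labels == 0)[None, :]
    d = _t_stats(data.matrix, group1, welch=welch)[:, 0]
    n_const = int((data.matrix.std(axis=1) == 0).sum())
    if n_const:
        logger.info("%d constant genes assigned d = 0", n_const)
    return dict(zip(data.genes, d))


def set_statistic(
    d: Mapping[str, float],
    weights: Mapping[str, float] | None,
    s: Iterable[str],
) -> float:
    """Weighted mean absolute gene statistic over the measured members of s.

    Genes absent from ``d`` (missing expression) are dropped; genes without
    a weight entry default to 1.
    """
    weights = weights or {}
    measured = [g for g in s if g in d]
    if not measured:
        raise ValueError("gene set has no measured genes")
    w = np.array([weights.get(g, 1.0) for g in measured], dtype=float)
    vals = np.array([abs(d[g]) for g in measured], dtype=float)
    return float((w * vals).sum() / w.sum())


# ---------------------------------------------------------------------------
# permutation machinery


@dataclass
class PermutationEnsemble:
    B: int
    stats: np.ndarray  # B x n_sets
    seed: int
    set_names: list[str]


def _set_matrices(
    data: ExpressionDataset,
    collection: GeneSetCollection,
    weights: pd.DataFrame | Mapping | None,
) -> tuple[list[str], np.ndarray]:
    """Weight matrix W (n_sets x genes): w_i for measured members, else 0.
    Sets with no measured genes are skipped with a warning."""
    gidx = {g: i for i, g in enumerate(data.genes)}
    per_set_weights: dict[str, dict[str, float]] = {}
    if weights is None:
        pass
    elif isinstance(weights, pd.DataFrame):
        for name, sub in weights.groupby("set"):
            per_set_weights[str(name)] = dict(zip(sub["gene"], sub["weight"]))
    else:  # flat mapping applied to every set
        flat = dict(weights)
        per_set_weights = {name: flat for name, _ in collection}

    names: list[str] = []
    rows: list[np.ndarray] = []
    for name, genes in collection:
        measured = [g for g in genes if g in gidx]
        if not measured:
            logger.warning("set %r has no measured genes; skipped", name)
            continue
        w = per_set_weights.get(name, {})
        row = np.zeros(len(data.genes))
        for g in measured:
            row[gidx[g]] = w.get(g, 1.0)
        names.append(name)
        rows.append(row)
    if not names:
        raise ValueError("no gene set overlaps the expression data")
    return names, np.vstack(rows)


def permutation_test(
    data: ExpressionDataset,
    collection: GeneSetCollection,
    weights: pd.DataFrame | Mapping | None,
    B: int,
    seed: int,
    welch: bool = False,
    smoothing: bool = False,
) -> tuple[pd.Series, PermutationEnsemble, pd.Series]:
    """Observed set statistics, the permutation ensemble, and p-values.

    Labels are permuted uniformly at random, independently for each of the
    B draws (sampling with replacement across draws); gene weights are held
    fixed. p_s = #{b : T*_sb >= T_s} / B, or (#+1)/(B+1) with smoothing.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    names, W = _set_matrices(data, collection, weights)
    wsum = W.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    obs_d = _t_stats(data.matrix, (data.labels == 0)[None, :], welch=welch)
    T_obs = ((W @ np.abs(obs_d)) / wsum)[:, 0]

    M = data.n_samples
    perms = np.empty((B, M), dtype=bool)
    base = data.labels == 0
    for b in range(B):
        perms[b] = base[rng.permutation(M)]
    perm_d = _t_stats(data.matrix, perms, welch=welch)  # genes x B
    T_perm = ((W @ np.abs(perm_d)) / wsum).T  # B x n_sets

    exceed = (T_perm >= T_obs[None, :]).sum(axis=0)
    if smoothing:
        p = (exceed + 1) / (B + 1)
    else:
        p = exceed / B
    ens = PermutationEnsemble(B=B, stats=T_perm, seed=seed, set_names=names)
    return (
        pd.Series(T_obs, index=names, name="T"),
        ens,
        pd.Series(p, index=names, name="p"),
    )


# ---------------------------------------------------------------------------
# multiple testing, normalization, ranking


def q_values(p: pd.Series | np.ndarray, method: str = "bh", lam: float = 0.5):
    """Benjamini-Hochberg step-up q-values (default), or a Storey-style
    variant that rescales BH by the estimated null fraction pi0."""
    arr = np.asarray(p, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "storey":
        pi0 = min(1.0, float((arr > lam).mean()) / (1.0 - lam)) if m else 1.0
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown q-value method {method!r}")
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def normalized_scores(
    T_obs: pd.Series, ens: PermutationEnsemble, scope: str = "per_set"
) -> pd.Series:
    """Z_s = (T_s - median(T*_s)) / sd(T*_s).

    ``scope='per_set'`` uses each set's own permuted values (default);
    ``scope='pooled'`` centers and scales by the pooled permuted values of
    all sets. Sets with zero permutation spread get NaN.
    """
    if ens.B < 2:
        raise ValueError("need at least 2 permutations for normalization")
    T = T_obs.reindex(ens.set_names).to_numpy()
    if scope == "per_set":
        med = np.median(ens.stats, axis=0)
        sd = ens.stats.std(axis=0, ddof=1)
    elif scope == "pooled":
        med = np.full(len(ens.set_names), np.median(ens.stats))
        sd = np.full(len(ens.set_names), ens.stats.std(ddof=1))
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (T - med) / sd
    z[sd == 0] = np.nan
    n_undef = int(np.isnan(z).sum())
    if n_undef:
        logger.warning("%d sets have undefined Z (zero permutation spread)", n_undef)
    return pd.Series(z, index=ens.set_names, name="Z")


def rank_by_z(Z: pd.Series) -> pd.Series:
    """Descending competition ranks (1 = largest Z; ties share the minimal
    rank). Sets with undefined Z are left unranked (NaN)."""
    defined = Z.dropna()
    ranks = _scipy_stats.rankdata(-defined.to_numpy(), method="min")
    out = pd.Series(np.nan, index=Z.index, name="rank")
    out.loc[defined.index] = ranks
    return out


def conserved_sets(
    rank_tables: list[Mapping[str, float] | pd.Series],
    rank_threshold: int,
) -> list[str]:
    """Sets ranked at or above (<=) ``rank_threshold`` in every table.

    A set missing from any table (or unranked there) is non-conserved.
    """
    if len(rank_tables) < 2:
        raise ValueError("need at least 2 rank tables")
    tables = [dict(pd.Series(t).dropna()) for t in rank_tables]
    candidates = sorted(tables[0])
    out = []
    for name in candidates:
        ranks = [t.get(name) for t in tables]
        if any(r is None for r in ranks):
            logger.info("set %r missing from a rank table; non-conserved", name)
            continue
        if all(r <= rank_threshold for r in ranks):
            out.append(name)
    return out


def count_significant(q, threshold: float) -> int:
    """Number of sets with q <= threshold (inclusive)."""
    arr = np.asarray(q, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("q-values must lie in [0, 1]")
    return int((arr <= threshold).sum())


# ---------------------------------------------------------------------------
# orchestration


def run_gsa(
    data: ExpressionDataset,
    collection: GeneSetCollection,
    weights: pd.DataFrame | Mapping | None,
    B: int,
    seed: int,
    fdr_threshold: float = 0.15,
    q_method: str = "bh",
    z_scope: str = "per_set",
    welch: bool = False,
    smoothing: bool = False,
) -> pd.DataFrame:
    """Full weighted GSA: one row per retained set with columns
    size_used, T, p, q, Z, rank and a ``significant`` flag at the given FDR
    threshold. Deterministic under a fixed seed."""
    T_obs, ens, p = permutation_test(
        data, collection, weights, B=B, seed=seed, welch=welch,
        smoothing=smoothing,
    )
    q = q_values(p, method=q_method)
    Z = normalized_scores(T_obs, ens, scope=z_scope)
    ranks = rank_by_z(Z)
    measured = set(data.genes)
    size_used = pd.Series(
        {name: len(set(genes) & measured) for name, genes in collection}
    ).reindex(ens.set_names)
    result = pd.DataFrame(
        {
            "size_used": size_used.astype(int),
            "T": T_obs,
            "p": p,
            "q": q,
            "Z": Z,
            "rank": ranks,
            "significant": q <= fdr_threshold,
        }
    )
    result.index.name = "set"
    return result


def write_results(
    result: pd.DataFrame, path: str | Path, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        result.to_csv(fh, sep="\t")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="set")
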