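"""Regulator-target network inference.

Two data-driven backends produce a non-negative regulators x genes weight
matrix:

* **COEN** — weighted co-expression: Pearson correlation, raised to a
  soft-threshold power chosen by the approximate scale-free topology
  criterion, then converted to the topological overlap measure (TOM),
  which credits shared neighbourhoods on top of direct similarity.  TOM
  is symmetric; direction is imposed by keeping only regulator rows.
* **GRN** — random-forest regression: each gene is regressed on the
  regulators and the edge weight W_ij is regulator i's impurity
  importance in the model for gene j, scaled by the model's explained
  variance.  Targets whose expression the forest cannot predict
  (out-of-bag R^2 <= 0 by default) are dropped as poor models.

The directed network is then extracted by keeping the top-ranked fraction
of candidate edges (default top 5%) and discarding unconnected nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestRegressor

from .io import ExpressionData

__all__ = [
    "WeightMatrix",
    "RegulatorNetwork",
    "pick_soft_power",
    "compute_tom",
    "coen_weights",
    "grn_importances",
    "filter_poor_models",
    "extract_topology",
    "hub_metrics",
    "infer_network",
]

logger = logging.getLogger(__name__)


@dataclass
class WeightMatrix:
    """Candidate regulator -> gene edge weights.

    ``weights`` has regulators as rows and genes as columns; self pairs
    (a regulator predicting itself) are masked with NaN and never become
    edges.  COEN weights are TOM values in [0, 1]; GRN weights are scaled
    random-forest importances (>= 0).
    """

    weights: pd.DataFrame  # index regulators, columns genes; NaN = masked

    def __post_init__(self) -> None:
        vals = self.weights.to_numpy()
        if np.nanmin(vals) < 0:
            raise ValueError("edge weights must be non-negative")
        for r in self.weights.index:
            if r in self.weights.columns and not np.isnan(self.weights.at[r, r]):
                raise ValueError(f"self-weight of {r!r} must be masked (NaN)")

    @property
    def regulators(self) -> list[str]:
        return self.weights.index.tolist()

    def n_candidates(self) -> int:
        return int(self.weights.notna().to_numpy().sum())


@dataclass
class RegulatorNetwork:
    """Directed regulator -> target network (retained edges only)."""

    edges: pd.DataFrame  # columns regulator, target, weight
    regulators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-loops are not allowed")
        reg_set = set(self.regulators)
        bad = set(self.edges["regulator"]) - reg_set
        if bad:
            raise ValueError(f"edge sources outside the regulator set: {sorted(bad)}")

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["regulator"]) | set(self.edges["target"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def target_sets(self, min_size: int = 0) -> dict[str, list[str]]:
        """Regulator -> regulon (targets of retained edges)."""
        out: dict[str, list[str]] = {}
        for reg, grp in self.edges.groupby("regulator", sort=True):
            targets = sorted(grp["target"])
            if len(targets) >= min_size:
                out[str(reg)] = targets
        return out

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.regulator, row.target, weight=row.weight)
        return g


# ---------------------------------------------------------------------------
# COEN


def _correlation(expr: ExpressionData, dtype=np.float64) -> tuple[np.ndarray, list[str]]:
    """|Pearson correlation| between gene rows; constant genes dropped."""
    x = expr.values.to_numpy(dtype=dtype)
    sd = x.std(axis=1)
    # relative tolerance: a constant row's numerical std is ~eps * |mean|
    keep = sd > 1e-10 * np.maximum(1.0, np.abs(x.mean(axis=1)))
    if not keep.all():
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant gene(s) before correlation")
    x = x[keep]
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    xc = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    cor = (xc @ xc.T) / x.shape[1]
    np.clip(np.abs(cor, out=cor), 0.0, 1.0, out=cor)
    return cor, genes


def _scale_free_r2(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k over logarithmic connectivity bins."""
    k = adj.sum(axis=0) - np.diag(adj)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = counts > 0
    if ok.sum() < 3:
        return 0.0
    log_k = np.log10(centers[ok])
    log_p = np.log10(counts[ok] / counts.sum())
    slope, intercept = np.polyfit(log_k, log_p, 1)
    resid = log_p - (slope * log_k + intercept)
    ss_tot = np.sum((log_p - log_p.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum(resid**2) / ss_tot)


def pick_soft_power(
    expr: ExpressionData,
    powers=tuple(range(1, 21)),
    r2_target: float = 0.85,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by approximate scale-free fit.

    Returns the smallest power whose connectivity distribution reaches
    R^2 >= ``r2_target``; if none does, the argmax-R^2 power is returned
    with a warning.  The fit table (power, r2, mean connectivity) is
    returned alongside for inspection.
    """
    if expr.n_samples < 4:
        raise ValueError("need >= 4 samples to pick a soft power")
    powers = sorted(int(b) for b in powers)
    if not powers or powers[0] < 1:
        raise ValueError("powers must be a non-empty list of integers >= 1")
    if not 0.0 < r2_target < 1.0:
        raise ValueError("r2_target must lie in (0, 1)")
    cor, _genes = _correlation(expr)
    rows = []
    best_power, best_r2 = powers[0], -np.inf
    chosen = None
    for beta in powers:
        adj = cor**beta
        r2 = _scale_free_r2(adj)
        rows.append({"power": beta, "r2": r2, "mean_k": float((adj.sum(0) - 1).mean())})
        if r2 > best_r2:
            best_power, best_r2 = beta, r2
        if chosen is None and r2 >= r2_target:
            chosen = beta
            break
    fit_table = pd.DataFrame(rows)
    if chosen is None:
        warnings.warn(
            f"no power reached scale-free R^2 {r2_target}; "
            f"using argmax power {best_power} (R^2={best_r2:.3f})"
        )
        chosen = best_power
    return chosen, fit_table


def _tom_from_adjacency(
    adj: np.ndarray, rows: np.ndarray | None = None, copy: bool = True
) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), diag = 1.

    ``rows`` restricts the output to those row indices (the formula is
    unchanged; column-wise quantities still use the full gene set).
    """
    a = adj.copy() if copy else adj
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    if rows is None:
        l = a @ a
        kmin = np.minimum.outer(k, k)
        with np.errstate(divide="ignore", invalid="ignore"):
            tom = (l + a) / (kmin + 1.0 - a)
        np.fill_diagonal(tom, 1.0)
        return np.nan_to_num(tom, nan=0.0)
    a_rows = a[rows]
    l = a_rows @ a
    kmin = np.minimum.outer(k[rows], k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a_rows) / (kmin + 1.0 - a_rows)
    tom = np.nan_to_num(tom, nan=0.0)
    for out_i, gene_i in enumerate(rows):
        tom[out_i, gene_i] = 1.0
    return tom


def compute_tom(expr_or_adj, beta: float = 1.0) -> pd.DataFrame:
    """Topological overlap matrix of the soft-thresholded co-expression net.

    Accepts either expression data (adjacency = |cor|^beta is built first)
    or a precomputed symmetric adjacency DataFrame.  Entries lie in
    [0, 1]; the diagonal is 1.
    """
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    if isinstance(expr_or_adj, ExpressionData):
        cor, genes = _correlation(expr_or_adj)
        adj = cor**beta
    else:
        adj_df = pd.DataFrame(expr_or_adj)
        genes = adj_df.index.tolist()
        adj = adj_df.to_numpy(dtype=float) ** beta if beta != 1 else adj_df.to_numpy(dtype=float)
    tom = _tom_from_adjacency(adj)
    return pd.DataFrame(tom, index=genes, columns=genes)


def coen_weights(
    expr: ExpressionData,
    regulators,
    beta: int | None = None,
    powers=tuple(range(1, 21)),
    r2_target: float = 0.85,
) -> WeightMatrix:
    """COEN candidate weights: TOM rows restricted to the regulators.

    Computes only the regulator rows of the TOM (identical values to the
    full matrix), which keeps memory linear in the regulator count.
    """
    regulators = [r for r in regulators if r in set(expr.gene_ids)]
    if len(regulators) < 1:
        raise ValueError("no regulator is present among the expression genes")
    if beta is None:
        beta, _ = pick_soft_power(expr, powers=powers, r2_target=r2_target)
    cor, genes = _correlation(expr, dtype=np.float32)
    gene_pos = {g: i for i, g in enumerate(genes)}
    regulators = [r for r in regulators if r in gene_pos]
    rows = np.array([gene_pos[r] for r in regulators])
    np.power(cor, beta, out=cor)  # in place: large matrices
    tom = _tom_from_adjacency(cor.astype(np.float64), rows=rows, copy=False)
    del cor
    w = pd.DataFrame(tom, index=regulators, columns=genes, dtype=float)
    for out_i, r in enumerate(regulators):
        w.at[r, r] = np.nan  # mask self pair
    w = w.clip(upper=1.0)
    return WeightMatrix(weights=w)


# ---------------------------------------------------------------------------
# GRN (random forest)


def _fit_one_target(y, feats, n_trees, seed, min_samples_leaf):
    # mtry = ceil(sqrt(p)): the usual square-root rule, but never so small
    # that tiny regulator panels force splits on uninformative features
    mtry = min(feats.shape[1], int(np.ceil(np.sqrt(feats.shape[1]))))
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_samples_leaf,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny-sample OOB warnings
        rf.fit(feats, y)
        quality = float(rf.oob_score_)
    importances = rf.feature_importances_
    scale = max(quality, 0.0)
    return importances * scale, quality


def grn_importances(
    expr: ExpressionData,
    regulators,
    n_trees: int = 1000,
    seed: int = 0,
    n_jobs: int = 1,
    min_samples_leaf: int = 1,
) -> tuple[WeightMatrix, pd.Series]:
    """Random-forest importance weights W_ij with out-of-bag model quality.

    For each gene j a forest predicts its (standardized) expression from
    all regulators except j itself; W_ij is regulator i's impurity
    importance rescaled so the column sums to the model's explained
    variance (out-of-bag R^2, floored at 0).  Each target gets its own
    child seed from one seed sequence, so results are identical for any
    ``n_jobs``.
    """
    gene_set = set(expr.gene_ids)
    regulators = [r for r in regulators if r in gene_set]
    if len(regulators) < 2:
        raise ValueError("need >= 2 regulators present in the expression data")
    if expr.n_samples < 5:
        raise ValueError("need >= 5 samples for random-forest inference")
    x = expr.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    reg_rows = np.array([idx[r] for r in regulators])
    feats_all = xs[reg_rows].T  # samples x regulators

    child_seeds = np.random.SeedSequence(seed).spawn(expr.n_genes)
    reg_index = {r: i for i, r in enumerate(regulators)}

    def job(j):
        gene = expr.gene_ids[j]
        if gene in reg_index:
            cols = [i for i, r in enumerate(regulators) if r != gene]
            feats = feats_all[:, cols]
        else:
            cols = list(range(len(regulators)))
            feats = feats_all
        rf_seed = int(child_seeds[j].generate_state(1)[0] % (2**31 - 1))
        imp, quality = _fit_one_target(xs[j], feats, n_trees, rf_seed, min_samples_leaf)
        full = np.full(len(regulators), np.nan)
        full[cols] = imp
        return full, quality

    results = Parallel(n_jobs=n_jobs)(delayed(job)(j) for j in range(expr.n_genes))
    w = np.column_stack([r[0] for r in results])
    quality = pd.Series([r[1] for r in results], index=expr.gene_ids, name="oob_r2")
    weights = pd.DataFrame(w, index=regulators, columns=expr.gene_ids)
    return WeightMatrix(weights=weights), quality


def filter_poor_models(
    wm: WeightMatrix, quality: pd.Series, threshold: float = 0.0
) -> WeightMatrix:
    """Mask target columns whose model quality is <= ``threshold``.

    Removes genes (and all their candidate edges) whose expression the
    forest could hardly predict from the regulators.
    """
    quality = quality.reindex(wm.weights.columns)
    if quality.isna().any():
        missing = quality.index[quality.isna()].tolist()
        raise ValueError(f"quality missing for targets: {missing[:5]}")
    w = wm.weights.copy()
    poor = quality.index[quality <= threshold]
    w.loc[:, poor] = np.nan
    return WeightMatrix(weights=w)


# ---------------------------------------------------------------------------
# topology extraction & hub metrics


def extract_topology(wm: WeightMatrix, edge_fraction: float = 0.05) -> RegulatorNetwork:
    """Retain the top-ranked fraction of candidate edges.

    Exactly ``ceil(edge_fraction * n_candidates)`` edges survive; ties at
    the cutoff are broken deterministically (weight desc, then regulator
    ID asc, then target ID asc).  Nodes without a retained edge drop out.
    """
    if not 0.0 < edge_fraction <= 1.0:
        raise ValueError("edge_fraction must lie in (0, 1]")
    w = wm.weights
    stacked = w.stack(future_stack=True).dropna()
    n_candidates = len(stacked)
    if n_candidates == 0:
        raise ValueError("no candidate edges (all masked)")
    n_keep = int(np.ceil(edge_fraction * n_candidates))
    df = stacked.rename("weight").reset_index()
    df.columns = ["regulator", "target", "weight"]
    df = df.sort_values(
        ["weight", "regulator", "target"], ascending=[False, True, True], kind="mergesort"
    ).head(n_keep)
    df = df.reset_index(drop=True)
    return RegulatorNetwork(edges=df, regulators=wm.regulators)


def hub_metrics(net: RegulatorNetwork) -> pd.DataFrame:
    """Per-node out-degree and out-closeness of the directed network.

    Out-degree counts distinct nodes a node points to.  Out-closeness is
    reachable-set closeness from the node (shortest paths outward, unit
    edge lengths) with the Wasserman-Faust size correction; nodes with no
    outgoing edges score 0.
    """
    g = net.to_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    out_deg = dict(g.out_degree())
    # closeness_centrality measures incoming paths; reverse to get outgoing
    out_clo = nx.closeness_centrality(g.reverse(), wf_improved=True)
    nodes = sorted(g.nodes())
    return pd.DataFrame(
        {
            "node": nodes,
            "is_regulator": [n in set(net.regulators) for n in nodes],
            "out_degree": [out_deg[n] for n in nodes],
            "out_closeness": [out_clo[n] for n in nodes],
        }
    ).set_index("node")


def infer_network(
    expr: ExpressionData,
    regulators,
    method: str = "coen",
    edge_fraction: float = 0.05,
    beta: int | None = None,
    powers=tuple(range(1, 21)),
    r2_target: float = 0.85,
    n_trees: int = 1000,
    grn_quality_threshold: float = 0.0,
    seed: int = 0,
    n_jobs: int = 1,
) -> RegulatorNetwork:
    """One-call network inference: weights -> (filter) -> top-edge topology."""
    if method == "coen":
        wm = coen_weights(expr, regulators, beta=beta, powers=powers, r2_target=r2_target)
    elif method == "grn":
        wm, quality = grn_importances(
            expr, regulators, n_trees=n_trees, seed=seed, n_jobs=n_jobs
        )
        wm = filter_poor_models(wm, quality, threshold=grn_quality_threshold)
    else:
        raise ValueError(f"unknown network method: {method!r} (use 'coen' or 'grn')")
    return extract_topology(wm, edge_fraction=edge_fraction)
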