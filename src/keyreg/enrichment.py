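"""Target-set enrichment: the P_E stage.

Each regulator's regulon (its retained network targets) is scored for
enrichment in the differential signal, by one of:

* **FET** — hypergeometric over-representation of a thresholded
  differential gene set among the targets: the p-value is the upper tail
  P(X >= K) of Hypergeom(N, M, s) where N is the network gene universe,
  M the differential genes inside it, s the regulon size and K the
  overlap.
* **GSEA** — threshold-free weighted enrichment: genes are sorted by a
  ranking metric r (z-scored -log of the differential p-values) and the
  enrichment score ES is the signed extremum of the running difference
  between the |r|-weighted hit distribution and the uniform miss
  distribution.  Significance comes from an empirical null built by
  shuffling the gene labels of r (default 1000 permutations, one shared
  permutation stream for all regulators), sign-matched one-sided with a
  +1 pseudo-count so p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult, bh_adjust
from .netinfer import RegulatorNetwork

__all__ = [
    "EnrichmentResult",
    "RankingMetric",
    "fet_enrich",
    "make_ranking_metric",
    "gsea_es",
    "gsea_empirical_p",
]

MIN_SET_SIZE = 3


@dataclass
class EnrichmentResult:
    """Per-regulator enrichment statistics (the P_E vector).

    ``table`` is indexed by regulator ID with columns ``method``,
    ``n_targets``, ``overlap``, ``es``, ``p_value``, ``p_adjusted``.
    Regulators skipped for too-small target sets carry NaN p-values.
    """

    table: pd.DataFrame

    @property
    def regulator_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def p_value(self) -> pd.Series:
        return self.table["p_value"]

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "regulator"
        out.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class RankingMetric:
    """Genes sorted decreasingly by r = z-scored -log differential p."""

    gene_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.r):
            raise ValueError("gene_ids and r must align")
        if not np.isfinite(self.r).all():
            raise ValueError("ranking metric contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.gene_ids)


def make_ranking_metric(de: DEResult, genes=None) -> RankingMetric:
    """Build the ranking metric r = standardize(-ln p), sorted descending.

    Standardization (mean 0, sample sd 1) makes the result independent of
    the log base.  Ties are broken by gene ID ascending; if all p-values
    are equal the metric degenerates to all zeros (with a warning).
    ``genes`` optionally restricts the universe (e.g. to network nodes).
    """
    tab = de.table if genes is None else de.table.loc[[g for g in de.gene_ids if g in set(genes)]]
    if tab.shape[0] < 2:
        raise ValueError("need at least 2 genes to build a ranking metric")
    p = np.clip(tab["p_value"].to_numpy(dtype=float), 1e-300, 1.0)
    neglog = -np.log(p)
    sd = neglog.std(ddof=1)
    if sd == 0:
        warnings.warn("all differential p-values equal; ranking metric is all zeros")
        r = np.zeros_like(neglog)
    else:
        r = (neglog - neglog.mean()) / sd
    order = sorted(range(len(r)), key=lambda i: (-r[i], tab.index[i]))
    return RankingMetric(
        gene_ids=[tab.index[i] for i in order],
        r=r[np.array(order)],
    )


# ---------------------------------------------------------------------------
# FET


def fet_enrich(
    net: RegulatorNetwork,
    de_genes,
    universe=None,
    min_set_size: int = MIN_SET_SIZE,
) -> EnrichmentResult:
    """Hypergeometric over-representation test for every regulon.

    The universe defaults to all network nodes; differential genes outside
    it are excluded.  For each regulator with s targets and overlap K, the
    p-value is the hypergeometric upper tail P(X >= K).  Regulators whose
    regulon (within the universe) has fewer than ``min_set_size`` genes
    are reported NA.
    """
    universe = set(universe) if universe is not None else set(net.nodes)
    n_universe = len(universe)
    de_set = set(de_genes) & universe
    m = len(de_set)
    if m == 0:
        warnings.warn("no differential gene inside the network universe; all p = 1")
    rows = []
    for reg, targets in net.target_sets().items():
        targets_in = [t for t in targets if t in universe]
        s = len(targets_in)
        k = sum(1 for t in targets_in if t in de_set)
        if s < min_set_size:
            rows.append((reg, s, k, np.nan))
            continue
        p = 1.0 if (m == 0 or k == 0) else float(
            stats.hypergeom.sf(k - 1, n_universe, m, s)
        )
        rows.append((reg, s, k, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["regulator", "n_targets", "overlap", "p_value"]
    ).set_index("regulator")
    table.insert(0, "method", "FET")
    table["es"] = np.nan
    table["p_adjusted"] = _bh_with_na(table["p_value"].to_numpy())
    return EnrichmentResult(table[["method", "n_targets", "overlap", "es", "p_value", "p_adjusted"]])


def _bh_with_na(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = np.maximum(bh_adjust(p[ok]), p[ok])
    return out


# ---------------------------------------------------------------------------
# GSEA


def _es_from_positions(abs_r: np.ndarray, hit_pos: np.ndarray) -> float:
    """ES for one target set given sorted |r| and (sorted) hit positions.

    The running difference P_hit - P_miss rises only at hit positions and
    falls linearly elsewhere, so its extrema occur immediately after or
    immediately before a hit (and the value at the end of the list is 0).
    """
    n = abs_r.size
    n_h = hit_pos.size
    if not 1 <= n_h < n:
        raise ValueError("target set must be a non-empty proper subset of the universe")
    w = abs_r[hit_pos]
    total = w.sum()
    denom_miss = n - n_h
    if total == 0:
        # all hit weights zero: P_hit never moves until normalization is
        # undefined; fall back to equal hit weights (degenerate flat metric)
        w = np.ones(n_h)
        total = float(n_h)
    cum = np.cumsum(w) / total
    j = np.arange(1, n_h + 1)
    after = cum - (hit_pos + 1 - j) / denom_miss
    before = np.concatenate(([0.0], cum[:-1])) - (hit_pos - (j - 1)) / denom_miss
    max_dp = max(after.max(), 0.0)
    min_dp = min(before.min(), 0.0)
    if max_dp >= -min_dp:
        return float(max_dp)
    return float(min_dp)


def _es_batch(abs_r: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Vectorized ES over a batch of hit-position sets (rows, sorted)."""
    n = abs_r.size
    n_h = hits.shape[1]
    denom_miss = n - n_h
    w = abs_r[hits]
    total = w.sum(axis=1, keepdims=True)
    flat = total[:, 0] == 0
    if flat.any():
        w[flat] = 1.0
        total[flat] = n_h
    cum = np.cumsum(w, axis=1) / total
    j = np.arange(1, n_h + 1)[None, :]
    after = cum - (hits + 1 - j) / denom_miss
    before = np.concatenate([np.zeros((hits.shape[0], 1)), cum[:, :-1]], axis=1) - (
        hits - (j - 1)
    ) / denom_miss
    max_dp = np.maximum(after.max(axis=1), 0.0)
    min_dp = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_dp >= -min_dp, max_dp, min_dp)


def gsea_es(metric: RankingMetric, target_set) -> float:
    """Weighted enrichment score of a target set along the sorted metric.

    Hits are weighted by |r| (normalized over the set); misses uniformly
    by 1/(N - N_H).  ES is the maximum running difference if it dominates
    in magnitude, else the minimum; ES lies in [-1, 1].  Returns NaN with
    a warning when the set is empty or covers the whole universe.
    """
    pos = {g: i for i, g in enumerate(metric.gene_ids)}
    hit = np.array(sorted(pos[g] for g in set(target_set) if g in pos), dtype=int)
    if hit.size == 0 or hit.size == metric.n:
        warnings.warn("target set empty or equal to the universe; ES undefined")
        return float("nan")
    return _es_from_positions(np.abs(metric.r), hit)


def gsea_empirical_p(
    metric: RankingMetric,
    target_sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    min_set_size: int = MIN_SET_SIZE,
) -> EnrichmentResult:
    """GSEA with a shared gene-permutation empirical null.

    One set of ``n_perm`` permutations of the gene labels of r is reused
    for every regulator (cheaper, and p-values are comparable across
    regulators).  The empirical p is one-sided on the sign of the
    observed ES, with a +1 pseudo-count:

        p = (1 + #{null ES at least as extreme, same sign})
            / (1 + #{null ES of the same sign})

    so the smallest attainable p is 1/(1 + same-sign count), never below
    1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    abs_r = np.abs(metric.r)
    n = metric.n
    pos = {g: i for i, g in enumerate(metric.gene_ids)}
    # position_perm[p, i] = where gene at sorted position i lands under perm p
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

    rows = []
    for reg in sorted(target_sets):
        genes = [g for g in target_sets[reg] if g in pos]
        n_h = len(set(genes))
        if n_h < min_set_size or n_h >= n:
            rows.append((reg, n_h, np.nan, np.nan))
            continue
        hit = np.array(sorted({pos[g] for g in genes}), dtype=int)
        es_obs = _es_from_positions(abs_r, hit)
        null = _es_batch(abs_r, np.sort(perms[:, hit], axis=1))
        if es_obs >= 0:
            same = null >= 0
            extreme = null >= es_obs
        else:
            same = null < 0
            extreme = null <= es_obs
        n_same = int(same.sum())
        if n_same == 0:
            warnings.warn(f"no permuted ES matches the sign of {reg}; p floored")
            p = 1.0 / (n_perm + 1)
        else:
            p = (1 + int((extreme & same).sum())) / (1 + n_same)
        rows.append((reg, n_h, es_obs, p))

    table = pd.DataFrame(
        rows, columns=["regulator", "n_targets", "es", "p_value"]
    ).set_index("regulator")
    table.insert(0, "method", "GSEA")
    table.insert(2, "overlap", table["n_targets"])
    table["p_adjusted"] = _bh_with_na(table["p_value"].to_numpy())
    return EnrichmentResult(table[["method", "n_targets", "overlap", "es", "p_value", "p_adjusted"]])
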