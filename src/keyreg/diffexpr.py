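"""Per-gene differential expression: the P_D stage of the pipeline.

Three tests are provided, covering the usual data kinds and designs:

* :func:`nb_wald_test` — negative-binomial Wald test for two-group count
  data (median-of-ratios size factors, method-of-moments gene-wise
  dispersion shrunk toward the across-gene trend);
* :func:`moderated_t_test` — linear model + empirical-Bayes variance
  shrinkage for two-group continuous (log-scale) data;
* :func:`likelihood_ratio_test` — nested-design likelihood-ratio test
  (NB likelihood for counts, Gaussian for continuous) for multi-group and
  time-series designs.

Each returns a :class:`DEResult` holding the raw p-value vector consumed
by the enrichment and ranking stages.  All p-values are clamped to
>= 1e-300 so downstream ``-log`` transforms stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionData

__all__ = [
    "DEResult",
    "bh_adjust",
    "estimate_size_factors",
    "nb_wald_test",
    "moderated_t_test",
    "likelihood_ratio_test",
    "design_matrix",
]

P_FLOOR = 1e-300
DISPERSION_FLOOR = 1e-8
LFC_PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """Per-gene differential statistics (the P_D vector plus effect sizes)."""

    table: pd.DataFrame  # index gene_id; columns log_fc, statistic, p_value, p_adjusted

    def __post_init__(self) -> None:
        required = {"log_fc", "statistic", "p_value", "p_adjusted"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DEResult table missing columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def p_value(self) -> pd.Series:
        return self.table["p_value"]

    @property
    def p_adjusted(self) -> pd.Series:
        return self.table["p_adjusted"]

    def significant_genes(self, fdr: float = 0.05) -> list[str]:
        """Genes with BH-adjusted p below ``fdr`` (the FET foreground set)."""
        return self.table.index[self.table["p_adjusted"] < fdr].tolist()

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    return stats.false_discovery_control(p, method="bh")


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, P_FLOOR, 1.0)


def _finish(gene_ids, log_fc, statistic, p) -> DEResult:
    p = _clamp(np.asarray(p, dtype=float))
    table = pd.DataFrame(
        {
            "log_fc": np.asarray(log_fc, dtype=float),
            "statistic": np.asarray(statistic, dtype=float),
            "p_value": p,
            "p_adjusted": np.maximum(bh_adjust(p), p),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return DEResult(table)


def _two_groups(data: ExpressionData, groups=None) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(groups, index=data.sample_ids) if groups is not None else data.groups
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {list(levels)}")
    mask_a = (labels == levels[0]).to_numpy()
    mask_b = (labels == levels[1]).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    return mask_a, mask_b


# ---------------------------------------------------------------------------
# counts path


def estimate_size_factors(counts: ExpressionData) -> np.ndarray:
    """Median-of-ratios size factors.

    For each sample j: factor_j = median over reference genes g of
    x_gj / geometric-mean_g, where the reference set is the genes with a
    positive geometric mean (i.e. no zero in any sample).
    """
    if counts.kind != "counts":
        raise ValueError("size factors are defined for counts data")
    x = counts.values.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; cannot form the "
            "median-of-ratios reference (filter all-zero-containing genes or "
            "use more genes)"
        )
    ref = x[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    return np.exp(np.median(ratios, axis=0))


def _nb_dispersion(q: np.ndarray, mask_a, mask_b, inv_sf_mean: float) -> np.ndarray:
    """Method-of-moments gene-wise NB dispersion, shrunk toward the trend mean.

    Uses Var(q) ~ mu * mean(1/sf) + alpha * mu^2 on size-factor-normalized
    counts, pooled over the two groups; gene-wise estimates are shrunk
    halfway (on the log scale) toward their across-gene mean.
    """
    n_a, n_b = mask_a.sum(), mask_b.sum()
    mu_a = q[:, mask_a].mean(axis=1)
    mu_b = q[:, mask_b].mean(axis=1)
    var_pooled = (
        (n_a - 1) * q[:, mask_a].var(axis=1, ddof=1)
        + (n_b - 1) * q[:, mask_b].var(axis=1, ddof=1)
    ) / (n_a + n_b - 2)
    mu = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_pooled - mu * inv_sf_mean) / mu**2
    alpha = np.clip(np.nan_to_num(alpha, nan=DISPERSION_FLOOR), DISPERSION_FLOOR, 10.0)
    log_trend = np.log(alpha).mean()
    return np.exp(0.5 * np.log(alpha) + 0.5 * log_trend)


def nb_wald_test(counts: ExpressionData, groups=None) -> DEResult:
    """Two-group NB Wald test on count data.

    Group means are estimated on size-factor-normalized counts; the Wald
    statistic is log2FC / SE(log2FC) with a delta-method SE using the
    gene-wise shrunken dispersion, referred to the standard normal.
    Genes with zero counts everywhere get log_fc = 0, p = 1.
    """
    mask_a, mask_b = _two_groups(counts, groups)
    sf = estimate_size_factors(counts)
    x = counts.values.to_numpy(dtype=float)
    q = x / sf[None, :]
    inv_sf_mean = float(np.mean(1.0 / sf))
    alpha = _nb_dispersion(q, mask_a, mask_b, inv_sf_mean)

    n_a, n_b = mask_a.sum(), mask_b.sum()
    mu_a = q[:, mask_a].mean(axis=1)
    mu_b = q[:, mask_b].mean(axis=1)
    log_fc = np.log2(mu_b + LFC_PSEUDOCOUNT) - np.log2(mu_a + LFC_PSEUDOCOUNT)

    # Var(log mu_hat_g) by the delta method: Var(mu_hat)/mu^2 with
    # Var(mu_hat) = mu * sum(1/sf_in_group)/n^2 + alpha * mu^2 / n
    def se_log(mu, mask, n):
        inv = np.sum(1.0 / sf[mask])
        mu_safe = mu + LFC_PSEUDOCOUNT
        return np.sqrt(inv / (n**2 * mu_safe) + alpha / n)

    se = np.sqrt(se_log(mu_a, mask_a, n_a) ** 2 + se_log(mu_b, mask_b, n_b) ** 2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log_fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (x == 0).all(axis=1)
    log_fc[all_zero] = 0.0
    z[all_zero] = 0.0
    p[all_zero] = 1.0
    return _finish(counts.gene_ids, log_fc, z, p)


# ---------------------------------------------------------------------------
# continuous path


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations on 1/trigamma)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments-matched scaled-inverse-chi-square prior (d0, s0^2) for
    gene-wise residual variances ~ s0^2 * chi2_df-scaled noise."""
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean, e_var = float(e.mean()), float(e.var(ddof=1))
    resid_var = e_var - float(special.polygamma(1, df / 2.0))
    if resid_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(resid_var)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t_test(
    data: ExpressionData,
    groups=None,
    prior_df: float | None = None,
) -> DEResult:
    """Two-group moderated t-test with empirical-Bayes variance shrinkage.

    Gene-wise residual variances are shrunk toward a pooled prior fitted
    by moment matching; the moderated t has ``df + prior_df`` degrees of
    freedom.  ``prior_df=0`` recovers the ordinary two-sample t-test;
    ``prior_df=None`` (default) estimates it from the data.
    """
    if data.kind != "continuous":
        raise ValueError("moderated t-test expects continuous data")
    mask_a, mask_b = _two_groups(data, groups)
    x = data.values.to_numpy(dtype=float)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    df = n_a + n_b - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    mean_a = x[:, mask_a].mean(axis=1)
    mean_b = x[:, mask_b].mean(axis=1)
    diff = mean_b - mean_a
    s2 = (
        (n_a - 1) * x[:, mask_a].var(axis=1, ddof=1)
        + (n_b - 1) * x[:, mask_b].var(axis=1, ddof=1)
    ) / df

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, df)
    elif prior_df == 0:
        d0, s0_2 = 0.0, 0.0
    else:
        d0, _s0 = prior_df, _fit_variance_prior(s2, df)[1]
        s0_2 = _s0

    if np.isinf(d0):
        post_var = np.full_like(s2, s0_2)
        total_df = np.inf
    else:
        post_var = (d0 * s0_2 + df * s2) / (d0 + df)
        total_df = d0 + df

    sed = np.sqrt(post_var * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sed > 0, diff / sed, 0.0)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    p[np.abs(t) == 0] = 1.0
    return _finish(data.gene_ids, diff, t, p)


# ---------------------------------------------------------------------------
# nested-design likelihood-ratio test


def design_matrix(annotations: pd.DataFrame, columns=()) -> np.ndarray:
    """Intercept + dummy-coded design for the given annotation columns.

    ``columns=()`` gives the intercept-only (reduced) design.  Categorical
    columns are dummy-coded dropping the first level; numeric columns enter
    as-is.
    """
    n = annotations.shape[0]
    blocks = [np.ones((n, 1))]
    for col in columns:
        v = annotations[col]
        if pd.api.types.is_numeric_dtype(v):
            blocks.append(v.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(v, drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
    return np.hstack(blocks)


def _check_nested(full: np.ndarray, reduced: np.ndarray) -> int:
    rank_full = np.linalg.matrix_rank(full)
    rank_red = np.linalg.matrix_rank(reduced)
    rank_joint = np.linalg.matrix_rank(np.hstack([full, reduced]))
    if rank_joint != rank_full:
        raise ValueError("reduced design is not nested in the full design")
    return rank_full - rank_red


def likelihood_ratio_test(
    data: ExpressionData,
    full_design: np.ndarray,
    reduced_design: np.ndarray,
) -> DEResult:
    """Per-gene LRT of a reduced design against a nested full design.

    Continuous data use the Gaussian profile likelihood
    (statistic = n * log(RSS_reduced / RSS_full)); counts use an NB GLM
    with a method-of-moments dispersion and log-size-factor offsets.  The
    statistic is referred to chi-square with df = rank difference.  The
    effect size reported is the range (max - min) of the full model's
    fitted values, a "maximal contrast" for multi-group designs.
    """
    full = np.asarray(full_design, dtype=float)
    reduced = np.asarray(reduced_design, dtype=float)
    if full.shape[0] != data.n_samples or reduced.shape[0] != data.n_samples:
        raise ValueError("design rows must match sample count")
    df_diff = _check_nested(full, reduced)
    n = data.n_samples
    if n - np.linalg.matrix_rank(full) <= 0:
        raise ValueError("full model has no residual degrees of freedom")

    if data.kind == "continuous":
        x = data.values.to_numpy(dtype=float)
        beta_f, *_ = np.linalg.lstsq(full, x.T, rcond=None)
        beta_r, *_ = np.linalg.lstsq(reduced, x.T, rcond=None)
        fit_f = (full @ beta_f).T
        rss_f = ((x - fit_f) ** 2).sum(axis=1)
        rss_r = ((x - (reduced @ beta_r).T) ** 2).sum(axis=1)
        eps = 1e-12 * np.maximum(1.0, rss_r)
        stat = n * (np.log(rss_r + eps) - np.log(rss_f + eps))
        stat = np.maximum(stat, 0.0)
        contrast = fit_f.max(axis=1) - fit_f.min(axis=1)
    else:
        stat, contrast = _nb_lrt(data, full, reduced)

    if df_diff == 0:
        p = np.ones_like(stat)
        stat = np.zeros_like(stat)
    else:
        p = stats.chi2.sf(stat, df_diff)
    return _finish(data.gene_ids, contrast, stat, p)


def _nb_lrt(counts: ExpressionData, full, reduced):
    import statsmodels.api as sm

    sf = estimate_size_factors(counts)
    offset = np.log(sf)
    x = counts.values.to_numpy(dtype=float)
    n = counts.n_samples
    stat = np.zeros(x.shape[0])
    contrast = np.zeros(x.shape[0])
    df_resid = n - np.linalg.matrix_rank(full)
    for g in range(x.shape[0]):
        y = x[g]
        if (y == 0).all():
            continue
        pois = sm.GLM(y, full, family=sm.families.Poisson(), offset=offset).fit()
        mu = np.maximum(pois.fittedvalues, 1e-8)
        alpha = max(
            float(np.sum(((y - mu) ** 2 - mu) / mu**2) / max(df_resid, 1)),
            DISPERSION_FLOOR,
        )
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            fit_f = sm.GLM(y, full, family=fam, offset=offset).fit()
            fit_r = sm.GLM(y, reduced, family=fam, offset=offset).fit()
            stat[g] = max(2.0 * (fit_f.llf - fit_r.llf), 0.0)
            mu_f = np.maximum(fit_f.fittedvalues / sf, 1e-8)
            contrast[g] = np.log2(mu_f.max() + LFC_PSEUDOCOUNT) - np.log2(
                mu_f.min() + LFC_PSEUDOCOUNT
            )
        except Exception:
            stat[g] = 0.0
    return stat, contrast
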