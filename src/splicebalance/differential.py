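"""Three-level differential testing with an empirical-Bayes moderated t.

Gene expression (GE), exon expression (EE) and splicing index (SI) values
are all tested with the same machinery: a pooled two-sample linear model
per feature whose residual variance s^2 is shrunk toward an empirical-
Bayes prior (d0, s0^2) fitted across features.  The posterior variance

    s_tilde^2 = (d0 * s0^2 + df * s^2) / (d0 + df)

replaces s^2 in the t-statistic, which then has d0 + df degrees of
freedom (standard normal in the limit d0 = infinity).  This is the
moderated t of the Smyth (2004) hierarchical model, restricted to the
two-group design; the prior is estimated by the method of moments on
log s^2 with trigamma inversion.

p-values are corrected per screen with the Benjamini-Hochberg step-up;
gene-level calls use a single stringent q threshold (default 0.001) at
both the gene level (GE) and the probe level (SI: a gene is called when
one or more of its probes passes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigurationError, DataError


@dataclass
class EBPrior:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ConfigurationError("d0 must be > 0 (use math.inf for no dispersion)")
        if not (self.s0_sq > 0):
            raise ConfigurationError("s0_sq must be > 0")


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    # trigamma(y) ~ 1/y for large y, ~ 1/y^2 for small y
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = special.polygamma(2, y)
        delta = (tri - x) / dif
        y -= delta
        if y <= 0:
            y = 1e-8
        if abs(delta) < tol * y:
            break
    return float(y)


def fit_eb_prior(s2_vector, df: float) -> EBPrior:
    """Fit (d0, s0^2) by moments of log s^2 under the scaled-F model.

    Under the hierarchical model s^2 | sigma^2 ~ sigma^2 chi^2_df / df and
    1/sigma^2 ~ chi^2_d0 / (d0 s0^2), the statistic e = log s^2 -
    digamma(df/2) + log(df/2) has variance trigamma(df/2) + trigamma(d0/2);
    matching the empirical variance of e yields d0 and then s0^2.  When
    the empirical variance does not exceed trigamma(df/2) the features
    are consistent with a single common variance and d0 = infinity.
    """
    s2 = np.asarray(s2_vector, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if (s2 < 0).any():
        raise DataError("negative variances supplied to fit_eb_prior")
    if (s2 == 0).all() or len(s2) == 0:
        raise DataError("all residual variances are zero; cannot fit a variance prior")
    s2 = s2[s2 > 0]
    z = np.log(s2)
    if np.ptp(z) == 0:
        # zero dispersion: all features share one variance exactly
        return EBPrior(math.inf, float(s2[0]))
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    if len(s2) < 10:
        warnings.warn("fewer than 10 positive variances: falling back to d0 = inf")
        return EBPrior(math.inf, float(np.mean(s2)))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # under-dispersed log-variances: a single prior variance explains
        # everything; the plug-in estimate is the mean observed variance
        return EBPrior(math.inf, float(np.mean(s2)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return EBPrior(d0, s0_sq)


def moderated_t_test(
    matrix: pd.DataFrame,
    groups,
    prior: EBPrior | str | None = "fit",
    group_order: tuple[str, str] | None = None,
    level: str = "GE",
) -> pd.DataFrame:
    """Per-feature two-group moderated t-test.

    Parameters
    ----------
    matrix : DataFrame
        features x samples.
    groups : sequence or Series
        group label per sample (exactly two distinct labels).
    prior : EBPrior, "fit", or None
        ``"fit"`` estimates the variance prior from the data; ``None``
        disables moderation (classical pooled t).
    group_order : optional (a, b)
        effect = mean(a) - mean(b); defaults to sorted label order.

    Returns a DifferentialTable (one row per feature) with columns
    ``gene_id`` left to the caller to join; includes ``q`` via
    :func:`bh_adjust` over the whole screen.
    """
    labels = pd.Series(np.asarray(groups), index=matrix.columns)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise DataError(f"moderated_t_test requires exactly two groups, got {uniq}")
    if group_order is None:
        group_order = (uniq[0], uniq[1])
    a, b = group_order
    if set((a, b)) != set(uniq):
        raise ConfigurationError(f"group_order {group_order} does not match labels {uniq}")
    xa = matrix.loc[:, labels == a].to_numpy(dtype=float)
    xb = matrix.loc[:, labels == b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise DataError("each group needs >= 2 samples")
    df = na + nb - 2
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    effect = mean_a - mean_b
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if prior == "fit":
        prior = fit_eb_prior(s2, df)
    if prior is None:
        post_s2, total_df = s2, float(df)
    else:
        if math.isinf(prior.d0):
            post_s2 = np.full_like(s2, prior.s0_sq)
            total_df = math.inf
        else:
            post_s2 = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
            total_df = prior.d0 + df
    se = np.sqrt(post_s2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, effect / se, np.where(effect == 0, 0.0, np.inf))
    if math.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), total_df)
    p = np.where((se == 0) & (effect == 0), 1.0, p)

    out = pd.DataFrame(
        {
            "level": level,
            "group_a": a,
            "group_b": b,
            "effect": effect,
            "s2": s2,
            "df": float(df),
            "t_mod": t_mod,
            "p": p,
        },
        index=matrix.index.rename("feature_id"),
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p_vector) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; rank order of
    the input is preserved and q >= p elementwise.
    """
    p = np.asarray(p_vector, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise DataError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_genes(
    ge_table: pd.DataFrame,
    si_table: pd.DataFrame,
    annotation: pd.DataFrame,
    q_threshold: float = 0.001,
) -> pd.DataFrame:
    """Gene-level differential calls from a GE screen and an SI screen.

    A gene is differentially expressed when its gene-level q is below the
    threshold, and has a splicing imbalance when the SI q of one or more
    of its probes is below the threshold.  Genes with a single probe are
    excluded from the splicing call (their SI is identically 1).

    Returns a GeneCallTable indexed by gene_id with ``de_flag``,
    ``si_flag`` and ``category`` in {GE_only, SI_only, both, neither}.
    """
    probe_gene = annotation.loc[si_table.index, "gene_id"]
    probe_counts = probe_gene.value_counts()
    multi = probe_counts.index[probe_counts >= 2]
    si_sub = si_table.loc[probe_gene.isin(multi)]
    si_genes = set(probe_gene.loc[si_sub.index])
    missing = si_genes - set(ge_table.index)
    if missing:
        raise DataError(f"genes in SI table absent from GE table: {sorted(missing)[:10]}")

    min_si_q = si_sub["q"].groupby(probe_gene.loc[si_sub.index]).min()
    genes = ge_table.index
    de_flag = ge_table["q"] < q_threshold
    si_flag = pd.Series(False, index=genes)
    si_flag.loc[min_si_q.index] = min_si_q < q_threshold
    category = np.select(
        [de_flag & si_flag, de_flag & ~si_flag, ~de_flag & si_flag],
        ["both", "GE_only", "SI_only"],
        default="neither",
    )
    return pd.DataFrame(
        {"de_flag": de_flag, "si_flag": si_flag, "category": category},
        index=genes.rename("gene_id"),
    )


def partition_summary(call_table: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of genes per differential category.

    Fractions are reported both over the perturbed-gene subset
    {GE_only, SI_only, both} (the bar-chart semantics of group-pair
    comparisons) and over all tested genes.
    """
    if len(call_table) == 0:
        raise DataError("empty gene-call table")
    cats = ["GE_only", "SI_only", "both", "neither"]
    counts = call_table["category"].value_counts().reindex(cats, fill_value=0)
    n_perturbed = int(counts[["GE_only", "SI_only", "both"]].sum())
    out = pd.DataFrame({"count": counts})
    out["fraction_all"] = counts / len(call_table)
    out["fraction_perturbed"] = [
        counts[c] / n_perturbed if (c != "neither" and n_perturbed) else np.nan
        for c in cats
    ]
    out.index.name = "category"
    return out


def pvalue_null_diagnostics(
    matrix: pd.DataFrame,
    groups,
    n_permutations: int = 200,
    seed: int = 0,
    alphas=(0.001, 0.01, 0.05),
) -> dict:
    """Compare the observed p-value distribution with two nulls.

    Null (i) is the uniform distribution; null (ii) is the Monte-Carlo
    distribution of p-values pooled over random permutations of the
    sample labels.  Deviation is summarized by Kolmogorov-Smirnov
    statistics plus the observed fraction of p-values below each alpha.
    """
    if n_permutations < 10:
        raise ConfigurationError("n_permutations must be >= 10")
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) != 2:
        raise DataError("diagnostics require exactly two groups")
    n_arrangements = math.comb(int(counts.sum()), int(counts[0]))
    if n_arrangements < 2:
        raise DataError("groups too small to permute distinctly")
    observed = moderated_t_test(matrix, labels)["p"].to_numpy()
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        pooled.append(moderated_t_test(matrix, perm)["p"].to_numpy())
    pooled = np.concatenate(pooled)
    ks_uniform = stats.kstest(observed, "uniform")
    ks_perm = stats.ks_2samp(observed, pooled)
    return {
        "ks_uniform": float(ks_uniform.statistic),
        "ks_uniform_p": float(ks_uniform.pvalue),
        "ks_perm": float(ks_perm.statistic),
        "ks_perm_p": float(ks_perm.pvalue),
        "n_permutations": n_permutations,
        "frac_below": {a: float(np.mean(observed < a)) for a in alphas},
        "perm_pvalues": pooled,
    }


def pairwise_similarity(matrix: pd.DataFrame, groups) -> dict:
    """Within- vs between-group sample similarity as R^2.

    R^2 is the squared Pearson correlation of every sample pair's feature
    vectors; pairs involving a constant sample are excluded with a
    warning.  The within/between difference is tested with a two-sided
    Mann-Whitney rank-sum test.
    """
    labels = pd.Series(np.asarray(groups), index=matrix.columns)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise DataError("pairwise_similarity requires >= 2 groups with >= 2 samples each")
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=0)
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant sample(s) from similarity")
    values = values[:, keep]
    lab = labels.to_numpy()[keep]
    r = np.corrcoef(values, rowvar=False)
    r2 = r**2
    n = values.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    same = lab[iu] == lab[ju]
    within = r2[iu, ju][same]
    between = r2[iu, ju][~same]
    if len(within) == 0 or len(between) == 0:
        raise DataError("need both within- and between-group sample pairs")
    stat = stats.mannwhitneyu(within, between, alternative="two-sided")
    return {
        "mean_within_r2": float(within.mean()),
        "mean_between_r2": float(between.mean()),
        "n_within_pairs": int(len(within)),
        "n_between_pairs": int(len(between)),
        "ranksum_p": float(stat.pvalue),
    }
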