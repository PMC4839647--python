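"""Per-feature differential testing between the cancer and normal arms of a split.

Genes: two-sample pooled-variance t-test, optionally with empirical-Bayes
variance shrinkage (a moderated t: per-gene variances are squeezed toward a
prior fitted by method of moments on the log sample variances, and the
reference t distribution gains the prior degrees of freedom).

Metabolites: a variance-equality F pretest chooses between the pooled and
Welch t-tests.  ``as_published`` uses the equal-variance test when the
pretest p < 0.05 (the published description, which inverts the conventional
rule); ``conventional`` does the reverse.

Multiple testing: Benjamini-Hochberg step-up across all features.
"""

from __future__ import annotations

import logging
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import Cohort, DifferentialResult, ValidationError
from .tissue_balance import DatasetSplit

__all__ = [
    "quantile_normalize",
    "benjamini_hochberg",
    "fit_variance_prior",
    "differential_genes",
    "differential_metabolites",
    "average_pvalues",
]

logger = logging.getLogger(__name__)

_MAX_DF = 1e6  # stands in for an infinite-prior t (≈ normal)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force every column onto the common reference distribution.

    The reference is the vector of row-wise means of the column-sorted
    values.  Ties within a column receive the mean of the reference values at
    their tied ranks.  Apply to the full cohort before any sample splitting.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError(f"expected a non-empty 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite entries")
    n, m = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        order = np.argsort(X[:, j], kind="mergesort")
        col = np.empty(n)
        col[order] = ref
        # average the reference over runs of tied input values
        _, inv, counts = np.unique(X[order, j], return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=ref)
        col[order] = (sums / counts)[inv]
        out[:, j] = col
    return out


def benjamini_hochberg(p_raw: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 (Newton on the monotone trigamma)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior df d0, prior variance s0^2).

    Models the per-feature sample variances as scaled F draws around a common
    prior: on z = log(s^2), E[z] and Var[z] are closed forms in digamma /
    trigamma, which are inverted here.  Returns ``d0 = inf`` when the
    observed spread of z is no larger than expected under a single shared
    variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValidationError("need >=2 positive variances to fit a prior")
    z = np.log(s2)
    d2 = df / 2.0
    evar = z.var(ddof=1) - special.polygamma(1, d2)
    emean = z.mean() - special.digamma(d2) + np.log(d2)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
    return float(d0), float(s0_2)


def _direction(mean_diff: float) -> str:
    return "up_in_cancer" if mean_diff > 0 else "down_in_cancer"


def _assign_ranks(
    feature_ids: Sequence[str], p_raw: np.ndarray, mean_diff: np.ndarray
) -> np.ndarray:
    """Ranks 1..n by ascending p, ties by |mean_diff| descending then id."""
    order = sorted(
        range(len(feature_ids)),
        key=lambda i: (p_raw[i], -abs(mean_diff[i]), feature_ids[i]),
    )
    ranks = np.empty(len(feature_ids), dtype=int)
    ranks[order] = np.arange(1, len(feature_ids) + 1)
    return ranks


def _build_results(
    feature_ids: Sequence[str],
    mean_diff: np.ndarray,
    statistic: np.ndarray,
    p_raw: np.ndarray,
    p_adj: np.ndarray,
) -> list[DifferentialResult]:
    ranks = _assign_ranks(feature_ids, p_raw, mean_diff)
    return [
        DifferentialResult(
            feature_id=fid,
            mean_diff=float(mean_diff[i]),
            statistic=float(statistic[i]),
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            direction=_direction(float(mean_diff[i])),
            rank=int(ranks[i]),
        )
        for i, fid in enumerate(feature_ids)
    ]


def _split_arms(split: DatasetSplit, cohort: Cohort, matrix: np.ndarray):
    xc = matrix[:, cohort.sample_index(split.cancer_ids)]
    xn = matrix[:, cohort.sample_index(split.normal_ids)]
    if xc.shape[1] < 2 or xn.shape[1] < 2:
        raise ValidationError(
            f"split {split.name!r}: need >=2 samples per arm, got "
            f"{xc.shape[1]} cancer / {xn.shape[1]} normal"
        )
    return xc, xn


def differential_genes(
    split: DatasetSplit,
    cohort: Cohort,
    moderation: bool = True,
    prior_df: float | None = None,
) -> list[DifferentialResult]:
    """Per-gene cancer-vs-normal t-test on the (pre-normalized) gene matrix.

    With ``moderation`` the per-gene pooled variance is replaced by the
    empirical-Bayes squeeze ``(d0*s0^2 + d*s^2) / (d0 + d)`` and the t uses
    d0 + d degrees of freedom.  ``prior_df`` overrides the fitted d0
    (``prior_df=0`` reproduces the ordinary pooled t exactly).
    """
    xc, xn = _split_arms(split, cohort, cohort.gene_matrix)
    n1, n2 = xc.shape[1], xn.shape[1]
    df = n1 + n2 - 2
    mean_diff = xc.mean(axis=1) - xn.mean(axis=1)
    s2 = ((n1 - 1) * xc.var(axis=1, ddof=1) + (n2 - 1) * xn.var(axis=1, ddof=1)) / df

    if moderation:
        if prior_df is None:
            d0, s0_2 = fit_variance_prior(s2, df)
        elif prior_df == 0:
            d0, s0_2 = 0.0, 1.0  # zero weight: s0_2 irrelevant
        else:
            d0, _ = prior_df, None
            _, s0_2 = fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_used = np.full_like(s2, s0_2)
            df_used = _MAX_DF
        else:
            s2_used = (d0 * s0_2 + df * s2) / (d0 + df)
            df_used = d0 + df
    else:
        s2_used, df_used = s2, df

    zero_var = s2_used == 0
    if np.any(zero_var):
        logger.warning(
            "%d feature(s) with zero variance in both arms; p set to 1", zero_var.sum()
        )
    se = np.sqrt(np.where(zero_var, 1.0, s2_used) * (1.0 / n1 + 1.0 / n2))
    t = np.where(zero_var, 0.0, mean_diff / se)
    p_raw = np.where(zero_var, 1.0, 2.0 * stats.t.sf(np.abs(t), df_used))
    p_raw = np.clip(p_raw, np.nextafter(0, 1), 1.0)
    p_adj = benjamini_hochberg(p_raw)
    return _build_results(cohort.gene_ids, mean_diff, t, p_raw, p_adj)


def differential_metabolites(
    split: DatasetSplit,
    cohort: Cohort,
    variance_rule: Literal["as_published", "conventional"] = "as_published",
    var_alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Per-metabolite t-test with an F variance-equality pretest.

    p_adj is still reported (BH over the 23 features) but significance calls
    in the published workflow use raw p.
    """
    if cohort.metabolite_matrix is None:
        raise ValidationError("cohort has no metabolite matrix")
    if variance_rule not in ("as_published", "conventional"):
        raise ValueError(f"unknown variance_rule {variance_rule!r}")
    xc, xn = _split_arms(split, cohort, cohort.metabolite_matrix)
    n1, n2 = xc.shape[1], xn.shape[1]
    mean_diff = xc.mean(axis=1) - xn.mean(axis=1)

    v1 = xc.var(axis=1, ddof=1)
    v2 = xn.var(axis=1, ddof=1)
    t_stat = np.empty(len(cohort.metabolite_ids))
    p_raw = np.empty_like(t_stat)
    for i in range(len(t_stat)):
        if v1[i] == 0 and v2[i] == 0:
            logger.warning(
                "metabolite %s has zero variance in both arms; p set to 1",
                cohort.metabolite_ids[i],
            )
            t_stat[i], p_raw[i] = 0.0, 1.0
            continue
        # two-sided F pretest on the variance ratio
        if v2[i] == 0 or v1[i] == 0:
            p_var = 0.0
        else:
            f = v1[i] / v2[i]
            cdf = stats.f.cdf(f, n1 - 1, n2 - 1)
            p_var = 2.0 * min(cdf, 1.0 - cdf)
        equal_var = (p_var < var_alpha) if variance_rule == "as_published" else (
            p_var >= var_alpha
        )
        res = stats.ttest_ind(xc[i], xn[i], equal_var=equal_var)
        t_stat[i], p_raw[i] = res.statistic, res.pvalue
    p_raw = np.clip(p_raw, np.nextafter(0, 1), 1.0)
    p_adj = benjamini_hochberg(p_raw)
    return _build_results(cohort.metabolite_ids, mean_diff, t_stat, p_raw, p_adj)


def average_pvalues(
    results_list: Sequence[Sequence[DifferentialResult]],
) -> list[DifferentialResult]:
    """Average raw p per feature over replicate splits (the unstratified summary).

    BH is recomputed on the averaged p.  Direction is the majority sign of
    the replicate mean differences; ties fall back to the sign of the mean.
    """
    if not results_list:
        raise ValidationError("results_list is empty")
    ref_ids = [r.feature_id for r in results_list[0]]
    ref_set = set(ref_ids)
    by_rep = []
    for k, res in enumerate(results_list):
        ids = {r.feature_id for r in res}
        if ids != ref_set:
            raise ValidationError(
                f"replicate {k} feature set differs from replicate 0 "
                f"(e.g. {sorted(ids ^ ref_set)[:5]})"
            )
        by_rep.append({r.feature_id: r for r in res})

    p_mean = np.array([np.mean([rep[f].p_raw for rep in by_rep]) for f in ref_ids])
    diffs = np.array([[rep[f].mean_diff for rep in by_rep] for f in ref_ids])
    stat_mean = np.array(
        [np.mean([rep[f].statistic for rep in by_rep]) for f in ref_ids]
    )
    sign_votes = np.sign(diffs).sum(axis=1)
    mean_diff = diffs.mean(axis=1)
    # majority sign, falling back to the mean's sign on a tie
    direction_value = np.where(sign_votes != 0, sign_votes, mean_diff)
    p_adj = benjamini_hochberg(p_mean)
    ranks = _assign_ranks(ref_ids, p_mean, mean_diff)
    return [
        DifferentialResult(
            feature_id=f,
            mean_diff=float(mean_diff[i]),
            statistic=float(stat_mean[i]),
            p_raw=float(p_mean[i]),
            p_adj=float(p_adj[i]),
            direction=_direction(float(direction_value[i]) or float(mean_diff[i])),
            rank=int(ranks[i]),
        )
        for i, f in enumerate(ref_ids)
    ]
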