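"""Per-unit differential methylation testing and multiple-testing correction.

At every unit (cytosine, tile or region) the methylated/unmethylated read
counts of each sample are modelled as binomial draws.  With replicates in at
least one group the methylation proportion :math:`P_i` of sample *i* is
modelled by logistic regression,

    logit(P_i) = beta0 + beta1 * T_i  (+ covariate terms),

where ``T_i`` is the treatment indicator (0 = control), and the null
``beta1 = 0`` is tested per unit — by likelihood ratio against a chi-square
reference by default, or by a Wald test.  With a single sample per group the
2x2 table of pooled counts is tested by Fisher's exact test instead.  The
relevant sample size is the total read coverage per group, not the number of
biological replicates.

P-values are corrected to q-values either by Benjamini-Hochberg or by a
sliding-linear-model (SLIM) estimate of the null proportion pi0 that rescales
the BH q-values (q_slim = pi0_hat * q_BH), which is less conservative when
many units are truly differential.

The methylation difference reported per unit is computed on pooled group
counts, ``100 * (sum_T m / sum_T cov - sum_C m / sum_C cov)``, so samples are
coverage-weighted exactly as in the binomial model.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import ValidationError
from .regionalize import UnitedMethylome

logger = logging.getLogger("bsmethkit")

DIFF_COLUMNS = ["chrom", "start", "end", "strand", "pvalue", "qvalue", "meth_diff"]

#: Default DMC/DMR extraction cutoffs: q-value < 0.01, |diff| > 25 points.
DEFAULT_QVALUE_CUT = 0.01
DEFAULT_DIFF_CUT = 25.0


@dataclass(frozen=True)
class ModelSpec:
    """Test configuration for :func:`calculate_diff_meth`.

    ``covariates`` maps covariate names to per-sample value sequences aligned
    to the united samples; categorical covariates are passed as strings and
    dummy-coded.  ``test`` selects the statistic for the logistic model;
    ``correction`` the p-to-q conversion.
    """

    covariates: dict[str, tuple] | None = None
    test: str = "likelihood_ratio"
    correction: str = "slim"

    def __post_init__(self) -> None:
        if self.test not in ("likelihood_ratio", "wald"):
            raise ValidationError("test must be 'likelihood_ratio' or 'wald'")
        if self.correction not in ("slim", "bh"):
            raise ValidationError("correction must be 'slim' or 'bh'")


# -- elementary tests ---------------------------------------------------------


def _ll(m, u):
    """sum m*log(m/(m+u)) + u*log(u/(m+u)) with 0*log(0) = 0."""
    from scipy.special import xlogy

    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    tot = m + u
    return xlogy(m, m) + xlogy(u, u) - xlogy(tot, tot)


def pooled_meth_diff(n_meth: np.ndarray, n_unmeth: np.ndarray,
                     treatment: np.ndarray) -> float:
    """Treatment minus control percent methylation on pooled counts."""
    treatment = np.asarray(treatment)
    t_mask = treatment != 0
    m = np.asarray(n_meth, dtype=float)
    u = np.asarray(n_unmeth, dtype=float)
    p_t = m[t_mask].sum() / (m[t_mask] + u[t_mask]).sum()
    p_c = m[~t_mask].sum() / (m[~t_mask] + u[~t_mask]).sum()
    return 100.0 * (p_t - p_c)


def logistic_test(n_meth, n_unmeth, treatment, spec: ModelSpec | None = None):
    """Binomial logistic-regression test of one unit.

    Parameters are per-sample methylated/unmethylated counts and the integer
    treatment vector (0 = control).  Returns ``(pvalue, meth_diff, beta1)``
    where ``beta1`` is the log odds ratio of the (first) treatment group
    versus control.  The default likelihood-ratio statistic compares the
    group-saturated fit with the pooled null against a chi-square with
    df = number of treatment parameters; it stays finite under complete
    separation (all-0% vs all-100%).
    """
    spec = spec or ModelSpec()
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    treatment = np.asarray(treatment, dtype=int)
    if len(np.unique(treatment)) < 2:
        raise ValidationError("logistic_test needs at least two treatment groups")
    if np.any(n_meth + n_unmeth < 1):
        raise ValidationError("every sample needs coverage >= 1")

    meth_diff = pooled_meth_diff(n_meth, n_unmeth, treatment)

    if spec.covariates or spec.test == "wald":
        pvalue, beta1 = _glm_test(n_meth, n_unmeth, treatment, spec)
        return pvalue, meth_diff, beta1

    groups = np.unique(treatment)
    m_g = np.array([n_meth[treatment == g].sum() for g in groups])
    u_g = np.array([n_unmeth[treatment == g].sum() for g in groups])
    g_stat = 2.0 * (_ll(m_g, u_g).sum() - _ll(m_g.sum(), u_g.sum()))
    g_stat = max(0.0, float(g_stat))
    df = len(groups) - 1
    pvalue = float(stats.chi2.sf(g_stat, df))

    p0 = m_g[groups == 0][0] / (m_g[groups == 0][0] + u_g[groups == 0][0])
    g1 = groups[groups != 0][0]
    p1 = m_g[groups == g1][0] / (m_g[groups == g1][0] + u_g[groups == g1][0])
    with np.errstate(divide="ignore"):
        beta1 = float(np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))) if 0 < p0 < 1 and 0 < p1 < 1 \
            else float(np.sign(p1 - p0) * np.inf)
    return pvalue, meth_diff, beta1


def _glm_test(n_meth, n_unmeth, treatment, spec: ModelSpec):
    """GLM route: binomial fit via statsmodels, LRT or Wald on treatment."""
    import statsmodels.api as sm

    n = len(n_meth)
    endog = np.column_stack([n_meth, n_unmeth])
    design = {"const": np.ones(n)}
    groups = np.unique(treatment)
    t_cols = []
    for g in groups[groups != 0]:
        col = f"treat_{g}"
        design[col] = (treatment == g).astype(float)
        t_cols.append(col)
    if spec.covariates:
        for name, values in spec.covariates.items():
            values = np.asarray(values)
            if len(values) != n:
                raise ValidationError(f"covariate {name!r} length {len(values)} != {n} samples")
            if values.dtype.kind in "OUS":  # categorical -> dummies, first level dropped
                levels = np.unique(values)
                for lv in levels[1:]:
                    design[f"{name}_{lv}"] = (values == lv).astype(float)
            else:
                design[name] = values.astype(float)
    exog_full = pd.DataFrame(design)
    exog_null = exog_full.drop(columns=t_cols)

    full = sm.GLM(endog, exog_full, family=sm.families.Binomial()).fit()
    beta1 = float(full.params[t_cols[0]]) if t_cols else np.nan
    if spec.test == "wald":
        z = full.params[t_cols[0]] / full.bse[t_cols[0]]
        pvalue = float(stats.chi2.sf(z * z, 1))
    else:
        null = sm.GLM(endog, exog_null, family=sm.families.Binomial()).fit()
        g_stat = max(0.0, float(null.deviance - full.deviance))
        pvalue = float(stats.chi2.sf(g_stat, len(t_cols)))
    return pvalue, beta1


def fisher_test(n_meth_t: int, n_unmeth_t: int, n_meth_c: int, n_unmeth_c: int):
    """Two-sided Fisher's exact test of a pooled 2x2 table (1-vs-1 designs).

    Uses the point-probability method: the p-value sums hypergeometric
    probabilities of all tables with the observed margins that are no more
    likely than the observed one.  Returns ``(pvalue, meth_diff)``.
    """
    for v in (n_meth_t, n_unmeth_t, n_meth_c, n_unmeth_c):
        if v < 0:
            raise ValidationError("counts must be non-negative")
    if n_meth_t + n_unmeth_t < 1 or n_meth_c + n_unmeth_c < 1:
        raise ValidationError("both samples need coverage >= 1")
    _, pvalue = stats.fisher_exact(
        [[n_meth_t, n_unmeth_t], [n_meth_c, n_unmeth_c]], alternative="two-sided"
    )
    meth_diff = 100.0 * (
        n_meth_t / (n_meth_t + n_unmeth_t) - n_meth_c / (n_meth_c + n_unmeth_c)
    )
    return float(pvalue), meth_diff


# -- vectorized per-unit machinery --------------------------------------------


def _lrt_pvalues_vectorized(meth_by_group: np.ndarray, unmeth_by_group: np.ndarray) -> np.ndarray:
    """Likelihood-ratio p-values for all units at once.

    Inputs are (units x groups) pooled count matrices.  Valid for the
    treatment-only design, where the binomial MLE is the per-group pooled
    proportion.
    """
    ll_full = _ll(meth_by_group, unmeth_by_group).sum(axis=1)
    ll_null = _ll(meth_by_group.sum(axis=1), unmeth_by_group.sum(axis=1))
    g_stat = np.maximum(0.0, 2.0 * (ll_full - ll_null))
    df = meth_by_group.shape[1] - 1
    return stats.chi2.sf(g_stat, df)


def _test_chunk(args) -> np.ndarray:
    """P-values for a chunk of units; top-level for process-pool pickling."""
    meth, unmeth, treatment, spec, use_fisher = args
    n_units = meth.shape[0]
    if use_fisher:
        t_idx = np.where(treatment != 0)[0][0]
        c_idx = np.where(treatment == 0)[0][0]
        out = np.empty(n_units)
        for i in range(n_units):
            out[i], _ = fisher_test(
                int(meth[i, t_idx]), int(unmeth[i, t_idx]),
                int(meth[i, c_idx]), int(unmeth[i, c_idx]),
            )
        return out
    if not spec.covariates and spec.test == "likelihood_ratio":
        groups = np.unique(treatment)
        m_g = np.column_stack([meth[:, treatment == g].sum(axis=1) for g in groups])
        u_g = np.column_stack([unmeth[:, treatment == g].sum(axis=1) for g in groups])
        return _lrt_pvalues_vectorized(m_g, u_g)
    out = np.empty(n_units)
    for i in range(n_units):
        out[i], _, _ = logistic_test(meth[i], unmeth[i], treatment, spec)
    return out


def calculate_diff_meth(u: UnitedMethylome, spec: ModelSpec | None = None,
                        workers: int = 1) -> pd.DataFrame:
    """Differential methylation across all units of a united methylome.

    Dispatches per the design: Fisher's exact test when there is exactly one
    sample per group (two groups), logistic regression otherwise.  Returns a
    DiffTable frame with columns ``chrom, start, end, strand, pvalue, qvalue,
    meth_diff`` in unit order; q-values come from :func:`adjust_pvalues` with
    the spec's correction.  Work is chunked by genomic position across
    ``workers`` processes and concatenated in unit order, so the result is
    identical for any ``workers >= 1``.
    """
    spec = spec or ModelSpec()
    if workers < 1:
        raise ValidationError("workers must be >= 1")
    treatment = np.asarray(u.treatments, dtype=int)
    groups, sizes = np.unique(treatment, return_counts=True)
    if 0 not in groups or len(groups) < 2:
        raise ValidationError("need a control group (treatment 0) and at least one test group")

    meth = np.column_stack([u.counts(s)[0] for s in u.samples]).astype(np.int64)
    unmeth = np.column_stack([u.counts(s)[1] for s in u.samples]).astype(np.int64)
    n_units = len(u)
    use_fisher = len(groups) == 2 and np.all(sizes == 1) and not spec.covariates

    if n_units == 0:
        pvalues = np.empty(0)
    else:
        bounds = np.linspace(0, n_units, min(workers, n_units) + 1).astype(int)
        chunks = [
            (meth[a:b], unmeth[a:b], treatment, spec, use_fisher)
            for a, b in zip(bounds[:-1], bounds[1:]) if b > a
        ]
        if workers > 1 and len(chunks) > 1:
            with ProcessPoolExecutor(max_workers=workers) as pool:
                parts = list(pool.map(_test_chunk, chunks))
        else:
            parts = [_test_chunk(c) for c in chunks]
        pvalues = np.concatenate(parts)

    t_mask = treatment != 0
    with np.errstate(invalid="ignore"):
        p_t = meth[:, t_mask].sum(axis=1) / (meth[:, t_mask] + unmeth[:, t_mask]).sum(axis=1)
        p_c = meth[:, ~t_mask].sum(axis=1) / (meth[:, ~t_mask] + unmeth[:, ~t_mask]).sum(axis=1)
    out = u.df[["chrom", "start", "end", "strand"]].copy()
    out["pvalue"] = pvalues
    out["qvalue"] = adjust_pvalues(pvalues, spec.correction) if n_units else pvalues
    out["meth_diff"] = 100.0 * (p_t - p_c)
    return out


# -- multiple-testing correction ----------------------------------------------

#: SLIM pi0-estimation defaults: sliding windows of width 0.3 stepped by 0.05
#: across the lambda range [0.4, 0.95] of the empirical p-value CDF.
SLIM_LAMBDA_MIN = 0.4
SLIM_LAMBDA_MAX = 0.95
SLIM_LAMBDA_STEP = 0.05
SLIM_WINDOW = 0.3


def estimate_pi0_slim(pvalues: np.ndarray) -> float:
    """Sliding-linear-model estimate of the null proportion pi0.

    The empirical CDF of p-values is locally linear where only true nulls
    contribute, with slope pi0.  Straight lines are fitted to the CDF over
    sliding lambda windows in the upper p range; the smallest fitted slope,
    clamped to [0, 1], is the pi0 estimate.  Returns 1.0 (the BH limit) when
    the fit is degenerate (too few distinct points or a non-positive slope).
    """
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return 1.0
    grid = np.arange(SLIM_LAMBDA_MIN, SLIM_LAMBDA_MAX + 1e-9, SLIM_LAMBDA_STEP)
    ecdf = np.array([(p <= lam).mean() for lam in grid])
    slopes = []
    n_pts = int(round(SLIM_WINDOW / SLIM_LAMBDA_STEP)) + 1
    for i in range(0, len(grid) - n_pts + 1):
        xs, ys = grid[i:i + n_pts], ecdf[i:i + n_pts]
        slope = np.polyfit(xs, ys, 1)[0]
        slopes.append(slope)
    if not slopes:
        return 1.0
    pi0 = float(min(slopes))
    if not np.isfinite(pi0) or pi0 <= 0.0:
        return 1.0
    return min(pi0, 1.0)


def adjust_pvalues(pvalues, method: str = "slim") -> np.ndarray:
    """Convert p-values to q-values.

    ``bh`` is the Benjamini-Hochberg step-up procedure
    (q_(i) = min_{j>=i} p_(j) * n / j, capped at 1).  ``slim`` rescales the
    BH q-values by the SLIM pi0 estimate, q_slim = pi0_hat * q_bh, and is
    therefore never more conservative than BH.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if method not in ("slim", "bh"):
        raise ValidationError("method must be 'slim' or 'bh'")
    q_bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q_bh
    pi0 = estimate_pi0_slim(p)
    return np.clip(pi0 * q_bh, 0.0, 1.0)


# -- extraction and summaries --------------------------------------------------


def get_methyl_diff(d: pd.DataFrame, qvalue_cut: float = DEFAULT_QVALUE_CUT,
                    diff_cut: float = DEFAULT_DIFF_CUT,
                    type: str = "all") -> pd.DataFrame:
    """Extract DMCs/DMRs from a DiffTable.

    Retains units with ``qvalue < qvalue_cut`` and ``|meth_diff| > diff_cut``
    (both strict).  ``type`` restricts to hypermethylated (diff > 0: higher
    methylation than the control group), hypomethylated (diff < 0) or all
    events; a ``class`` column labels each retained row.
    """
    if type not in ("hyper", "hypo", "all"):
        raise ValidationError("type must be hyper, hypo or all")
    keep = (d["qvalue"] < qvalue_cut) & (d["meth_diff"].abs() > diff_cut)
    if type == "hyper":
        keep &= d["meth_diff"] > 0
    elif type == "hypo":
        keep &= d["meth_diff"] < 0
    out = d[keep].copy()
    out["class"] = np.where(out["meth_diff"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)


def diff_per_chromosome(d: pd.DataFrame, u: UnitedMethylome,
                        qvalue_cut: float = DEFAULT_QVALUE_CUT,
                        diff_cut: float = DEFAULT_DIFF_CUT) -> pd.DataFrame:
    """Per-chromosome percentages of hyper- and hypomethylated units.

    For each chromosome (plus a genome-wide ``all`` row): the number of
    covered units, and hyper%/hypo% = 100 * DMC count / covered units at the
    given cutoffs.
    """
    dmc = get_methyl_diff(d, qvalue_cut, diff_cut, "all")
    covered = u.df.groupby("chrom").size()
    rows = []
    for chrom, n_cov in covered.items():
        sel = dmc[dmc["chrom"] == chrom]
        n_hyper = int((sel["class"] == "hyper").sum())
        n_hypo = int((sel["class"] == "hypo").sum())
        rows.append((chrom, int(n_cov), n_hyper, n_hypo,
                     100.0 * n_hyper / n_cov, 100.0 * n_hypo / n_cov))
    total = covered.sum()
    if total:
        rows.append(("all", int(total),
                     int((dmc["class"] == "hyper").sum()),
                     int((dmc["class"] == "hypo").sum()),
                     100.0 * (dmc["class"] == "hyper").sum() / total,
                     100.0 * (dmc["class"] == "hypo").sum() / total))
    return pd.DataFrame(
        rows, columns=["chrom", "covered", "n_hyper", "n_hypo", "hyper_pct", "hypo_pct"]
    )
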