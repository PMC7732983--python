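"""Count statistics: NB differential expression, three-group trend tests,
shape classification, proportion z-tests, and sample QC.

The differential-expression machinery is a single, self-contained negative
binomial (NB2) procedure:

* per-sample size factors by the median-of-ratios rule;
* per-feature dispersion by method of moments on normalized counts, shrunk
  toward a fitted mean-dispersion trend ``a/mu + b`` with an adaptive
  (empirical-Bayes) weight — pure trend when gene-wise estimates scatter no
  more than their sampling noise, increasingly gene-wise otherwise;
* group means by NB score equations (Newton, vectorized over features);
* a two-sided Wald test on the log-fold-change between two conditions, and
* a likelihood-ratio test (chi-square, df = conditions - 1) comparing a
  one-mean-per-condition model against a single shared mean.

The adaptive shrinkage is what keeps both tests calibrated at three
replicates per group: plugging noisy per-gene dispersions into Wald or LRT
statistics inflates type-I error, while over-smoothing sacrifices power on
genuinely heterogeneous data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import CountMatrix

log = logging.getLogger(__name__)

FC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.05
MIN_DISPERSION = 1e-8


# ---------------------------------------------------------------- multiple testing

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-aware).

    NaN entries are excluded from the family (they stay NaN and do not count
    in the denominator).
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


# ---------------------------------------------------------------- size factors

def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization rule).

    factor_s = median over features (positive in every sample) of
    raw[f, s] / geometric-mean_f. If no feature is positive in all samples,
    falls back to library-size scaling; in both cases log-factors are
    mean-centered so factors multiply to 1.
    """
    mat = raw.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        logs = np.log(mat[all_pos])
        loggeo = logs.mean(axis=1, keepdims=True)
        logf = np.median(logs - loggeo, axis=0)
    else:
        log.warning("no feature positive in all samples; "
                    "falling back to library-size scaling")
        libs = mat.sum(axis=0)
        if (libs <= 0).any():
            raise ValueError("sample with zero total count")
        logf = np.log(libs)
    logf = logf - logf.mean()
    return pd.Series(np.exp(logf), index=raw.columns, name="size_factor")


# ---------------------------------------------------------------- NB internals

def _fit_group_means(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                     n_iter: int = 60) -> np.ndarray:
    """Per-feature NB mean (on the normalized scale q, mu_j = s_j q).

    Solves the score equation sum_j (y_j - s_j q) / (1 + alpha s_j q) = 0
    by vectorized Newton iteration; y is features x samples, s samples,
    alpha per feature. Returns q >= 0 (0 for all-zero rows).
    """
    q = y.sum(axis=1) / s.sum()
    a = alpha[:, None]
    for _ in range(n_iter):
        mu = s[None, :] * q[:, None]
        denom = 1.0 + a * mu
        f = ((y - mu) / denom).sum(axis=1)
        fp = -(s[None, :] * (1.0 + a * y) / denom**2).sum(axis=1)
        step = f / fp
        q_new = np.clip(q - step, 0.0, None)
        if np.allclose(q_new, q, rtol=1e-12, atol=1e-14):
            q = q_new
            break
        q = q_new
    return q


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of NB2 log-pmf; alpha per feature, mu features x samples."""
    mu = np.clip(mu, 1e-12, None)
    r = 1.0 / alpha[:, None]
    p = r / (r + mu)
    return sps.nbinom.logpmf(y, r, p).sum(axis=1)


def estimate_dispersions(raw: pd.DataFrame, factors: pd.Series,
                         groups: list[list[str]]) -> np.ndarray:
    """Trend-shrunken method-of-moments NB dispersions.

    Gene-wise estimates come from the pooled within-group variance of
    size-factor-normalized counts; a mean-dispersion trend a/mu + b is
    fitted across features, and gene-wise estimates are shrunk toward it in
    log space with an adaptive weight: the share of the observed spread of
    log gene-wise estimates around the trend that exceeds their sampling
    noise (approximated by trigamma(residual_df / 2), the log-variance of a
    scaled chi-square). When features share one dispersion the weight
    collapses to zero (pure trend); heterogeneous dispersions keep their
    gene-wise component. Uninformative gene-wise estimates (at the floor)
    take the trend value. Dispersions are floored at 1e-8.
    """
    from scipy.special import polygamma

    y = raw.to_numpy(dtype=float)
    s = factors.reindex(raw.columns).to_numpy()
    q = y / s[None, :]
    n = y.shape[1]
    G = len(groups)
    idx = {c: i for i, c in enumerate(raw.columns)}
    ss = np.zeros(y.shape[0])
    for grp in groups:
        cols = [idx[c] for c in grp]
        sub = q[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    dof = max(n - G, 1)
    var_w = ss / dof
    m = q.mean(axis=1)
    inv_s = (1.0 / s).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_disp = (var_w - m * inv_s) / m**2
    raw_disp = np.where(np.isfinite(raw_disp), raw_disp, MIN_DISPERSION)
    raw_disp = np.clip(raw_disp, MIN_DISPERSION, None)

    # fit trend alpha(mu) = a/mu + b on informative features
    use = (m > 0) & (raw_disp > MIN_DISPERSION * 10)
    if use.sum() >= 10:
        X = np.column_stack([1.0 / m[use], np.ones(use.sum())])
        coef, *_ = np.linalg.lstsq(X, raw_disp[use], rcond=None)
        a_t = max(coef[0], 0.0)
        b_t = max(coef[1], MIN_DISPERSION)
    else:
        a_t, b_t = 0.0, max(float(np.median(raw_disp)), MIN_DISPERSION)
    with np.errstate(divide="ignore"):
        trend = np.where(m > 0, a_t / np.clip(m, 1e-12, None) + b_t, b_t)
    trend = np.clip(trend, MIN_DISPERSION, None)

    if use.sum() >= 10:
        resid = np.log(raw_disp[use]) - np.log(trend[use])
        s2_total = float(np.var(resid))
        s2_samp = float(polygamma(1, dof / 2.0))
        w = max(0.0, 1.0 - s2_samp / s2_total) if s2_total > 0 else 0.0
    else:
        w = 0.0
    shrunk = np.exp(w * np.log(raw_disp) + (1.0 - w) * np.log(trend))
    shrunk = np.where(use, shrunk, trend)
    return np.clip(shrunk, MIN_DISPERSION, None)


# ---------------------------------------------------------------- DE (Wald)

def de_test(matrix: CountMatrix, cond_a: str = "SEN", cond_b: str = "SEN+M",
            fc_threshold: float = FC_THRESHOLD,
            fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Two-condition NB Wald differential expression (cond_b vs cond_a).

    Returns one row per feature: baseMean (mean normalized count), log2fc,
    p, fdr (BH), and ``called`` (fdr < 0.05 and |FC| >= 1.5, i.e.
    |log2fc| >= log2 1.5). All-zero features get p = NaN and are excluded
    from the BH family.
    """
    sa = matrix.condition_samples(cond_a)
    sb = matrix.condition_samples(cond_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per condition")
    cols = sa + sb
    raw = matrix.raw[cols]
    factors = size_factors(raw)
    alpha = estimate_dispersions(raw, factors, [sa, sb])

    y = raw.to_numpy(dtype=float)
    s = factors.to_numpy()
    na = len(sa)
    ya, yb = y[:, :na], y[:, na:]
    s_a, s_b = s[:na], s[na:]
    qa = _fit_group_means(ya, s_a, alpha)
    qb = _fit_group_means(yb, s_b, alpha)

    nonzero = y.sum(axis=1) > 0
    # moderated means for Wald when a group is all zero
    qa_w = np.where(qa > 0, qa, 0.5 / s_a.sum())
    qb_w = np.where(qb > 0, qb, 0.5 / s_b.sum())
    info_a = (s_a[None, :] * qa_w[:, None]
              / (1.0 + alpha[:, None] * s_a[None, :] * qa_w[:, None])).sum(axis=1)
    info_b = (s_b[None, :] * qb_w[:, None]
              / (1.0 + alpha[:, None] * s_b[None, :] * qb_w[:, None])).sum(axis=1)
    se = np.sqrt(1.0 / info_a + 1.0 / info_b)
    lfc = np.log2(qb_w) - np.log2(qa_w)
    wald = (np.log(qb_w) - np.log(qa_w)) / se
    p = 2.0 * sps.norm.sf(np.abs(wald))
    p = np.where(nonzero, p, np.nan)
    lfc = np.where(nonzero, lfc, np.nan)
    fdr = bh_adjust(p)
    base_mean = (y / s[None, :]).mean(axis=1)
    called = (fdr < fdr_threshold) & (np.abs(lfc) >= np.log2(fc_threshold))
    called = np.where(np.isnan(fdr), False, called)
    return pd.DataFrame({
        "baseMean": base_mean,
        "log2fc": lfc,
        "p": p,
        "fdr": fdr,
        "called": called.astype(bool),
    }, index=raw.index)


# ---------------------------------------------------------------- LRT trend

def lrt_trend(matrix: CountMatrix,
              condition_order: tuple[str, str, str] = ("Young", "SEN", "SEN+M"),
              fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Three-group NB likelihood-ratio trend test with shape classification.

    Full model: one mean per condition; reduced: one shared mean; same
    dispersion in both. Statistic 2*(lfull - lred) referred to chi-square
    with df = 2; BH across features. Group means are reported on the
    size-factor-normalized count scale and the trend shape (linear-up/down,
    U, inverted-U, flat) is classified at fdr < 0.05.
    """
    group_cols = [matrix.condition_samples(c) for c in condition_order]
    if any(len(g) < 2 for g in group_cols):
        raise ValueError("need >= 2 replicates per condition")
    cols = [c for grp in group_cols for c in grp]
    raw = matrix.raw[cols]
    factors = size_factors(raw)
    alpha = estimate_dispersions(raw, factors, group_cols)

    y = raw.to_numpy(dtype=float)
    s = factors.to_numpy()
    idx = {c: i for i, c in enumerate(cols)}
    means = []
    ll_full = np.zeros(y.shape[0])
    for grp in group_cols:
        j = [idx[c] for c in grp]
        qg = _fit_group_means(y[:, j], s[j], alpha)
        means.append(qg)
        ll_full += _nb_loglik(y[:, j], s[j][None, :] * qg[:, None], alpha)
    q0 = _fit_group_means(y, s, alpha)
    ll_red = _nb_loglik(y, s[None, :] * q0[:, None], alpha)

    stat = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    nonzero = y.sum(axis=1) > 0
    p = sps.chi2.sf(stat, df=len(group_cols) - 1)
    p = np.where(nonzero, p, np.nan)
    fdr = bh_adjust(p)
    out = pd.DataFrame({
        f"mean_{c}": m for c, m in zip(condition_order, means)
    }, index=raw.index)
    out["lrt_stat"] = np.where(nonzero, stat, np.nan)
    out["p"] = p
    out["fdr"] = fdr
    out["shape"] = [
        classify_shape(tuple(means[g][i] for g in range(len(group_cols))),
                       fdr[i], fdr_threshold)
        for i in range(y.shape[0])
    ]
    return out


def classify_shape(group_means, fdr: float,
                   fdr_threshold: float = FDR_THRESHOLD) -> str:
    """Trend shape across ordered conditions (Young -> SEN -> SEN+M).

    Flat unless the trend test is significant; otherwise linear when both
    transitions move the same way (or one is zero), U when expression falls
    then rises, inverted-U when it rises then falls.
    """
    if not np.isfinite(fdr) or fdr >= fdr_threshold:
        return "flat"
    m1, m2, m3 = group_means
    d1, d2 = m2 - m1, m3 - m2
    if d1 == 0 and d2 == 0:
        return "flat"
    if d1 < 0 < d2:
        return "U"
    if d1 > 0 > d2:
        return "inverted-U"
    return "linear-up" if (d1 + d2) > 0 else "linear-down"


# ---------------------------------------------------------------- proportions

def ztest_proportions(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided pooled two-proportion z-test p-value.

    Degenerate tables (no successes anywhere, or all successes) return 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if x1 > n1 or x2 > n2 or min(x1, x2) < 0:
        raise ValueError("successes must satisfy 0 <= x <= n")
    if x1 + x2 == 0 or x1 + x2 == n1 + n2:
        return 1.0
    from statsmodels.stats.proportion import proportions_ztest

    stat, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(p)


def global_category_test(counts_a, counts_b, method: str = "chi2",
                         n_perm: int = 10000, seed: int = 0) -> float:
    """Homogeneity of the pooled category distribution between two conditions.

    ``counts_a``/``counts_b`` are per-category totals (same order). Default
    is the chi-square test of homogeneity; ``method="permutation"`` runs a
    Monte-Carlo permutation of the chi-square statistic instead.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    table = np.vstack([a, b])
    if table.shape[1] < 2:
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        log.warning("chi-square homogeneity: expected cell below 5")
    if method == "chi2":
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(p)
    if method != "permutation":
        raise ValueError("method must be 'chi2' or 'permutation'")
    stat_obs, _, _, _ = sps.chi2_contingency(table, correction=False)
    rng = np.random.default_rng(seed)
    n_a = int(a.sum())
    pool = np.repeat(np.arange(a.size), (a + b).astype(int))
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        pa = np.bincount(pool[:n_a], minlength=a.size)
        tab = np.vstack([pa, a + b - pa])
        st, _, _, _ = sps.chi2_contingency(tab, correction=False)
        if st >= stat_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------- QC

@dataclass
class QCSummary:
    pearson: pd.DataFrame
    pca_coords: pd.DataFrame
    variance_fractions: np.ndarray


def qc_summary(rpm: pd.DataFrame) -> QCSummary:
    """Pairwise Pearson correlation and PCA of samples on log2(RPM + 1).

    Constant feature rows are dropped before PCA; variance fractions are
    per-component shares of total variance (non-increasing, summing to <= 1).
    """
    if rpm.shape[1] < 2:
        raise ValueError("QC needs at least two samples")
    x = np.log2(rpm.to_numpy(dtype=float) + 1.0)
    corr = np.corrcoef(x, rowvar=False)
    pearson = pd.DataFrame(corr, index=rpm.columns, columns=rpm.columns)

    keep = x.std(axis=1) > 0
    if keep.sum() < x.shape[0]:
        log.info("dropping %d constant feature(s) before PCA",
                 int((~keep).sum()))
    xm = x[keep].T                      # samples x features
    xm = xm - xm.mean(axis=0, keepdims=True)
    u, sv, _ = np.linalg.svd(xm, full_matrices=False)
    total = (sv**2).sum()
    frac = sv**2 / total if total > 0 else np.zeros_like(sv)
    k = min(xm.shape[0] - 1, len(sv)) or 1
    coords = pd.DataFrame(
        (u * sv)[:, :k], index=rpm.columns,
        columns=[f"PC{i+1}" for i in range(k)])
    return QCSummary(pearson, coords, frac[:k])
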