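"""Simplified negative-binomial differential expression with a two-estimator
consensus rule.

Two deliberately different NB tests are run per two-group contrast:

* method A — a Wald test on the log2 fold change of median-of-ratios
  normalized means, with per-feature dispersion shrunk toward a mean-
  dependent trend (DESeq-flavoured);
* method B — a conditional exact test on TMM-equalized pseudo-counts with a
  common dispersion (edgeR-flavoured).

The consensus call requires all three gates simultaneously: |log2FC| > 1,
Benjamini-Hochberg adjusted p of method A < 0.05, and raw p of method B
< 0.05, with the sign of the fold change setting the direction.

These are documented simplified estimators, not numerical re-creations of
the published packages; the decision rule is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

LFC_THRESHOLD = 1.0
ALPHA_A = 0.05
ALPHA_B = 0.05
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class DeRecord:
    feature_id: str
    contrast_id: str
    log2fc: float
    p_method_a: float
    padj_method_a: float
    p_method_b: float
    mean_control: float
    mean_treated: float
    call: str  # up | down | ns


@dataclass(frozen=True)
class NormalizationFactors:
    sample_ids: tuple[str, ...]
    size_factors: np.ndarray  # median-of-ratios
    tmm_factors: np.ndarray   # trimmed mean of M-values, geometric mean 1


def size_factors_median_of_ratios(counts: pd.DataFrame) -> np.ndarray:
    """Per-sample median of count / feature-geometric-mean ratios.

    Only features with all-positive counts enter; if none exist, falls back
    to library-size ratios (normalized to geometric mean 1).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        lib = mat.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("sample with zero total counts")
        sf = lib / np.exp(np.mean(np.log(lib)))
        return sf
    sub = mat[positive]
    geo = np.exp(np.mean(np.log(sub), axis=1, keepdims=True))
    return np.median(sub / geo, axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
    reference: int | None = None,
) -> np.ndarray:
    """Trimmed mean of M-values vs a reference sample.

    The reference defaults to the sample whose upper-quartile count fraction
    is closest to the mean of those fractions.  Factors are renormalized so
    their geometric mean is exactly 1.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    if reference is None:
        frac = np.array([
            np.quantile(mat[:, j][mat[:, j] > 0], 0.75) / lib[j]
            if (mat[:, j] > 0).any() else 0.0
            for j in range(mat.shape[1])
        ])
        reference = int(np.argmin(np.abs(frac - frac.mean())))
    ref = mat[:, reference] / lib[reference]
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == reference:
            continue
        obs = mat[:, j] / lib[j]
        keep = (obs > 0) & (ref > 0)
        if keep.sum() < 2:
            continue
        m = np.log2(obs[keep] / ref[keep])
        a = 0.5 * np.log2(obs[keep] * ref[keep])
        m_lo, m_hi = np.quantile(m, [m_trim, 1 - m_trim])
        a_lo, a_hi = np.quantile(a, [a_trim, 1 - a_trim])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if sel.any():
            factors[j] = 2.0 ** np.mean(m[sel])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def normalization_factors(counts: pd.DataFrame) -> NormalizationFactors:
    return NormalizationFactors(
        sample_ids=tuple(counts.columns),
        size_factors=size_factors_median_of_ratios(counts),
        tmm_factors=tmm_factors(counts),
    )


def estimate_dispersion(
    counts: pd.DataFrame,
    groups: Sequence[int],
    method: str = "shrunken",
    size_factors: np.ndarray | None = None,
    prior_df: float = 20.0,
) -> np.ndarray:
    """Per-feature NB dispersion phi (variance = mu + phi mu^2), phi >= 0.

    ``moments_pooled``: phi = max(0, (s^2 - mbar) / mbar^2) with the sample
    variance pooled within groups of the normalized counts.  ``shrunken``:
    the moments estimate shrunk toward a mean-trend (median phi in ~20
    quantile bins of the mean), weighted by residual d.f. against
    ``prior_df`` pseudo-degrees of freedom.
    """
    groups = np.asarray(groups)
    if any((groups == g).sum() < 2 for g in np.unique(groups)):
        raise ValueError("need >= 2 replicates per condition to estimate dispersion")
    mat = counts.to_numpy(dtype=float)
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    q = mat / size_factors  # normalized counts

    n = q.shape[1]
    n_groups = len(np.unique(groups))
    resid_df = n - n_groups
    # pooled within-group variance
    ss = np.zeros(mat.shape[0])
    for g in np.unique(groups):
        sub = q[:, groups == g]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / resid_df
    mbar = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(mbar > 0, (s2 - mbar) / np.maximum(mbar, 1e-12) ** 2, 0.0)
    if method == "moments_pooled":
        return np.maximum(phi_raw, 0.0)
    if method != "shrunken":
        raise ValueError(f"unknown dispersion method {method!r}")

    # mean-dependent trend: the per-bin MEAN of the untruncated moment
    # estimates (a median, or truncating at 0 first, is biased low because
    # the estimator's sampling distribution is right-skewed at few replicates)
    order = np.argsort(mbar)
    n_bins = min(20, max(1, mat.shape[0] // 50))
    trend = np.zeros_like(phi_raw)
    bins = np.array_split(order, n_bins)
    for idx in bins:
        trend[idx] = max(np.mean(phi_raw[idx]), 0.0)
    w = resid_df / (resid_df + prior_df)
    return np.maximum(w * phi_raw + (1 - w) * trend, 0.0)


def common_dispersion(counts: pd.DataFrame, groups: Sequence[int],
                      size_factors: np.ndarray | None = None) -> float:
    """A single trimmed-mean dispersion across informative features."""
    phi = estimate_dispersion(counts, groups, method="moments_pooled",
                              size_factors=size_factors)
    mbar = (counts.to_numpy(dtype=float)).mean(axis=1)
    informative = mbar >= 1
    if not informative.any():
        return 0.0
    return float(stats.trim_mean(phi[informative], 0.25))


def nb_wald_test(
    counts: pd.DataFrame,
    groups: Sequence[int],
    size_factors: np.ndarray,
    dispersions: np.ndarray,
) -> pd.DataFrame:
    """Method A: per-feature (log2fc, p) from an NB Wald statistic.

    log2fc = log2((mean_treated + 0.5) / (mean_control + 0.5)) of normalized
    means (groups coded 0=control, 1=treated); SE via the delta method under
    NB variance mu + phi mu^2; two-sided p from the normal reference.
    """
    groups = np.asarray(groups)
    mat = counts.to_numpy(dtype=float)
    q = mat / size_factors
    ctrl, trt = groups == 0, groups == 1
    m0 = q[:, ctrl].mean(axis=1)
    m1 = q[:, trt].mean(axis=1)
    lfc = np.log2((m1 + PSEUDOCOUNT) / (m0 + PSEUDOCOUNT))

    def group_var(m: np.ndarray, cols: np.ndarray) -> np.ndarray:
        sf = size_factors[cols]
        ng = cols.sum()
        # Var(mean of K_ij/s_j) with Var(K_ij) = mu_j + phi mu_j^2, mu_j = m s_j
        return (m[:, None] / sf + dispersions[:, None] * m[:, None] ** 2).sum(axis=1) / ng**2

    var0 = group_var(m0, ctrl)
    var1 = group_var(m1, trt)
    ln2 = np.log(2.0)
    se2 = var1 / ((m1 + PSEUDOCOUNT) ** 2) + var0 / ((m0 + PSEUDOCOUNT) ** 2)
    se = np.sqrt(se2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    empty = (m0 == 0) & (m1 == 0)
    lfc[empty], p[empty] = 0.0, 1.0
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {"log2fc": lfc, "p": p, "mean_control": m0, "mean_treated": m1},
        index=counts.index,
    )


def _exact_nb_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Conditional two-sided exact NB test on group sums.

    Under the null both groups share a mean; the split of the total between
    the group sums (each NB with dispersion phi/n) is conditioned on, and
    the p-value sums probabilities of splits no more likely than observed.
    phi = 0 reduces to a binomial split test.
    """
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi <= 0:
        logf = stats.binom.logpmf(k, s, n_a / (n_a + n_b))
    else:
        mu = s / (n_a + n_b)  # common per-sample mean given the total
        r_a, r_b = n_a / phi, n_b / phi
        log_a = stats.nbinom.logpmf(k, r_a, r_a / (r_a + n_a * mu))
        log_b = stats.nbinom.logpmf(k[::-1], r_b, r_b / (r_b + n_b * mu))
        logf = log_a + log_b
        logf = logf - logsumexp(logf)  # condition on the observed total
    f = np.exp(logf)
    p = float(f[f <= f[sum_a] * (1 + 1e-10)].sum())
    return min(p, 1.0)


def nb_exact_test(
    counts: pd.DataFrame,
    groups: Sequence[int],
    tmm: np.ndarray,
    phi: float,
) -> pd.DataFrame:
    """Method B: conditional exact NB test on TMM-equalized pseudo-counts."""
    groups = np.asarray(groups)
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    eff = lib * tmm
    eff = np.where(eff <= 0, 1.0, eff)
    common = np.exp(np.mean(np.log(eff)))
    pseudo = np.rint(mat * (common / eff)).astype(np.int64)
    ctrl, trt = groups == 0, groups == 1
    n_a, n_b = int(trt.sum()), int(ctrl.sum())
    sums_a = pseudo[:, trt].sum(axis=1)
    sums_b = pseudo[:, ctrl].sum(axis=1)
    pvals = np.array([
        _exact_nb_pvalue(int(a), int(b), n_a, n_b, phi)
        for a, b in zip(sums_a, sums_b)
    ])
    return pd.DataFrame({"p": pvals}, index=counts.index)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def consensus_call(
    table: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha_a: float = ALPHA_A,
    alpha_b: float = ALPHA_B,
) -> pd.Series:
    """up iff log2fc > t and padj_a < alpha_a and p_b < alpha_b; down symmetric."""
    required = {"log2fc", "padj_a", "p_b"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing method results: {sorted(missing)}")
    sig = (table["padj_a"] < alpha_a) & (table["p_b"] < alpha_b)
    call = np.where(
        sig & (table["log2fc"] > lfc_threshold), "up",
        np.where(sig & (table["log2fc"] < -lfc_threshold), "down", "ns"),
    )
    return pd.Series(call, index=table.index, name="call")


def run_contrast(
    matrix,
    contrast_id: str,
    dispersion_method: str = "shrunken",
    lfc_threshold: float = LFC_THRESHOLD,
    alpha_a: float = ALPHA_A,
    alpha_b: float = ALPHA_B,
) -> pd.DataFrame:
    """Run both tests + BH + consensus for one pathogen-vs-control contrast.

    ``matrix`` is a CountMatrix whose design maps sample ids to conditions;
    ``contrast_id`` is e.g. "PAO1_F1" (treated) vs OP50 of the same
    generation (control).
    """
    pathogen, generation = contrast_id.rsplit("_", 1)
    sheet = pd.DataFrame(matrix.design.samples)
    sel = sheet[
        (sheet["generation"] == generation)
        & (sheet["bacterium"].isin(["OP50", pathogen]))
    ]
    sample_ids = list(sel["sample_id"])
    groups = (sel["bacterium"] == pathogen).astype(int).to_numpy()
    sub = matrix.counts[sample_ids]
    return run_two_group(
        sub, groups, contrast_id,
        dispersion_method=dispersion_method,
        lfc_threshold=lfc_threshold, alpha_a=alpha_a, alpha_b=alpha_b,
    )


def run_two_group(
    counts: pd.DataFrame,
    groups: Sequence[int],
    contrast_id: str = "contrast",
    dispersion_method: str = "shrunken",
    lfc_threshold: float = LFC_THRESHOLD,
    alpha_a: float = ALPHA_A,
    alpha_b: float = ALPHA_B,
) -> pd.DataFrame:
    """Two-group consensus DE on a raw counts table (0=control, 1=treated)."""
    groups = np.asarray(groups)
    sf = size_factors_median_of_ratios(counts)
    tmm = tmm_factors(counts)
    phi = estimate_dispersion(counts, groups, method=dispersion_method,
                              size_factors=sf)
    wald = nb_wald_test(counts, groups, sf, phi)
    phi_common = common_dispersion(counts, groups, size_factors=sf)
    exact = nb_exact_test(counts, groups, tmm, phi_common)
    table = pd.DataFrame(
        {
            "feature_id": counts.index,
            "contrast_id": contrast_id,
            "log2fc": wald["log2fc"],
            "p_a": wald["p"],
            "padj_a": benjamini_hochberg(wald["p"].to_numpy()),
            "p_b": exact["p"],
            "mean_control": wald["mean_control"],
            "mean_treated": wald["mean_treated"],
        },
        index=counts.index,
    )
    table["call"] = consensus_call(table, lfc_threshold, alpha_a, alpha_b)
    return table


def run_all_contrasts(matrix, **kwargs) -> dict[str, pd.DataFrame]:
    return {c: run_contrast(matrix, c, **kwargs) for c in matrix.design.contrasts}


def de_records(table: pd.DataFrame) -> list[DeRecord]:
    return [
        DeRecord(
            feature_id=row.feature_id, contrast_id=row.contrast_id,
            log2fc=row.log2fc, p_method_a=row.p_a, padj_method_a=row.padj_a,
            p_method_b=row.p_b, mean_control=row.mean_control,
            mean_treated=row.mean_treated, call=row.call,
        )
        for row in table.itertuples(index=False)
    ]
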