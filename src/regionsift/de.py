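"""Two-group negative-binomial differential expression on count matrices.

The workflow mirrors the classic exact-test pipeline for small RNA counts:

1. low-count filtering (keep rows with >= min_count in >= min_samples samples);
2. TMM normalization — trimmed mean of M-values against a reference sample,
   30 % M-trim and 5 % A-trim, factors rescaled so their logs sum to zero;
3. a common NB dispersion phi (variance = mu + phi*mu^2) estimated by a
   method-of-moments median over rows;
4. a two-sided exact NB test per row, conditioning on the total of the two
   group pseudo-sums after scaling every sample to a common effective
   library size, with two-sided p the summed probability of outcomes as or
   less likely than the one observed;
5. Benjamini-Hochberg FDR.

log2 fold changes are treatment vs control on prior-count-stabilized
normalized group means; the prior never enters the test itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEParams",
    "filter_low_counts",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_test",
    "bh_adjust",
    "run_de",
]

# two-sided tie guard: include outcomes with mass <= observed * (1 + eps) so
# float noise can never exclude the observed outcome from its own tail
_TIE_EPS = 1e-8


@dataclass(frozen=True)
class DEParams:
    """Filtering, significance and stabilization knobs for one DE run."""

    min_count: int = 1
    min_samples: int = 2
    alpha: float = 0.05
    prior_count: float = 0.5
    dispersion: float | None = None  # None = estimate from the data

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.prior_count <= 0:
            raise ValueError("prior_count must be > 0")


def _as_matrix(counts: pd.DataFrame) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("count matrix contains negative values")
    return x


def filter_low_counts(
    counts: pd.DataFrame, min_count: int = 1, min_samples: int = 2
) -> pd.DataFrame:
    """Keep rows with count >= min_count in at least min_samples samples."""
    x = _as_matrix(counts)
    keep = (x >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference is the sample whose upper quartile (of library-size-scaled
    counts) is closest to the mean upper quartile.  For each sample, genes
    expressed in both it and the reference contribute a log-ratio M and a
    log-abundance A; the most extreme 30 % of M and 5 % of A are trimmed and
    the factor is 2**mean(M) over the survivors.  Factors are rescaled to
    have zero log-sum, so they carry only compositional (not library-size)
    differences.
    """
    x = _as_matrix(counts)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts; TMM factor undefined")

    scaled = x / lib
    uq = np.array([np.quantile(scaled[:, j][x[:, j] > 0], 0.75) if (x[:, j] > 0).any()
                   else 0.0 for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        both = (x[:, j] > 0) & (x[:, ref] > 0)
        if not both.any():
            continue
        pj, pr = scaled[both, j], scaled[both, ref]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        keep = np.ones(m.size, dtype=bool)
        if m.size > 1:
            m_lo, m_hi = np.quantile(m, [0.30, 0.70])
            a_lo, a_hi = np.quantile(a, [0.05, 0.95])
            keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
            if not keep.any():
                keep[:] = True
        log_factors[j] = m[keep].mean()
    log_factors -= log_factors.mean()  # zero log-sum
    return pd.Series(2.0 ** log_factors, index=counts.columns, name="tmm_factor")


def _effective_sizes(counts: pd.DataFrame, factors: pd.Series) -> np.ndarray:
    lib = np.asarray(counts.sum(axis=0), dtype=float)
    return lib * np.asarray(factors.loc[counts.columns], dtype=float)


def _split_groups(counts: pd.DataFrame, groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(list(groups))
    levels = np.sort(pd.unique(g))  # direction fixed by label order, not appearance
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    return g == levels[0], g == levels[1]


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: Sequence, factors: pd.Series | None = None
) -> float:
    """Method-of-moments common dispersion from within-group moments.

    Counts are scaled to a common effective library size; per row and group,
    the sample variance s2 and mean m give the moment estimate
    (s2 - m) / m**2 of phi (since var = mu + phi*mu^2).  The estimate is the
    median over rows of the group-averaged moments, floored at zero, so a
    Poisson-like matrix returns ~0.
    """
    if factors is None:
        factors = tmm_factors(counts)
    x = _as_matrix(counts)
    g1, g2 = _split_groups(counts, groups)
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs >= 2 samples to estimate dispersion")
    eff = _effective_sizes(counts, factors)
    z = x * (np.exp(np.mean(np.log(eff))) / eff)  # common-size scaled counts

    ests = []
    for mask in (g1, g2):
        m = z[:, mask].mean(axis=1)
        s2 = z[:, mask].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            e = (s2 - m) / m**2
        ests.append(np.where(m > 0, e, np.nan))
    per_row = np.nanmean(np.column_stack(ests), axis=1)
    per_row = per_row[np.isfinite(per_row)]
    if per_row.size == 0:
        return 0.0
    return float(max(0.0, np.median(np.maximum(per_row, 0.0))))


def _conditional_log_pmf(t: int, mean1: float, mean2: float, size1: float, size2: float):
    """Log-mass over k=0..t of group-1 sum given total t, up to normalization."""
    k = np.arange(t + 1)
    if np.isinf(size1):  # Poisson limit -> binomial conditional
        p = mean1 / (mean1 + mean2)
        return stats.binom.logpmf(k, t, p), k
    lp = stats.nbinom.logpmf(k, size1, size1 / (size1 + mean1)) + \
        stats.nbinom.logpmf(t - k, size2, size2 / (size2 + mean2))
    return lp, k


def _exact_p(y1: int, t: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional NB test of group-1 sum y1 given total t."""
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)  # per-sample null mean given the total
    if phi == 0:
        size1 = size2 = np.inf
    else:
        size1, size2 = n1 / phi, n2 / phi
    lp, _ = _conditional_log_pmf(t, n1 * mu, n2 * mu, size1, size2)
    lp = lp - logsumexp(lp)
    obs = lp[y1]
    tail = lp[lp <= obs + np.log1p(_TIE_EPS)]
    return float(min(1.0, np.exp(logsumexp(tail))))


def exact_test(
    counts: pd.DataFrame,
    groups: Sequence,
    factors: pd.Series | None = None,
    dispersion: float = 0.0,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """Two-sided exact NB test per row, group 2 vs group 1.

    Every sample is linearly scaled to the common effective library size
    (geometric mean of effective sizes) and summed within its group; the
    test conditions on the row's total pseudo-sum, with the null per-sample
    mean taken as total/(n1+n2) and group sums NB-distributed with shape
    n_g/phi.  With phi = 0 this reduces to the exact two-sided binomial test
    with p = n1/(n1+n2).

    Returns a DataFrame with columns logFC (log2, group 2 vs group 1,
    prior-count stabilized), logCPM, PValue, FDR.
    """
    if factors is None:
        factors = tmm_factors(counts)
    x = _as_matrix(counts)
    g1, g2 = _split_groups(counts, groups)
    n1, n2 = int(g1.sum()), int(g2.sum())
    eff = _effective_sizes(counts, factors)
    common = np.exp(np.mean(np.log(eff)))
    pseudo = x * (common / eff)

    s1 = np.rint(pseudo[:, g1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(pseudo[:, g2].sum(axis=1)).astype(np.int64)

    pvals = np.array([
        _exact_p(int(a), int(a + b), n1, n2, dispersion) for a, b in zip(s1, s2)
    ])

    m1 = pseudo[:, g1].mean(axis=1) + prior_count
    m2 = pseudo[:, g2].mean(axis=1) + prior_count
    logfc = np.log2(m2 / m1)
    logcpm = np.log2((pseudo.mean(axis=1) + prior_count) / common * 1e6)

    out = pd.DataFrame(
        {"logFC": logfc, "logCPM": logcpm, "PValue": pvals},
        index=counts.index,
    )
    out["FDR"] = bh_adjust(out["PValue"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: pd.DataFrame, groups: Sequence, params: DEParams | None = None
) -> pd.DataFrame:
    """Filter, normalize, estimate dispersion, test, adjust — one call."""
    params = params or DEParams()
    filtered = filter_low_counts(counts, params.min_count, params.min_samples)
    if filtered.empty:
        return pd.DataFrame(columns=["logFC", "logCPM", "PValue", "FDR"])
    factors = tmm_factors(filtered)
    phi = (
        params.dispersion
        if params.dispersion is not None
        else estimate_common_dispersion(filtered, groups, factors)
    )
    return exact_test(filtered, groups, factors, phi, params.prior_count)
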