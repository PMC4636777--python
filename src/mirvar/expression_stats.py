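"""Expression filtering, TMM/CPM normalization and differential expression.

The differential-expression test is the two-group exact test for
negative-binomial counts: library sizes are equalized, group sums are formed,
and the p-value is the probability — under the conditional distribution of
the first group's sum given the total (negative hypergeometric with sizes
n_A/phi and n_B/phi; binomial in the Poisson limit phi = 0) — of outcomes
whose probability does not exceed that of the observed split (two-sided).
A common dispersion phi is estimated by the method of moments.  Significance
follows the conventional small-RNA thresholds: |log2 fold change| >= 1 and
Benjamini-Hochberg FDR < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .reference_io import CountTable


@dataclass
class FilterParams:
    """Low-expression filter: >= min_reads in >= min_samples of some group.

    ``group_exceptions`` lowers the required sample number for named groups
    (e.g. a group with a failed library).
    """

    min_reads: int = 10
    min_samples: int = 4
    group_exceptions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")

    def required(self, group: str) -> int:
        return self.group_exceptions.get(group, self.min_samples)


@dataclass
class DEParams:
    min_abs_log2fc: float = 1.0
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or not (0 < self.max_fdr <= 1):
            raise ValueError("thresholds must be positive")


def expression_filter(table: CountTable, params: FilterParams) -> CountTable:
    """Keep tags expressed at >= min_reads in enough samples of some group."""
    counts = table.counts
    groups = sorted(set(table.groups.values()))
    keep = np.zeros(len(counts), dtype=bool)
    for g in groups:
        samples = table.samples_of(g)
        req = params.required(g)
        if len(samples) < req:
            raise ValueError(
                f"group {g} has {len(samples)} samples but requires {req}"
            )
        n_ok = (counts[samples] >= params.min_reads).sum(axis=1).values
        keep |= n_ok >= req
    return CountTable(counts=counts.loc[keep].copy(), groups=dict(table.groups))


# ---------------------------------------------------------------------------
# TMM normalization


def tmm_factors(
    counts: pd.DataFrame,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile (of counts/library
    size) is closest to the mean upper-quartile.  For each sample, M (log2
    ratio vs reference) and A (mean log2 abundance) are computed over tags
    non-zero in both; the top and bottom ``log_ratio_trim`` fraction of M and
    ``abs_expr_trim`` fraction of A are discarded and the factor is 2 to the
    mean of the surviving M values.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("all-zero sample in count table")
    frac = counts.div(lib, axis=1)
    uq = frac.apply(lambda c: np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0)
    ref = (uq - uq.mean()).abs().idxmin()
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        both = (counts[s] > 0) & (counts[ref] > 0)
        y, r = frac.loc[both, s].values, frac.loc[both, ref].values
        if len(y) == 0:
            factors[s] = 1.0
            continue
        m = np.log2(y / r)
        a = 0.5 * np.log2(y * r)
        n = len(m)
        lo_m, hi_m = int(np.floor(n * log_ratio_trim)), n - int(np.floor(n * log_ratio_trim))
        lo_a, hi_a = int(np.floor(n * abs_expr_trim)), n - int(np.floor(n * abs_expr_trim))
        keep_m = np.zeros(n, bool)
        keep_m[np.argsort(m, kind="stable")[lo_m:hi_m]] = True
        keep_a = np.zeros(n, bool)
        keep_a[np.argsort(a, kind="stable")[lo_a:hi_a]] = True
        kept = m[keep_m & keep_a]
        factors[s] = float(2.0 ** np.mean(kept)) if len(kept) else 1.0
    f = pd.Series(factors).reindex(counts.columns)
    f /= np.exp(np.mean(np.log(f)))  # geometric mean 1
    return f


def tmm_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Return (scaling factors, normalized counts-per-million).

    Normalized value = count / (library size x factor) x 1e6.
    """
    factors = tmm_factors(counts)
    eff = counts.sum(axis=0).astype(float) * factors
    cpm = counts.div(eff, axis=1) * 1e6
    return factors, cpm


# ---------------------------------------------------------------------------
# dispersion


def estimate_common_dispersion(normalized: pd.DataFrame, groups: dict[str, str]) -> float:
    """Method-of-moments pooled NB dispersion on normalized counts.

    For every tag and every group with >= 2 replicates, (s^2 - m)/m^2 is
    computed from the within-group mean and variance; the estimate is the
    mean of these, floored at 0 tag-wise.  With < 2 replicates everywhere
    returns 0 with a warning.
    """
    vals = []
    for g in sorted(set(groups.values())):
        samples = [s for s in normalized.columns if groups[s] == g]
        if len(samples) < 2:
            continue
        sub = normalized[samples].values
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        vals.append(np.maximum(0.0, (v[ok] - m[ok]) / m[ok] ** 2))
    if not vals:
        warnings.warn("no group has >= 2 replicates; dispersion set to 0")
        return 0.0
    pooled = np.concatenate(vals)
    return float(pooled.mean()) if len(pooled) else 0.0


# ---------------------------------------------------------------------------
# exact test


def _equalize_libraries(counts: pd.DataFrame, factors: pd.Series | None) -> tuple[pd.DataFrame, float]:
    """Scale every library to the geometric mean effective size and round."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns)
    common = float(np.exp(np.mean(np.log(lib))))
    pseudo = counts.mul(common / lib, axis=1).round().astype(int)
    return pseudo, common


def _exact_logpmf(s: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log pmf of group-A sum a = 0..s conditional on total s.

    With per-sample NB size r = 1/phi, the group sums have sizes n_a*r and
    n_b*r and the conditional law is negative hypergeometric, free of the
    mean.  phi = 0 is the binomial (Poisson) limit.
    """
    a = np.arange(s + 1, dtype=float)
    if phi <= 0:
        p = n_a / (n_a + n_b)
        logpmf = (
            gammaln(s + 1) - gammaln(a + 1) - gammaln(s - a + 1)
            + a * np.log(p) + (s - a) * np.log1p(-p)
        )
    else:
        ra, rb = n_a / phi, n_b / phi
        logpmf = (
            gammaln(a + ra) - gammaln(a + 1) - gammaln(ra)
            + gammaln(s - a + rb) - gammaln(s - a + 1) - gammaln(rb)
        )
        logpmf -= logsumexp(logpmf)
    return logpmf


def exact_test_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p: mass of outcomes no more probable than observed."""
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    logpmf = _exact_logpmf(s, n_a, n_b, phi)
    obs = logpmf[sum_a]
    extreme = logpmf <= obs + 1e-10  # float-tolerant "as or more extreme"
    return float(min(1.0, np.exp(logsumexp(logpmf[extreme]))))


def nb_exact_test(
    table: CountTable,
    group_a: str,
    group_b: str,
    phi: float,
    factors: pd.Series | None = None,
    params: DEParams | None = None,
) -> pd.DataFrame:
    """Per-tag two-group NB exact test; log2FC of B over A on the CPM scale.

    Counts are first equalized to a common library size (TMM-effective sizes
    when ``factors`` is given).  log2fc = log2((cpmB + 0.5) / (cpmA + 0.5)).
    Returns a DataFrame indexed by tag with log2fc, p, fdr and significant.
    """
    params = params or DEParams()
    sa = table.samples_of(group_a)
    sb = table.samples_of(group_b)
    if not sa or not sb:
        raise ValueError("both groups must have samples")
    pseudo, common = _equalize_libraries(table.counts[sa + sb], factors)
    sums_a = pseudo[sa].sum(axis=1).values
    sums_b = pseudo[sb].sum(axis=1).values
    pvals = np.array([
        exact_test_pvalue(int(a), int(b), len(sa), len(sb), phi)
        for a, b in zip(sums_a, sums_b)
    ])
    cpm_a = sums_a / len(sa) / common * 1e6
    cpm_b = sums_b / len(sb) / common * 1e6
    log2fc = np.log2((cpm_b + 0.5) / (cpm_a + 0.5))
    zero = (sums_a + sums_b) == 0
    log2fc[zero] = 0.0
    fdr = bh_adjust(pvals)
    res = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "significant": (np.abs(log2fc) >= params.min_abs_log2fc) & (fdr < params.max_fdr),
        },
        index=table.counts.index,
    )
    res.attrs["contrast"] = (group_a, group_b)
    return res


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def venn_sets(de_lists: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every intersection region of 2-3 labeled sets.

    Keys are sorted tuples of the labels an element belongs to; regions
    partition the union.
    """
    if not (2 <= len(de_lists) <= 3):
        raise ValueError("venn_sets expects 2 or 3 sets")
    labels = sorted(de_lists)
    universe = set().union(*de_lists.values())
    regions: dict[tuple[str, ...], int] = {}
    for el in universe:
        key = tuple(l for l in labels if el in de_lists[l])
        regions[key] = regions.get(key, 0) + 1
    # include empty regions for a complete partition report
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            regions.setdefault(combo, 0)
    return regions
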