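"""Country-discriminant ASV detection on depth-normalized counts.

The workflow mirrors the DESeq2-style analysis chain used for zero-inflated
amplicon tables: ``poscounts`` size factors (geometric means over positive
counts only, robust to the many zeros of ASV tables), per-ASV log2-fold
ratios between production countries, Wald tests with a negative-binomial
variance model, and Benjamini-Hochberg FDR control.  The design controls
for manufacturing method nested within country (~ country +
country:method): country means are averages of (country, method) cell
means, so a method imbalance between countries does not masquerade as a
country effect.

Dispersion is estimated per ASV by method of moments from within-cell
variability (floored at 1e-8); this deliberately omits DESeq2's shrinkage
and outlier machinery, and the error control of the simplification is
verified by simulation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import CountTable, SampleSheet

__all__ = [
    "DAResult",
    "abundance_filter",
    "poscounts_size_factors",
    "wald_da_test",
    "bh_adjust",
]

_DISP_FLOOR = 1e-8
_PSEUDO = 0.5  # added to both country means when either is zero, keeps lfc finite


@dataclass
class DAResult:
    """Per-ASV differential-abundance table.

    ``table`` columns: mean_A, mean_B (normalized country means), lfc
    (log2 A over B), se, z, p, padj, overabundant_in ({'A','B','none'}).
    """

    table: pd.DataFrame
    size_factors: pd.Series
    q: float

    def overabundant(self, country: str) -> list[str]:
        return list(self.table.index[self.table["overabundant_in"] == country])


def abundance_filter(counts: CountTable, min_total: int = 1000) -> CountTable:
    """Keep ASVs whose read total across all samples is >= ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = counts.counts.sum(axis=1)
    return CountTable(counts.counts[totals >= min_total].copy(), counts.marker)


def poscounts_size_factors(counts: CountTable) -> pd.Series:
    """Per-sample ``poscounts`` size factors.

    The per-ASV reference is the n-th root of the product of its *positive*
    counts (n = number of samples, zeros contribute a factor of 1), and a
    sample's factor is the median ratio of its positive counts to positive
    references, rescaled so the geometric mean of all factors is 1.
    """
    mat = counts.counts.to_numpy(float)
    if (mat.sum(axis=0) == 0).any():
        bad = [s for s, tot in counts.sample_totals().items() if tot == 0]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    n = mat.shape[1]
    with np.errstate(divide="ignore"):
        logs = np.where(mat > 0, np.log(mat), 0.0)
    log_ref = logs.sum(axis=1) / n  # n-th root of product over positive counts
    ref = np.exp(log_ref)
    factors = np.empty(n)
    for j in range(n):
        ok = (mat[:, j] > 0) & (ref > 0)
        if not ok.any():
            raise ValueError(f"sample {counts.sample_ids[j]!r} shares no positive ASV")
        factors[j] = np.median(mat[ok, j] / ref[ok])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cell_stats(y: np.ndarray, cells: list[np.ndarray]):
    """Per-cell means/variances of normalized counts; y is asvs x samples."""
    means = np.stack([y[:, idx].mean(axis=1) for idx in cells], axis=1)
    var_list, w_list = [], []
    for idx in cells:
        n_c = len(idx)
        if n_c >= 2:
            var_list.append(y[:, idx].var(axis=1, ddof=1))
            w_list.append(n_c - 1)
    return means, var_list, w_list


def _mom_dispersion(means: np.ndarray, var_list, w_list) -> np.ndarray:
    """Per-ASV NB dispersion alpha from var = mu + alpha mu^2, pooled over cells."""
    n_asv = means.shape[0]
    num = np.zeros(n_asv)
    den = np.zeros(n_asv)
    for var, w, mu in zip(var_list, np.asarray(w_list, float), means.T):
        ok = mu > 0
        contrib = np.zeros(n_asv)
        contrib[ok] = (var[ok] - mu[ok]) / mu[ok] ** 2
        num += w * contrib
        den += w * ok
    alpha = np.divide(num, den, out=np.zeros(n_asv), where=den > 0)
    return np.maximum(alpha, _DISP_FLOOR)


def _trended_dispersion(alpha_mom: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Stabilize per-ASV dispersions against a fitted mean-dispersion trend.

    Per-ASV moment estimates carry few degrees of freedom and underestimate
    the dispersion for a sizeable fraction of ASVs, which inflates Wald
    statistics.  A parametric trend alpha(mu) = a0 + a1/mu is fitted across
    ASVs (iteratively trimmed least squares on the positive estimates) and
    each ASV's working dispersion is the larger of its own estimate and the
    trend value — a conservative stand-in for DESeq2's shrinkage.
    """
    ok = (alpha_mom > _DISP_FLOOR) & (mu > 0)
    if ok.sum() < 10:
        base = np.median(alpha_mom[ok]) if ok.any() else _DISP_FLOOR
        return np.maximum(alpha_mom, base)
    x = 1.0 / mu[ok]
    y = alpha_mom[ok]
    keep = np.ones(len(y), bool)
    coef = np.array([np.median(y), 0.0])
    for _ in range(10):
        design = np.column_stack([np.ones(keep.sum()), x[keep]])
        coef, *_ = np.linalg.lstsq(design, y[keep], rcond=None)
        fit = coef[0] + coef[1] * x
        resid = y / np.maximum(fit, _DISP_FLOOR)
        new_keep = (resid > 1e-4) & (resid < 15.0)  # trim outlying ratios
        if (new_keep == keep).all():
            break
        keep = new_keep
        if keep.sum() < 10:
            break
    trend = np.maximum(coef[0] + coef[1] / np.maximum(mu, 1e-12), _DISP_FLOOR)
    return np.maximum(alpha_mom, trend)


def wald_da_test(
    counts: CountTable,
    sheet: SampleSheet,
    q: float = 0.05,
    exclude_groups: tuple[str, ...] = (),
) -> DAResult:
    """Wald tests for country-differential ASVs on normalized counts.

    ``counts`` is expected to be control/excipient-filtered and
    abundance-filtered already; held-out prediction groups (e.g. ``E-5``)
    are dropped via ``exclude_groups``.  Per ASV the log2-fold change of
    country A over country B is computed from method-adjusted country means
    (pseudo-count 0.5 added to both when either is zero), its standard error
    follows from the NB variance mu + alpha mu^2 by the delta method, and
    the two-sided normal p-value is BH-adjusted.  ASVs with padj < q are
    flagged overabundant in the country with the higher mean.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    sheet.resolve(counts)
    meta = sheet.data.loc[counts.sample_ids]
    tablets = meta[
        (meta["sample_type"] == "tablet") & ~meta["group_label"].isin(exclude_groups)
    ]
    for country in ("A", "B"):
        n_c = int((tablets["country"] == country).sum())
        if n_c < 2:
            raise ValueError(f"country {country!r} has {n_c} tablet sample(s); need >= 2")
    sub = counts.subset_samples(list(tablets.index))
    sf = poscounts_size_factors(sub)
    y = sub.counts.to_numpy(float) / sf.to_numpy()[None, :]

    cells: dict[tuple[str, str], np.ndarray] = {}
    for key, idx in tablets.groupby(["country", "manufacturing"]).groups.items():
        cells[key] = tablets.index.get_indexer(idx)
    cell_list = list(cells.values())
    means, var_list, w_list = _cell_stats(y, cell_list)
    alpha = _mom_dispersion(means, var_list, w_list)
    alpha = _trended_dispersion(alpha, y.mean(axis=1))
    df_resid = sum(len(idx) for idx in cell_list) - len(cell_list)

    country_mean = {}
    country_var = {}
    for country in ("A", "B"):
        keys = [k for k in cells if k[0] == country]
        cols = [means[:, list(cells).index(k)] for k in keys]
        mu = np.mean(cols, axis=0)
        # var(cell mean) under NB: (m + alpha m^2)/n_c; country mean averages cells
        v = np.zeros_like(mu)
        for k in keys:
            m_c = means[:, list(cells).index(k)]
            v += (m_c + alpha * m_c**2) / len(cells[k])
        v /= len(keys) ** 2
        country_mean[country] = mu
        country_var[country] = v

    mu_a, mu_b = country_mean["A"], country_mean["B"]
    va, vb = country_var["A"], country_var["B"]
    zero_either = (mu_a == 0) | (mu_b == 0)
    mu_a_adj = np.where(zero_either, mu_a + _PSEUDO, mu_a)
    mu_b_adj = np.where(zero_either, mu_b + _PSEUDO, mu_b)
    lfc = np.log2(mu_a_adj / mu_b_adj)
    ln2 = np.log(2.0)
    se = np.sqrt(va / mu_a_adj**2 + vb / mu_b_adj**2) / ln2
    both_zero = (mu_a == 0) & (mu_b == 0)
    z = np.zeros_like(lfc)
    ok = se > 0
    z[ok] = lfc[ok] / se[ok]
    # t reference at the residual df of the cell-means model: the dispersion
    # (hence se) is estimated from few samples, and a normal reference is
    # visibly anticonservative at this design size
    p = 2.0 * stats.t.sf(np.abs(z), df=max(df_resid, 1))
    p[~ok & (lfc == 0)] = 1.0
    p[both_zero] = 1.0
    padj = bh_adjust(p)
    flag = np.where(
        (padj < q) & (lfc > 0), "A", np.where((padj < q) & (lfc < 0), "B", "none")
    )
    table = pd.DataFrame(
        {
            "mean_A": mu_a,
            "mean_B": mu_b,
            "lfc": lfc,
            "se": se,
            "z": z,
            "p": p,
            "padj": padj,
            "overabundant_in": flag,
        },
        index=sub.counts.index,
    )
    return DAResult(table=table, size_factors=sf, q=q)
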