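"""Community-level analyses: iterative rarefaction, alpha/beta diversity,
rank-based group tests, PERMANOVA, dispersion homogeneity and shared-ASV
summaries.

PERMANOVA follows the classical partitioning of a Gower-centered squared
dissimilarity matrix with *sequential* (Type-I) sums of squares in the
user-given term order, pseudo-F ratios against the residual, and p-values
from whole-row permutations, as in ``vegan::adonis``.  Dispersion
homogeneity mirrors ``vegan::betadisper``: distances to group centers are
computed in the full principal-coordinate embedding with the standard
negative-eigenvalue correction (imaginary-axis contributions subtracted in
the squared distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables_io import CountTable

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "PermanovaTable",
    "KruskalDunnResult",
    "DispersionResult",
    "rarefy_iterative",
    "alpha_diversity",
    "kruskal_dunn",
    "bray_curtis",
    "pcoa",
    "permanova",
    "betadisper",
    "shared_asvs",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    data: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.ids):
            raise ValueError("ids length does not match matrix size")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.data = d
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class Ordination:
    """Principal-coordinate embedding: sample scores on axes ordered by
    non-increasing eigenvalue, with the full eigenvalue spectrum retained."""

    coords: pd.DataFrame  # samples x positive axes
    eigvals: np.ndarray  # all eigenvalues, descending (may include negatives)
    proportion_explained: np.ndarray  # per retained axis, relative to sum of positive eigvals


@dataclass
class PermanovaTable:
    """adonis-style ANOVA table: one row per term plus Residual and Total."""

    table: pd.DataFrame  # index term; columns Df, SS, R2, EV, F, p
    n_perm: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class KruskalDunnResult:
    statistic: float  # Kruskal-Wallis chi-squared (tie-corrected)
    pvalue: float
    pairwise: pd.DataFrame  # group1, group2, z, p, p_adj (Holm)


@dataclass
class DispersionResult:
    distances: pd.Series  # per-sample distance to its group center
    group_means: pd.Series
    statistic: float | None  # one-way F on distances (None if untestable)
    pvalue: float | None
    excluded_groups: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rarefaction & alpha diversity
# ---------------------------------------------------------------------------


def rarefy_iterative(
    counts: CountTable, depth: int = 5000, n_iter: int = 100, seed: int | None = None
) -> CountTable:
    """Iteratively rarefy each sample to ``depth`` reads.

    For every retained sample, ``n_iter`` independent without-replacement
    subsamples of size ``depth`` are drawn and the per-ASV mean across
    iterations is rounded half-up, mirroring ``EcolUtils::rrarefy.perm``.
    Samples whose total is below ``depth`` are dropped with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if seed is None:
        raise ValueError("seed is mandatory for reproducible rarefaction")
    rng = np.random.default_rng(seed)
    totals = counts.sample_totals()
    shallow = list(totals.index[totals < depth])
    if shallow:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below rarefaction depth {depth}: {shallow}",
            stacklevel=2,
        )
    kept = [s for s in counts.sample_ids if s not in set(shallow)]
    out = {}
    for s in kept:
        vec = counts.counts[s].to_numpy(np.int64)
        acc = np.zeros(len(vec), dtype=float)
        for _ in range(n_iter):
            acc += rng.multivariate_hypergeometric(vec, depth)
        out[s] = np.floor(acc / n_iter + 0.5).astype(np.int64)  # round half-up
    rarefied = pd.DataFrame(out, index=counts.counts.index)
    return CountTable(rarefied, counts.marker)


def alpha_diversity(counts: CountTable) -> pd.DataFrame:
    """Per-sample richness S (# ASVs with nonzero count) and Shannon H in nats.

    H = -sum p_i ln p_i over the sample's relative abundances.
    """
    rows = {}
    for s in counts.sample_ids:
        vec = counts.counts[s].to_numpy(float)
        total = vec.sum()
        if total <= 0:
            raise ValueError(f"sample {s!r} has all-zero counts; alpha diversity undefined")
        p = vec[vec > 0] / total
        rows[s] = {"richness": int((vec > 0).sum()), "shannon": float(-(p * np.log(p)).sum())}
    return pd.DataFrame.from_dict(rows, orient="index")[["richness", "shannon"]]


# ---------------------------------------------------------------------------
# rank-based group tests
# ---------------------------------------------------------------------------


def kruskal_dunn(values, groups) -> KruskalDunnResult:
    """Kruskal-Wallis rank-sum test followed by Dunn's pairwise post-hoc z
    tests with Holm adjustment over all pairs.

    Dunn's z uses pooled mean-rank differences with the standard tie
    correction: z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    by = {g: values[groups == g] for g in levels}
    small = [g for g, v in by.items() if len(v) < 2]
    if small:
        raise ValueError(f"group(s) with < 2 observations: {small}")
    stat, p = stats.kruskal(*[by[g] for g in levels])

    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    rows = []
    for i, gi in enumerate(levels):
        for gj in levels[i + 1 :]:
            ni, nj = len(by[gi]), len(by[gj])
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            rows.append({"group1": gi, "group2": gj, "z": z, "p": 2 * stats.norm.sf(abs(z))})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = multipletests(pw["p"], method="holm")[1]
    return KruskalDunnResult(statistic=float(stat), pvalue=float(p), pairwise=pw)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(counts: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y) between samples."""
    mat = counts.counts.to_numpy(float).T  # samples x asvs
    zero = mat.sum(axis=1) == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(counts.sample_ids, zero) if z]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(d, counts.sample_ids)


def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = -(1/2) J D^2 J with J = I - 11'/n."""
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _pcoa_eigen(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the Gower matrix, eigenvalues descending."""
    g = _gower_center(d)
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


def pcoa(dist: DistanceMatrix) -> Ordination:
    """Classical scaling (principal coordinates) of a dissimilarity matrix.

    Axes are restricted to positive eigenvalues; the full spectrum, including
    any negative eigenvalues from non-Euclidean dissimilarities, is reported.
    """
    vals, vecs = _pcoa_eigen(dist.data)
    tol = max(1e-10, 1e-10 * abs(vals).max()) if len(vals) else 0.0
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    pos_sum = vals[pos].sum()
    prop = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    return Ordination(
        coords=pd.DataFrame(coords, index=dist.ids, columns=axes),
        eigvals=vals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _one_hot(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    return (labels[:, None] == levels[None, :]).astype(float)


def _term_matrix(term: str, design: pd.DataFrame) -> np.ndarray:
    """Design columns for a term: one-hot for a factor, elementwise products
    of one-hot columns for an ``a:b`` crossing."""
    parts = term.split(":")
    mats = []
    for pt in parts:
        if pt not in design.columns:
            raise KeyError(f"unknown factor {pt!r}")
        lab = design[pt].to_numpy()
        if len(pd.unique(lab)) < 2:
            raise ValueError(f"factor {pt!r} is constant")
        mats.append(_one_hot(lab))
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(out), -1)
    return out


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaTable:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Terms are entered sequentially in the given order (a term may be a
    factor name or an ``a:b`` crossing); each term's pseudo-F is tested by
    whole-row permutation of the Gower-centered matrix, with the observed
    statistic included in both numerator and denominator of the p-value.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    design = design.loc[dist.ids]
    if terms is None:
        terms = list(design.columns)
    n = dist.n
    g = _gower_center(dist.data)
    ss_total = float(np.trace(g))

    # cumulative orthonormal bases including the intercept
    ones = np.ones((n, 1))
    cum = ones
    q_prev = ones / np.sqrt(n)
    hat_prev = q_prev @ q_prev.T
    rank_prev = 1
    deltas, dfs = [], []
    for term in terms:
        cum = np.hstack([cum, _term_matrix(term, design)])
        u, sv, _ = np.linalg.svd(cum, full_matrices=False)
        rank = int((sv > sv[0] * 1e-10).sum())
        basis = u[:, :rank]  # orthonormal basis for the cumulative column space
        hat = basis @ basis.T
        deltas.append(hat - hat_prev)
        dfs.append(rank - rank_prev)
        hat_prev, rank_prev = hat, rank
    resid_proj = np.eye(n) - hat_prev
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("model saturates the samples; no residual degrees of freedom")
    if any(df <= 0 for df in dfs):
        raise ValueError("a term adds no degrees of freedom (aliased with earlier terms)")

    def _ss(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float((dh * gmat).sum()) for dh in deltas])
        ss_res = float((resid_proj * gmat).sum())
        return ss_terms, ss_res

    ss_obs, ss_res_obs = _ss(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = _ss(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_res_p / df_res)
        exceed += f_p >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "Df": dfs[i],
                "SS": ss_obs[i],
                "R2": ss_obs[i] / ss_total,
                "EV": 100.0 * ss_obs[i] / ss_total,
                "F": f_obs[i],
                "p": pvals[i],
            }
        )
    rows.append(
        {
            "Df": df_res,
            "SS": ss_res_obs,
            "R2": ss_res_obs / ss_total,
            "EV": 100.0 * ss_res_obs / ss_total,
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"Df": n - 1, "SS": ss_total, "R2": 1.0, "EV": 100.0, "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaTable(table=table, n_perm=n_perm)


# ---------------------------------------------------------------------------
# dispersion homogeneity
# ---------------------------------------------------------------------------


def _spatial_median(x: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the geometric (spatial) median."""
    m = x.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(x - m, axis=1)
        if (d < 1e-12).any():
            d = np.maximum(d, 1e-12)
        w = 1.0 / d
        new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def betadisper(
    dist: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None
) -> DispersionResult:
    """Multivariate homogeneity of group dispersions.

    Samples are embedded by PCoA; each sample's squared distance to its
    group's spatial median accumulates positively over real axes and
    negatively over imaginary (negative-eigenvalue) axes.  Group differences
    in mean dispersion are tested with a one-way F statistic under label
    permutation.  Groups of size 1 are excluded from the test with a warning
    (their distances are still returned, as zero).
    """
    groups = pd.Series(np.asarray(groups), index=dist.ids)
    vals, vecs = _pcoa_eigen(dist.data)
    tol = max(1e-10, 1e-10 * abs(vals).max()) if len(vals) else 0.0
    pos, neg = vals > tol, vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])

    sq = pd.Series(0.0, index=dist.ids)
    for gname, idx in groups.groupby(groups).groups.items():
        sel = groups.index.get_indexer(idx)
        c_real = _spatial_median(real[sel]) if real.shape[1] else np.zeros(0)
        c_imag = imag[sel].mean(axis=0) if imag.shape[1] else np.zeros(0)
        d2 = np.zeros(len(sel))
        if real.shape[1]:
            d2 += ((real[sel] - c_real) ** 2).sum(axis=1)
        if imag.shape[1]:
            d2 -= ((imag[sel] - c_imag) ** 2).sum(axis=1)
        sq.iloc[sel] = np.sqrt(np.maximum(d2, 0.0))
    distances = sq

    sizes = groups.value_counts()
    singletons = list(sizes.index[sizes < 2])
    if singletons:
        warnings.warn(
            f"group(s) of size 1 excluded from dispersion test: {singletons}", stacklevel=2
        )
    testable = groups[~groups.isin(singletons)]
    group_means = distances.groupby(groups).mean()
    if testable.nunique() < 2:
        if len(singletons) and groups.nunique() == 1:
            raise ValueError("dispersion test needs >= 2 groups")
        return DispersionResult(distances, group_means, None, None, singletons)

    d_test = distances[testable.index].to_numpy()
    labels = testable.to_numpy()

    def _f(dvals: np.ndarray, lab: np.ndarray) -> float:
        grand = dvals.mean()
        ss_b = ss_w = 0.0
        k = 0
        for gname in pd.unique(lab):
            v = dvals[lab == gname]
            ss_b += len(v) * (v.mean() - grand) ** 2
            ss_w += ((v - v.mean()) ** 2).sum()
            k += 1
        df_b, df_w = k - 1, len(dvals) - k
        if ss_w <= 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = _f(d_test, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if _f(d_test, rng.permutation(labels)) >= f_obs - 1e-12:
            exceed += 1
    pval = (1.0 + exceed) / (1.0 + n_perm)
    return DispersionResult(distances, group_means, float(f_obs), float(pval), singletons)


# ---------------------------------------------------------------------------
# shared ASVs
# ---------------------------------------------------------------------------


def shared_asvs(counts: CountTable, grouping) -> pd.DataFrame:
    """Pairwise matrix of ASVs shared between sample groups.

    Entry (g, h) counts ASVs with a nonzero read in at least one sample of g
    AND at least one sample of h; the diagonal is each group's richness.
    """
    if isinstance(grouping, pd.Series) and isinstance(grouping.dtype, pd.CategoricalDtype):
        levels = list(grouping.cat.categories)
        grouping = pd.Series(grouping.to_numpy(), index=counts.sample_ids)
    else:
        grouping = pd.Series(np.asarray(grouping), index=counts.sample_ids)
        levels = list(pd.unique(grouping))
    presence = {}
    for g in levels:
        cols = grouping.index[grouping == g]
        if len(cols) == 0:
            raise ValueError(f"empty group {g!r}")
        presence[g] = (counts.counts[list(cols)] > 0).any(axis=1).to_numpy()
    out = pd.DataFrame(0, index=levels, columns=levels, dtype=int)
    for g in levels:
        for h in levels:
            out.loc[g, h] = int((presence[g] & presence[h]).sum())
    return out
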