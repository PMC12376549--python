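"""Community and microcosm statistics.

RPKM abundance, alpha diversity (Shannon, natural log), Bray-Curtis
dissimilarity, rank-based permutation tests (ANOSIM, Mantel) with the
add-one p-value estimator p = (1 + #{R* >= R}) / (1 + nperm), Spearman
correlation networks with Benjamini-Hochberg FDR edge filtering,
cumulative CO2-C from interval trap amounts, the microbial metabolic
quotient qCO2, and group comparisons (one-way ANOVA with Duncan's multiple
range letters; Welch/pooled t-tests).

Conventions
-----------
* Abundance matrices are contigs (rows) x samples (columns).
* Distance matrices are square pandas frames indexed by sample id.
* All permutation routines are deterministic under an integer seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------- abundance

def rpkm(counts: pd.DataFrame, lengths, totals) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    rpkm[i, s] = counts[i, s] / (length_i / 1e3) / (total_s / 1e6).
    ``lengths`` maps contig -> bp; ``totals`` maps sample -> mapped reads.
    """
    lengths = pd.Series(lengths).reindex(counts.index)
    totals = pd.Series(totals).reindex(counts.columns)
    if lengths.isna().any():
        raise ValueError(f"missing lengths for contigs: {list(lengths.index[lengths.isna()])}")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    bad = totals.index[totals.isna() | (totals <= 0)]
    if len(bad):
        raise ValueError(f"non-positive mapped-read total for sample(s): {list(bad)}")
    out = counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    return out


def shannon(matrix: pd.DataFrame) -> pd.Series:
    """Per-sample Shannon index H = -sum p_i ln p_i over non-zero taxa.

    All-zero samples get a missing value (H undefined) with a warning.
    """
    out = {}
    for sample in matrix.columns:
        x = matrix[sample].to_numpy(dtype=float)
        total = x.sum()
        if total <= 0:
            warnings.warn(f"sample {sample!r} is all zero; Shannon undefined")
            out[sample] = np.nan
            continue
        p = x[x > 0] / total
        out[sample] = float(-(p * np.log(p)).sum())
    return pd.Series(out, name="shannon")


def richness(matrix: pd.DataFrame) -> pd.Series:
    return (matrix > 0).sum(axis=0).rename("richness")


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(u, v) = 1 - 2 sum_i min(u_i, v_i) / sum_i (u_i + v_i), in [0, 1].
    Distances to an all-zero sample are 1 by convention (warned).
    """
    X = matrix.to_numpy(dtype=float).T
    zero = X.sum(axis=1) <= 0
    if zero.any():
        warnings.warn(
            f"all-zero sample(s) {list(matrix.columns[zero])}; distances set to 1"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(X, metric="braycurtis"))
    D[np.isnan(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=matrix.columns, columns=matrix.columns)


def _square(dist: pd.DataFrame) -> tuple[np.ndarray, list]:
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    ids = list(dist.index) if isinstance(dist, pd.DataFrame) else list(range(D.shape[0]))
    return D, ids


# ------------------------------------------------------- permutation tests

@dataclass
class PermutationResult:
    statistic: float
    pvalue: float
    nperm: int


def _anosim_r(ranks: np.ndarray, iu, labels: np.ndarray) -> np.ndarray:
    """ANOSIM R for each row of ``labels`` (shape (B, n))."""
    within = labels[:, iu[0]] == labels[:, iu[1]]
    m = ranks.size
    rw = np.where(within, ranks, 0.0).sum(axis=1) / within.sum(axis=1)
    rb = np.where(~within, ranks, 0.0).sum(axis=1) / (~within).sum(axis=1)
    return (rb - rw) / (m / 2.0)


def anosim(dist: pd.DataFrame, groups, nperm: int = 999, seed=None) -> PermutationResult:
    """Analysis of similarities: rank-based test of group separation.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    ranks over all M = n(n-1)/2 pairwise distances; R is in [-1, 1] and
    invariant under monotone transforms of the distances. p is estimated
    by label permutation with the add-one rule.
    """
    D, ids = _square(dist)
    groups = np.asarray(pd.Series(groups).reindex(ids) if isinstance(groups, (pd.Series, dict))
                        else groups)
    if len(groups) != len(ids):
        raise ValueError("groups must align with the distance matrix samples")
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (sizes < 2).any():
        raise ValueError(f"groups of size 1 not allowed: {list(sizes.index[sizes < 2])}")
    n = len(ids)
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(D[iu])
    codes = pd.factorize(groups)[0]
    r_obs = float(_anosim_r(ranks, iu, codes[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(nperm)])
    r_perm = _anosim_r(ranks, iu, perms)
    p = (1 + int(np.sum(r_perm >= r_obs))) / (1 + nperm)
    return PermutationResult(r_obs, p, nperm)


def anosim_exact(dist: pd.DataFrame, groups) -> tuple[float, float]:
    """Exact ANOSIM p over all distinct label assignments (small n only)."""
    D, _ = _square(dist)
    n = D.shape[0]
    codes = pd.factorize(np.asarray(groups))[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(D[iu])
    r_obs = float(_anosim_r(ranks, iu, codes[None, :])[0])
    perms = np.array(list(itertools.permutations(codes)))
    perms = np.unique(perms, axis=0)
    r_all = _anosim_r(ranks, iu, perms)
    p = float(np.mean(r_all >= r_obs - 1e-12))
    return r_obs, p


def mantel(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    nperm: int = 999,
    method: str = "spearman",
    seed=None,
    alternative: str = "greater",
) -> PermutationResult:
    """Mantel correlation between two distance matrices over shared samples.

    r is the (rank) correlation of the upper triangles; p comes from
    permuting one matrix's sample order, add-one estimator. A constant
    upper triangle makes r undefined (returned as missing).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method: {method!r}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    A, ids1 = _square(d1)
    B, ids2 = _square(d2)
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if set(ids1) != set(ids2):
            raise ValueError("distance matrices must cover the same samples")
        B = d2.loc[ids1, ids1].to_numpy(dtype=float)
    elif A.shape != B.shape:
        raise ValueError("distance matrices must have matching shape")
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    x, y = A[iu], B[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant distance matrix; Mantel r undefined")
        return PermutationResult(np.nan, np.nan, nperm)
    if method == "spearman":
        # sample reordering permutes the pair multiset, so ranks can be
        # computed once on the matrix and permuted with it
        x = stats.rankdata(x)
        Y = np.zeros_like(B)
        Y[iu] = stats.rankdata(y)
        Y = Y + Y.T
    else:
        Y = B
    y0 = Y[iu]

    def corr(yv: np.ndarray) -> float:
        return float(np.corrcoef(x, yv)[0, 1])

    r_obs = corr(y0)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(nperm):
        idx = rng.permutation(n)
        yp = Y[np.ix_(idx, idx)][iu]
        r_p = corr(yp)
        if alternative == "greater":
            hit = r_p >= r_obs
        else:
            hit = abs(r_p) >= abs(r_obs)
        count += bool(hit)
    p = (1 + count) / (1 + nperm)
    return PermutationResult(r_obs, p, nperm)


# -------------------------------------------------------- correlation nets

def corr_network(
    features: pd.DataFrame,
    r_threshold: float = 0.7,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Spearman co-occurrence edges: |r| > r_threshold and BH q < q_threshold.

    ``features`` is samples (rows) x features (columns); needs >= 4 samples.
    Both inequalities are strict, as printed. Constant features are dropped
    with a warning; FDR is controlled over the full pairwise family.
    """
    if features.shape[0] < 4:
        raise ValueError("correlation network needs at least 4 samples")
    const = features.columns[features.nunique() <= 1]
    if len(const):
        warnings.warn(f"constant features dropped: {list(const)}")
        features = features.drop(columns=const)
    cols = list(features.columns)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        res = stats.spearmanr(features[a], features[b])
        rows.append({"feature_a": a, "feature_b": b,
                     "r": float(res.statistic), "p": float(res.pvalue)})
    edges = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p"])
    if edges.empty:
        edges["q"] = []
        return edges
    edges["q"] = multipletests(edges["p"], method="fdr_bh")[1]
    keep = (edges["r"].abs() > r_threshold) & (edges["q"] < q_threshold)
    return edges[keep].reset_index(drop=True)


# ------------------------------------------------------------- microcosms

def cumulative_co2(series: pd.DataFrame) -> pd.DataFrame:
    """Cumulative CO2-C trajectories from interval trap amounts.

    ``series`` is long-form with columns sample_id, day, co2_c (the amount
    trapped over the interval ending at ``day``). Alkali traps integrate
    the interval, so the cumulative value at day k is the prefix sum of
    interval amounts — no interpolation. Days must strictly increase
    within a sample and amounts must be nonnegative.
    """
    required = {"sample_id", "day", "co2_c"}
    if not required <= set(series.columns):
        raise ValueError(f"microcosm series needs columns {sorted(required)}")
    if (series["co2_c"] < 0).any():
        raise ValueError("negative interval CO2-C amount")
    out = []
    for sid, grp in series.groupby("sample_id", sort=True):
        days = grp["day"].to_numpy()
        if not np.all(np.diff(days) > 0):
            raise ValueError(f"day grid not strictly increasing for sample {sid!r}")
        cum = grp["co2_c"].cumsum()
        out.append(pd.DataFrame({
            "sample_id": sid, "day": days, "cumulative_co2_c": cum.to_numpy(),
        }))
    return pd.concat(out, ignore_index=True)


def qco2(cumulative_co2_c, mbc, duration_days) -> float | np.ndarray | pd.Series:
    """Microbial metabolic quotient, mg CO2-C per mg MBC per day.

    qCO2 = cumulative CO2-C / (MBC * duration). MBC of zero gives a
    missing value with a warning.
    """
    if np.any(np.asarray(duration_days) <= 0):
        raise ValueError("duration must be positive")
    mbc_arr = np.asarray(mbc, dtype=float)
    if np.any(mbc_arr == 0):
        warnings.warn("MBC of zero; qCO2 undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(cumulative_co2_c, dtype=float) / (mbc_arr * np.asarray(duration_days, dtype=float))
    out = np.where(mbc_arr == 0, np.nan, out)
    if isinstance(cumulative_co2_c, pd.Series):
        return pd.Series(out, index=cumulative_co2_c.index, name="qco2")
    if out.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------- group contrasts

@dataclass
class GroupCompareResult:
    method: str
    statistic: float
    pvalue: float
    means: pd.Series
    letters: pd.Series | None = None

    def summary(self) -> str:
        lines = [f"{self.method}: statistic={self.statistic:.4g} p={self.pvalue:.4g}"]
        for g in self.means.index:
            letter = f" {self.letters[g]}" if self.letters is not None else ""
            lines.append(f"  {g}: mean={self.means[g]:.4g}{letter}")
        return "\n".join(lines)


def _duncan_significant(means: np.ndarray, ns: np.ndarray, mse: float,
                        df: int, alpha: float) -> np.ndarray:
    """Pairwise significance by Duncan's multiple range test.

    Means must be sorted descending. A pair spanning r means differs when
    its gap exceeds R_r = q(1-(1-alpha)^(r-1); r, df) * sqrt(MSE/n_h);
    pairs inside a non-significant wider range inherit non-significance
    (the usual multiple-range protection).
    """
    k = len(means)
    n_h = k / np.sum(1.0 / ns)     # harmonic mean group size
    nonsig = np.zeros((k, k), dtype=bool)
    if mse <= 0:
        # degenerate: no within-group variance; separated iff means differ
        for i in range(k):
            for j in range(i, k):
                nonsig[i, j] = np.isclose(means[i], means[j])
        crit = None
    else:
        crit = {}
        for r in range(2, k + 1):
            level = 1 - (1 - alpha) ** (r - 1)
            crit[r] = stats.studentized_range.ppf(1 - level, r, df) * np.sqrt(mse / n_h)
    for span in range(k - 1, 0, -1):           # widest spans first
        for i in range(0, k - span):
            j = i + span
            if mse > 0:
                ns_pair = (means[i] - means[j]) <= crit[span + 1]
            else:
                ns_pair = nonsig[i, j]
            if ns_pair or (i > 0 and nonsig[i - 1, j]) or (j < k - 1 and nonsig[i, j + 1]):
                nonsig[i, j] = True
    np.fill_diagonal(nonsig, True)
    return nonsig


def _letters_from_nonsig(nonsig: np.ndarray, names: list) -> pd.Series:
    """Compact letter display from a (sorted-order) non-significance matrix.

    The range protection makes non-significance closed under sub-intervals,
    so homogeneous subsets are maximal intervals of the mean-sorted order.
    """
    k = len(names)
    jmax = [max(j for j in range(i, k) if nonsig[i, j]) for i in range(k)]
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        if intervals and intervals[-1][1] >= jmax[i]:
            continue        # contained in an earlier homogeneous interval
        intervals.append((i, jmax[i]))
    letters = {name: "" for name in names}
    for idx, (i, j) in enumerate(intervals):
        letter = chr(ord("a") + idx)
        for g in range(i, j + 1):
            letters[names[g]] += letter
    return pd.Series(letters)


def group_compare(
    values,
    groups,
    method: str = "anova_duncan",
    alpha: float = 0.05,
    equal_var: bool = False,
) -> GroupCompareResult:
    """Compare group means: one-way ANOVA + Duncan letters, or a t-test.

    ``anova_duncan`` returns the ANOVA F and p plus a compact letter
    display from Duncan's multiple range test (groups sharing a letter are
    not separated at ``alpha``). ``ttest`` handles exactly two groups
    (Welch by default; pooled with ``equal_var=True``).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(groups)})
    grouped = [g["value"].to_numpy() for _, g in df.groupby("group", sort=True)]
    names = sorted(df["group"].unique().tolist())
    means = df.groupby("group", sort=True)["value"].mean()

    if method == "ttest":
        if len(grouped) != 2:
            raise ValueError("t-test needs exactly two groups")
        res = stats.ttest_ind(grouped[0], grouped[1], equal_var=equal_var)
        return GroupCompareResult("ttest", float(res.statistic), float(res.pvalue), means)
    if method != "anova_duncan":
        raise ValueError(f"unknown method: {method!r}")
    if len(grouped) < 2:
        raise ValueError("ANOVA needs at least two groups")

    ns = np.array([len(g) for g in grouped])
    sse = sum(((g - g.mean()) ** 2).sum() for g in grouped)
    dferr = int(ns.sum() - len(grouped))
    mse = sse / dferr if dferr > 0 else 0.0
    if mse > 0:
        f_res = stats.f_oneway(*grouped)
        fstat, p = float(f_res.statistic), float(f_res.pvalue)
    else:
        same = all(np.isclose(means.iloc[0], m) for m in means)
        fstat, p = (0.0, 1.0) if same else (np.inf, 0.0)

    order = np.argsort(-means.to_numpy(), kind="stable")
    sorted_names = [names[i] for i in order]
    nonsig = _duncan_significant(means.to_numpy()[order], ns[order], mse, dferr, alpha)
    letters = _letters_from_nonsig(nonsig, sorted_names).reindex(names)
    return GroupCompareResult("anova_duncan", fstat, p, means, letters)
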