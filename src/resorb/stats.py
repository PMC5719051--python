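"""Classical statistics layer: one-way ANOVA with compact letter display,
t-tests, PCA of the element correlation matrix, standardised major axis
(SMA) line fits and sequential (Type I) variance partitioning.

SMA is the symmetric line fit used when neither variable is the "response"
and both carry measurement error: slope = sign(r) * sd(y)/sd(x), so the
fit is reciprocal (slope_yx = 1/slope_xy) and the significance test is the
Pearson correlation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "SMAFit",
    "VariancePartition",
    "one_way_anova",
    "letter_groups",
    "one_sample_t",
    "two_sample_t",
    "pca_elements",
    "sma_fit",
    "variance_partition",
    "correlation_table",
]


@dataclass
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float


@dataclass
class SMAFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


@dataclass
class VariancePartition:
    """Sequential (Type I) decomposition of the total sum of squares.

    ``proportions`` maps each factor, in entry order, to its share of the
    total SS; ``residual`` completes the sum to 1.
    """

    factors: list[str]
    proportions: dict[str, float]
    residual: float


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {}
    for lab in pd.unique(labels):
        groups[lab] = values[labels == lab]
    return groups


def one_way_anova(values, group_labels) -> AnovaResult:
    """Classical one-way ANOVA from the SS decomposition."""
    groups = _split_groups(values, group_labels)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(g) < 1 for g in groups.values()):
        raise ValueError("empty group")
    x = np.concatenate(list(groups.values()))
    n, k = len(x), len(groups)
    if n - k < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, float(ss_between), float(ss_within))


def letter_groups(values, group_labels, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from pairwise Tukey HSD at ``alpha``.

    Groups not significantly different share a letter; letters are assigned
    a, b, c ... to the maximal cliques of the non-significance graph in
    descending order of the largest group mean they contain, so 'a' always
    marks the highest-mean group.
    """
    groups = _split_groups(values, group_labels)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("letter display needs at least two groups")
    means = {g: groups[g].mean() for g in names}
    if len(names) == 2:
        p = stats.ttest_ind(groups[names[0]], groups[names[1]]).pvalue
        pmat = {frozenset(names): p}
    else:
        res = stats.tukey_hsd(*[groups[g] for g in names])
        pmat = {
            frozenset((names[i], names[j])): res.pvalue[i, j]
            for i in range(len(names))
            for j in range(i + 1, len(names))
        }
    G = nx.Graph()
    G.add_nodes_from(names)
    for pair, p in pmat.items():
        if p >= alpha:
            G.add_edge(*pair)
    cliques = list(nx.find_cliques(G))
    cliques.sort(key=lambda c: -max(means[g] for g in c))
    letters = {g: "" for g in names}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in clique:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in names}


def one_sample_t(values, mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test (default against 0% resorption)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if x.std(ddof=1) == 0:
        if x.mean() == mu0:
            logger.warning("zero variance with mean equal to mu0; p = 1 by convention")
            return 0.0, 1.0
        raise ValueError("degenerate one-sample t-test: zero variance, mean != mu0")
    res = stats.ttest_1samp(x, mu0)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(values, reference) -> tuple[float, float]:
    """Welch two-sample t-test against a reference sample or summary.

    ``reference`` is either a vector of values or a ``(mean, sd, n)``
    triple (for published reference datasets available only as summaries).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if isinstance(reference, tuple) and len(reference) == 3:
        m, sd, n = reference
        res = stats.ttest_ind_from_stats(
            x.mean(), x.std(ddof=1), len(x), m, sd, n, equal_var=False
        )
    else:
        res = stats.ttest_ind(x, np.asarray(reference, dtype=float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pca_elements(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the element correlation matrix.

    Columns are standardised to zero mean / unit variance before the
    eigendecomposition (elements span orders of magnitude, so the
    correlation rather than covariance structure is the object of
    interest).  Returns the orthonormal loading matrix (variables x
    components) and the percent variance explained per component.
    """
    X = pd.DataFrame(matrix).astype(float)
    if X.isna().any().any():
        raise ValueError("PCA requires complete rows (no missing element values)")
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 observations")
    sd = X.std(ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    R = np.corrcoef((X - X.mean()) / sd, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] *= -1
    loadings = pd.DataFrame(
        eigvec,
        index=X.columns,
        columns=[f"PC{j + 1}" for j in range(eigvec.shape[1])],
    )
    variance_explained = 100.0 * eigval / eigval.sum()
    return loadings, variance_explained


def sma_fit(x, y) -> SMAFit:
    """Standardised major axis fit of y against x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired data with n >= 3")
    sdx, sdy = x.std(ddof=1), y.std(ddof=1)
    if sdx == 0 or sdy == 0:
        raise ValueError("SMA undefined for a constant variable")
    r, p = stats.pearsonr(x, y)
    slope = (np.sign(r) if r != 0 else 1.0) * sdy / sdx
    intercept = y.mean() - slope * x.mean()
    return SMAFit(float(slope), float(intercept), float(r), float(p), len(x))


def variance_partition(response, factors: pd.DataFrame) -> VariancePartition:
    """Sequential (Type I) SS share of each categorical factor, in order.

    Factor order matters (each factor is credited with the variance it
    explains beyond those entered before it); the caller's column order is
    honoured and reported.
    """
    factors = pd.DataFrame(factors).astype(str)
    y = np.asarray(response, dtype=float)
    if len(y) != len(factors):
        raise ValueError("response and factors differ in length")
    total = float(((y - y.mean()) ** 2).sum())
    if total == 0:
        raise ValueError("response has zero variance")

    # nested least-squares fits: SS_factor = RSS drop when the factor's
    # dummies join the design.  Robust to partial aliasing (e.g. a plant
    # group confined to a subset of sites), which sequential GLM SS
    # tolerates by construction; a factor adding no rank at all is an error.
    def rss(X: np.ndarray) -> float:
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    X = np.ones((len(y), 1))
    prev_rss, prev_rank = rss(X), 1
    props: dict[str, float] = {}
    for col in factors.columns:
        dummies = pd.get_dummies(factors[col], drop_first=True).to_numpy(dtype=float)
        X = np.hstack([X, dummies])
        rank = np.linalg.matrix_rank(X)
        if rank == prev_rank:
            raise ValueError(f"factor {col!r} fully aliased with preceding terms")
        cur_rss = rss(X)
        props[col] = (prev_rss - cur_rss) / total
        prev_rss, prev_rank = cur_rss, rank
    residual = prev_rss / total
    return VariancePartition(list(factors.columns), props, residual)


def correlation_table(
    pairs: list[tuple[str, str]],
    individual: pd.DataFrame | None = None,
    species: pd.DataFrame | None = None,
    tree=None,
) -> pd.DataFrame:
    """Pearson r and p per trait pair at up to three analysis levels.

    Levels: ``individual`` (all leaves), ``species`` (species means) and
    ``species_PIC`` (correlation of independent contrasts, computed through
    the origin on the supplied tree).  Output rows are pairs, columns are
    level x {r, p, n}; entries with fewer than 3 usable observations are
    missing with a warning.
    """
    from .phylo import pic_correlation  # local import to avoid cycle

    levels: dict[str, pd.DataFrame | None] = {
        "individual": individual,
        "species": species,
    }
    rows = []
    for a, b in pairs:
        row: dict[str, object] = {"pair": f"{a}-{b}"}
        for level, df in levels.items():
            if df is None or a not in df.columns or b not in df.columns:
                continue
            sub = df[[a, b]].dropna()
            if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
                logger.warning("pair %s-%s at level %s: n < 3 or constant; skipped", a, b, level)
                row[f"{level}_r"] = np.nan
                row[f"{level}_p"] = np.nan
                row[f"{level}_n"] = len(sub)
                continue
            r, p = stats.pearsonr(sub[a], sub[b])
            row[f"{level}_r"] = float(r)
            row[f"{level}_p"] = float(p)
            row[f"{level}_n"] = len(sub)
        if tree is not None and species is not None and a in species.columns and b in species.columns:
            sub = species[[a, b]].dropna()
            common = [t for t in tree.tip_labels if t in sub.index]
            if len(common) >= 3:
                r, p, n = pic_correlation(
                    tree, sub.loc[common, a], sub.loc[common, b]
                ) if len(common) == tree.n_tips else _pic_on_subtree(tree, sub, a, b, common)
                row["species_PIC_r"] = np.nan if r is None else r
                row["species_PIC_p"] = np.nan if p is None else p
                row["species_PIC_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def _pic_on_subtree(tree, sub, a, b, common):
    # species missing a trait are dropped listwise; contrasts need the full
    # tip set, so fall back to the common subset only when it covers the tree
    logger.warning(
        "PIC level skipped for %s-%s: %d of %d tree tips have data",
        a, b, len(common), tree.n_tips,
    )
    return None, None, len(common)
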