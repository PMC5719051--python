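"""Phylogenetic comparative statistics: Blomberg's K, a tip-shuffling
permutation test of phylogenetic signal, and Felsenstein's independent
contrasts (PIC).

Blomberg's K compares the observed ratio of the trait's variance around the
phylogenetically weighted (GLS) mean to its GLS error variance against the
ratio expected under Brownian motion on the same tree:

    K = (MSE0 / MSE)_observed / (MSE0 / MSE)_expected

with a_hat = (1' C^-1 x) / (1' C^-1 1),
MSE0 = sum (x_i - a_hat)^2 / (n - 1),
MSE  = (x - a_hat)' C^-1 (x - a_hat) / (n - 1),
expected ratio = [tr(C) - n / (1' C^-1 1)] / (n - 1),

where C is the phylogenetic variance-covariance matrix.  K = 1 under
Brownian motion; K < 1 means less resemblance among relatives than BM
predicts, K > 1 more.  Significance is assessed by shuffling trait values
across tips and comparing the variance of standardised contrasts (lower
variance = more signal), the conventional one-tailed randomisation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS
from .tree import Phylogeny

__all__ = [
    "SignalResult",
    "ContrastSet",
    "vcv_matrix",
    "blomberg_k",
    "signal_test",
    "pic",
    "pic_correlation",
    "encode_group_trait",
]


@dataclass
class SignalResult:
    trait_name: str
    K: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_species: int


@dataclass
class ContrastSet:
    """Standardised independent contrasts, one per internal node of the
    binarised tree (post-order); n tips yield n - 1 contrasts."""

    contrasts: np.ndarray
    tip_labels: list[str]

    def __len__(self) -> int:
        return len(self.contrasts)


def _trait_vector(tree_or_labels, trait) -> np.ndarray:
    """Align a trait mapping/Series to a tip-label order."""
    labels = (
        tree_or_labels.tip_labels if isinstance(tree_or_labels, Phylogeny) else tree_or_labels
    )
    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    if isinstance(trait, dict):
        missing = [l for l in labels if l not in trait]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]}")
        return np.array([float(trait[l]) for l in labels])
    x = np.asarray(trait, dtype=float)
    if x.shape != (len(labels),):
        raise ValueError("trait vector length does not match number of tips")
    return x


def vcv_matrix(tree: Phylogeny) -> pd.DataFrame:
    """Phylogenetic variance-covariance matrix as a labelled DataFrame."""
    C, labels = tree.vcv()
    return pd.DataFrame(C, index=labels, columns=labels)


def _k_stat(C: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    try:
        Cinv_x = np.linalg.solve(C, x)
        Cinv_1 = np.linalg.solve(C, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular phylogenetic covariance matrix: {exc}") from exc
    denom = Cinv_1.sum()
    a_hat = Cinv_x.sum() / denom
    resid = x - a_hat
    mse0 = resid @ resid / (n - 1)
    if mse0 == 0:
        raise ValueError("signal undefined for constant trait")
    mse = resid @ np.linalg.solve(C, resid) / (n - 1)
    expected = (np.trace(C) - n / denom) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: Phylogeny, trait) -> float:
    """Blomberg's K for one trait (mapping, Series or tip-ordered vector)."""
    C, labels = tree.vcv()
    x = _trait_vector(labels, trait)
    return _k_stat(C, x)


def signal_test(
    tree: Phylogeny,
    trait,
    n_perm: int = 999,
    seed: int | None = None,
    trait_name: str = "trait",
) -> SignalResult:
    """Randomisation test of phylogenetic signal, K reported alongside.

    Observed statistic: mean squared standardised contrast (the PIC
    variance); null distribution: trait values shuffled across tips
    ``n_perm`` times; p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _trait_vector(tree, trait)
    if np.all(x == x[0]):
        raise ValueError("signal undefined for constant trait")
    K = blomberg_k(tree, x)
    schedule = tree.pruning_schedule()
    rng = np.random.default_rng(seed)
    X = np.empty((n_perm + 1, len(x)))
    X[0] = x
    for i in range(1, n_perm + 1):
        X[i] = rng.permutation(x)
    pic_var = np.mean(schedule.contrasts(X) ** 2, axis=1)
    p = (1 + np.sum(pic_var[1:] <= pic_var[0])) / (n_perm + 1)
    return SignalResult(
        trait_name=trait_name,
        K=K,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        n_species=len(x),
    )


def pic(tree: Phylogeny, trait) -> ContrastSet:
    """Felsenstein's standardised independent contrasts (post-order)."""
    schedule = tree.pruning_schedule()
    x = _trait_vector(schedule.tip_labels, trait)
    return ContrastSet(schedule.contrasts(x)[0], schedule.tip_labels)


def pic_correlation(tree: Phylogeny, x, y) -> tuple[float | None, float | None, int]:
    """Correlation of two traits' independent contrasts, through the origin.

    r = sum(cx*cy) / sqrt(sum(cx^2) * sum(cy^2)); p from
    t = r * sqrt((n-2)/(1-r^2)) on n-2 df with n = number of contrasts.
    Returns (r, p, n_contrasts); (None, None, n) when either contrast set
    is identically zero.
    """
    schedule = tree.pruning_schedule()
    cx = schedule.contrasts(_trait_vector(schedule.tip_labels, x))[0]
    cy = schedule.contrasts(_trait_vector(schedule.tip_labels, y))[0]
    n = len(cx)
    sxx, syy = cx @ cx, cy @ cy
    if sxx == 0 or syy == 0:
        return None, None, n
    r = float(cx @ cy / np.sqrt(sxx * syy))
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


GROUP_CODES = {g: i + 1 for i, g in enumerate(GROUPS)}  # Eu=1, Se=2, Ps=3, Gl=4


def encode_group_trait(group_of, mode: str = "integer"):
    """Numeric coding of the plant-group label for signal tests.

    ``integer`` (default): fixed order Eu=1, Se=2, Ps=3, Gl=4 (a single K
    per the group trait).  ``indicator``: one 0/1 trait per group.
    """
    series = pd.Series(group_of)
    unknown = sorted(set(series) - set(GROUP_CODES))
    if unknown:
        raise ValueError(f"unknown group label(s): {unknown}")
    if mode == "integer":
        return series.map(GROUP_CODES).astype(float)
    if mode == "indicator":
        return pd.DataFrame(
            {g: (series == g).astype(float) for g in GROUPS}, index=series.index
        )
    raise ValueError(f"unknown mode {mode!r}")
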