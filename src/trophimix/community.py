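"""Community comparison of diet tables across predator groups.

Bray-Curtis dissimilarity (on abundances or presence/absence), a
rank-based permutation ANOSIM, the simplified Morisita (Morisita-Horn)
niche-overlap index with the conventional 0.60 significance threshold,
and a nonmetric MDS embedding for visualisation.

ANOSIM follows Clarke (1993): with mid-ranks of all pairwise
dissimilarities, R = (mean between-group rank - mean within-group rank)
/ (M/2), M = n(n-1)/2. The permutation p-value includes the observed
statistic, p = (#{R_perm >= R_obs} + 1) / (n_perm + 1), so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.manifold import MDS


@dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class OverlapResult:
    index: float
    significant_overlap: bool
    threshold: float = 0.60


def bray_curtis(matrix, presence_absence: bool = False) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, d = sum|x-y| / sum(x+y).

    With ``presence_absence`` the rows are binarised first (the result
    is then the Sorensen complement). A row of all zeros has undefined
    dissimilarity to nonzero rows; those distances are set to 1 and the
    rows flagged in ``result.attrs['zero_rows']`` (zero-zero pairs get 0).
    """
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires nonnegative data")
    if presence_absence:
        x = (x > 0).astype(float)
    zero = x.sum(axis=1) == 0
    d = np.zeros((x.shape[0], x.shape[0]))
    nz = ~zero
    if nz.sum() >= 2:
        d[np.ix_(nz, nz)] = squareform(pdist(x[nz], metric="braycurtis"))
    d[np.ix_(zero, nz)] = 1.0
    d[np.ix_(nz, zero)] = 1.0
    out = pd.DataFrame(d, index=index, columns=index)
    out.attrs["zero_rows"] = list(index[zero])
    return out


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m: int) -> float:
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return (rb - rw) / (m / 2.0)


def anosim(
    dissimilarity,
    group_labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Permutation ANOSIM on a square dissimilarity matrix.

    Requires at least two groups, each with at least two members
    (within-group ranks are undefined for singletons). Deterministic
    under a fixed seed.
    """
    d = np.asarray(
        dissimilarity.to_numpy() if isinstance(dissimilarity, pd.DataFrame) else dissimilarity,
        dtype=float,
    )
    labels = np.asarray(group_labels)
    n = d.shape[0]
    if d.shape != (n, n) or labels.shape != (n,):
        raise ValueError("dissimilarity must be n x n with n group labels")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if counts.min() < 2:
        small = uniq[counts < 2]
        raise ValueError(f"group(s) of size 1 not allowed: {list(map(str, small))}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])  # mid-ranks for ties
    m = n * (n - 1) // 2
    within_obs = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, within_obs, m)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        within = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, within, m) >= r_obs:
            count_ge += 1
    p = (count_ge + 1) / (n_permutations + 1)
    return AnosimResult(float(r_obs), float(p), n_permutations, seed)


def anosim_exact(dissimilarity, group_labels) -> AnosimResult:
    """Exhaustive-enumeration ANOSIM over all distinct label assignments.

    Exact reference for small problems (feasible up to ~10 samples):
    enumerates every way of assigning the multiset of labels to samples
    and reports p = #{R >= R_obs} / #assignments (the observed labelling
    is one of them).
    """
    d = np.asarray(
        dissimilarity.to_numpy() if isinstance(dissimilarity, pd.DataFrame) else dissimilarity,
        dtype=float,
    )
    labels = np.asarray(group_labels)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    m = n * (n - 1) // 2
    within_obs = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, within_obs, m)

    # enumerate assignments as positions of each label class
    idx = np.arange(n)
    classes = [np.sum(labels == u) for u in np.unique(labels)]

    def assignments(remaining, sizes):
        if not sizes:
            yield ()
            return
        for combo in combinations(remaining, sizes[0]):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in assignments(rest, sizes[1:]):
                yield (combo,) + tail

    total = 0
    count_ge = 0
    for assign in assignments(tuple(idx), classes):
        lab = np.empty(n, dtype=int)
        for ci, members in enumerate(assign):
            lab[list(members)] = ci
        within = lab[iu[0]] == lab[iu[1]]
        r = _anosim_r(ranks, within, m)
        total += 1
        if r >= r_obs - 1e-12:
            count_ge += 1
    return AnosimResult(float(r_obs), count_ge / total, total, None)


def morisita_simplified(p, q, threshold: float = 0.60) -> OverlapResult:
    """Simplified Morisita (Morisita-Horn) overlap of two compositions.

    C = 2 sum(p_i q_i) / (sum p_i^2 + sum q_i^2) on internally
    normalised vectors; overlap above ``threshold`` (0.60 by
    convention) is flagged as significant.
    """
    if isinstance(p, pd.Series) or isinstance(q, pd.Series):
        p = pd.Series(p, dtype=float)
        q = pd.Series(q, dtype=float)
        cats = p.index.union(q.index)
        p = p.reindex(cats, fill_value=0.0).to_numpy()
        q = q.reindex(cats, fill_value=0.0).to_numpy()
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("compositions must have matching categories")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("compositions must be nonnegative")
    if p.sum() == 0 or q.sum() == 0:
        raise ValueError("composition sums to zero")
    p = p / p.sum()
    q = q / q.sum()
    c = 2.0 * np.dot(p, q) / (np.dot(p, p) + np.dot(q, q))
    return OverlapResult(float(c), bool(c > threshold), threshold)


def kruskal_stress(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities,
    using isotonic-regressed disparities (the nonmetric criterion)."""
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(d_obs.shape[0], k=1)
    dhat = squareform(pdist(coords))[iu]
    order = d_obs[iu]
    disp = IsotonicRegression().fit_transform(order, dhat)
    denom = float(np.sum(dhat**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dhat - disp) ** 2) / denom))


def nmds(
    dissimilarity,
    k: int = 2,
    n_starts: int = 4,
    seed: int | None = None,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, float]:
    """Nonmetric MDS by stress majorization (SMACOF) with monotone regression.

    Returns the best-of-``n_starts`` configuration and its Kruskal
    stress-1. A visualisation aid; stress depends on the data at hand.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        index = dissimilarity.index
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        index = pd.RangeIndex(d.shape[0])
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points n={n}")
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        random_state=seed,
        max_iter=max_iter,
        normalized_stress=True,
    )
    coords = mds.fit_transform(d)
    stress = kruskal_stress(d, coords)
    cols = [f"axis{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=index, columns=cols), stress
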