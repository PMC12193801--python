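"""Population-level comparison statistics.

Three tools: a two-sided permutation test on Welch's t statistic for
single quantifiers, the exact cross-match test of Rosenbaum for whole
multivariate populations (optimal non-bipartite minimum-distance
matching of the pooled sample under standardized Euclidean distance),
and a PCA morphospace with loadings and kernel density estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

from .io_config import get_logger

__all__ = [
    "CrossMatchResult",
    "MorphospaceEmbedding",
    "permutation_welch_test",
    "standardized_distances",
    "crossmatch_null_pmf",
    "crossmatch_test",
    "pca_morphospace",
    "morphospace_density",
    "star_code",
    "benjamini_hochberg",
]

logger = get_logger(__name__)


def star_code(p: float) -> str:
    """Significance stars as used in the report output."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    nx_, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    denom = math.sqrt(vx / nx_ + vy / ny)
    if denom == 0:
        return 0.0 if np.mean(x) == np.mean(y) else math.inf
    return float((np.mean(x) - np.mean(y)) / denom)


def permutation_welch_test(
    x,
    y,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided permutation test with Welch's t as the statistic.

    Group labels are permuted ``n_permutations`` times and the p-value
    is (1 + #{|t*| ≥ |t_obs|}) / (n_permutations + 1). Deterministic
    given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    t_obs = abs(_welch_t(x, y))
    if t_obs == 0:
        return 1.0

    pooled = np.concatenate([x, y])
    n, m = len(pooled), len(x)
    # vectorized permutations: random keys -> argsort -> permuted pools
    count = 0
    batch = 2000
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm = pooled[order]
        px, py = perm[:, :m], perm[:, m:]
        vx = np.var(px, axis=1, ddof=1)
        vy = np.var(py, axis=1, ddof=1)
        denom = np.sqrt(vx / m + vy / (n - m))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.abs(px.mean(axis=1) - py.mean(axis=1)) / denom
        t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf)
        count += int((t_perm >= t_obs - 1e-12).sum())
        done += b
    return (1 + count) / (n_permutations + 1)


def standardized_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All pairwise standardized Euclidean distances of the pooled sample.

    d(x, y) = sqrt(Σ_j (x_j − y_j)² / s_j²) with s_j the pooled sample
    SD of column j. Zero-variance columns are dropped with a warning;
    if every column has zero variance an error is raised.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must have the same number of columns")
    pooled = np.vstack([A, B])
    if not np.isfinite(pooled).all():
        raise ValueError("undefined entries in input matrices")
    sd = pooled.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero variance")
    if not keep.all():
        logger.warning(
            "standardized_distances: dropping %d zero-variance column(s)",
            int((~keep).sum()),
        )
    z = pooled[:, keep] / sd[keep]
    diff = z[:, None, :] - z[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def crossmatch_null_pmf(m: int, n: int) -> dict[int, float]:
    """Exact null distribution of the cross-match count A1.

    For pooled size N = m + n (even), under random group assignment of a
    fixed perfect matching,

        P(A1 = a1) = 2^a1 (N/2)! / [C(N, m) a0! a1! a2!]

    with a0 = (m − a1)/2 and a2 = (n − a1)/2, over all a1 of the parity
    of m with a0, a2 ≥ 0.
    """
    if m < 1 or n < 1:
        raise ValueError("both group sizes must be >= 1")
    N = m + n
    if N % 2 != 0:
        raise ValueError("pooled size must be even; resolve parity first")
    log_choose = math.lgamma(N + 1) - math.lgamma(m + 1) - math.lgamma(n + 1)
    pmf: dict[int, float] = {}
    for a1 in range(m % 2, min(m, n) + 1, 2):
        a0 = (m - a1) // 2
        a2 = (n - a1) // 2
        logp = (
            a1 * math.log(2)
            + math.lgamma(N // 2 + 1)
            - log_choose
            - math.lgamma(a0 + 1)
            - math.lgamma(a1 + 1)
            - math.lgamma(a2 + 1)
        )
        pmf[a1] = math.exp(logp)
    total = sum(pmf.values())
    return {a1: p / total for a1, p in pmf.items()}


@dataclass
class CrossMatchResult:
    m: int
    n: int
    a0: int
    a1: int
    a2: int
    p_value: float  # exact lower tail P(A1 <= a1)
    mid_p: float  # P(A1 < a1) + P(A1 = a1)/2; calibrated decision rule
    null_pmf: dict[int, float]
    matching: list[tuple[int, int]]
    total_distance: float
    ghost_dropped: tuple[int, int] | None = None  # (ghost index, its partner)


def min_weight_perfect_matching(dist: np.ndarray) -> list[tuple[int, int]]:
    """Exact minimum-total-distance perfect matching of an even number of
    points given their full distance matrix (blossom algorithm)."""
    N = dist.shape[0]
    if N % 2 != 0:
        raise ValueError("perfect matching needs an even number of points")
    G = nx.Graph()
    for i in range(N):
        for j in range(i + 1, N):
            G.add_edge(i, j, weight=float(dist[i, j]))
    matching = nx.min_weight_matching(G)
    return sorted(tuple(sorted(edge)) for edge in matching)


def crossmatch_test(A: np.ndarray, B: np.ndarray) -> CrossMatchResult:
    """Exact cross-match two-sample test.

    The pooled points are paired by an exact minimum-distance perfect
    matching under standardized Euclidean distance; A1 counts pairs that
    span the two groups. Few cross-matches indicate separation, so the
    p-value is the lower tail P(A1 ≤ a1) under the exact null.

    Odd pooled sizes are handled by appending a ghost point at distance
    0 to every real point; the ghost's partner is discarded from the
    counts and the null uses the reduced group sizes.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    m, n = A.shape[0], B.shape[0]
    if m + n < 4:
        raise ValueError("need at least 4 pooled observations")
    dist = standardized_distances(A, B)
    N = m + n
    labels = np.array([0] * m + [1] * n)

    ghost_dropped = None
    if N % 2 == 1:
        padded = np.zeros((N + 1, N + 1))
        padded[:N, :N] = dist
        pairs = min_weight_perfect_matching(padded)
        ghost_pairs = [p for p in pairs if N in p]
        partner = min(ghost_pairs[0])
        ghost_dropped = (N, partner)
        pairs = [p for p in pairs if N not in p]
        if labels[partner] == 0:
            m -= 1
        else:
            n -= 1
    else:
        pairs = min_weight_perfect_matching(dist)

    total = float(sum(dist[i, j] for i, j in pairs))
    a1 = sum(1 for i, j in pairs if labels[i] != labels[j])
    a0 = sum(1 for i, j in pairs if labels[i] == 0 and labels[j] == 0)
    a2 = sum(1 for i, j in pairs if labels[i] == 1 and labels[j] == 1)
    pmf = crossmatch_null_pmf(m, n)
    p = min(1.0, sum(prob for k, prob in pmf.items() if k <= a1))
    # mid-p corrects the conservativeness of the discrete exact tail
    mid = min(1.0, sum(prob for k, prob in pmf.items() if k < a1) + 0.5 * pmf.get(a1, 0.0))
    return CrossMatchResult(
        m=m,
        n=n,
        a0=a0,
        a1=a1,
        a2=a2,
        p_value=p,
        mid_p=mid,
        null_pmf=pmf,
        matching=pairs,
        total_distance=total,
        ghost_dropped=ghost_dropped,
    )


@dataclass
class MorphospaceEmbedding:
    loadings: np.ndarray  # (d, k) orthonormal columns
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # (cells, k)
    column_means: np.ndarray
    column_sds: np.ndarray
    columns: list[str] = field(default_factory=list)


def pca_morphospace(
    matrix: np.ndarray, k: int = 2, columns: list[str] | None = None
) -> MorphospaceEmbedding:
    """PCA of the z-scored quantifier matrix.

    Columns are standardized (sample SD) before decomposition; the sign
    convention makes each component's largest-magnitude loading
    positive, so scores are reproducible across row orders.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    if k > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("k too large for the matrix shape")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd_safe

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # (d, k)
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return MorphospaceEmbedding(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=scores,
        column_means=mean,
        column_sds=sd,
        columns=list(columns) if columns is not None else [],
    )


def morphospace_density(
    scores: np.ndarray,
    conditions: np.ndarray | list,
    grid_size: int = 100,
    padding: float = 0.25,
) -> dict:
    """Gaussian kernel density of 2D scores per condition on one shared
    grid. Each condition's density integrates to ≈ 1 over the grid.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be (cells, 2)")
    conditions = np.asarray(conditions)
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = hi - lo
    lo = lo - padding * span - 1e-9
    hi = hi + padding * span + 1e-9
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(xs, ys)
    positions = np.vstack([gx.ravel(), gy.ravel()])

    for cond in np.unique(conditions):
        if (conditions == cond).sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 points")
    densities = {}
    for cond in np.unique(conditions):
        pts = scores[conditions == cond]
        kde = sps.gaussian_kde(pts.T)
        densities[cond] = kde(positions).reshape(grid_size, grid_size)
    return {"x": xs, "y": ys, "density": densities}


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default report is uncorrected)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adjusted, 1.0)
    return out
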