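"""Phenetic distance analysis: UPGMA dendrogram with multiscale-bootstrap support.

Strains are clustered on the Euclidean distances between their rows of
the scaled (centred, sd-1 per character) matrix of per-strain means,
significant characters only.  Agglomeration is UPGMA / average linkage:
at each step the pair of clusters with the smallest size-weighted average
distance merges, at height distance/2, giving an ultrametric dendrogram.

Cluster support is assessed by multiscale bootstrap resampling: the
characters (columns) are resampled with replacement at a range of sample
sizes r·m, the dendrogram is rebuilt each time, and the per-scale
bootstrap probabilities BP_r of each observed cluster are combined by
fitting  Φ⁻¹(1 − BP_r) = v·√r + c/√r  by weighted least squares.  The
approximately unbiased p-value of a cluster is AU = 1 − Φ(v − c); BP is
the plain bootstrap probability at r = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .charstats import DivergenceTest, StrainProfile
from .coding import scale_columns, strain_mean_frame
from .data_io import Tree, TreeNode, ValidationError

__all__ = [
    "DistanceMatrix",
    "SupportedDendrogram",
    "scaled_mean_matrix",
    "euclidean_distances",
    "upgma",
    "cophenetic",
    "fit_au",
    "multiscale_bootstrap",
    "DEFAULT_SCALES",
]

#: Resampling scales r used by default: 0.5, 0.6, ..., 1.4.
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValidationError("distances must be non-negative")


def scaled_mean_matrix(profiles: Mapping[str, StrainProfile],
                       tests: Sequence[DivergenceTest]) -> pd.DataFrame:
    """Strains × significant characters, each column centred and sd-1 scaled.

    Constant columns carry no distance information and are dropped with a
    warning (they cannot be standardised).
    """
    means = strain_mean_frame(profiles, tests)
    if means.empty:
        raise ValidationError("no significant characters to cluster on")
    scaled, constant = scale_columns(means, drop_constant=True)
    if constant:
        import warnings

        warnings.warn(f"dropped constant character column(s): {constant}")
    return scaled


def euclidean_distances(matrix: pd.DataFrame | np.ndarray,
                        taxa: Optional[Sequence[str]] = None) -> DistanceMatrix:
    """Pairwise Euclidean distances between strain rows."""
    if isinstance(matrix, pd.DataFrame):
        taxa = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        taxa = list(taxa) if taxa is not None else [str(i) for i in range(len(X))]
    if np.isnan(X).any():
        raise ValidationError("distance input must have no missing entries")
    return DistanceMatrix(taxa=taxa, d=squareform(pdist(X, metric="euclidean")))


def upgma(dist: DistanceMatrix) -> Tree:
    """Average-linkage (UPGMA) dendrogram with merge heights = distance/2.

    Ties are broken deterministically: among equally close pairs the one
    with the lexicographically smallest (sorted) member-label pair wins.
    """
    n = len(dist.taxa)
    if n < 2:
        raise ValidationError("UPGMA needs ≥2 taxa")
    # active clusters: key -> (sorted member tuple, size, node)
    clusters: dict[int, tuple[tuple[str, ...], int, TreeNode]] = {
        i: ((t,), 1, TreeNode(label=t, height=0.0)) for i, t in enumerate(dist.taxa)
    }
    d = {(min(i, j), max(i, j)): dist.d[i, j]
         for i in range(n) for j in range(i + 1, n)}
    next_key = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a_i, a in enumerate(keys):
            for b in keys[a_i + 1:]:
                cand = (d[(a, b)], min(clusters[a][0][0], clusters[b][0][0]),
                        max(clusters[a][0][0], clusters[b][0][0]), a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        dmin, _, _, a, b = best
        ma, sa, na = clusters[a]
        mb, sb, nb = clusters[b]
        node = TreeNode(children=[na, nb], height=dmin / 2.0)
        merged = tuple(sorted(ma + mb))
        del clusters[a], clusters[b]
        for k in clusters:
            key_a = (min(a, k), max(a, k))
            key_b = (min(b, k), max(b, k))
            d[(min(next_key, k), max(next_key, k))] = (
                sa * d[key_a] + sb * d[key_b]
            ) / (sa + sb)
        clusters[next_key] = (merged, sa + sb, node)
        next_key += 1
    (_, _, root), = clusters.values()
    return Tree(root, rooted=True)


def cophenetic(tree: Tree) -> DistanceMatrix:
    """Cophenetic distances implied by a dendrogram (2 × merge height)."""
    taxa = tree.leaf_labels()
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    d = np.zeros((n, n))

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        groups = [walk(c) for c in node.children]
        h = node.height if node.height is not None else 0.0
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for u in groups[gi]:
                    for v in groups[gj]:
                        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 2.0 * h
        return [t for g in groups for t in g]

    walk(tree.root)
    return DistanceMatrix(taxa=taxa, d=d)


# ---------------------------------------------------------------------------
# multiscale bootstrap


@dataclass
class SupportedDendrogram:
    """UPGMA dendrogram plus per-cluster AU/BP support.

    ``support`` has one row per internal cluster: the member taxa
    (pipe-joined), bp (bootstrap probability at scale 1), au
    (approximately unbiased p-value), the fitted signed distance v and
    curvature c, and the number of scales used in the fit.
    """

    tree: Tree
    support: pd.DataFrame
    n_boot: int
    scales: tuple[float, ...]
    seed: int


def _cluster_sets(tree: Tree) -> list[frozenset]:
    """Internal-node leafsets below the root, largest first."""
    out = [c for c in tree.clades() if len(c) >= 2]
    return sorted(out, key=lambda s: (-len(s), sorted(s)))


def fit_au(scales: Sequence[float], bp: Sequence[float], n_boot: int
           ) -> tuple[float, float, float, int]:
    """Fit the multiscale model and return (v, c, au, n_scales_used).

    ψ_r = Φ⁻¹(1 − BP_r) is regressed on (√r, 1/√r) by weighted least
    squares with binomial weights n·φ(ψ)²/(BP(1−BP)).  Only scales with
    0 < BP < 1 enter the fit.  Degenerate clusters short-circuit: always
    recovered → AU 1, never → AU 0; fewer than two usable scales → AU NaN.
    """
    r = np.asarray(scales, dtype=float)
    p = np.asarray(bp, dtype=float)
    if np.all(p >= 1.0):
        return np.nan, np.nan, 1.0, 0
    if np.all(p <= 0.0):
        return np.nan, np.nan, 0.0, 0
    use = (p > 0.0) & (p < 1.0)
    if use.sum() < 2:
        return np.nan, np.nan, np.nan, int(use.sum())
    r, p = r[use], p[use]
    psi = norm.ppf(1.0 - p)
    wts = n_boot * norm.pdf(psi) ** 2 / (p * (1.0 - p))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    sw = np.sqrt(wts)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], psi * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - norm.cdf(v - c))
    return v, c, au, int(use.sum())


def multiscale_bootstrap(matrix: pd.DataFrame, *, n_boot: int = 1000,
                         scales: Sequence[float] = DEFAULT_SCALES,
                         seed: int, restandardize: bool = True
                         ) -> SupportedDendrogram:
    """UPGMA with AU/BP cluster support by multiscale column resampling.

    ``matrix`` is the scaled strains × characters frame; characters are
    the resampling units.  At each scale r, ``n_boot`` resamples of
    round(r·m) columns are drawn with replacement, optionally
    re-standardised, and the dendrogram rebuilt; BP_r of a cluster is the
    fraction of resamples whose dendrogram contains it.  All randomness
    flows from ``seed`` (bit-reproducible).
    """
    X = matrix.to_numpy(dtype=float)
    taxa = [str(t) for t in matrix.index]
    n, m = X.shape
    if n < 3:
        raise ValidationError("cluster support needs ≥3 strains")
    observed = upgma(euclidean_distances(matrix))
    clusters = _cluster_sets(observed)
    rng = np.random.default_rng(seed)

    counts = np.zeros((len(clusters), len(scales)), dtype=int)
    cindex = {c: i for i, c in enumerate(clusters)}
    for si, r in enumerate(scales):
        m_r = max(int(round(r * m)), 1)
        for _ in range(n_boot):
            cols = rng.integers(0, m, size=m_r)
            Xb = X[:, cols].astype(float)
            if restandardize:
                mu = Xb.mean(axis=0)
                sd = Xb.std(axis=0, ddof=1)
                ok = sd > 0
                Xb = np.where(ok, (Xb - mu) / np.where(ok, sd, 1.0), 0.0)
            db = squareform(pdist(Xb, metric="euclidean"))
            tb = upgma(DistanceMatrix(taxa=taxa, d=db))
            for c in tb.clades():
                i = cindex.get(c)
                if i is not None:
                    counts[i, si] += 1

    rows = []
    s1 = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    for i, c in enumerate(clusters):
        bp_r = counts[i] / n_boot
        v, cc, au, used = fit_au(scales, bp_r, n_boot)
        rows.append({
            "cluster": "|".join(sorted(c)),
            "bp": float(bp_r[s1]),
            "au": au, "v": v, "c": cc, "n_scales": used,
        })
    support = pd.DataFrame(rows, columns=["cluster", "bp", "au", "v", "c", "n_scales"])
    return SupportedDendrogram(tree=observed, support=support, n_boot=n_boot,
                               scales=tuple(scales), seed=seed)
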