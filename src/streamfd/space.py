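"""Functional trait space: Gower dissimilarity, PCoA embedding, quality.

The trait space is built once per dataset: a Gower dissimilarity between
taxa computed block-wise over fuzzy trait groups, embedded by principal
coordinate analysis (classical metric MDS).  Because the block-Manhattan
Gower matrix is generally non-Euclidean, a correction (square-root
transform by default, Cailliez optionally) is applied before the
eigendecomposition.  The number of functional axes retained for hull-based
metrics is chosen by the mean squared deviation (mSD) between the original
Gower distances and the distances re-measured in the first *m* axes, both
rescaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde

from .traits import TraitTable, TraitDataError

__all__ = [
    "FunctionalSpace",
    "gower_distance",
    "pcoa_embedding",
    "dimension_quality",
    "choose_dimensionality",
    "trait_density",
    "build_space",
]

_EIG_TOL = 1e-9


def gower_distance(traits: TraitTable) -> pd.DataFrame:
    """Gower dissimilarity between taxa from a normalized fuzzy trait table.

    Per trait group g the block distance is half the Manhattan distance
    between the taxa's relative-frequency profiles,
    ``d_g(i,j) = 1/2 * sum_k |p_ik - p_jk|``, which lies in [0, 1] because
    each profile sums to one.  The overall distance is the unweighted mean
    over groups (all groups weighted equally).
    """
    if not traits.normalized:
        raise TraitDataError("gower_distance requires a normalized trait table")
    if traits.missing is not None and traits.missing.to_numpy().any():
        bad = traits.missing.index[traits.missing.any(axis=1)].tolist()
        raise TraitDataError(f"taxa with missing trait groups: {bad[:5]}...")
    groups = traits.groups
    n = len(traits.taxa)
    acc = np.zeros((n, n))
    for g in groups:
        block = traits.group_block(g).to_numpy(dtype=float)
        acc += 0.5 * squareform(pdist(block, metric="cityblock"))
    d = acc / len(groups)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.taxa, columns=traits.taxa)


def _cailliez_constant(d: np.ndarray) -> float:
    """Additive constant making d + c (off-diagonal) Euclidean-embeddable."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    delta1 = -0.5 * j @ (d**2) @ j
    delta2 = -0.5 * j @ d @ j
    top = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    bottom = np.hstack([-np.eye(n), -4.0 * delta2])
    eigs = np.linalg.eigvals(np.vstack([top, bottom]))
    return float(max(eigs.real.max(), 0.0))


def _corrected(d: np.ndarray, correction: str) -> np.ndarray:
    if correction == "sqrt":
        return np.sqrt(d)
    if correction == "cailliez":
        c = _cailliez_constant(d)
        out = d + c
        np.fill_diagonal(out, 0.0)
        return out
    if correction == "none":
        return d.copy()
    raise ValueError(f"unknown eigenvalue correction {correction!r}")


def pcoa_embedding(
    distance: pd.DataFrame, correction: str = "none"
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Principal coordinate analysis of a distance matrix.

    Classical metric multidimensional scaling (Gower double-centering and
    eigendecomposition), delegated to scikit-bio.  Only axes with positive
    eigenvalues are retained; variance explained is each eigenvalue over the
    sum of positive eigenvalues.

    Returns (coordinates, eigenvalues, variance_explained).
    """
    d = np.asarray(distance, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    d = _corrected(d, correction)
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(d, method="eigh", number_of_dimensions=0)
    eig = res.eigvals.to_numpy()
    keep = eig > _EIG_TOL * max(eig.max(), 1.0)
    coords = res.samples.to_numpy()[:, keep]
    eig = eig[keep]
    var = eig / eig.sum() if eig.sum() > 0 else eig
    cols = [f"A{i + 1}" for i in range(coords.shape[1])]
    coords_df = pd.DataFrame(coords, index=distance.index, columns=cols)
    return coords_df, eig, var


def _scaled01(x: np.ndarray) -> np.ndarray:
    mx = x.max()
    return x / mx if mx > 0 else x


def dimension_quality(
    distance: pd.DataFrame,
    coordinates: pd.DataFrame,
    m_candidates=None,
) -> pd.Series:
    """Embedding quality (mSD) for candidate dimensionalities.

    For each m, Euclidean distances in the first m axes and the original
    Gower distances are each rescaled to [0, 1] by their maxima, and the
    quality is the mean over taxon pairs of the squared deviation.  Lower
    is better; a perfect m-dimensional embedding gives 0.
    """
    max_m = coordinates.shape[1]
    if m_candidates is None:
        m_candidates = range(1, max_m + 1)
    m_candidates = list(m_candidates)
    if any(m < 1 or m > max_m for m in m_candidates):
        raise ValueError(f"m candidates must lie in [1, {max_m}]")
    d_obs = _scaled01(squareform(np.asarray(distance, dtype=float), checks=False))
    x = coordinates.to_numpy()
    out = {}
    for m in m_candidates:
        d_emb = _scaled01(pdist(x[:, :m]))
        out[m] = float(np.mean((d_obs - d_emb) ** 2))
    return pd.Series(out, name="mSD").rename_axis("m")


def choose_dimensionality(quality: pd.Series, cap: int | None = None) -> int:
    """Dimensionality minimizing mSD, optionally capped; ties to smaller m."""
    q = quality if cap is None else quality[quality.index <= cap]
    if q.empty:
        raise ValueError("no candidate dimensionality under the cap")
    return int(q.index[np.argmin(q.to_numpy())])


def trait_density(
    coordinates: pd.DataFrame,
    weights=None,
    gridsize: int = 128,
    pad_bw: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-kernel density of trait combinations on the first two axes.

    Diagnostic surface describing how densely taxa (optionally abundance
    weighted) occupy the plane of the two leading functional axes.
    Bandwidth by Scott's rule; the evaluation grid extends ``pad_bw``
    bandwidths beyond the data range so the grid integral is ~1.

    Returns (x grid, y grid, density) with density of shape
    (gridsize, gridsize), rows indexing y.
    """
    pts = coordinates.to_numpy()[:, :2]
    if pts.shape[0] < 3 or np.unique(pts, axis=0).shape[0] < 3:
        raise ValueError("trait density needs at least 3 distinct points")
    w = None if weights is None else np.asarray(weights, dtype=float)
    kde = gaussian_kde(pts.T, bw_method="scott", weights=w)
    sd = np.sqrt(np.diag(kde.covariance))
    lo = pts.min(axis=0) - pad_bw * sd
    hi = pts.max(axis=0) + pad_bw * sd
    gx = np.linspace(lo[0], hi[0], gridsize)
    gy = np.linspace(lo[1], hi[1], gridsize)
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(gridsize, gridsize)
    return gx, gy, dens


@dataclass
class FunctionalSpace:
    """Gower distances plus their PCoA embedding and quality diagnostics.

    ``distance`` is the raw Gower matrix (used for Rao's Q), ``corrected``
    the matrix actually embedded; full-dimensional Euclidean distances among
    ``coordinates`` reproduce ``corrected``.  ``m_alpha``/``m_beta`` are the
    dimensionalities selected for hull-based alpha metrics and for the beta
    overlap space.
    """

    distance: pd.DataFrame
    corrected: pd.DataFrame
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    quality: pd.Series
    m_alpha: int
    m_beta: int
    correction: str

    @property
    def taxa(self) -> pd.Index:
        return self.distance.index

    def taxon_positions(self, taxa) -> np.ndarray:
        return self.distance.index.get_indexer(taxa)


def build_space(
    traits: TraitTable,
    correction: str = "sqrt",
    m_cap_alpha: int = 3,
    m_cap_beta: int = 3,
    max_quality_m: int = 10,
) -> FunctionalSpace:
    """Construct the functional space for a normalized trait table."""
    dist = gower_distance(traits)
    coords, eig, var = pcoa_embedding(dist, correction=correction)
    m_hi = min(max_quality_m, coords.shape[1])
    quality = dimension_quality(dist, coords, range(1, m_hi + 1))
    corrected = pd.DataFrame(
        squareform(pdist(coords.to_numpy())), index=dist.index, columns=dist.columns
    )
    return FunctionalSpace(
        distance=dist,
        corrected=corrected,
        coordinates=coords,
        eigenvalues=eig,
        variance_explained=var,
        quality=quality,
        m_alpha=choose_dimensionality(quality, cap=m_cap_alpha),
        m_beta=choose_dimensionality(quality, cap=m_cap_beta),
        correction=correction,
    )
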