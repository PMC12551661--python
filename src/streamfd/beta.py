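"""Functional beta diversity via convex-hull overlap, with decomposition.

The functional beta diversity of a site pair compares the trait-space
volumes occupied by the two communities in a low-dimensional (default 3D)
functional space.  With hull volumes V_a, V_b and intersection volume
V_shared, the unique parts are B = V_a - V_shared and C = V_b - V_shared
and the Jaccard-family decomposition is

    beta_total = (B + C) / (V_shared + B + C)
    beta_turn  = 2 min(B, C) / (V_shared + 2 min(B, C))
    beta_nest  = beta_total - beta_turn

Turnover measures replacement of functional strategies; the
nestedness-resultant component measures the degree to which one
community's strategies are a volume subset of the other's.

The intersection volume is computed exactly by combining the half-space
representations of both hulls, locating an interior point by linear
programming (Chebyshev center) and handing the joint half-space system to
Qhull.  A Monte-Carlo rejection estimate is used as a fallback when the
exact route fails numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .alpha import CommunityMatrix, DOWNSTREAM, UPSTREAM
from .space import FunctionalSpace

__all__ = [
    "hull_intersection_volume",
    "beta_decompose",
    "pair_beta_at",
    "compute_beta",
    "BetaResult",
]

_VOL_TOL = 1e-9


def _chebyshev_center(halfspaces: np.ndarray):
    """Center and radius of the largest ball inside Ax + b <= 0."""
    a, b = halfspaces[:, :-1], halfspaces[:, -1]
    norms = np.linalg.norm(a, axis=1)
    ndim = a.shape[1]
    res = linprog(
        c=np.r_[np.zeros(ndim), -1.0],
        A_ub=np.hstack([a, norms[:, None]]),
        b_ub=-b,
        bounds=[(None, None)] * ndim + [(0, None)],
        method="highs",
    )
    if not res.success:
        return None, 0.0
    return res.x[:-1], float(res.x[-1])


def _interior_from_vertices(hull_a, hull_b, halfspaces):
    """Cheap strict interior point of the intersection, if one is obvious.

    The mean of all hull vertices lying inside the *other* hull is interior
    whenever the hulls genuinely overlap; checking it against the joint
    half-space system avoids a linear program in the common case.
    """
    pts = np.vstack(
        [hull_a.points[hull_a.vertices], hull_b.points[hull_b.vertices]]
    )
    a, b = halfspaces[:, :-1], halfspaces[:, -1]
    inside = (pts @ a.T + b <= 0).all(axis=1)
    if not inside.any():
        return None
    center = pts[inside].mean(axis=0)
    margin = (center @ a.T + b).max()
    return center if margin < -1e-10 else None


def _mc_intersection(hull_a: ConvexHull, hull_b: ConvexHull, rng, n_samples: int):
    """Rejection-sampling estimate of the intersection volume and its SE."""
    lo = np.maximum(hull_a.min_bound, hull_b.min_bound)
    hi = np.minimum(hull_a.max_bound, hull_b.max_bound)
    if (hi <= lo).any():
        return 0.0, 0.0
    box_vol = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_samples, len(lo)))
    inside = np.ones(n_samples, dtype=bool)
    for hull in (hull_a, hull_b):
        a, b = hull.equations[:, :-1], hull.equations[:, -1]
        inside &= (pts @ a.T + b <= 1e-12).all(axis=1)
    frac = inside.mean()
    se = box_vol * np.sqrt(frac * (1 - frac) / n_samples)
    return box_vol * frac, float(se)


def hull_intersection_volume(
    points_a: np.ndarray,
    points_b: np.ndarray,
    rng=None,
    mc_samples: int = 100_000,
) -> tuple[float, float, float, bool]:
    """Volumes of two convex hulls and of their intersection.

    Returns ``(V_a, V_b, V_shared, mc_fallback)``.  NaNs when either point
    set is degenerate (fewer than d+1 affinely independent points).  The
    exact route intersects the hulls' half-space systems; ``mc_fallback``
    marks pairs where a Monte-Carlo estimate had to be used instead.
    """
    try:
        hull_a = ConvexHull(np.asarray(points_a, dtype=float))
        hull_b = ConvexHull(np.asarray(points_b, dtype=float))
    except QhullError:
        return float("nan"), float("nan"), float("nan"), False
    halfspaces = np.vstack([hull_a.equations, hull_b.equations])
    center = _interior_from_vertices(hull_a, hull_b, halfspaces)
    if center is None:
        # No cheap interior point; fall back to the Chebyshev-center LP.
        center, radius = _chebyshev_center(halfspaces)
        if center is None or radius <= _VOL_TOL:
            # Empty interior: disjoint or touching on a measure-zero set.
            return hull_a.volume, hull_b.volume, 0.0, False
    try:
        hsi = HalfspaceIntersection(halfspaces, center)
        v_shared = ConvexHull(hsi.intersections).volume
    except QhullError:
        rng = np.random.default_rng(0) if rng is None else rng
        v_shared, _se = _mc_intersection(hull_a, hull_b, rng, mc_samples)
        return hull_a.volume, hull_b.volume, float(v_shared), True
    v_shared = min(v_shared, hull_a.volume, hull_b.volume)
    return hull_a.volume, hull_b.volume, float(v_shared), False


def beta_decompose(
    v_a: float, v_b: float, v_shared: float, family: str = "jaccard"
) -> tuple[float, float, float]:
    """Decompose hull overlap into total, turnover and nestedness components.

    Jaccard family by default; ``family='sorensen'`` uses the Sorensen
    analogue (2a denominator, Simpson turnover).  Identical hulls give
    (0, 0, 0); disjoint hulls (1, 1, 0); strictly nested hulls have zero
    turnover.  Undefined (NaN) when all volumes are zero.
    """
    if not (v_shared <= min(v_a, v_b) + 1e-6 * max(v_a, v_b, 1.0)):
        raise ValueError("V_shared exceeds a hull volume")
    b = max(v_a - v_shared, 0.0)
    c = max(v_b - v_shared, 0.0)
    if v_shared + b + c <= 0:
        return float("nan"), float("nan"), float("nan")
    mn = min(b, c)
    if family == "jaccard":
        total = (b + c) / (v_shared + b + c)
        turn = 2 * mn / (v_shared + 2 * mn) if (v_shared + 2 * mn) > 0 else 0.0
    elif family == "sorensen":
        total = (b + c) / (2 * v_shared + b + c)
        turn = mn / (v_shared + mn) if (v_shared + mn) > 0 else 0.0
    else:
        raise ValueError(f"unknown beta family {family!r}")
    return float(total), float(turn), float(total - turn)


def pair_beta_at(
    idx_up: np.ndarray,
    idx_down: np.ndarray,
    coords_m: np.ndarray,
    family: str = "jaccard",
    rng=None,
) -> dict[str, float]:
    """Beta components for one pair given taxon positions in the beta space."""
    m = coords_m.shape[1]
    if len(idx_up) <= m or len(idx_down) <= m:
        return _undefined_beta()
    v_a, v_b, v_sh, fallback = hull_intersection_volume(
        coords_m[idx_up], coords_m[idx_down], rng=rng
    )
    if np.isnan(v_a) or np.isnan(v_b):
        return _undefined_beta()
    total, turn, nest = beta_decompose(v_a, v_b, v_sh, family=family)
    return {
        "v_up": v_a,
        "v_down": v_b,
        "v_shared": v_sh,
        "beta_total": total,
        "beta_turn": turn,
        "beta_nest": nest,
        "mc_fallback": float(fallback),
    }


def _undefined_beta() -> dict[str, float]:
    nan = float("nan")
    return {
        "v_up": nan,
        "v_down": nan,
        "v_shared": nan,
        "beta_total": nan,
        "beta_turn": nan,
        "beta_nest": nan,
        "mc_fallback": 0.0,
    }


@dataclass
class BetaResult:
    """Per-pair hull volumes and beta components (NaN rows = undefined)."""

    table: pd.DataFrame
    family: str
    m: int


def compute_beta(
    communities: CommunityMatrix,
    space: FunctionalSpace,
    pairs: pd.DataFrame,
    m: int | None = None,
    family: str = "jaccard",
    rng=None,
) -> BetaResult:
    """Beta decomposition for every site pair.

    ``pairs`` must carry ``upstream``/``downstream`` site-id columns indexed
    by pair id.  Pairs where either community has too few taxa to span an
    m-dimensional hull are reported with NaN components and flagged, not
    padded.
    """
    m = space.m_beta if m is None else m
    coords_m = space.coordinates.to_numpy()[:, :m]
    site_idx = communities.site_indices(space.taxa)
    rows = []
    for pair_id, row in pairs.iterrows():
        up, down = site_idx[row[UPSTREAM]][0], site_idx[row[DOWNSTREAM]][0]
        rows.append(pd.Series(pair_beta_at(up, down, coords_m, family, rng), name=pair_id))
    table = pd.DataFrame(rows).rename_axis("pair_id")
    table["undefined"] = table["beta_total"].isna()
    return BetaResult(table=table, family=family, m=m)
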