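"""Per-community functional alpha diversity metrics.

Implements the standard abundance-weighted metric set for a community of S
taxa with relative abundances p_i located in a functional trait space:

* CWM  — community-weighted mean trait profile, ``CWM_k = sum_i p_i t_ik``;
* FRic — functional richness, the convex-hull volume of the community in
  the first m functional axes (optionally standardized by the pool hull);
* FEve — functional evenness from the minimum spanning tree of the
  community in the full space, abundance weighted;
* FDis — functional dispersion, abundance-weighted mean distance to the
  abundance-weighted centroid in the full space;
* Rao's quadratic entropy Q on the raw Gower distances, Simpson diversity
  D = 1 - sum p_i^2, and functional redundancy FR = Q / D.

Metrics that are undefined for a community (e.g. FRic with S <= m taxa,
FEve with S < 3) are returned as NaN and flagged, never coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .space import FunctionalSpace
from .traits import TraitTable

__all__ = [
    "CommunityMatrix",
    "cwm",
    "fric",
    "feve",
    "fdis",
    "rao_simpson_redundancy",
    "alpha_metrics_at",
    "compute_alpha",
    "ALPHA_METRICS",
]

ALPHA_METRICS = ("fric", "feve", "fdis", "rao_q", "simpson", "redundancy")

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"


@dataclass
class CommunityMatrix:
    """Site x taxon abundances with site metadata and EPT flags.

    ``abundance`` rows are sites, columns taxa (counts, >= 0).  ``sites`` is
    indexed by site id with at least ``pair_id`` and ``position``
    (upstream/downstream) columns.  ``ept_flags`` is a per-taxon boolean.
    """

    abundance: pd.DataFrame
    sites: pd.DataFrame
    ept_flags: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("negative abundances")
        if not self.abundance.index.equals(self.sites.index):
            self.sites = self.sites.loc[self.abundance.index]

    @property
    def taxa(self) -> pd.Index:
        return self.abundance.columns

    def relative(self) -> pd.DataFrame:
        tot = self.abundance.sum(axis=1)
        if (tot <= 0).any():
            empty = tot.index[tot <= 0].tolist()
            raise ValueError(f"empty communities: {empty}")
        return self.abundance.div(tot, axis=0)

    def site_indices(self, space_taxa: pd.Index):
        """Per site: (positions of present taxa in space order, rel. abundances)."""
        pos_of = {t: i for i, t in enumerate(space_taxa)}
        cols = self.abundance.columns
        out = {}
        rel = self.relative().to_numpy()
        arr = self.abundance.to_numpy()
        for si, site in enumerate(self.abundance.index):
            nz = np.flatnonzero(arr[si] > 0)
            idx = np.array([pos_of[cols[j]] for j in nz], dtype=int)
            out[site] = (idx, rel[si, nz])
        return out

    def subset_pairs(self, pair_ids) -> "CommunityMatrix":
        keep = self.sites["pair_id"].isin(list(pair_ids))
        ab = self.abundance.loc[keep]
        ab = ab.loc[:, ab.sum(axis=0) > 0]
        return CommunityMatrix(
            abundance=ab,
            sites=self.sites.loc[keep],
            ept_flags=None if self.ept_flags is None else self.ept_flags[ab.columns],
        )


def cwm(community: pd.Series, traits: TraitTable) -> pd.Series:
    """Community-weighted mean trait profile over all modalities.

    ``CWM_k = sum_i p_i t_ik`` with p the relative abundances.  Because each
    taxon's profile sums to one within every trait group, so does the CWM.
    """
    present = community[community > 0]
    missing = present.index.difference(traits.taxa)
    if len(missing):
        raise ValueError(f"taxa without trait profiles: {list(missing)[:5]}")
    p = present / present.sum()
    t = traits.affinities.loc[present.index].to_numpy()
    return pd.Series(p.to_numpy() @ t, index=traits.affinities.columns, name="cwm")


def fric(points: np.ndarray, standardize_volume: float | None = None) -> float:
    """Convex-hull volume of the community in the first m functional axes.

    NaN when the point set has too few points (S <= m) or is degenerate
    (affinely dependent), since a flat hull has no m-volume.  When
    ``standardize_volume`` (the taxon-pool hull volume) is given, the result
    is the occupied fraction of the pool's functional volume, in (0, 1].
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] <= pts.shape[1]:
        return float("nan")
    try:
        vol = ConvexHull(pts).volume
    except QhullError:
        return float("nan")
    if standardize_volume is not None:
        if standardize_volume <= 0:
            return float("nan")
        vol /= standardize_volume
    return float(vol)


def _mst_edges(dist_sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MST edge index pairs on a dense distance matrix (Prim's algorithm).

    Dense Prim is O(S^2), faster than sparse-graph routines at community
    sizes, and keeps exact-zero distances (functionally identical taxa) as
    ordinary edges.  Ties are broken by the smallest vertex index, i.e.
    lexicographic taxon order, for determinism.
    """
    d = np.asarray(dist_sub, dtype=float)
    s = d.shape[0]
    in_tree = np.zeros(s, dtype=bool)
    best = d[0].copy()
    parent = np.zeros(s, dtype=np.intp)
    in_tree[0] = True
    best[0] = np.inf
    ii = np.empty(s - 1, dtype=np.intp)
    jj = np.empty(s - 1, dtype=np.intp)
    for k in range(s - 1):
        v = int(np.argmin(best))
        ii[k], jj[k] = parent[v], v
        in_tree[v] = True
        best[v] = np.inf
        upd = d[v]
        closer = ~in_tree & (upd < best)
        best[closer] = upd[closer]
        parent[closer] = v
    return ii, jj


def feve(dist_sub: np.ndarray, p: np.ndarray) -> float:
    """Functional evenness from the minimum spanning tree.

    MST branches l = (i, j) are weighted EW_l = d_ij / (p_i + p_j), the
    partial weights PEW_l = EW_l / sum EW compared against the perfectly
    even value 1/(S-1):

        FEve = [sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)] / [1 - 1/(S-1)]

    1 for perfectly regular spacing and abundances; undefined (NaN) for
    S < 3.
    """
    s = len(p)
    if s < 3:
        return float("nan")
    ii, jj = _mst_edges(np.asarray(dist_sub, dtype=float))
    ew = dist_sub[ii, jj] / (p[ii] + p[jj])
    tot = ew.sum()
    if tot <= 0:
        return float("nan")
    pew = ew / tot
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def fdis(coords: np.ndarray, p: np.ndarray) -> float:
    """Abundance-weighted mean distance to the weighted centroid."""
    x = np.asarray(coords, dtype=float)
    c = p @ x
    return float(p @ np.linalg.norm(x - c, axis=1))


def rao_simpson_redundancy(
    dist_sub: np.ndarray, p: np.ndarray
) -> tuple[float, float, float]:
    """Rao's quadratic entropy, Simpson diversity, functional redundancy.

    ``Q = sum_ij d_ij p_i p_j`` on the raw Gower distances, Simpson
    ``D = 1 - sum p_i^2`` and ``FR = Q / D`` (the expected trait distance
    between two individuals from different taxa).  FR is undefined for
    monocultures (D = 0).
    """
    q = float(p @ np.asarray(dist_sub, dtype=float) @ p)
    simpson = float(1.0 - (p**2).sum())
    fr = q / simpson if simpson > 0 else float("nan")
    return q, simpson, fr


def alpha_metrics_at(
    idx: np.ndarray,
    p: np.ndarray,
    coords: np.ndarray,
    d_gower: np.ndarray,
    d_corr: np.ndarray,
    m: int,
    pool_volume: float | None = None,
    which=ALPHA_METRICS,
) -> dict[str, float]:
    """All alpha metrics for a community given by taxon positions ``idx``.

    Fast array path shared by observed and null computations: the null
    model only permutes ``idx`` through the pool, reusing the same
    coordinate and distance matrices.
    """
    out: dict[str, float] = {}
    if "fric" in which:
        out["fric"] = fric(coords[idx, :m], standardize_volume=pool_volume)
    if "feve" in which:
        out["feve"] = feve(d_corr[np.ix_(idx, idx)], p)
    if "fdis" in which:
        out["fdis"] = fdis(coords[idx], p)
    if {"rao_q", "simpson", "redundancy"} & set(which):
        q, simpson, fr = rao_simpson_redundancy(d_gower[np.ix_(idx, idx)], p)
        out.update({"rao_q": q, "simpson": simpson, "redundancy": fr})
    return out


def compute_alpha(
    communities: CommunityMatrix,
    space: FunctionalSpace,
    traits: TraitTable,
    m: int | None = None,
    standardize_fric: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alpha metrics and CWM profiles for every site.

    Returns ``(alpha, cwms)``: one row per site with the metric columns and
    species richness S, and the site x modality CWM table.  FRic uses the
    first ``m`` axes (default: the space's selected alpha dimensionality),
    standardized by the pool hull volume when ``standardize_fric``.
    """
    m = space.m_alpha if m is None else m
    coords = space.coordinates.to_numpy()
    d_gower = space.distance.to_numpy()
    d_corr = space.corrected.to_numpy()
    pool_vol = None
    if standardize_fric:
        pool_vol = fric(coords[:, :m])
    site_idx = communities.site_indices(space.taxa)
    rows, cwms = [], []
    trait_sub = traits.affinities.loc[space.taxa].to_numpy()
    for site, (idx, p) in site_idx.items():
        met = alpha_metrics_at(idx, p, coords, d_gower, d_corr, m, pool_vol)
        met["richness"] = len(idx)
        rows.append(pd.Series(met, name=site))
        cwms.append(p @ trait_sub[idx])
    alpha = pd.DataFrame(rows).rename_axis("site")
    cwm_df = pd.DataFrame(
        np.asarray(cwms),
        index=alpha.index,
        columns=traits.affinities.columns,
    ).rename_axis("site")
    return alpha, cwm_df
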