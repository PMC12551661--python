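"""Trait-shuffling null models, standardized effect sizes, significance.

Functional diversity is constrained by taxonomic richness, so observed
metric values are compared against a null distribution obtained by
shuffling taxon identities on the trait matrix: community membership and
abundances stay fixed, only the functional categorization of taxa changes.
Labels are shuffled over the *total* taxon pool (not per community), each
randomization using an independent permutation; the default ensemble size
is R = 999.

For each site (alpha metrics) or site pair (beta components) the
standardized effect size is SES = (obs - mean(null)) / sd(null) and the
two-tailed Monte-Carlo p-value uses the add-one rank convention

    p = 2 * min(#{null >= obs} + 1, #{null <= obs} + 1) / (R + 1)

capped at 1, so p is never exactly zero.  Degenerate nulls (sd = 0) leave
the SES undefined and are excluded from significance counts.

Because a shuffle is a pure relabelling, null metrics are computed by
permuting each community's taxon positions through the pool — the Gower
matrix and PCoA coordinates are computed once and reused, which keeps a
999-randomization run tractable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alpha import ALPHA_METRICS, CommunityMatrix, alpha_metrics_at, fric
from .beta import pair_beta_at
from .space import FunctionalSpace
from .traits import TraitTable

__all__ = [
    "shuffle_traits",
    "trait_permutations",
    "ses_and_test",
    "summarize_ensembles",
    "significant_fraction",
    "alpha_null_ensembles",
    "beta_null_ensembles",
]

BETA_COMPONENTS = ("beta_total", "beta_turn", "beta_nest")


def shuffle_traits(traits: TraitTable, rng: np.random.Generator) -> TraitTable:
    """One null trait table: taxon labels permuted over the full pool.

    Row *contents* are reassigned among taxa; the multiset of trait
    profiles is unchanged, as is everything community-side.
    """
    perm = rng.permutation(len(traits.taxa))
    aff = pd.DataFrame(
        traits.affinities.to_numpy()[perm],
        index=traits.taxa,
        columns=traits.affinities.columns,
    )
    lev = pd.Series(
        traits.coding_level.to_numpy()[perm], index=traits.taxa, name="coding_level"
    )
    miss = None
    if traits.missing is not None:
        miss = pd.DataFrame(
            traits.missing.to_numpy()[perm],
            index=traits.taxa,
            columns=traits.missing.columns,
        )
    return TraitTable(
        affinities=aff, coding_level=lev, normalized=traits.normalized, missing=miss
    )


def trait_permutations(n_taxa: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """R independent full-pool permutations, one per randomization."""
    return np.stack([rng.permutation(n_taxa) for _ in range(r)])


def ses_and_test(
    observed: float, null_values: np.ndarray, alpha: float = 0.05
) -> dict[str, float | bool]:
    """SES and two-tailed Monte-Carlo significance for one observed value."""
    nulls = np.asarray(null_values, dtype=float)
    nulls = nulls[~np.isnan(nulls)]
    r = len(nulls)
    out = {
        "null_mean": float("nan"),
        "null_sd": float("nan"),
        "ses": float("nan"),
        "p": float("nan"),
        "significant": False,
        "undefined": True,
    }
    if np.isnan(observed) or r < 2:
        return out
    mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    out["null_mean"], out["null_sd"] = mean, sd
    if sd == 0.0:
        return out
    out["ses"] = (observed - mean) / sd
    ge = int((nulls >= observed).sum())
    le = int((nulls <= observed).sum())
    out["p"] = min(1.0, 2.0 * (min(ge, le) + 1) / (r + 1))
    out["significant"] = out["p"] <= alpha
    out["undefined"] = False
    return out


def summarize_ensembles(
    observed: pd.DataFrame, nulls: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Tidy per-unit, per-metric summary of null ensembles.

    ``observed`` is unit x metric; ``nulls`` has shape (R, units, metrics)
    aligned with it.
    """
    rows = []
    for ui, unit in enumerate(observed.index):
        for mi, metric in enumerate(observed.columns):
            rec = {"unit": unit, "metric": metric, "observed": observed.iat[ui, mi]}
            rec.update(ses_and_test(observed.iat[ui, mi], nulls[:, ui, mi], alpha))
            rows.append(rec)
    return pd.DataFrame(rows)


def significant_fraction(
    summary: pd.DataFrame, exclude_undefined: bool = True
) -> pd.DataFrame:
    """Per-metric count and proportion of units with significant SES."""
    if summary.empty:
        raise ValueError("no ensembles to summarize")
    out = []
    for metric, grp in summary.groupby("metric", sort=False):
        denom = grp.loc[~grp["undefined"]] if exclude_undefined else grp
        n = len(denom)
        k = int(denom["significant"].sum())
        out.append(
            {
                "metric": metric,
                "n_significant": k,
                "n_units": n,
                "proportion": k / n if n else float("nan"),
            }
        )
    return pd.DataFrame(out)


def _null_chunk_alpha(perms, site_items, coords, d_gower, d_corr, m, pool_vols, which):
    out = np.empty((len(perms), len(site_items), len(which)))
    for ri, perm in enumerate(perms):
        for si, (idx, p) in enumerate(site_items):
            met = alpha_metrics_at(
                perm[idx], p, coords, d_gower, d_corr, m, pool_vols, which=which
            )
            out[ri, si] = [met[k] for k in which]
    return out


def alpha_null_ensembles(
    communities: CommunityMatrix,
    space: FunctionalSpace,
    permutations: np.ndarray,
    metrics=ALPHA_METRICS,
    m: int | None = None,
    standardize_fric: bool = True,
    alpha: float = 0.05,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Null ensembles and SES for alpha metrics at every site.

    Note the pool hull volume used to standardize FRic is invariant under
    label shuffling, so the same constant serves observed and null values.
    """
    m = space.m_alpha if m is None else m
    metrics = tuple(metrics)
    coords = space.coordinates.to_numpy()
    d_gower = space.distance.to_numpy()
    d_corr = space.corrected.to_numpy()
    pool_vol = fric(coords[:, :m]) if standardize_fric else None
    site_idx = communities.site_indices(space.taxa)
    sites = list(site_idx)
    items = [site_idx[s] for s in sites]

    obs = np.array(
        [
            [
                alpha_metrics_at(idx, p, coords, d_gower, d_corr, m, pool_vol, metrics)[k]
                for k in metrics
            ]
            for idx, p in items
        ]
    )
    observed = pd.DataFrame(obs, index=pd.Index(sites, name="site"), columns=metrics)

    chunks = _split(permutations, n_workers)
    args = (items, coords, d_gower, d_corr, m, pool_vol, metrics)
    if n_workers > 1:
        from joblib import Parallel, delayed

        parts = Parallel(n_jobs=n_workers)(
            delayed(_null_chunk_alpha)(c, *args) for c in chunks
        )
    else:
        parts = [_null_chunk_alpha(c, *args) for c in chunks]
    nulls = np.concatenate(parts, axis=0)
    return summarize_ensembles(observed, nulls, alpha)


def _null_chunk_beta(perms, pair_items, coords_m, family):
    out = np.empty((len(perms), len(pair_items), len(BETA_COMPONENTS)))
    for ri, perm in enumerate(perms):
        for pi, (idx_up, idx_down) in enumerate(pair_items):
            met = pair_beta_at(perm[idx_up], perm[idx_down], coords_m, family)
            out[ri, pi] = [met[k] for k in BETA_COMPONENTS]
    return out


def beta_null_ensembles(
    communities: CommunityMatrix,
    space: FunctionalSpace,
    pairs: pd.DataFrame,
    permutations: np.ndarray,
    m: int | None = None,
    family: str = "jaccard",
    alpha: float = 0.05,
    n_workers: int = 1,
) -> pd.DataFrame:
    """Null ensembles and SES for beta components at every site pair."""
    m = space.m_beta if m is None else m
    coords_m = space.coordinates.to_numpy()[:, :m]
    site_idx = communities.site_indices(space.taxa)
    pair_ids = list(pairs.index)
    items = [
        (site_idx[row["upstream"]][0], site_idx[row["downstream"]][0])
        for _, row in pairs.iterrows()
    ]
    obs = np.array(
        [
            [pair_beta_at(iu, idn, coords_m, family)[k] for k in BETA_COMPONENTS]
            for iu, idn in items
        ]
    )
    observed = pd.DataFrame(
        obs, index=pd.Index(pair_ids, name="pair_id"), columns=BETA_COMPONENTS
    )
    chunks = _split(permutations, n_workers)
    if n_workers > 1:
        from joblib import Parallel, delayed

        parts = Parallel(n_jobs=n_workers)(
            delayed(_null_chunk_beta)(c, items, coords_m, family) for c in chunks
        )
    else:
        parts = [_null_chunk_beta(c, items, coords_m, family) for c in chunks]
    nulls = np.concatenate(parts, axis=0)
    return summarize_ensembles(observed, nulls, alpha)


def _split(permutations: np.ndarray, n_workers: int) -> list[np.ndarray]:
    """Deterministic chunking: results depend only on permutation order."""
    n_workers = max(1, int(n_workers))
    if n_workers == 1 or len(permutations) <= 1:
        return [permutations]
    return [c for c in np.array_split(permutations, n_workers) if len(c)]
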