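"""Paired upstream/downstream statistics for the WWTP design.

Each wastewater treatment plant (WWTP) contributes one site pair; the unit
of inference is the pair.  Trait shifts are summarized as delta CWM =
upstream CWM - downstream CWM per trait modality and tested against zero
with one-sample Wilcoxon signed-rank tests; alpha metrics and their SES
values are compared between positions with paired Wilcoxon tests; beta SES
values are correlated with effluent covariates (connected households,
population equivalents, and log-transformed BOD, ammonium and total
phosphorus) by Spearman rank correlation.  A subset analysis keeps only
pairs whose *upstream* community has at least 50% EPT individuals and
re-runs the whole pipeline — including functional-space reconstruction —
on that subset.

Wilcoxon convention: zeros handled by the Pratt method, exact distribution
for n <= 25 without ties, normal approximation with continuity correction
otherwise.  P-values across the 49 trait modalities are reported
uncorrected (a Benjamini-Hochberg option exists but is off by default).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, wilcoxon

from .alpha import DOWNSTREAM, UPSTREAM, CommunityMatrix
from .traits import ept_proportion

__all__ = [
    "wilcoxon_signed_rank",
    "delta_cwm",
    "delta_cwm_tests",
    "paired_tests",
    "covariate_correlations",
    "upstream_ept_shares",
    "ept_subset",
]

LOG_COVARIATES = ("bod", "nh4", "total_p")
LINEAR_COVARIATES = ("households", "population_equivalents")


def wilcoxon_signed_rank(values: np.ndarray, exact_max_n: int = 25):
    """One-sample Wilcoxon signed-rank test against zero.

    Pratt zero handling; exact null distribution for small samples without
    ties, normal approximation with continuity correction otherwise.
    All-zero samples return (nan, 1.0) by convention — no evidence of a
    shift.  Returns ``(statistic, p, n_nonzero)``.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n_nonzero = int((v != 0).sum())
    if len(v) == 0 or n_nonzero == 0:
        return float("nan"), 1.0, n_nonzero
    method = "exact" if len(v) <= exact_max_n else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = wilcoxon(
            v, zero_method="pratt", correction=True, method=method,
            alternative="two-sided",
        )
    return float(res.statistic), float(res.pvalue), n_nonzero


def delta_cwm(cwm_df: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-pair trait shift: upstream CWM minus downstream CWM.

    Positive values mean the modality is better represented upstream.
    Within each trait group the deltas of one pair sum to zero, because
    both CWMs allocate a unit budget per group.
    """
    up = cwm_df.loc[pairs[UPSTREAM]].to_numpy()
    down = cwm_df.loc[pairs[DOWNSTREAM]].to_numpy()
    return pd.DataFrame(up - down, index=pairs.index, columns=cwm_df.columns)


def delta_cwm_tests(
    cwm_df: pd.DataFrame,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sample Wilcoxon test of each modality's delta CWM against zero.

    Returns ``(deltas, tests)`` where ``tests`` has one row per modality
    with the statistic, (uncorrected) p-value and significance flag;
    modalities whose deltas are all zero are flagged undefined.
    """
    deltas = delta_cwm(cwm_df, pairs)
    rows = []
    for col in deltas.columns:
        d = deltas[col].to_numpy()
        stat, p, n_nonzero = wilcoxon_signed_rank(d)
        rows.append(
            {
                "group": col[0],
                "modality": col[1],
                "median_delta": float(np.median(d)),
                "statistic": stat,
                "p": p,
                "n_nonzero": n_nonzero,
                "undefined": n_nonzero == 0,
            }
        )
    tests = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = ~tests["undefined"]
        adj = np.full(len(tests), np.nan)
        adj[ok.to_numpy()] = multipletests(tests.loc[ok, "p"], method="fdr_bh")[1]
        tests["p_adjusted"] = adj
        tests["significant"] = tests["p_adjusted"] <= alpha
    else:
        tests["significant"] = (~tests["undefined"]) & (tests["p"] <= alpha)
    return deltas, tests


def paired_tests(
    values: pd.Series | pd.DataFrame,
    pairs: pd.DataFrame,
    min_pairs: int = 3,
    on_insufficient: str = "raise",
) -> pd.DataFrame:
    """Paired Wilcoxon test (upstream vs downstream) per metric column.

    ``values`` is indexed by site id.  Pairs where either member is
    undefined (NaN) are excluded pairwise; the usable n is reported.
    A metric with fewer than ``min_pairs`` usable pairs is refused
    (``on_insufficient='raise'``) or reported with a NaN p-value
    (``'skip'``, used by the pipeline on small subsets).
    """
    df = values.to_frame() if isinstance(values, pd.Series) else values
    rows = []
    for col in df.columns:
        up = df[col].reindex(pairs[UPSTREAM]).to_numpy()
        down = df[col].reindex(pairs[DOWNSTREAM]).to_numpy()
        ok = ~(np.isnan(up) | np.isnan(down))
        n_used = int(ok.sum())
        if n_used < min_pairs:
            if on_insufficient == "raise":
                raise ValueError(
                    f"metric {col!r}: only {n_used} usable pairs (< {min_pairs})"
                )
            rows.append(
                {
                    "metric": col,
                    "n_pairs": n_used,
                    "n_excluded": int(len(up) - n_used),
                    "statistic": float("nan"),
                    "p": float("nan"),
                }
            )
            continue
        stat, p, _ = wilcoxon_signed_rank(up[ok] - down[ok])
        rows.append(
            {
                "metric": col,
                "n_pairs": n_used,
                "n_excluded": int(len(up) - n_used),
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _log_transform(x: pd.Series) -> pd.Series:
    """Natural log; zeros offset by half the minimum positive value."""
    x = x.astype(float)
    pos = x[x > 0]
    if pos.empty:
        return pd.Series(np.nan, index=x.index)
    offset = 0.5 * pos.min()
    return np.log(x.where(x > 0, other=offset))


def covariate_correlations(
    beta_ses: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of beta SES components with WWTP covariates.

    ``beta_ses`` is a pair x component table of SES values (columns such as
    beta_total/beta_turn/beta_nest).  Effluent concentrations (BOD, NH4+,
    total P) are natural-log transformed first — immaterial for the rank
    correlation itself but it keeps reported scales conventional.  Constant
    covariates give an undefined (NaN) rho, flagged.
    """
    rows = []
    covs: dict[str, pd.Series] = {}
    for c in LINEAR_COVARIATES:
        if c in pairs.columns:
            covs[c] = pairs[c].astype(float)
    for c in LOG_COVARIATES:
        if c in pairs.columns:
            covs[f"log_{c}"] = _log_transform(pairs[c])
    for comp in beta_ses.columns:
        y = beta_ses[comp].reindex(pairs.index)
        for name, x in covs.items():
            ok = ~(x.isna() | y.isna())
            if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                rho, p = float("nan"), float("nan")
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = spearmanr(x[ok], y[ok])
            rows.append(
                {
                    "component": comp,
                    "covariate": name,
                    "rho": float(rho),
                    "p": float(p),
                    "n": int(ok.sum()),
                    "undefined": bool(np.isnan(rho)),
                }
            )
    return pd.DataFrame(rows)


def upstream_ept_shares(
    communities: CommunityMatrix, pairs: pd.DataFrame
) -> pd.Series:
    """EPT individual share of the upstream community of every pair."""
    if communities.ept_flags is None:
        raise ValueError("community matrix has no EPT flags")
    shares = {}
    for pair_id, row in pairs.iterrows():
        ab = communities.abundance.loc[row[UPSTREAM]]
        shares[pair_id] = ept_proportion(ab, communities.ept_flags)
    return pd.Series(shares, name="ept_share").rename_axis("pair_id")


def ept_subset(
    communities: CommunityMatrix,
    pairs: pd.DataFrame,
    threshold: float = 0.5,
) -> tuple[CommunityMatrix, pd.DataFrame, pd.Series]:
    """Pairs whose upstream community is EPT dominated (share >= threshold).

    The threshold is inclusive: an upstream share of exactly 0.5 is
    retained under the default.  Returns the subset community matrix
    (taxa never observed in the subset dropped), the subset pair table and
    the per-pair upstream shares.  An empty subset is a valid result.
    """
    shares = upstream_ept_shares(communities, pairs)
    keep = shares[shares >= threshold].index
    sub_pairs = pairs.loc[keep]
    if len(keep) == 0:
        empty = CommunityMatrix(
            abundance=communities.abundance.iloc[0:0],
            sites=communities.sites.iloc[0:0],
            ept_flags=communities.ept_flags,
        )
        return empty, sub_pairs, shares
    return communities.subset_pairs(keep), sub_pairs, shares
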