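"""End-to-end orchestration of the paired functional-diversity analysis.

Stage order: trait gap-filling and normalization -> functional space
(Gower + PCoA + dimensionality choice) -> alpha metrics and CWMs -> beta
overlap decomposition -> trait-shuffling null models with SES -> paired
statistics and covariate correlations -> EPT-dominated subset re-run with
full space reconstruction.  Every run is reproducible byte-for-byte from
its seed; the manifest records the configuration, ensemble size and counts
at every filtering step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import CommunityMatrix, compute_alpha
from .beta import BetaResult, compute_beta
from .io import RunConfig, save_space, write_json, write_trait_table
from .nulls import (
    alpha_null_ensembles,
    beta_null_ensembles,
    significant_fraction,
    trait_permutations,
)
from .pairs import (
    covariate_correlations,
    delta_cwm_tests,
    ept_subset,
    paired_tests,
    upstream_ept_shares,
)
from .space import FunctionalSpace, build_space
from .traits import TaxonomyTable, TraitTable, apply_merge, fill_gaps

log = logging.getLogger("streamfd")

__all__ = ["AnalysisResult", "prepare", "analyse", "run_pipeline"]


@dataclass
class AnalysisResult:
    """All tables produced for one dataset (full run or EPT subset)."""

    space: FunctionalSpace
    alpha: pd.DataFrame
    cwm: pd.DataFrame
    beta: BetaResult
    alpha_ses: pd.DataFrame
    beta_ses: pd.DataFrame
    delta_cwm: pd.DataFrame
    delta_cwm_stats: pd.DataFrame
    paired_alpha: pd.DataFrame
    paired_ses: pd.DataFrame
    correlations: pd.DataFrame
    sig_fractions: pd.DataFrame


def prepare(
    traits_raw: TraitTable,
    taxonomy: TaxonomyTable,
    communities: CommunityMatrix,
):
    """Gap-fill and normalize traits; merge community columns accordingly."""
    observed = [t for t in communities.taxa if communities.abundance[t].sum() > 0]
    filled, mapping, coverage = fill_gaps(traits_raw, taxonomy, observed)
    merged_ab = apply_merge(communities.abundance, mapping)
    ept = None
    if communities.ept_flags is not None:
        # a merged taxon counts as EPT when any of its members does
        flags = {}
        for orig, final in mapping.items():
            flags[final] = flags.get(final, False) or bool(communities.ept_flags.get(orig, False))
        ept = pd.Series(flags).reindex(merged_ab.columns).fillna(False)
    merged = CommunityMatrix(abundance=merged_ab, sites=communities.sites, ept_flags=ept)
    log.info(
        "gap-filling: %d input taxa -> %d final taxa (%d dropped)",
        coverage.n_input, coverage.n_final, len(coverage.dropped),
    )
    return filled.subset(sorted(merged_ab.columns)), merged, mapping, coverage


def analyse(
    traits: TraitTable,
    communities: CommunityMatrix,
    pairs: pd.DataFrame,
    config: RunConfig,
    rng: np.random.Generator,
    m_cap_alpha: int | None = None,
) -> AnalysisResult:
    """Run space construction, metrics, null models and paired statistics."""
    cap_a = config.m_cap_alpha if m_cap_alpha is None else m_cap_alpha
    space = build_space(
        traits,
        correction=config.correction,
        m_cap_alpha=cap_a,
        m_cap_beta=config.m_cap_beta,
        max_quality_m=max(cap_a, config.m_cap_beta, 6),
    )
    alpha, cwm_df = compute_alpha(
        communities, space, traits, standardize_fric=config.standardize_fric
    )
    beta = compute_beta(
        communities, space, pairs, family=config.beta_family
    )
    perms = trait_permutations(len(space.taxa), config.randomizations, rng)
    alpha_ses = alpha_null_ensembles(
        communities,
        space,
        perms,
        standardize_fric=config.standardize_fric,
        alpha=config.alpha_level,
        n_workers=config.n_workers,
    )
    beta_ses = beta_null_ensembles(
        communities,
        space,
        pairs,
        perms,
        family=config.beta_family,
        alpha=config.alpha_level,
        n_workers=config.n_workers,
    )
    if config.redundancy_complement:
        # report FR' = 1 - Q/D; SES flips sign, p/significance unchanged
        alpha["redundancy"] = 1.0 - alpha["redundancy"]
        mask = alpha_ses["metric"] == "redundancy"
        for col, flip in (("observed", True), ("null_mean", True), ("ses", False)):
            alpha_ses.loc[mask, col] = (
                1.0 - alpha_ses.loc[mask, col] if flip else -alpha_ses.loc[mask, col]
            )

    deltas, delta_stats = delta_cwm_tests(cwm_df, pairs, alpha=config.alpha_level)
    paired_alpha = paired_tests(
        alpha.drop(columns=["richness"]), pairs, on_insufficient="skip"
    )
    ses_wide = alpha_ses.pivot(index="unit", columns="metric", values="ses")
    ses_wide.columns = [f"ses_{c}" for c in ses_wide.columns]
    defined = ses_wide.columns[ses_wide.notna().sum(axis=0) >= 3]
    paired_ses = paired_tests(ses_wide[defined], pairs, on_insufficient="skip")
    beta_ses_wide = beta_ses.pivot(index="unit", columns="metric", values="ses")
    correlations = covariate_correlations(beta_ses_wide, pairs)
    sig = pd.concat(
        [
            significant_fraction(alpha_ses).assign(scale="alpha"),
            significant_fraction(beta_ses).assign(scale="beta"),
        ],
        ignore_index=True,
    )
    return AnalysisResult(
        space=space,
        alpha=alpha,
        cwm=cwm_df,
        beta=beta,
        alpha_ses=alpha_ses,
        beta_ses=beta_ses,
        delta_cwm=deltas,
        delta_cwm_stats=delta_stats,
        paired_alpha=paired_alpha,
        paired_ses=paired_ses,
        correlations=correlations,
        sig_fractions=sig,
    )


def _write_result(res: AnalysisResult, out: Path, config: RunConfig, prefix: str = "") -> None:
    p = lambda name: out / f"{prefix}{name}"
    save_space(res.space, out, prefix=f"{prefix}space", write_distance=config.write_distance)
    res.alpha.to_csv(p("alpha.csv"))
    cwm_flat = res.cwm.copy()
    cwm_flat.columns = [f"{g}:{m}" for g, m in cwm_flat.columns]
    cwm_flat.to_csv(p("cwm.csv"))
    res.beta.table.to_csv(p("beta.csv"))
    res.alpha_ses.to_csv(p("alpha_ses.csv"), index=False)
    res.beta_ses.to_csv(p("beta_ses.csv"), index=False)
    dc = res.delta_cwm.copy()
    dc.columns = [f"{g}:{m}" for g, m in dc.columns]
    dc.to_csv(p("delta_cwm.csv"))
    res.delta_cwm_stats.to_csv(p("delta_cwm_tests.csv"), index=False)
    res.paired_alpha.to_csv(p("paired_alpha_tests.csv"), index=False)
    res.paired_ses.to_csv(p("paired_ses_tests.csv"), index=False)
    res.correlations.to_csv(p("covariate_correlations.csv"), index=False)
    res.sig_fractions.to_csv(p("significant_fractions.csv"), index=False)


def run_pipeline(
    traits_raw: TraitTable,
    taxonomy: TaxonomyTable,
    communities: CommunityMatrix,
    pairs: pd.DataFrame,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> tuple[AnalysisResult, AnalysisResult | None, dict]:
    """Full analysis: prepare, analyse, EPT-subset re-run, write outputs.

    Returns the full-dataset result, the EPT-subset result (None when the
    subset is empty or too small to test) and the manifest dictionary.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))

    traits, merged, mapping, coverage = prepare(traits_raw, taxonomy, communities)
    write_trait_table(traits, out / "traits_filled.csv")
    coverage.to_frame().to_csv(out / "coverage.csv", index=False)
    merged.abundance.to_csv(out / "community_merged.csv", index_label="site")

    full = analyse(traits, merged, pairs, config, rng)
    _write_result(full, out, config)

    shares = upstream_ept_shares(merged, pairs)
    shares.to_csv(out / "ept_shares.csv")
    sub_comm, sub_pairs, _ = ept_subset(merged, pairs, threshold=config.ept_threshold)
    ept_res = None
    if len(sub_pairs) >= 3:
        sub_traits = traits.subset(sorted(sub_comm.taxa))
        ept_res = analyse(
            sub_traits, sub_comm, sub_pairs, config, rng,
            m_cap_alpha=config.m_cap_ept_alpha,
        )
        _write_result(ept_res, out, config, prefix="ept_")
    else:
        log.info("EPT subset has %d pairs; subset analysis skipped", len(sub_pairs))

    manifest = {
        "version": __version__,
        "config": {k: getattr(config, k) for k in vars(config)},
        "n_sites": int(len(merged.abundance)),
        "n_pairs": int(len(pairs)),
        "n_taxa_final": int(coverage.n_final),
        "n_taxa_dropped": len(coverage.dropped),
        "coverage_levels": coverage.level_counts,
        "m_alpha": int(full.space.m_alpha),
        "m_beta": int(full.space.m_beta),
        "ept_pairs": int(len(sub_pairs)),
        "ept_m_alpha": None if ept_res is None else int(ept_res.space.m_alpha),
    }
    write_json(manifest, out / "manifest.json")
    return full, ept_res, manifest
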