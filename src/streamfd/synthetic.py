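"""Synthetic paired-community data with the structure the analysis assumes.

Generates everything the pipeline consumes — a fuzzy-coded trait table
over a regional taxon pool with a three-level taxonomy (including taxa
lacking species-level coding, to exercise gap-filling), paired
upstream/downstream communities below simulated wastewater treatment
plants, WWTP covariates whose effluent concentrations increase with
decreasing plant size class, and EPT membership flags — plus the ground
truth needed for recovery tests.

The default scenario mirrors the scale of a state biomonitoring dataset:
169 site pairs (338 communities), a 444-taxon pool, nine trait groups with
49 modalities in total, and a minority of pairs whose upstream community
is dominated (>= 50% of individuals) by the sensitive EPT insect orders.

An optional *trait-filtering effect* multiplies the downstream expected
abundance of every taxon with affinity >= 0.5 for a chosen trait modality
by ``effect_strength`` (1 = no effect, 0 = extirpation).  Downstream
communities are resampled from the penalized upstream relative abundances,
so pairs are coupled as in the real paired design.  The effect construct
is synthetic plumbing for parameter-recovery tests, not an ecological
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alpha import DOWNSTREAM, UPSTREAM, CommunityMatrix
from .traits import TaxonomyTable, TraitTable, normalize_fuzzy

__all__ = ["SyntheticScenario", "generate_trait_table", "generate_pairs", "generate"]


class InvalidScenario(ValueError):
    """Raised when scenario parameters are inconsistent."""


#: Per-size-class covariate means: (share of WWTPs, households,
#: population equivalents, BOD mg/L, NH4+ mg/L, total P mg/L).  Smaller
#: size classes emit higher effluent concentrations.
DEFAULT_COVARIATE_MODEL: dict[int, tuple[float, float, float, float, float, float]] = {
    1: (23 / 169, 536, 590, 10.8, 7.1, 2.5),
    2: (47 / 169, 2253, 2779, 6.9, 4.8, 1.8),
    3: (25 / 169, 5990, 7615, 4.4, 1.3, 1.7),
    4: (70 / 169, 23553, 34455, 3.6, 1.1, 0.7),
    5: (4 / 169, 166000, 248750, 3.8, 0.8, 0.4),
}


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic paired-community dataset.

    ``modalities_per_group`` defaults to nine groups totalling 49
    modalities.  ``dominance_alpha`` is the symmetric Dirichlet
    concentration of within-community relative abundances (small values =
    strongly dominated communities, the common case in stream samples).
    ``trait_concentration`` is the Dirichlet concentration of fuzzy
    affinities within a trait group; fuzzy-coded databases are peaky
    (most taxa load on one or two modalities), hence the small default.
    """

    seed: int
    n_pairs: int = 169
    pool_size: int = 444
    n_trait_groups: int = 9
    modalities_per_group: tuple[int, ...] = (8, 7, 7, 4, 5, 6, 3, 4, 5)
    ept_fraction: float = 0.35
    dominance_alpha: float = 0.3
    richness_range: tuple[int, int] = (15, 50)
    effect_modality: tuple[str, str] | None = None
    effect_strength: float = 1.0
    covariate_model: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL)
    )
    trait_concentration: float = 0.35
    affinity_scale: int = 3
    uncoded_fraction: float = 0.15
    ept_mix_beta: tuple[float, float] = (1.1, 3.0)
    total_abundance: tuple[int, int] = (200, 2000)
    share_intermediate: bool = False

    def validate(self) -> None:
        if len(self.modalities_per_group) != self.n_trait_groups:
            raise InvalidScenario("modalities_per_group length != n_trait_groups")
        if any(k < 2 for k in self.modalities_per_group):
            raise InvalidScenario("every trait group needs >= 2 modalities")
        if not (0.0 <= self.effect_strength <= 1.0):
            raise InvalidScenario("effect_strength must lie in [0, 1]")
        if not (0.0 <= self.ept_fraction <= 1.0):
            raise InvalidScenario("ept_fraction must lie in [0, 1]")
        lo, hi = self.richness_range
        if lo < 1 or hi < lo or hi > self.pool_size:
            raise InvalidScenario("invalid richness_range")
        if self.pool_size < 5 or self.n_pairs < 1:
            raise InvalidScenario("pool_size/n_pairs too small")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of the scenario."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _group_names(scenario: SyntheticScenario) -> list[tuple[str, list[str]]]:
    return [
        (f"g{gi + 1}", [f"g{gi + 1}m{k + 1}" for k in range(nk)])
        for gi, nk in enumerate(scenario.modalities_per_group)
    ]


def _taxonomy(scenario: SyntheticScenario, rng) -> pd.DataFrame:
    """Random three-level taxonomy: ~6 species per family, 1-3 per genus."""
    records = []
    fam = gen = 0
    while len(records) < scenario.pool_size:
        fam += 1
        for _ in range(int(rng.integers(1, 4))):  # genera in family
            gen += 1
            for sp in range(int(rng.integers(1, 4))):  # species in genus
                if len(records) >= scenario.pool_size:
                    break
                name = f"f{fam:03d}g{gen:04d}s{sp + 1}"
                records.append(
                    {
                        "taxon": name,
                        "species": name,
                        "genus": f"f{fam:03d}g{gen:04d}",
                        "family": f"f{fam:03d}",
                        "level": "species",
                    }
                )
    return pd.DataFrame(records).set_index("taxon")


def generate_trait_table(
    scenario: SyntheticScenario,
) -> tuple[TraitTable, TaxonomyTable]:
    """Fuzzy trait table plus taxonomy for the regional pool.

    Affinities are drawn per trait group from a symmetric Dirichlet,
    discretized to the 0..affinity_scale integer scale used by fuzzy
    coding, and left unnormalized (the pipeline normalizes).  A configurable
    fraction of taxa is left entirely uncoded to exercise taxonomic
    gap-filling; the first member of each family always stays coded so
    every taxon remains resolvable at family level.
    """
    scenario.validate()
    rng = scenario.rng(0)
    taxonomy = _taxonomy(scenario, rng)
    taxa = taxonomy.index
    n = len(taxa)
    blocks = []
    cols = []
    for gname, mods in _group_names(scenario):
        probs = rng.dirichlet(
            np.full(len(mods), scenario.trait_concentration), size=n
        )
        scores = np.rint(probs * scenario.affinity_scale).astype(float)
        zero_rows = scores.sum(axis=1) == 0
        if zero_rows.any():  # rounding can null a flat profile; keep the mode
            scores[zero_rows, probs[zero_rows].argmax(axis=1)] = 1.0
        blocks.append(scores)
        cols.extend((gname, m) for m in mods)
    aff = pd.DataFrame(
        np.hstack(blocks), index=taxa, columns=pd.MultiIndex.from_tuples(cols)
    )
    # Uncoded taxa: all-zero rows, skipping each family's first member.
    protected = taxonomy.groupby("family", sort=False).head(1).index
    candidates = taxa.difference(protected)
    n_uncoded = int(round(scenario.uncoded_fraction * n))
    n_uncoded = min(n_uncoded, len(candidates))
    uncoded = rng.choice(candidates.to_numpy(), size=n_uncoded, replace=False)
    aff.loc[uncoded] = 0.0
    traits = TraitTable(affinities=aff)
    return traits, TaxonomyTable(table=taxonomy)


def _penalized_taxa(
    scenario: SyntheticScenario, traits: TraitTable
) -> pd.Index:
    """Taxa hit by the downstream filter: affinity >= 0.5 for the modality."""
    if scenario.effect_modality is None:
        return pd.Index([])
    norm = traits if traits.normalized else normalize_fuzzy(traits)
    col = norm.affinities[scenario.effect_modality]
    return norm.taxa[col.to_numpy() >= 0.5]


@dataclass
class GroundTruth:
    """What the generator imposed, for recovery tests."""

    effect_modality: tuple[str, str] | None
    effect_strength: float
    penalized_taxa: list[str]
    expected_delta_cwm: pd.Series  # per pair, for the effect modality
    upstream_expected: pd.DataFrame  # pair x taxon upstream sampling probs

    @property
    def expected_sign(self) -> int:
        """Sign of the expected delta CWM (upstream - downstream) for the
        filtered modality: +1 whenever the filter actually removes weight."""
        med = self.expected_delta_cwm.median()
        return int(np.sign(med)) if np.isfinite(med) else 0


def generate_pairs(
    scenario: SyntheticScenario, traits: TraitTable
) -> tuple[CommunityMatrix, pd.DataFrame, GroundTruth]:
    """Paired communities, pair/covariate table and ground truth.

    Upstream: richness drawn uniformly from ``richness_range``, member taxa
    sampled from the pool with an EPT bias drawn per pair from
    ``ept_mix_beta`` (creating an EPT-dominance gradient), relative
    abundances from a symmetric Dirichlet, counts multinomial.  Downstream:
    counts resampled from the upstream relative abundances after applying
    the effect penalty, coupling the two members of a pair.
    """
    scenario.validate()
    rng = scenario.rng(1)
    taxa = traits.taxa
    n_pool = len(taxa)
    penalized = _penalized_taxa(scenario, traits)
    pen_mask = taxa.isin(penalized).astype(float)
    penalty = np.where(pen_mask > 0, scenario.effect_strength, 1.0)

    n_ept = int(round(scenario.ept_fraction * n_pool))
    ept_taxa = rng.choice(taxa.to_numpy(), size=n_ept, replace=False)
    ept_flags = pd.Series(taxa.isin(ept_taxa), index=taxa, name="ept")

    # Effect-modality column of the normalized trait table, for ground truth.
    norm = traits if traits.normalized else normalize_fuzzy(traits)
    t_col = (
        norm.affinities[scenario.effect_modality].to_numpy()
        if scenario.effect_modality is not None
        else np.zeros(n_pool)
    )

    lo, hi = scenario.richness_range
    ab_lo, ab_hi = scenario.total_abundance
    ept_arr = ept_flags.to_numpy()
    abund_rows, site_meta, pair_rows = [], [], []
    exp_delta, up_expected = {}, {}
    prev_down = None

    for i in range(scenario.n_pairs):
        pair_id = f"P{i + 1:03d}"
        if scenario.share_intermediate and prev_down is not None and i % 2 == 1:
            up_counts, up_site = prev_down
        else:
            s = int(rng.integers(lo, hi + 1))
            mix = rng.beta(*scenario.ept_mix_beta)
            w = np.where(ept_arr, mix / max(ept_arr.sum(), 1),
                         (1 - mix) / max((~ept_arr.astype(bool)).sum(), 1))
            members = rng.choice(n_pool, size=s, replace=False, p=w / w.sum())
            rel = rng.dirichlet(np.full(s, scenario.dominance_alpha))
            n_up = int(np.exp(rng.uniform(np.log(ab_lo), np.log(ab_hi))))
            up_counts = np.zeros(n_pool)
            up_counts[members] = rng.multinomial(max(n_up, 1), rel)
            while up_counts.sum() == 0:  # guard: never an empty community
                up_counts[members] = rng.multinomial(max(n_up, 1), rel)
            up_site = f"{pair_id}U"
            abund_rows.append(up_counts)
            site_meta.append({"site": up_site, "pair_id": pair_id, "position": UPSTREAM})

        p_up = up_counts / up_counts.sum()
        q = p_up * penalty
        q_sum = q.sum()
        if q_sum == 0:  # filter extirpated everything sampled; downstream empty-guard
            q = p_up.copy()
            q_sum = 1.0
        q = q / q_sum
        n_down = int(np.exp(rng.uniform(np.log(ab_lo), np.log(ab_hi))))
        down_counts = rng.multinomial(max(n_down, 1), q)
        down_site = f"{pair_id}D"
        abund_rows.append(down_counts)
        site_meta.append({"site": down_site, "pair_id": pair_id, "position": DOWNSTREAM})
        if scenario.share_intermediate:
            # this downstream community doubles as the next pair's upstream
            prev_down = (down_counts.astype(float), down_site)

        exp_delta[pair_id] = float(p_up @ t_col - q @ t_col)
        up_expected[pair_id] = p_up

        size_class, hh, pe, bod, nh4, tp = _covariates(scenario, rng)
        pair_rows.append(
            {
                "pair_id": pair_id,
                UPSTREAM: up_site,
                DOWNSTREAM: down_site,
                "size_class": size_class,
                "households": hh,
                "population_equivalents": pe,
                "bod": bod,
                "nh4": nh4,
                "total_p": tp,
            }
        )

    sites = pd.DataFrame(site_meta).set_index("site")
    # With shared intermediate sites a community can serve two pairs; keep
    # one abundance row per unique site id.
    ab = pd.DataFrame(abund_rows, index=sites.index, columns=taxa)
    ab = ab[~ab.index.duplicated()]
    sites = sites[~sites.index.duplicated()]
    communities = CommunityMatrix(abundance=ab, sites=sites, ept_flags=ept_flags)
    pair_table = pd.DataFrame(pair_rows).set_index("pair_id")
    truth = GroundTruth(
        effect_modality=scenario.effect_modality,
        effect_strength=scenario.effect_strength,
        penalized_taxa=list(penalized),
        expected_delta_cwm=pd.Series(exp_delta, name="expected_delta"),
        upstream_expected=pd.DataFrame(up_expected, index=taxa).T,
    )
    return communities, pair_table, truth


def _covariates(scenario: SyntheticScenario, rng):
    model = scenario.covariate_model
    classes = sorted(model)
    probs = np.array([model[c][0] for c in classes])
    k = int(rng.choice(classes, p=probs / probs.sum()))
    _, hh, pe, bod, nh4, tp = model[k]
    jitter = lambda mu, sd: float(mu * np.exp(rng.normal(0.0, sd)))
    return (
        k,
        jitter(hh, 0.4),
        jitter(pe, 0.4),
        jitter(bod, 0.5),
        jitter(nh4, 0.5),
        jitter(tp, 0.5),
    )


def generate(
    scenario: SyntheticScenario,
) -> tuple[TraitTable, TaxonomyTable, CommunityMatrix, pd.DataFrame, GroundTruth]:
    """Full synthetic dataset for one scenario."""
    traits, taxonomy = generate_trait_table(scenario)
    communities, pair_table, truth = generate_pairs(scenario, traits)
    return traits, taxonomy, communities, pair_table, truth
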