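"""Fuzzy-coded trait tables: normalization, taxonomic gap-filling, EPT shares.

Macroinvertebrate trait databases score each taxon's affinity to the
modalities of a trait group (e.g. the feeding-type group with modalities
shredder, grazer, predator, ...) on a small integer scale.  Before any
distance or community-weighted computation the scores of each group are
converted to relative frequencies so every group contributes a unit budget
per taxon.  Monitoring datasets rarely have species-level trait coverage for
every recorded taxon, so uncoded taxa inherit the mean profile of their
coded relatives at the next taxonomic level up (genus, then family), and
community taxa raised to the same parent are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "TaxonomyTable",
    "CoverageReport",
    "normalize_fuzzy",
    "fill_gaps",
    "apply_merge",
    "ept_proportion",
]


class TraitDataError(ValueError):
    """Raised for malformed trait data (negative scores, bad group layout)."""


@dataclass
class TraitTable:
    """Taxon x trait-modality affinity matrix with trait-group structure.

    Parameters
    ----------
    affinities
        DataFrame indexed by taxon with a two-level column index
        ``(trait group, modality)``.  Non-negative scores; raw integer
        affinities before normalization, relative frequencies after.
    coding_level
        Taxonomic level each taxon's traits were coded at
        (``original``/``subspecies``/``genus``/``family``).
    normalized
        Whether each group's scores sum to one per taxon.
    """

    affinities: pd.DataFrame
    coding_level: pd.Series | None = None
    normalized: bool = False
    missing: pd.DataFrame | None = None  # taxon x group boolean, set on normalize

    def __post_init__(self) -> None:
        if not isinstance(self.affinities.columns, pd.MultiIndex):
            raise TraitDataError(
                "trait columns must be a (group, modality) MultiIndex"
            )
        if (self.affinities.values < 0).any():
            raise TraitDataError("negative trait affinity scores")
        if self.coding_level is None:
            self.coding_level = pd.Series(
                "original", index=self.affinities.index, name="coding_level"
            )

    @property
    def taxa(self) -> pd.Index:
        return self.affinities.index

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.affinities.columns.get_level_values(0)))

    @property
    def n_modalities(self) -> int:
        return self.affinities.shape[1]

    def group_block(self, group: str) -> pd.DataFrame:
        return self.affinities[group]

    def complete_taxa(self) -> pd.Index:
        """Taxa with a positive score sum in every trait group."""
        ok = np.ones(len(self.taxa), dtype=bool)
        for g in self.groups:
            ok &= self.group_block(g).to_numpy().sum(axis=1) > 0
        return self.taxa[ok]

    def subset(self, taxa) -> "TraitTable":
        return replace(
            self,
            affinities=self.affinities.loc[taxa],
            coding_level=self.coding_level.loc[taxa],
            missing=None if self.missing is None else self.missing.loc[taxa],
        )


@dataclass
class TaxonomyTable:
    """Taxon -> (species, genus, family) lookup used for trait gap-filling.

    ``table`` is indexed by taxon identifier with columns ``species``,
    ``genus``, ``family`` (missing ranks as NaN/empty) and ``level`` giving
    the rank of the record itself.
    """

    table: pd.DataFrame

    REQUIRED = ("species", "genus", "family")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise TraitDataError(f"taxonomy table lacks column {col!r}")

    def parent_chain(self, taxon: str) -> list[tuple[str, str]]:
        """Ordered (rank, name) parents above ``taxon``, genus first."""
        row = self.table.loc[taxon]
        chain = []
        for rank in ("genus", "family"):
            name = row[rank]
            if isinstance(name, str) and name:
                chain.append((rank, name))
        return chain

    def members_of(self, rank: str, name: str) -> pd.Index:
        return self.table.index[self.table[rank] == name]


@dataclass
class CoverageReport:
    """Trait-coverage accounting produced by :func:`fill_gaps`."""

    level_counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0
    n_final: int = 0
    dropped: list[str] = field(default_factory=list)

    @property
    def level_shares(self) -> dict[str, float]:
        total = sum(self.level_counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in self.level_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": lvl, "n_taxa": n, "share": self.level_shares[lvl]}
            for lvl, n in self.level_counts.items()
        ]
        return pd.DataFrame(rows)


def normalize_fuzzy(traits: TraitTable) -> TraitTable:
    """Convert raw affinity scores to per-group relative frequencies.

    Each taxon's scores within a trait group are divided by the group sum.
    Groups whose scores are all zero carry no information; they are left at
    zero and flagged in ``missing`` rather than imputed.  Idempotent.
    """
    vals = traits.affinities.to_numpy(dtype=float, copy=True)
    if (vals < 0).any():
        raise TraitDataError("negative trait affinity scores")
    groups = traits.groups
    missing = np.zeros((vals.shape[0], len(groups)), dtype=bool)
    out = vals.copy()
    for gi, g in enumerate(groups):
        cols = traits.affinities.columns.get_loc(g)
        block = vals[:, cols]
        sums = block.sum(axis=1)
        zero = sums == 0
        missing[:, gi] = zero
        sums_safe = np.where(zero, 1.0, sums)
        out[:, cols] = block / sums_safe[:, None]
    aff = pd.DataFrame(out, index=traits.taxa, columns=traits.affinities.columns)
    miss = pd.DataFrame(missing, index=traits.taxa, columns=groups)
    return replace(traits, affinities=aff, normalized=True, missing=miss)


def _mean_profile(
    norm: TraitTable, donors: pd.Index
) -> pd.Series | None:
    """Unweighted mean of donor profiles, renormalized per group.

    Returns None when some trait group has no information among donors.
    """
    cols = norm.affinities.columns
    prof = norm.affinities.loc[donors].to_numpy().mean(axis=0)
    out = prof.copy()
    level0 = cols.get_level_values(0)
    for g in norm.groups:
        mask = (level0 == g).to_numpy() if hasattr(level0 == g, "to_numpy") else (level0 == g)
        s = prof[mask].sum()
        if s <= 0:
            return None
        out[mask] = prof[mask] / s
    return pd.Series(out, index=cols)


def fill_gaps(
    traits: TraitTable,
    taxonomy: TaxonomyTable,
    community_taxa: list[str] | pd.Index | None = None,
    min_coded_descendants: int = 1,
) -> tuple[TraitTable, dict[str, str], CoverageReport]:
    """Assign trait profiles to uncoded taxa by taxonomic aggregation.

    A taxon counts as coded when every trait group has a positive score sum.
    Uncoded taxa are raised to the nearest parent (genus, then family) with
    at least ``min_coded_descendants`` coded descendants in the pool; the
    raised taxon receives the unweighted mean of its coded descendants'
    normalized profiles, renormalized per group.  Community taxa raised to
    the same parent collapse into a single final taxon (abundances summed
    via the returned mapping and :func:`apply_merge`).  Taxa that cannot be
    resolved even at family level are reported as dropped, never silently
    removed.

    Returns
    -------
    (filled trait table over final taxa, original->final name mapping,
    coverage report)
    """
    norm = traits if traits.normalized else normalize_fuzzy(traits)
    if community_taxa is None:
        community_taxa = list(norm.taxa)
    community_taxa = list(community_taxa)
    unknown = [t for t in community_taxa if t not in norm.taxa]
    if unknown:
        raise TraitDataError(f"community taxa absent from trait pool: {unknown}")

    coded = set(norm.complete_taxa())
    report = CoverageReport(n_input=len(community_taxa))
    mapping: dict[str, str] = {}
    profiles: dict[str, pd.Series] = {}
    levels: dict[str, str] = {}

    for taxon in sorted(community_taxa):
        if taxon in coded:
            mapping[taxon] = taxon
            profiles[taxon] = norm.affinities.loc[taxon]
            levels[taxon] = str(norm.coding_level.loc[taxon])
            continue
        placed = False
        for rank, parent in taxonomy.parent_chain(taxon):
            members = taxonomy.members_of(rank, parent)
            donors = pd.Index(sorted(set(members) & coded))
            if len(donors) < min_coded_descendants:
                continue
            prof = _mean_profile(norm, donors)
            if prof is None:
                continue
            final = f"{parent}_agg"
            mapping[taxon] = final
            if final not in profiles:
                profiles[final] = prof
                levels[final] = rank
            placed = True
            break
        if not placed:
            report.dropped.append(taxon)

    for lvl in ("original", "subspecies", "genus", "family"):
        n = sum(1 for t in mapping if levels[mapping[t]] == lvl)
        if n:
            report.level_counts[lvl] = n
    report.n_final = len(profiles)

    order = sorted(profiles)
    if order:
        aff = pd.DataFrame(
            [profiles[t] for t in order], index=pd.Index(order, name="taxon")
        )
        aff.columns = norm.affinities.columns
    else:
        aff = pd.DataFrame(
            np.empty((0, norm.n_modalities)),
            index=pd.Index([], name="taxon"),
            columns=norm.affinities.columns,
        )
    filled = TraitTable(
        affinities=aff,
        coding_level=pd.Series({t: levels[t] for t in order}, name="coding_level"),
        normalized=True,
    )
    filled = normalize_fuzzy(filled)  # exact per-group unit sums after averaging
    return filled, mapping, report


def apply_merge(abundance: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Merge community columns according to a gap-filling taxon mapping.

    Columns absent from the mapping (dropped taxa) are removed; columns that
    map to the same final taxon are summed, conserving total abundance of
    mapped taxa.
    """
    kept = [t for t in abundance.columns if t in mapping]
    merged = abundance[kept].T.groupby([mapping[t] for t in kept]).sum().T
    merged = merged[sorted(merged.columns)]
    merged.columns.name = abundance.columns.name
    return merged


def ept_proportion(abundance, ept_flags) -> float:
    """Share of individuals belonging to EPT taxa.

    EPT = Ephemeroptera, Plecoptera, Trichoptera, the pollution-sensitive
    insect orders used to flag high-quality communities.

    Parameters
    ----------
    abundance
        Per-taxon abundance vector (Series or array), total > 0.
    ept_flags
        Boolean flags aligned with ``abundance``.
    """
    a = np.asarray(pd.Series(abundance), dtype=float)
    if a.size == 0 or a.sum() <= 0:
        raise ValueError("EPT proportion undefined for an empty community")
    if (a < 0).any():
        raise ValueError("negative abundances")
    if isinstance(abundance, pd.Series) and isinstance(ept_flags, pd.Series):
        flags = ept_flags.reindex(abundance.index).fillna(False).to_numpy(dtype=bool)
    else:
        flags = np.asarray(ept_flags, dtype=bool)
    return float(a[flags].sum() / a.sum())
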