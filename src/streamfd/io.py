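"""Readers/writers for the plain-text dataset and result formats.

All artefacts are CSV (communities, trait tables, taxonomy, pair tables,
space coordinates) or YAML/JSON (scenario and run configuration,
manifest).  The trait table uses a two-row header encoding the
(trait group, modality) column structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alpha import CommunityMatrix
from .space import (
    FunctionalSpace,
    choose_dimensionality,
)
from .synthetic import SyntheticScenario
from .traits import TaxonomyTable, TraitDataError, TraitTable

__all__ = [
    "RunConfig",
    "read_trait_table",
    "write_trait_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_community",
    "write_community",
    "read_pairs",
    "write_pairs",
    "read_inputs",
    "write_dataset",
    "save_space",
    "load_space",
    "scenario_to_yaml",
    "scenario_from_yaml",
]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Dimensionality caps follow the study design: hull metrics and the beta
    space use at most 3 axes on the full dataset; the EPT-subset alpha
    space may use up to 8 axes.
    """

    community: str = "community.csv"
    sites: str = "sites.csv"
    traits: str = "traits.csv"
    taxonomy: str = "taxonomy.csv"
    pairs: str = "pairs.csv"
    ept: str = "ept.csv"
    out_dir: str = "results"
    randomizations: int = 999
    alpha_level: float = 0.05
    m_cap_alpha: int = 3
    m_cap_beta: int = 3
    m_cap_ept_alpha: int = 8
    standardize_fric: bool = True
    beta_family: str = "jaccard"
    correction: str = "sqrt"
    redundancy_complement: bool = False
    ept_threshold: float = 0.5
    seed: int = 0
    n_workers: int = 1
    write_distance: bool = False

    def __post_init__(self) -> None:
        if self.randomizations < 99:
            raise ValueError("randomizations must be >= 99")
        if not (0.0 < self.alpha_level < 1.0):
            raise ValueError("alpha_level must lie in (0, 1)")
        if not (0.0 <= self.ept_threshold <= 1.0):
            raise ValueError("ept_threshold must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# ---------------------------------------------------------------- trait table

def write_trait_table(traits: TraitTable, path) -> None:
    df = traits.affinities.copy()
    df.insert(0, ("meta", "coding_level"), traits.coding_level)
    df.to_csv(path, index_label="taxon")


def read_trait_table(path, normalized: bool | None = None) -> TraitTable:
    try:
        df = pd.read_csv(path, header=[0, 1], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise TraitDataError(f"malformed fuzzy trait header in {path}: {exc}") from exc
    if df.columns.nlevels != 2 or df.empty:
        raise TraitDataError(f"{path}: expected a two-row (group, modality) header")
    coding = None
    if ("meta", "coding_level") in df.columns:
        coding = df[("meta", "coding_level")].rename("coding_level")
        df = df.drop(columns=[("meta", "coding_level")])
    vals = df.to_numpy(dtype=float)
    if normalized is None:
        # Detect: every group row-sum 0 or ~1.
        normalized = True
        for g in dict.fromkeys(df.columns.get_level_values(0)):
            s = df[g].sum(axis=1)
            if not np.all((s < 1e-9) | (np.abs(s - 1) < 1e-6)):
                normalized = False
                break
    table = TraitTable(
        affinities=df.astype(float), coding_level=coding, normalized=normalized
    )
    return table


# ------------------------------------------------------------------ taxonomy

def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    taxonomy.table.to_csv(path, index_label="taxon")


def read_taxonomy(path) -> TaxonomyTable:
    return TaxonomyTable(table=pd.read_csv(path, index_col="taxon"))


# --------------------------------------------------------------- communities

def write_community(communities: CommunityMatrix, com_path, sites_path, ept_path=None) -> None:
    communities.abundance.to_csv(com_path, index_label="site")
    communities.sites.to_csv(sites_path, index_label="site")
    if ept_path is not None and communities.ept_flags is not None:
        communities.ept_flags.astype(int).rename("ept").to_csv(ept_path, index_label="taxon")


def read_community(com_path, sites_path, ept_path=None, drop_empty=True):
    """Load a community matrix; empty site rows are warned about and excluded."""
    ab = pd.read_csv(com_path, index_col="site")
    ab.columns.name = "taxon"
    sites = pd.read_csv(sites_path, index_col="site").loc[ab.index]
    ept = None
    if ept_path is not None and Path(ept_path).exists():
        flags = pd.read_csv(ept_path, index_col="taxon")["ept"].astype(bool)
        ept = flags.reindex(ab.columns, fill_value=False).astype(bool)
    warnings_out: list[str] = []
    empty = ab.index[ab.sum(axis=1) <= 0]
    if len(empty):
        warnings_out.append(f"excluded {len(empty)} empty site rows: {list(empty)}")
        if drop_empty:
            ab = ab.drop(index=empty)
            sites = sites.drop(index=empty)
    return CommunityMatrix(abundance=ab, sites=sites, ept_flags=ept), warnings_out


# --------------------------------------------------------------------- pairs

def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, index_label="pair_id")


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="pair_id")


# ------------------------------------------------------------------ datasets

def read_inputs(config: RunConfig, base: str | Path = "."):
    """Load and cross-validate all pipeline inputs.

    Community taxa must be resolvable against the trait pool (directly or
    via taxonomy); offenders cause a hard error naming them.
    """
    base = Path(base)
    traits = read_trait_table(base / config.traits)
    taxonomy = read_taxonomy(base / config.taxonomy)
    communities, warns = read_community(
        base / config.community, base / config.sites, base / config.ept
    )
    pairs = read_pairs(base / config.pairs)
    known = set(traits.taxa) | set(taxonomy.table.index)
    offenders = [t for t in communities.taxa if t not in known]
    if offenders:
        raise TraitDataError(
            f"community taxa absent from traits and taxonomy: {offenders[:10]}"
        )
    for col in ("upstream", "downstream"):
        missing = pairs[col][~pairs[col].isin(communities.abundance.index)]
        if len(missing):
            raise ValueError(f"pair table references unknown sites: {list(missing)}")
    return traits, taxonomy, communities, pairs, warns


def write_dataset(
    traits: TraitTable,
    taxonomy: TaxonomyTable,
    communities: CommunityMatrix,
    pairs: pd.DataFrame,
    out_dir,
    config: RunConfig | None = None,
) -> RunConfig:
    """Write a full dataset in the layout :func:`read_inputs` expects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()
    write_trait_table(traits, out / cfg.traits)
    write_taxonomy(taxonomy, out / cfg.taxonomy)
    write_community(communities, out / cfg.community, out / cfg.sites, out / cfg.ept)
    write_pairs(pairs, out / cfg.pairs)
    return cfg


# ------------------------------------------------------------------- spaces

def save_space(space: FunctionalSpace, out_dir, prefix: str = "space", write_distance=False) -> None:
    out = Path(out_dir)
    space.coordinates.to_csv(out / f"{prefix}_axes.csv", index_label="taxon")
    pd.DataFrame(
        {
            "eigenvalue": space.eigenvalues,
            "variance_explained": space.variance_explained,
        },
        index=space.coordinates.columns,
    ).to_csv(out / f"{prefix}_eigen.csv", index_label="axis")
    space.quality.to_csv(out / f"{prefix}_quality.csv")
    if write_distance:
        space.distance.to_csv(out / f"{prefix}_gower.csv", index_label="taxon")


def load_space(
    out_dir,
    traits: TraitTable,
    prefix: str = "space",
    correction: str = "sqrt",
    m_cap_alpha: int = 3,
    m_cap_beta: int = 3,
) -> FunctionalSpace:
    """Rebuild a FunctionalSpace from saved axes (distances recomputed)."""
    from scipy.spatial.distance import pdist, squareform

    from .space import gower_distance

    out = Path(out_dir)
    coords = pd.read_csv(out / f"{prefix}_axes.csv", index_col="taxon")
    eigen = pd.read_csv(out / f"{prefix}_eigen.csv", index_col="axis")
    quality = pd.read_csv(out / f"{prefix}_quality.csv", index_col="m")["mSD"]
    dist = gower_distance(traits).loc[coords.index, coords.index]
    corrected = pd.DataFrame(
        squareform(pdist(coords.to_numpy())), index=coords.index, columns=coords.index
    )
    return FunctionalSpace(
        distance=dist,
        corrected=corrected,
        coordinates=coords,
        eigenvalues=eigen["eigenvalue"].to_numpy(),
        variance_explained=eigen["variance_explained"].to_numpy(),
        quality=quality,
        m_alpha=choose_dimensionality(quality, cap=m_cap_alpha),
        m_beta=choose_dimensionality(quality, cap=m_cap_beta),
        correction=correction,
    )


# ----------------------------------------------------------------- scenarios

def scenario_to_yaml(scenario: SyntheticScenario, path) -> None:
    data = dataclasses.asdict(scenario)
    data["modalities_per_group"] = list(scenario.modalities_per_group)
    data["richness_range"] = list(scenario.richness_range)
    data["ept_mix_beta"] = list(scenario.ept_mix_beta)
    data["total_abundance"] = list(scenario.total_abundance)
    if scenario.effect_modality is not None:
        data["effect_modality"] = list(scenario.effect_modality)
    data["covariate_model"] = {
        int(k): list(v) for k, v in scenario.covariate_model.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def scenario_from_yaml(path) -> SyntheticScenario:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("modalities_per_group", "richness_range", "ept_mix_beta", "total_abundance"):
        if key in data:
            data[key] = tuple(data[key])
    if data.get("effect_modality") is not None:
        data["effect_modality"] = tuple(data["effect_modality"])
    if "covariate_model" in data:
        data["covariate_model"] = {
            int(k): tuple(v) for k, v in data["covariate_model"].items()
        }
    return SyntheticScenario(**data)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
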