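"""Trait-table processing: fuzzy normalization, gap-filling, EPT shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import streamfd as sfd
from streamfd.traits import TraitDataError, TaxonomyTable

from conftest import make_trait_table


class TestNormalizeFuzzy:
    def test_proportional_scaling(self):
        t = make_trait_table({"t1": [3, 1, 0]}, [("g", ["a", "b", "c"])])
        out = sfd.normalize_fuzzy(t)
        assert out.affinities.loc["t1"].tolist() == [0.75, 0.25, 0.0]

    def test_all_zero_group_flagged_missing_not_imputed(self):
        t = make_trait_table(
            {"t1": [1, 1, 0, 0]}, [("g1", ["a", "b"]), ("g2", ["x", "y"])]
        )
        out = sfd.normalize_fuzzy(t)
        assert out.missing.loc["t1", "g2"]
        assert not out.missing.loc["t1", "g1"]
        assert out.affinities.loc["t1", "g2"].sum() == 0.0

    def test_idempotent(self, toy_traits):
        again = sfd.normalize_fuzzy(toy_traits)
        pd.testing.assert_frame_equal(again.affinities, toy_traits.affinities)

    def test_negative_affinity_rejected(self):
        df = pd.DataFrame(
            [[1.0, -0.5]],
            index=["t1"],
            columns=pd.MultiIndex.from_tuples([("g", "a"), ("g", "b")]),
        )
        with pytest.raises(TraitDataError):
            sfd.TraitTable(affinities=df)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 3), min_size=5, max_size=5),
                    min_size=2, max_size=8))
    def test_group_sums_one_or_flagged(self, rows):
        t = make_trait_table(
            {f"t{i}": r for i, r in enumerate(rows)},
            [("g1", ["a", "b"]), ("g2", ["x", "y", "z"])],
        )
        out = sfd.normalize_fuzzy(t)
        for g in out.groups:
            sums = out.affinities[g].sum(axis=1).to_numpy()
            flagged = out.missing[g].to_numpy()
            assert np.allclose(sums[~flagged], 1.0, atol=1e-12)
            assert np.all(sums[flagged] == 0.0)


def _toy_taxonomy():
    rows = {
        # genus A has one coded donor (a1) and one uncoded member (a2)
        "a1": ("a1", "genA", "famA"),
        "a2": ("a2", "genA", "famA"),
        "b1": ("b1", "genB", "famA"),
        "c1": ("c1", "genC", "famB"),
    }
    return TaxonomyTable(
        table=pd.DataFrame(
            [(s, g, f, "species") for s, g, f in rows.values()],
            index=pd.Index(rows, name="taxon"),
            columns=["species", "genus", "family", "level"],
        )
    )


class TestFillGaps:
    def test_uncoded_taxon_receives_genus_mean(self):
        t = make_trait_table(
            {"a1": [2, 2], "a2": [0, 0], "b1": [4, 0], "c1": [0, 4]},
            [("g", ["a", "b"])],
        )
        filled, mapping, report = sfd.fill_gaps(t, _toy_taxonomy())
        assert mapping["a2"] == "genA_agg"
        # single donor a1 -> raised profile equals a1's normalized profile
        assert filled.affinities.loc["genA_agg"].tolist() == [0.5, 0.5]
        assert report.level_counts == {"original": 3, "genus": 1}

    def test_all_coded_is_noop_with_full_coverage(self, toy_traits):
        tax = TaxonomyTable(
            table=pd.DataFrame(
                {
                    "species": list(toy_traits.taxa),
                    "genus": "gen1",
                    "family": "fam1",
                    "level": "species",
                },
                index=toy_traits.taxa,
            )
        )
        filled, mapping, report = sfd.fill_gaps(toy_traits, tax)
        assert mapping == {t: t for t in toy_traits.taxa}
        assert report.level_shares == {"original": 1.0}
        pd.testing.assert_frame_equal(
            filled.affinities.sort_index(),
            toy_traits.affinities.sort_index(),
            check_names=False,
        )

    def test_merge_collapses_ten_taxa_to_seven_conserving_abundance(self):
        # two uncoded taxa in each of three genera merge into one raised
        # taxon per genus: 4 coded originals + 3 raised = 7 final taxa
        rng = np.random.default_rng(4)
        taxa = [f"s{i}" for i in range(10)]
        genus = ["gA"] * 3 + ["gB"] * 3 + ["gC"] * 4
        tax = TaxonomyTable(
            table=pd.DataFrame(
                {"species": taxa, "genus": genus, "family": "fam", "level": "species"},
                index=pd.Index(taxa, name="taxon"),
            )
        )
        scores = {t: list(rng.integers(1, 4, size=2)) for t in taxa}
        for un in ("s1", "s2", "s4", "s5", "s7", "s8"):
            scores[un] = [0, 0]
        t = make_trait_table(scores, [("g", ["a", "b"])])
        filled, mapping, report = sfd.fill_gaps(t, tax)
        assert report.n_final == 7
        ab = pd.DataFrame(
            rng.integers(1, 50, size=(3, 10)), columns=taxa,
            index=["u1", "u2", "u3"],
        )
        merged = sfd.apply_merge(ab, mapping)
        assert merged.shape[1] == report.n_final
        assert merged.to_numpy().sum() == ab.to_numpy().sum()
        members = [t for t, f in mapping.items() if f == "gA_agg"]
        pd.testing.assert_series_equal(
            merged["gA_agg"], ab[members].sum(axis=1), check_names=False
        )

    def test_order_independent(self):
        t = make_trait_table(
            {"a1": [2, 2], "a2": [0, 0], "b1": [4, 0], "c1": [0, 4]},
            [("g", ["a", "b"])],
        )
        f1, m1, _ = sfd.fill_gaps(t, _toy_taxonomy(), ["a1", "a2", "b1", "c1"])
        f2, m2, _ = sfd.fill_gaps(t, _toy_taxonomy(), ["c1", "b1", "a2", "a1"])
        assert m1 == m2
        pd.testing.assert_frame_equal(f1.affinities, f2.affinities)

    def test_unresolvable_taxon_reported_dropped(self):
        t = make_trait_table({"x1": [0, 0], "x2": [0, 0]}, [("g", ["a", "b"])])
        tax = TaxonomyTable(
            table=pd.DataFrame(
                {"species": ["x1", "x2"], "genus": ["gX", "gX"],
                 "family": ["fX", "fX"], "level": "species"},
                index=pd.Index(["x1", "x2"], name="taxon"),
            )
        )
        filled, mapping, report = sfd.fill_gaps(t, tax)
        assert sorted(report.dropped) == ["x1", "x2"]
        assert mapping == {}


class TestEptProportion:
    @pytest.mark.parametrize(
        "abund,flags,expected",
        [
            ([50, 50], [True, False], 0.5),
            ([3, 4], [True, True], 1.0),
            ([1, 3], [True, False], 0.25),
        ],
    )
    def test_values(self, abund, flags, expected):
        assert sfd.ept_proportion(abund, flags) == expected

    def test_boundary_half_is_retained_by_subset(self):
        # a pair with exactly 50% upstream EPT individuals stays in the subset
        ab = pd.DataFrame(
            {"e": [50, 10], "n": [50, 10]}, index=["P1U", "P1D"]
        )
        sites = pd.DataFrame(
            {"pair_id": ["P1", "P1"], "position": ["upstream", "downstream"]},
            index=ab.index,
        )
        comm = sfd.CommunityMatrix(
            abundance=ab, sites=sites,
            ept_flags=pd.Series({"e": True, "n": False}),
        )
        pairs = pd.DataFrame(
            {"upstream": ["P1U"], "downstream": ["P1D"]},
            index=pd.Index(["P1"], name="pair_id"),
        )
        _, sub_pairs, shares = sfd.ept_subset(comm, pairs, threshold=0.5)
        assert shares["P1"] == 0.5
        assert list(sub_pairs.index) == ["P1"]

    def test_empty_community_errors(self):
        with pytest.raises(ValueError):
            sfd.ept_proportion([0, 0], [True, False])
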