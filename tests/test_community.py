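"""Rarefaction, richness, functional groups, and the reappearance statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sednit.community import (
    OtuTable,
    assign_functional_groups,
    expected_rarefied_richness,
    rarefy,
    rarefy_counts,
    reappearance_fraction,
    richness,
    total_sum_scale,
)


def make_table(counts: dict, zones: dict, taxonomy: dict | None = None) -> OtuTable:
    df = pd.DataFrame(counts)
    meta = pd.DataFrame(
        {"depth_m": {s: float(i) for i, s in enumerate(df.columns)},
         "zone": zones}
    )
    tax = pd.Series(taxonomy or {o: "Bacteria;Something" for o in df.index})
    return OtuTable(df, meta, tax.reindex(df.index).fillna("Bacteria;Something"))


class TestRarefy:
    def test_sample_at_depth_returned_unchanged(self):
        counts = np.array([400, 350, 250])
        out = rarefy_counts(counts, 1000, np.random.default_rng(0))
        assert np.array_equal(out, counts)

    def test_single_otu_sample(self):
        out = rarefy_counts(np.array([5000]), 1000, np.random.default_rng(0))
        assert out.tolist() == [1000]

    def test_totals_exactly_depth_and_reproducible(self):
        counts = np.array([700, 400, 250, 80, 10])
        a = rarefy_counts(counts, 1000, np.random.default_rng(7))
        b = rarefy_counts(counts, 1000, np.random.default_rng(7))
        assert a.sum() == 1000
        assert np.array_equal(a, b)
        assert np.all(a <= counts)

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            rarefy_counts(np.array([10, 10]), 0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            rarefy_counts(np.array([10, 10]), 100, np.random.default_rng(0))

    def test_shallow_samples_excluded(self):
        table = make_table(
            {"deep": {"a": 900, "b": 300}, "shallow": {"a": 5, "b": 3}},
            {"deep": "surface", "shallow": "oxic"},
        )
        out = rarefy(table, depth=1000, seed=0)
        assert list(out.counts.columns) == ["deep"]

    def test_mean_richness_matches_hypergeometric_expectation(self):
        """Monte-Carlo mean over 1000 seeds vs the exact combinatorial
        expectation sum_i (1 - C(N-n_i, d)/C(N, d)) on a 5-OTU toy sample."""
        counts = np.array([1200, 600, 150, 40, 10])
        depth = 100
        expected = expected_rarefied_richness(counts, depth)
        sims = [
            richness(rarefy_counts(counts, depth, np.random.default_rng(seed)))
            for seed in range(1000)
        ]
        mc = np.mean(sims)
        se = np.std(sims, ddof=1) / np.sqrt(len(sims))
        assert abs(mc - expected) < 4 * se + 1e-9


class TestRichness:
    def test_all_zero(self):
        assert richness(np.zeros(10)) == 0

    def test_counts_nonzero(self):
        assert richness(np.array([0, 3, 1, 0, 7, 2, 0, 0, 4])) == 5

    def test_rarefaction_never_increases_richness(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            counts = rng.integers(0, 60, size=30)
            if counts.sum() < 100:
                continue
            sub = rarefy_counts(counts, 100, rng)
            assert richness(sub) <= richness(counts)


class TestFunctionalGroups:
    def test_surface_aoa_share(self):
        """21 of 100 reads in Nitrosopumilales OTUs is a 21% AOA share."""
        table = make_table(
            {"s": {"aoa1": 15, "aoa2": 6, "other1": 79}},
            {"s": "surface"},
            {"aoa1": "Archaea;Thaumarchaeota;Nitrosopumilales;x",
             "aoa2": "Archaea;Thaumarchaeota;Nitrosopumilales;y",
             "other1": "Bacteria;Chloroflexi;z"},
        )
        out = assign_functional_groups(table)
        assert out.loc["s", "AOA"] == pytest.approx(21.0)
        assert out.loc["s"].sum() == pytest.approx(100.0)

    def test_unmapped_taxa_pool_into_other(self):
        table = make_table({"s": {"x": 10, "y": 30}}, {"s": "surface"})
        out = assign_functional_groups(table)
        assert out.loc["s", "other"] == pytest.approx(100.0)
        assert (out.loc["s", ["AOA", "AOB", "NOB", "denitrifiers"]] == 0).all()

    def test_overlapping_map_rejected(self):
        table = make_table(
            {"s": {"x": 10}}, {"s": "surface"}, {"x": "Bacteria;Nitrospira;x"}
        )
        with pytest.raises(ValueError, match="multiple groups"):
            assign_functional_groups(
                table, {"NOB": ("Nitrospira",), "alt": ("Nitrospira",)})

    def test_permutation_invariance(self):
        tax = {"a": "Bacteria;Nitrospira;u", "b": "Bacteria;Pseudomonas;v",
               "c": "Bacteria;Chloroflexi;w"}
        t1 = make_table({"s": {"a": 5, "b": 10, "c": 85}}, {"s": "surface"}, tax)
        t2 = make_table({"s": {"c": 85, "a": 5, "b": 10}}, {"s": "surface"}, tax)
        out1 = assign_functional_groups(t1)
        out2 = assign_functional_groups(t2)
        pd.testing.assert_frame_equal(out1, out2)


class TestTotalSumScale:
    def test_single_otu(self):
        out = total_sum_scale(pd.DataFrame({"s": [7]}))
        assert out.loc[0, "s"] == 1.0

    def test_equal_counts(self):
        out = total_sum_scale(pd.DataFrame({"s": [5, 5, 5, 5]}))
        assert np.allclose(out["s"], 0.25)

    def test_scale_invariance(self):
        a = pd.DataFrame({"s": [3, 9, 18]})
        out1 = total_sum_scale(a)
        out2 = total_sum_scale(a * 17)
        pd.testing.assert_frame_equal(out1, out2)

    def test_zero_total_sample_omitted(self):
        out = total_sum_scale(pd.DataFrame({"ok": [1, 1], "empty": [0, 0]}))
        assert list(out.columns) == ["ok"]


class TestReappearance:
    def _constructed(self, n_surface=32, n_reappear=24):
        counts = {}
        otus = [f"o{i}" for i in range(n_surface)]
        counts["surf"] = {o: 10 for o in otus}
        counts["mid"] = {o: 0 for o in otus}
        counts["oatz"] = {o: (10 if i < n_reappear else 0) for i, o in enumerate(otus)}
        return make_table(counts, {"surf": "surface", "mid": "anoxic", "oatz": "OATZ"})

    def test_constructed_three_quarters(self):
        res = reappearance_fraction(self._constructed())
        assert res.fraction == pytest.approx(0.75)
        assert res.n_surface == 32 and res.n_reappearing == 24

    def test_empty_target_zone(self):
        res = reappearance_fraction(self._constructed(n_reappear=0))
        assert res.fraction == 0.0

    def test_matches_set_algebra_oracle_on_random_tables(self):
        """(surface & ~gap & target) / (surface & ~gap), brute force."""
        rng = np.random.default_rng(11)
        zones = {"s1": "surface", "s2": "surface", "g1": "oxic", "g2": "anoxic",
                 "t1": "OATZ", "t2": "OATZ"}
        for _ in range(20):
            counts = {s: {f"o{i}": int(rng.integers(0, 3)) for i in range(40)}
                      for s in zones}
            table = make_table(counts, zones)
            df = table.counts
            surface = (df[["s1", "s2"]] > 0).any(axis=1)
            gap = (df[["g1", "g2"]] > 0).any(axis=1)
            target = (df[["t1", "t2"]] > 0).any(axis=1)
            denom = (surface & ~gap)
            if denom.sum() == 0:
                continue
            expected = (denom & target).sum() / denom.sum()
            res = reappearance_fraction(table)
            assert res.fraction == pytest.approx(expected)

    def test_no_surface_otus_is_an_error(self):
        table = make_table({"s": {"a": 0}, "t": {"a": 1}},
                           {"s": "surface", "t": "OATZ"})
        with pytest.raises(ValueError, match="no OTUs detected"):
            reappearance_fraction(table)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_fraction_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        zones = {"s": "surface", "g": "oxic", "t": "OATZ"}
        counts = {s: {f"o{i}": int(rng.integers(0, 4)) for i in range(15)}
                  for s in zones}
        table = make_table(counts, zones)
        try:
            res = reappearance_fraction(table)
        except ValueError:
            return
        if res.n_surface:
            assert 0.0 <= res.fraction <= 1.0


class TestOtuTableValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_table({"s": {"a": -1}}, {"s": "surface"})

    def test_missing_metadata_rejected(self):
        df = pd.DataFrame({"s": {"a": 1}})
        meta = pd.DataFrame({"depth_m": {"other": 0.0}})
        with pytest.raises(ValueError, match="without metadata"):
            OtuTable(df, meta, pd.Series({"a": "t"}))
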