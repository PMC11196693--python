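"""Dataset I/O, quality/occurrence filters, transforms and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stoichflex.dataset as dsm
from stoichflex.dataset import (
    Dataset,
    ParseError,
    SchemaError,
    aggregate_sites,
    center_within_species,
    filter_np_outliers,
    filter_occurrence,
    log_transform,
    normalize_to_global_mean,
    read_dataset,
    replace_with_species_means,
    species_summaries,
    write_dataset,
    yeo_johnson,
    yeo_johnson_inverse,
)
from stoichflex.synthetic import SyntheticConfig, generate

from conftest import build_dataset


class TestReadWrite:
    def test_np_ratio_filled_from_concentrations(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "species,site_id,leaf_n,leaf_p\n"
            "A,s1,20,1\nB,s1,20,1\nA,s2,20,1\n"
        )
        ds = read_dataset(p)
        assert ds.n_records == 3
        assert (ds.df["np_ratio"] == 20.0).all()

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("species,leaf_n,leaf_p\nA,20,1\n")
        with pytest.raises(SchemaError, match="site_id"):
            read_dataset(p)

    def test_non_numeric_trait_reports_row(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("species,site_id,leaf_n,leaf_p\nA,s1,20,1\nB,s1,oops,1\n")
        with pytest.raises(ParseError, match="row 1"):
            read_dataset(p)

    def test_schema_mapping(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("taxon,plot,N,P\nA,s1,20,1\n")
        ds = read_dataset(p, schema={"species": "taxon", "site_id": "plot",
                                     "leaf_n": "N", "leaf_p": "P"})
        assert ds.df.loc[0, "species"] == "A"

    def test_round_trip_identity_on_generated_fixture(self, tmp_path):
        ds, _ = generate(SyntheticConfig(n_species=10, n_sites=10, seed=7))
        assert ds.n_records == 100
        p = tmp_path / "round.csv"
        write_dataset(ds, p)
        back = read_dataset(p)
        assert list(back.covariate_names) == list(ds.covariate_names)
        for col in ("record_id", "species", "site_id"):
            assert (back.df[col] == ds.df[col]).all()
        for col in ("leaf_n", "leaf_p", "np_ratio"):
            np.testing.assert_allclose(back.df[col], ds.df[col], rtol=1e-12)


class TestNPFilter:
    def test_strict_inequality_at_threshold(self):
        ds = build_dataset(
            [{"species": "A", "site_id": "s1", "leaf_n": r, "leaf_p": 1.0}
             for r in (10.0, 69.9, 70.0, 70.1)]
        )
        out, report = filter_np_outliers(ds)
        assert sorted(out.df["np_ratio"]) == [10.0, 69.9, 70.0]
        assert report.n_removed == 1

    def test_no_outliers_is_identity(self, random_dataset):
        out, report = filter_np_outliers(random_dataset)
        assert report.fraction_removed == 0.0
        assert out.n_records == random_dataset.n_records

    def test_planted_fraction_on_large_fixture(self):
        rng = np.random.default_rng(0)
        n = 10_000
        leaf_n = rng.lognormal(3.0, 0.3, n)
        leaf_p = leaf_n / rng.uniform(5, 40, n)  # ratios in (5, 40)
        rows = pd.DataFrame({
            "record_id": [f"r{i}" for i in range(n)],
            "species": "A", "site_id": "s1", "leaf_n": leaf_n, "leaf_p": leaf_p,
        })
        rows["np_ratio"] = rows["leaf_n"] / rows["leaf_p"]
        planted = rng.choice(n, 4, replace=False)
        rows.loc[planted, "leaf_p"] = rows.loc[planted, "leaf_n"] / 80.0
        rows["np_ratio"] = rows["leaf_n"] / rows["leaf_p"]
        ds = Dataset(rows)
        out, report = filter_np_outliers(ds)
        # independent oracle: direct scan
        assert report.n_removed == int((rows["np_ratio"] > 70).sum()) == 4
        assert report.fraction_removed == 0.0004

    def test_idempotent(self, random_dataset):
        once, _ = filter_np_outliers(random_dataset, threshold=25)
        twice, rep = filter_np_outliers(once, threshold=25)
        assert rep.n_removed == 0
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestOccurrenceFilter:
    def test_all_well_replicated_retained(self):
        rows = [
            {"species": f"sp{i}", "site_id": f"s{j}", "leaf_n": 20.0, "leaf_p": 1.0}
            for i in range(6) for j in range(6)
        ]
        ds = build_dataset(rows)
        out, report = filter_occurrence(ds)
        assert report.n_removed == 0
        assert out.n_records == 36

    def test_lonely_species_removed_by_site_criterion(self):
        rows = [
            {"species": "loner", "site_id": f"s{j}", "leaf_n": 20.0, "leaf_p": 1.0}
            for j in range(10)
        ]
        # a well-mixed block so the filter has survivors
        rows += [
            {"species": f"sp{i}", "site_id": f"t{j}", "leaf_n": 20.0, "leaf_p": 1.0}
            for i in range(5) for j in range(5)
        ]
        ds = build_dataset(rows)
        out, _ = filter_occurrence(ds)
        assert "loner" not in set(out.df["species"])
        assert out.n_records == 25

    def test_matches_brute_force_recount(self):
        ds, _ = generate(SyntheticConfig(n_species=30, n_sites=40, occupancy=0.2, seed=11))
        out, report = filter_occurrence(ds)
        df = ds.df
        sp_ok = df.groupby("species")["site_id"].nunique() >= 5
        si_ok = df.groupby("site_id")["species"].nunique() >= 5
        keep = df["species"].map(sp_ok) & df["site_id"].map(si_ok)
        assert out.n_records == int(keep.sum())
        assert report.n_removed == int((~keep).sum())
        assert report.fraction_removed == report.n_removed / len(df)

    def test_iterated_is_subset_of_single_pass(self):
        ds, _ = generate(SyntheticConfig(n_species=30, n_sites=40, occupancy=0.18, seed=3))
        single, _ = filter_occurrence(ds)
        iterated, _ = filter_occurrence(ds, iterate=True)
        assert set(iterated.df["record_id"]) <= set(single.df["record_id"])
        # fixed point: re-filtering the iterated output removes nothing
        again, rep = filter_occurrence(iterated, iterate=True)
        assert rep.n_removed == 0

    def test_empty_result_raises(self):
        ds = build_dataset(
            [{"species": "A", "site_id": "s1", "leaf_n": 20.0, "leaf_p": 1.0}]
        )
        with pytest.raises(dsm.EmptyResultError):
            filter_occurrence(ds)

    def test_filter_order_matters(self):
        # a record with extreme N:P that props up a species' site count:
        # N:P-first removes the record, then the species fails the filter
        rows = [
            {"species": "X", "site_id": f"s{j}", "leaf_n": 20.0, "leaf_p": 1.0}
            for j in range(4)
        ]
        rows.append({"species": "X", "site_id": "s4", "leaf_n": 80.0, "leaf_p": 1.0})
        rows += [
            {"species": f"sp{i}", "site_id": f"s{j}", "leaf_n": 20.0, "leaf_p": 1.0}
            for i in range(5) for j in range(5)
        ]
        ds = build_dataset(rows)
        np_first, _ = filter_occurrence(filter_np_outliers(ds)[0])
        occ_first, _ = filter_np_outliers(filter_occurrence(ds)[0])
        assert "X" not in set(np_first.df["species"])
        assert "X" in set(occ_first.df["species"])


class TestAggregation:
    def test_site_mean_of_two_records(self):
        ds = build_dataset([
            {"species": "A", "site_id": "s1", "leaf_n": 10.0, "leaf_p": 1.0},
            {"species": "B", "site_id": "s1", "leaf_n": 20.0, "leaf_p": 1.0},
        ])
        agg = aggregate_sites(ds)
        assert agg.loc["s1", "leaf_n"] == 15.0
        assert agg.loc["s1", "n_species"] == 2

    def test_single_record_site_equals_record(self, random_dataset):
        one = Dataset(random_dataset.df.iloc[:1].copy(), random_dataset.covariate_names)
        agg = aggregate_sites(one)
        assert agg.iloc[0]["leaf_n"] == one.df.iloc[0]["leaf_n"]

    def test_matches_groupby_oracle(self):
        ds, _ = generate(SyntheticConfig(n_species=25, n_sites=50, occupancy=0.5,
                                         occupancy_mode="random", seed=5))
        agg = aggregate_sites(ds)
        oracle = ds.df.groupby("site_id")["leaf_n"].mean()
        np.testing.assert_allclose(agg["leaf_n"].sort_index(), oracle.sort_index(), rtol=1e-12)

    def test_species_means_weighting_differs_when_unbalanced(self):
        ds = build_dataset([
            {"species": "A", "site_id": "s1", "leaf_n": 10.0, "leaf_p": 1.0},
            {"species": "A", "site_id": "s1", "leaf_n": 10.0, "leaf_p": 1.0},
            {"species": "B", "site_id": "s1", "leaf_n": 40.0, "leaf_p": 1.0},
        ])
        assert aggregate_sites(ds).loc["s1", "leaf_n"] == 20.0
        assert aggregate_sites(ds, weighting="species_means").loc["s1", "leaf_n"] == 25.0

    def test_grand_mean_preserved_under_record_weighting(self, random_dataset):
        agg = aggregate_sites(random_dataset)
        weighted = (agg["leaf_n"] * agg["n_records"]).sum() / agg["n_records"].sum()
        assert weighted == pytest.approx(random_dataset.df["leaf_n"].mean(), rel=1e-12)


class TestModifications:
    def test_center_within_species_toy(self, toy_two_species):
        out = center_within_species(toy_two_species, traits=["leaf_n"])
        a = out.df.loc[out.df["species"] == "A", "leaf_n"].to_numpy()
        np.testing.assert_allclose(sorted(a), [-1.0, 1.0])

    def test_single_record_species_center_to_zero(self):
        ds = build_dataset([
            {"species": f"sp{i}", "site_id": "s1", "leaf_n": float(10 + i), "leaf_p": 1.0}
            for i in range(4)
        ])
        out = center_within_species(ds, traits=["leaf_n"])
        np.testing.assert_allclose(out.df["leaf_n"], 0.0)

    def test_centered_variance_is_within_ss_over_n(self, random_dataset):
        out = center_within_species(random_dataset, traits=["leaf_n"])
        df = random_dataset.df
        within_ss = ((df["leaf_n"] - df.groupby("species")["leaf_n"].transform("mean")) ** 2).sum()
        assert np.var(out.df["leaf_n"]) == pytest.approx(within_ss / len(df), rel=1e-10)

    def test_replace_with_species_means_toy(self, toy_two_species):
        out = replace_with_species_means(toy_two_species, traits=["leaf_n"])
        assert (out.df.loc[out.df["species"] == "A", "leaf_n"] == 2.0).all()
        assert (out.df.loc[out.df["species"] == "B", "leaf_n"] == 10.0).all()
        summ = species_summaries(toy_two_species)
        assert summ.loc["A", "leaf_n"] == 2.0

    def test_replace_preserves_grand_mean(self, random_dataset):
        out = replace_with_species_means(random_dataset, traits=["leaf_n"])
        assert out.df["leaf_n"].mean() == pytest.approx(
            random_dataset.df["leaf_n"].mean(), rel=1e-12)

    def test_normalize_to_global_mean_formula(self, toy_two_species):
        # x' = x - species mean + grand mean; grand mean = (1+3+10+10)/4 = 6
        out = normalize_to_global_mean(toy_two_species, traits=["leaf_n"])
        a = sorted(out.df.loc[out.df["species"] == "A", "leaf_n"])
        b = sorted(out.df.loc[out.df["species"] == "B", "leaf_n"])
        np.testing.assert_allclose(a, [5.0, 7.0])
        np.testing.assert_allclose(b, [6.0, 6.0])
        means = out.df.groupby("species")["leaf_n"].mean()
        np.testing.assert_allclose(means, 6.0, atol=1e-10)

    def test_normalize_single_species_is_identity(self):
        ds = build_dataset([
            {"species": "A", "site_id": f"s{j}", "leaf_n": v, "leaf_p": 1.0}
            for j, v in enumerate([3.0, 5.0, 9.0])
        ])
        out = normalize_to_global_mean(ds, traits=["leaf_n"])
        np.testing.assert_allclose(out.df["leaf_n"], ds.df["leaf_n"])

    def test_center_and_normalize_differ_by_grand_mean(self, random_dataset):
        centered = center_within_species(random_dataset, traits=["leaf_n"])
        normalized = normalize_to_global_mean(random_dataset, traits=["leaf_n"])
        diff = normalized.df["leaf_n"] - centered.df["leaf_n"]
        np.testing.assert_allclose(diff, random_dataset.df["leaf_n"].mean(), rtol=1e-12)


class TestTransforms:
    def test_log_transform_values(self):
        ds = build_dataset([
            {"species": "A", "site_id": "s1", "leaf_n": float(np.e), "leaf_p": 1.0},
        ])
        out = log_transform(ds, traits=["leaf_n", "leaf_p"])
        assert out.df["leaf_n"].iloc[0] == pytest.approx(1.0)
        assert out.df["leaf_p"].iloc[0] == 0.0

    def test_log_transform_rejects_nonpositive(self, toy_two_species):
        ds = center_within_species(toy_two_species)  # introduces non-positives
        with pytest.raises(ValueError, match="record"):
            log_transform(ds, traits=["leaf_n"])

    def test_yeo_johnson_closed_forms(self):
        x = np.array([0.0, 0.5, 1.0, 4.0])
        # lambda = 1: identity on nonnegative input
        from scipy.stats import yeojohnson as yj
        np.testing.assert_allclose(yj(x, 1.0), x)
        # lambda = 0: log1p on nonnegative input
        np.testing.assert_allclose(yj(x, 0.0), np.log1p(x))

    def test_yeo_johnson_reduces_skew_and_inverts(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0.0, 1.0, 2000)
        res = yeo_johnson(x)
        from scipy.stats import skew
        assert abs(skew(res.values)) < abs(skew(x))
        back = yeo_johnson_inverse(res.values, res.lmbda)
        np.testing.assert_allclose(back, x, rtol=1e-8)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(min_value=0.1, max_value=200.0), min_size=2, max_size=40),
       st.floats(min_value=5.0, max_value=100.0))
def test_np_filter_idempotent_property(ratios, threshold):
    ds = build_dataset([
        {"species": "A", "site_id": "s1", "leaf_n": r, "leaf_p": 1.0} for r in ratios
    ])
    try:
        once, _ = filter_np_outliers(ds, threshold=threshold)
    except Exception:
        return
    twice, rep = filter_np_outliers(once, threshold=threshold)
    assert rep.n_removed == 0
    assert (once.df["np_ratio"] <= threshold).all()
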