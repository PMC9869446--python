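import io
import math

import numpy as np
import pandas as pd
import pytest

from hiveforage import interactions as ia


@pytest.fixture()
def coded(toy_interactions):
    return ia.code_complexity(toy_interactions)


class TestReadInteractions:
    def test_round_trips_through_csv(self, toy_interactions):
        buf = io.StringIO()
        toy_interactions.to_csv(buf, index=False)
        buf.seek(0)
        df = ia.read_interactions(buf)
        assert len(df) == len(toy_interactions)
        assert set(df["sociality"]) == {"eusocial", "solitary"}

    def test_missing_columns_named(self):
        buf = io.StringIO("bee_species,sociality\nA,eusocial\n")
        with pytest.raises(ValueError, match="plant_species"):
            ia.read_interactions(buf)

    def test_empty_file_with_header_ok(self):
        cols = "bee_species,sociality,plant_species,symmetry"
        df = ia.read_interactions(io.StringIO(cols + "\n"))
        assert df.empty

    def test_intermediate_sociality_dropped(self, toy_interactions):
        extra = toy_interactions.copy()
        extra.loc[len(extra)] = ["X", "Xg", "subsocial", 3.0, "radial", 1.0,
                                 "Plant_x", 1, 1]
        buf = io.StringIO()
        extra.to_csv(buf, index=False)
        buf.seek(0)
        assert len(ia.read_interactions(buf)) == len(toy_interactions)

    def test_nonpositive_proboscis_rejected(self):
        buf = io.StringIO(
            "bee_species,sociality,plant_species,symmetry,proboscis_mm\n"
            "A,eusocial,P,radial,-2.0\n"
        )
        with pytest.raises(ValueError, match="proboscis"):
            ia.read_interactions(buf)


class TestComplexityCoding:
    def test_three_mm_is_shallow(self):
        df = pd.DataFrame(
            {"bee_species": ["a", "a"], "sociality": ["solitary"] * 2,
             "plant_species": ["p", "p"], "symmetry": ["radial"] * 2,
             "corolla_mm": [3.0, 3.0 + 1e-9], "proboscis_mm": [2.0, 2.0]}
        )
        out = ia.code_complexity(df)
        assert list(out["is_deep"]) == [0.0, 1.0]

    def test_missing_corolla_is_na(self, toy_interactions):
        df = toy_interactions.copy()
        df.loc[0, "corolla_mm"] = np.nan
        out = ia.code_complexity(df)
        assert math.isnan(out.loc[0, "is_deep"])


class TestComplexityCounts:
    def test_counts_partition_visits(self, coded):
        counts = ia.complexity_counts(coded)
        assert counts["radial"] == 6 and counts["bilateral"] == 4
        assert counts.sum() == len(coded)

    def test_single_row(self):
        df = pd.DataFrame({"symmetry": ["radial"]})
        counts = ia.complexity_counts(df)
        assert counts["radial"] == 1 and counts["bilateral"] == 0


class TestPerSpeciesProportions:
    def test_species_level_values(self, coded):
        species, groups = ia.per_species_proportions(coded, "bilateral")
        sp = species.set_index("bee_species")["proportion"]
        assert sp["Apis_a"] == pytest.approx(0.75)
        assert sp["Andrena_b"] == pytest.approx(0.5)
        assert sp["Halictus_c"] == pytest.approx(0.0)
        g = groups.set_index("sociality")
        assert g.loc["eusocial", "mean"] == pytest.approx(0.75)
        assert g.loc["solitary", "mean"] == pytest.approx(0.25)
        # two solitary species at 0.5 and 0.0: sd(ddof=1)/sqrt(2)
        assert g.loc["solitary", "se"] == pytest.approx(
            np.std([0.5, 0.0], ddof=1) / np.sqrt(2)
        )

    def test_single_species_group_has_no_se(self, coded):
        _, groups = ia.per_species_proportions(coded, "bilateral")
        g = groups.set_index("sociality")
        assert g.loc["eusocial", "n_species"] == 1
        assert math.isnan(g.loc["eusocial", "se"])

    def test_invariant_to_row_order_and_duplication(self, coded):
        shuffled = coded.sample(frac=1.0, random_state=3).reset_index(drop=True)
        tripled = pd.concat([coded] * 3, ignore_index=True)
        base = ia.per_species_proportions(coded, "bilateral")[1]
        for variant in (shuffled, tripled):
            got = ia.per_species_proportions(variant, "bilateral")[1]
            pd.testing.assert_frame_equal(
                got.sort_values("sociality").reset_index(drop=True),
                base.sort_values("sociality").reset_index(drop=True),
            )

    def test_deep_trait_uses_strict_threshold(self, coded):
        species, _ = ia.per_species_proportions(coded, "deep")
        sp = species.set_index("bee_species")["proportion"]
        # Andrena_b visits: 5 mm (deep) and 3 mm (shallow)
        assert sp["Andrena_b"] == pytest.approx(0.5)


class TestGroupMeanCorolla:
    def test_species_and_visit_conventions(self, coded):
        _, groups = ia.group_mean_corolla(coded)
        g = groups.set_index("sociality")
        assert g.loc["eusocial", "species_mean_mm"] == pytest.approx(5.0)
        # solitary species means: 4.0 and 2.0 -> group mean 3.0
        assert g.loc["solitary", "species_mean_mm"] == pytest.approx(3.0)
        assert g.loc["solitary", "visit_mean_mm"] == pytest.approx(
            np.mean([5.0, 3.0, 1.0, 2.0, 3.0, 2.0])
        )

    def test_constant_corolla_zero_se(self):
        df = pd.DataFrame(
            {"bee_species": list("aabb"), "sociality": ["solitary"] * 4,
             "plant_species": ["p"] * 4, "symmetry": ["radial"] * 4,
             "corolla_mm": [2.0] * 4, "proboscis_mm": [3.0] * 4}
        )
        _, groups = ia.group_mean_corolla(df)
        assert groups["species_mean_mm"].iloc[0] == 2.0
        assert groups["species_se_mm"].iloc[0] == 0.0


class TestSizeClassSummary:
    def test_shares_sum_to_one_per_flower_class(self, coded):
        out = ia.size_class_summary(coded).set_index("size_class")
        for col in out.columns:
            assert out[col].sum() == pytest.approx(1.0)

    def test_single_bin_table(self):
        df = pd.DataFrame(
            {"bee_species": ["a"] * 3, "sociality": ["solitary"] * 3,
             "plant_species": ["p"] * 3, "symmetry": ["radial"] * 3,
             "corolla_mm": [1.0] * 3, "proboscis_mm": [2.0, 2.5, 1.0]}
        )
        out = ia.size_class_summary(df).set_index("size_class")
        assert out.loc["0-3", "share_of_radial_visits"] == pytest.approx(1.0)

    def test_boundary_12mm_in_top_bin(self, coded):
        df = coded.copy()
        df.loc[0, "proboscis_mm"] = 12.0
        out = ia.size_class_summary(df).set_index("size_class")
        assert out.loc["9-12", "share_of_bilateral_visits"] > 0


class TestChoiceRegression:
    def test_balanced_toy_gives_null_coefficients(self):
        rows = []
        for soc in ("solitary", "eusocial"):
            for prob in (2.0, 8.0):
                for sym in ("radial", "bilateral"):
                    for _ in range(3):
                        rows.append((f"sp_{soc}_{prob}", soc, prob, "p", sym, 1.0))
        df = pd.DataFrame(rows, columns=["bee_species", "sociality",
                                         "proboscis_mm", "plant_species",
                                         "symmetry", "corolla_mm"])
        tab = ia.fit_choice_regression(df, "bilateral").set_index("term")
        assert np.all(np.abs(tab["coef"]) < 1e-6)

    def test_recovers_known_positive_effect(self):
        from hiveforage.synth import GeneratorSpec, generate_interactions

        hits = 0
        for seed in range(10):
            spec = GeneratorSpec(seed=seed, symmetry_coefs=(-1.5, 0.0, 0.3, 0.0),
                                 phylo_signal=0.0, visits_mean=150)
            table, _, _ = generate_interactions(spec)
            tab = ia.fit_choice_regression(table, "bilateral").set_index("term")
            hits += tab.loc["proboscis_mm", "coef"] > 0
        assert hits == 10

    def test_separation_flagged(self):
        n = 40
        prob = np.linspace(1, 10, n)
        df = pd.DataFrame(
            {"bee_species": [f"s{i}" for i in range(n)],
             "sociality": ["solitary"] * n,
             "proboscis_mm": prob,
             "plant_species": ["p"] * n,
             "symmetry": np.where(prob > 5, "bilateral", "radial"),
             "corolla_mm": 1.0}
        )
        tab = ia.fit_choice_regression(df, "bilateral")
        assert tab.attrs["separation"]

    def test_empty_input_raises(self):
        df = pd.DataFrame(columns=["bee_species", "sociality", "proboscis_mm",
                                   "plant_species", "symmetry", "corolla_mm"])
        with pytest.raises(ValueError):
            ia.fit_choice_regression(df, "bilateral")
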