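import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from designvar.exposure_analysis import (
    class_aa_frequencies,
    class_entropy_by_protein,
    class_entropy_summary,
    entropy_rsa_correlation,
    join_site_table,
    paired_comparison,
    summarize_conditions,
)
from designvar.msa_io import Alignment, build_site_map, column_counts
from designvar.site_statistics import EntropyVector, site_entropy, site_frequencies
from designvar.solvent_accessibility import RSAProfile, THREE_CLASS, TWO_CLASS


def make_table(rsa, entropy, condition="x"):
    return pd.DataFrame({"rsa": rsa, f"entropy_{condition}": entropy})


def profile_from(rsas):
    return RSAProfile([(i + 1, "A", None, r) for i, r in enumerate(rsas)])


class TestJoinSiteTable:
    def test_join_is_lossless_modulo_exclusions(self):
        rsa = profile_from([0.1, 0.2, 0.3])
        positions = np.array([1, 2, 3, 4])  # position 4 missing from RSA
        ev = EntropyVector(np.array([0.5, 0.6, 0.7, 0.8]))
        table = join_site_table({"n": ev}, positions, rsa)
        assert len(table) == 3
        assert table["position"].tolist() == [1, 2, 3]
        assert table["entropy_n"].tolist() == [0.5, 0.6, 0.7]

    def test_exposure_classes_assigned(self):
        rsa = profile_from([0.01, 0.1, 0.5])
        ev = EntropyVector(np.zeros(3))
        table = join_site_table({"n": ev}, np.array([1, 2, 3]), rsa, THREE_CLASS)
        assert table["exposure_class"].tolist() == [
            "buried",
            "partially_buried",
            "exposed",
        ]


class TestEntropyRsaCorrelation:
    def test_perfect_linear_relation(self):
        rsa = np.linspace(0.1, 1.0, 10)
        table = make_table(rsa, 2 * rsa)
        for method in ("pearson", "spearman"):
            res = entropy_rsa_correlation(table, "x", method)
            assert res.coefficient == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        rsa = np.linspace(0.1, 1.0, 10)
        res = entropy_rsa_correlation(make_table(rsa, 1.5 - rsa), "x")
        assert res.coefficient == pytest.approx(-1.0)

    def test_matches_product_moment_formula(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(50), rng.random(50)
        res = entropy_rsa_correlation(make_table(x, y), "x")
        # independent hand-rolled product-moment loop
        mx, my = sum(x) / 50, sum(y) / 50
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = (
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
        ) ** 0.5
        assert res.coefficient == pytest.approx(num / den, abs=1e-12)

    def test_constant_axis_is_error_not_zero(self):
        table = make_table(np.full(5, 0.3), np.arange(5.0))
        with pytest.raises(ValueError, match="undefined"):
            entropy_rsa_correlation(table, "x")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariance_under_rsa_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(30)
        y = rng.random(30)
        base_p = entropy_rsa_correlation(make_table(x, y), "x", "pearson").coefficient
        base_s = entropy_rsa_correlation(make_table(x, y), "x", "spearman").coefficient
        # positive affine transform leaves pearson unchanged
        aff = entropy_rsa_correlation(make_table(3.2 * x + 0.7, y), "x", "pearson")
        assert aff.coefficient == pytest.approx(base_p, abs=1e-9)
        # strictly monotone transform leaves spearman unchanged
        mono = entropy_rsa_correlation(make_table(np.exp(2 * x), y), "x", "spearman")
        assert mono.coefficient == pytest.approx(base_s, abs=1e-9)


class TestClassEntropySummary:
    def test_one_site_per_class(self):
        rsa = profile_from([0.01, 0.1, 0.5])
        ev = EntropyVector(np.array([0.1, 0.5, 1.2]))
        table = join_site_table({"n": ev}, np.array([1, 2, 3]), rsa, THREE_CLASS)
        frame = class_entropy_by_protein(table, ["n"], THREE_CLASS)
        assert frame["mean_entropy"].tolist() == pytest.approx([0.1, 0.5, 1.2])

    def test_single_protein_median_equals_its_means(self):
        rsa = profile_from([0.01, 0.1, 0.5])
        ev = EntropyVector(np.array([0.1, 0.5, 1.2]))
        table = join_site_table({"n": ev}, np.array([1, 2, 3]), rsa, THREE_CLASS)
        frame = class_entropy_by_protein(table, ["n"], THREE_CLASS)
        summary = class_entropy_summary([frame])
        assert summary["median"].tolist() == pytest.approx([0.1, 0.5, 1.2])

    def test_natural_scenario_class_ordering(self, default_scenario):
        """Exposed sites are more variable than partial, which beat buried."""
        natural = default_scenario["natural"]
        rsa = default_scenario["rsa"]
        smap = build_site_map(natural)
        counts = column_counts(natural, smap)
        ev = site_entropy(site_frequencies(counts))
        table = join_site_table({"natural": ev}, counts.positions, rsa, THREE_CLASS)
        frame = class_entropy_by_protein(table, ["natural"], THREE_CLASS)
        by_class = dict(zip(frame["exposure_class"], frame["mean_entropy"]))
        assert by_class["exposed"] > by_class["partially_buried"] > by_class["buried"]


class TestClassAaFrequencies:
    def test_single_buried_leu_column(self):
        aln = Alignment([("r", "L"), ("a", "L"), ("b", "L")], "r")
        smap = build_site_map(aln)
        rsa = profile_from([0.01])
        frame = class_aa_frequencies([aln], [smap], [rsa], TWO_CLASS)
        buried = frame[frame["exposure_class"] == "buried"].set_index("aa")
        assert buried.loc["L", "frequency"] == 1.0
        exposed = frame[frame["exposure_class"] == "exposed"]
        assert exposed["frequency"].isna().all()  # empty class flagged as missing

    def test_pooling_across_proteins(self):
        aln1 = Alignment([("r", "A"), ("a", "A")], "r")
        aln2 = Alignment([("r", "A"), ("a", "A")], "r")
        maps = [build_site_map(aln1), build_site_map(aln2)]
        rsas = [profile_from([0.8]), profile_from([0.9])]
        frame = class_aa_frequencies([aln1, aln2], maps, rsas, TWO_CLASS)
        exposed = frame[frame["exposure_class"] == "exposed"].set_index("aa")
        assert exposed.loc["A", "frequency"] == 1.0

    def test_class_vectors_sum_to_one(self, default_scenario):
        natural = default_scenario["natural"]
        smap = build_site_map(natural)
        frame = class_aa_frequencies(
            [natural], [smap], [default_scenario["rsa"]], TWO_CLASS
        )
        sums = frame.groupby("exposure_class")["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_design_set_has_zero_cys_everywhere(self, default_scenario):
        design = default_scenario["designs"][0.6]
        smap = build_site_map(design)
        frame = class_aa_frequencies(
            [design], [smap], [default_scenario["rsa"]], TWO_CLASS
        )
        cys = frame[frame["aa"] == "C"]["frequency"]
        assert (cys.dropna() == 0).all()

    def test_mismatched_lists_rejected(self):
        aln = Alignment([("r", "A"), ("a", "A")], "r")
        with pytest.raises(ValueError):
            class_aa_frequencies([aln], [], [profile_from([0.5])])

    def test_buried_hydrophobic_enrichment(self, default_scenario):
        """Generator reproduces core hydrophobic enrichment in pooled frequencies."""
        natural = default_scenario["natural"]
        smap = build_site_map(natural)
        frame = class_aa_frequencies(
            [natural], [smap], [default_scenario["rsa"]], TWO_CLASS
        )
        hydro = set("AVILMFWYC")
        pivot = frame.pivot(index="aa", columns="exposure_class", values="frequency")
        buried_h = pivot.loc[list(hydro & set(pivot.index)), "buried"].sum()
        exposed_h = pivot.loc[list(hydro & set(pivot.index)), "exposed"].sum()
        assert buried_h > exposed_h


class TestSummarizeConditions:
    def test_textbook_quartiles(self):
        df = pd.DataFrame(
            {
                "protein_id": [f"p{i}" for i in range(5)],
                "condition": ["c"] * 5,
                "metric": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        out = summarize_conditions(df, ["metric"])
        row = out.iloc[0]
        assert (row["median"], row["q1"], row["q3"]) == (3.0, 2.0, 4.0)

    def test_single_protein_collapses_quartiles(self):
        df = pd.DataFrame(
            {"protein_id": ["p"], "condition": ["c"], "metric": [0.42]}
        )
        row = summarize_conditions(df, ["metric"]).iloc[0]
        assert row["min"] == row["q1"] == row["median"] == row["q3"] == row["max"] == 0.42


class TestPairedComparison:
    def test_basic_shape(self):
        rng = np.random.default_rng(0)
        x = rng.random(10)
        y = x + 0.5 + rng.normal(0, 0.01, 10)
        out = paired_comparison(x, y)
        assert out["mean_diff"] == pytest.approx(np.mean(x - y))
        assert 0 <= out["p"] <= 1
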