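"""In-silico expectation, deviation normalization, origin classes, amounts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatscape.comparative import (
    additivity_report,
    classify_parental_origin,
    flag_deviating_clusters,
    in_silico_expectation,
    normalized_deviation,
    proportions_to_amounts,
)
from repeatscape.reference import (
    GENOME_SIZES,
    POLYPLOIDS,
    genome_size_summaries,
    repeat_proportions,
)

prop = st.floats(0.0, 1.0, allow_nan=False)


class TestInSilicoExpectation:
    def test_total_repeat_expectation(self):
        """Parental totals and 1C sizes give the published 72.5% additive null."""
        assert in_silico_expectation(0.710, 0.738, 2.865, 3.52) == pytest.approx(
            0.7254, abs=5e-4
        )

    def test_equal_parents_identity(self):
        assert in_silico_expectation(0.3, 0.3, 1.7, 9.2) == pytest.approx(0.3)

    def test_size_weighting(self):
        assert in_silico_expectation(0.0, 0.10, 1.0, 3.0) == pytest.approx(0.075)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            in_silico_expectation(0.1, 0.2, 0.0, 3.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(pm=prop, pp=prop, gm=st.floats(0.1, 30), gp=st.floats(0.1, 30))
    def test_convex_combination(self, pm, pp, gm, gp):
        e = in_silico_expectation(pm, pp, gm, gp)
        assert min(pm, pp) - 1e-12 <= e <= max(pm, pp) + 1e-12


class TestNormalizedDeviation:
    @pytest.mark.parametrize(
        "obs, exp, value",
        [(0.3, 0.3, 0.0), (0.0, 0.4, -1.0), (0.2, 0.1, 0.5), (0.0, 0.0, 0.0)],
    )
    def test_anchor_points(self, obs, exp, value):
        assert normalized_deviation(obs, exp) == pytest.approx(value)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(o=st.floats(0, 1), e=st.floats(0, 1))
    def test_bounded_antisymmetric_zero_iff_equal(self, o, e):
        d = normalized_deviation(o, e)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-normalized_deviation(e, o))
        if o != e:
            assert d != 0.0


class TestParentalOrigin:
    @pytest.mark.parametrize(
        "pm, pp, expected",
        [
            (0.036, 0.005, "maternal-larger"),   # the MITE-like contrast
            (0.010, 0.010, "similar"),
            (0.010, 0.0125, "paternal-larger"),  # 0.0025/0.0125 = 20%, inclusive
            (0.010, 0.0124, "similar"),
        ],
    )
    def test_classes_and_boundary(self, pm, pp, expected):
        assert classify_parental_origin(pm, pp) == expected

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            classify_parental_origin(0.0, 0.0)


def brute_force_flags(table, min_prop, dev_thr, origin_thr):
    """Row-by-row literal evaluation of the filtering and retention rules."""
    m, p = table.attrs["maternal"], table.attrs["paternal"]
    polys = table.attrs["polyploids"]
    out = {}
    for cid, row in table.iterrows():
        values = [row[m], row[p]] + [row[q] for q in polys]
        if max(values) < min_prop:
            continue
        big, small = max(row[m], row[p]), min(row[m], row[p])
        if (big - small) / big >= origin_thr:
            origin = "maternal-larger" if row[m] > row[p] else "paternal-larger"
        else:
            origin = "similar"
        retained = False
        for q in polys:
            e, o = row["in_silico"], row[q]
            if (e == 0 and o > 0) or (e > 0 and abs(o - e) / e > dev_thr):
                retained = True
        out[cid] = (origin, retained)
    return out


def random_table(rng, n_clusters):
    polys = ["q1", "q2"]
    gm, gp = rng.uniform(0.5, 5), rng.uniform(0.5, 5)
    rows = {}
    for sp in ["m", "p", *polys]:
        vals = rng.uniform(0, 0.05, n_clusters)
        vals[rng.random(n_clusters) < 0.3] *= 0.02  # push some below min_proportion
        rows[sp] = vals
    table = pd.DataFrame(rows)
    # avoid the degenerate both-parents-zero case the classifier rejects
    table.loc[(table["m"] == 0) & (table["p"] == 0), "m"] = 1e-6
    table["in_silico"] = (table["m"] * gm + table["p"] * gp) / (gm + gp)
    table["lineage"] = "unclassified"
    table.index.name = "cluster_id"
    table.attrs.update(maternal="m", paternal="p", polyploids=polys)
    return table


class TestFlagDeviatingClusters:
    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            table = random_table(rng, int(rng.integers(1, 50)))
            records = flag_deviating_clusters(table)
            expected = brute_force_flags(table, 0.001, 0.20, 0.20)
            assert {r.cluster_id for r in records} == set(expected)
            for r in records:
                assert (r.parental_origin, r.retained) == expected[r.cluster_id]

    def test_additive_cluster_not_retained(self):
        table = random_table(np.random.default_rng(15), 5)
        for q in table.attrs["polyploids"]:
            table[q] = table["in_silico"]
        assert not any(r.retained for r in flag_deviating_clusters(table))

    def test_uniformly_rare_cluster_dropped(self):
        table = random_table(np.random.default_rng(16), 3)
        table.loc[:, ["m", "p", "q1", "q2", "in_silico"]] = 0.0005
        assert flag_deviating_clusters(table) == []

    def test_table_tsv_round_trip(self, tmp_path):
        from repeatscape.comparative import read_comparative_table

        table = random_table(np.random.default_rng(19), 8)
        path = tmp_path / "clusters.tsv"
        table.to_csv(path, sep="\t")
        back = read_comparative_table(path, "m", "p", ["q1", "q2"])
        ref, again = flag_deviating_clusters(table), flag_deviating_clusters(back)
        assert [(r.cluster_id, r.parental_origin, r.retained) for r in ref] == [
            (r.cluster_id, r.parental_origin, r.retained) for r in again
        ]

    def test_missing_in_silico_rejected(self):
        table = random_table(np.random.default_rng(17), 3).drop(columns="in_silico")
        with pytest.raises(ValueError):
            flag_deviating_clusters(table)

    def test_deviations_reported_per_polyploid(self):
        table = random_table(np.random.default_rng(18), 1)
        table.loc[0, ["m", "p", "in_silico", "q1", "q2"]] = [0.02, 0.02, 0.02, 0.04, 0.01]
        (rec,) = flag_deviating_clusters(table)
        assert rec.deviation["q1"] == pytest.approx(0.5)
        assert rec.deviation["q2"] == pytest.approx(-0.5)
        assert rec.retained


class TestAmounts:
    def test_haploid_total_repeat_amounts(self):
        assert proportions_to_amounts(0.710, 2.865) == pytest.approx(2.03, abs=0.005)

    def test_mite_like_diploid_amounts(self):
        assert proportions_to_amounts(0.036, 5.73) * 1000 == pytest.approx(206.3, abs=0.05)
        assert proportions_to_amounts(0.005, 7.04) * 1000 == pytest.approx(35.2, abs=0.05)

    def test_zero_proportion(self):
        assert proportions_to_amounts(0.0, 14.2) == 0.0


class TestAdditivityReport:
    """The published genome sizes + proportion table reproduce the in-text
    derived amounts (printed rounding)."""

    @pytest.fixture(scope="class")
    def report(self):
        return additivity_report(
            repeat_proportions(), genome_size_summaries(), "fuc", "inc", list(POLYPLOIDS)
        )

    def test_parental_totals_1c(self, report):
        a = report["amounts_1c_gbp"]
        assert a.loc["Total repeats", "fuc"] == pytest.approx(2.03, abs=0.005)
        assert a.loc["Total repeats", "inc"] == pytest.approx(2.60, abs=0.005)

    def test_max_total_repeat_difference_among_polyploids(self, report):
        assert report["max_polyploid_diff_2c_gbp"]["Total repeats"] == pytest.approx(
            1.24, abs=0.005
        )
        assert report["max_polyploid_diff_pair"]["Total repeats"] == "pra vs pur"

    def test_tandem_repeat_difference(self, report):
        assert report["max_polyploid_diff_2c_gbp"]["Tandem repeats"] * 1000 == pytest.approx(
            816, abs=0.5
        )

    def test_identical_columns_no_differences(self):
        props = repeat_proportions()
        for sp in POLYPLOIDS:
            props[sp] = props["pur"]
        rep = additivity_report(props, genome_size_summaries(), "fuc", "inc", ["pur", "bal"])
        sizes_equal = GENOME_SIZES.loc["pur", "size_2c_gbp"] == GENOME_SIZES.loc["bal", "size_2c_gbp"]
        if not sizes_equal:  # equal proportions but different sizes still differ in Gbp
            assert (rep["max_polyploid_diff_2c_gbp"] >= 0).all()
        same = additivity_report(
            props.assign(bal=props["pur"]),
            {**genome_size_summaries(), "bal": genome_size_summaries()["pur"]},
            "fuc", "inc", ["pur", "bal"],
        )
        assert np.allclose(same["max_polyploid_diff_2c_gbp"], 0.0)

    def test_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="nosuch"):
            additivity_report(
                repeat_proportions(), genome_size_summaries(), "fuc", "inc", ["nosuch"]
            )
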