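"""Flow-cytometry summaries, pg->Gbp conversion, additivity, pairwise tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatscape.genomesize import (
    CytometrySample,
    additive_expectation,
    pairwise_size_tests,
    picograms_to_gigabases,
    relative_difference,
    summarize_species,
)
from repeatscape.reference import GENOME_SIZES


def sample(sid, species, *runs, ploidy=2):
    return CytometrySample(sample_id=sid, species=species, ploidy=ploidy, runs=tuple(runs))


class TestPicogramConversion:
    @pytest.mark.parametrize(
        "pg, c_level, expected",
        [(2.93, 2, 5.73), (3.60, 2, 7.04), (0.0, 2, 0.0), (1.0, 1, 0.978)],
    )
    def test_known_values(self, pg, c_level, expected):
        assert picograms_to_gigabases(pg, c_level) == pytest.approx(expected, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            picograms_to_gigabases(-1.0, 2)

    def test_reproduces_every_published_2c_cell(self):
        """Each printed 2C (Gbp) cell follows from its 1C (pg) mean at 0.978."""
        for _, row in GENOME_SIZES.iterrows():
            computed = picograms_to_gigabases(row["mean_1c_pg"], c_level=2)
            assert computed == pytest.approx(row["size_2c_gbp"], abs=0.02)


class TestSummaries:
    def test_mean_and_sem_over_sample_means(self):
        samples = [sample("a", "sp", 2.9), sample("b", "sp", 3.0), sample("c", "sp", 2.8)]
        s = summarize_species(samples, "sp")
        assert s.mean_1c_pg == pytest.approx(2.9)
        assert s.sem_1c_pg == pytest.approx(0.1 / np.sqrt(3), abs=1e-4)

    def test_single_sample_sem_zero_with_flag(self):
        with pytest.warns(UserWarning):
            s = summarize_species([sample("a", "sp", 3.5)], "sp")
        assert (s.mean_1c_pg, s.sem_1c_pg, s.single_sample) == (3.5, 0.0, True)

    def test_runs_averaged_within_sample_first(self):
        samples = [sample("a", "sp", 2.0, 2.2), sample("b", "sp", 2.4, 2.6)]
        assert summarize_species(samples, "sp").mean_1c_pg == pytest.approx(2.3)

    def test_unknown_species_named_in_error(self):
        with pytest.raises(ValueError, match="nosuch"):
            summarize_species([sample("a", "sp", 2.0)], "nosuch")

    def test_sem_invariant_under_reordering(self):
        samples = [sample(f"s{i}", "sp", 2.0 + 0.1 * i, 2.1 + 0.1 * i) for i in range(5)]
        ref = summarize_species(samples, "sp")
        perm = summarize_species(samples[::-1], "sp")
        swapped_runs = [
            sample(s.sample_id, "sp", *s.runs[::-1]) for s in samples
        ]
        assert perm.sem_1c_pg == pytest.approx(ref.sem_1c_pg)
        assert summarize_species(swapped_runs, "sp").sem_1c_pg == pytest.approx(ref.sem_1c_pg)

    def test_invalid_samples_rejected(self):
        with pytest.raises(ValueError):
            sample("a", "sp", -2.0)
        with pytest.raises(ValueError):
            CytometrySample("a", "sp", 2, ())
        with pytest.raises(ValueError):
            sample("a", "sp", 2.0, ploidy=3)


class TestAdditiveExpectation:
    def test_single_pair_degenerate_ci(self):
        ae = additive_expectation([sample("m", "f", 2.93)], [sample("p", "i", 3.60)])
        assert ae.mean_1c_pg == pytest.approx(6.53)
        assert ae.ci_low_1c_pg == ae.ci_high_1c_pg == ae.mean_1c_pg

    def test_all_pairwise_combinations(self):
        ae = additive_expectation(
            [sample("m1", "f", 2.8), sample("m2", "f", 3.0)],
            [sample("p1", "i", 3.5), sample("p2", "i", 3.7)],
        )
        assert sorted(ae.combinations) == pytest.approx([6.3, 6.5, 6.5, 6.7])
        assert ae.mean_1c_pg == pytest.approx(6.5)
        assert ae.ci_low_1c_pg < 6.5 < ae.ci_high_1c_pg

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            additive_expectation([], [sample("p", "i", 3.6)])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        m=st.lists(st.floats(0.5, 20), min_size=1, max_size=6),
        p=st.lists(st.floats(0.5, 20), min_size=1, max_size=6),
    )
    def test_mean_is_sum_of_parent_means(self, m, p):
        """Distributivity: the combination mean equals the sum of side means."""
        ms = [sample(f"m{i}", "f", v) for i, v in enumerate(m)]
        ps = [sample(f"p{i}", "i", v) for i, v in enumerate(p)]
        ae = additive_expectation(ms, ps)
        assert ae.mean_1c_pg == pytest.approx(np.mean(m) + np.mean(p), rel=1e-9)
        assert len(ae.combinations) == len(m) * len(p)
        assert ae.ci_low_1c_pg <= ae.mean_1c_pg <= ae.ci_high_1c_pg


def brute_force_bh(pvals):
    """Step-up Benjamini-Hochberg straight from the definition."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestPairwiseTests:
    def test_identical_groups_p_near_one(self):
        samples = [sample(f"a{i}", "A", 2.0, 2.2) for i in range(3)]
        samples += [sample(f"b{i}", "B", 2.0, 2.2) for i in range(3)]
        t = pairwise_size_tests(samples)
        assert t["p_raw"].iloc[0] == pytest.approx(1.0)
        assert t["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        samples = [sample(f"a{i}", "A", 10.0 + 0.01 * rng.normal()) for i in range(5)]
        samples += [sample(f"b{i}", "B", 20.0 + 0.01 * rng.normal()) for i in range(5)]
        t = pairwise_size_tests(samples)
        assert t["p_adj"].iloc[0] < 0.001

    def test_undersampled_species_reported_untestable(self):
        samples = [sample("a1", "A", 2.0), sample("b1", "B", 3.0), sample("b2", "B", 3.1)]
        t = pairwise_size_tests(samples)
        row = t.set_index(["species_a", "species_b"]).loc[("A", "B")]
        assert not row["testable"] and np.isnan(row["p_adj"])

    def test_adjusted_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        samples = []
        for j, sp in enumerate("ABCD"):
            mu = 2.0 + 0.3 * j
            samples += [sample(f"{sp}{i}", sp, mu + 0.1 * rng.normal()) for i in range(4)]
        t = pairwise_size_tests(samples).sort_values("p_raw")
        assert t["p_adj"].is_monotonic_increasing

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_bh_matches_step_up_definition(self, pvals):
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(adj, brute_force_bh(pvals), atol=1e-12)


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "a, b, baseline, expected",
        [
            (3.60, 2.93, "smaller", 0.2287),
            (5.0, 5.0, "smaller", 0.0),
            (1.25, 1.00, "larger", 0.20),
        ],
    )
    def test_values(self, a, b, baseline, expected):
        assert relative_difference(a, b, baseline) == pytest.approx(expected, abs=1e-4)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(0.0, 0.0)
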