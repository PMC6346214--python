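import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varicourse.enrichment import (
    compare_feature,
    count_tf_per_gene,
    family_enrichment,
    fragment_gene,
    fragmentation_control,
    matched_size_subset,
    presence_enrichment,
    set_overrepresentation,
    shannon_entropy,
    tissue_specificity_entropy,
)
from varicourse.hvg import variability_table
from varicourse.quantify import compute_tpm, filter_genes
from varicourse.simulate import SimConfig, generate_dataset  # noqa: F401 (fixtures)


class TestCompareFeature:
    def test_identical_samples_non_significant(self):
        feat = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        out = compare_feature(feat, ["a", "b", "c", "d"], ["a", "b", "c", "d"])
        assert out.p == pytest.approx(1.0)

    def test_small_sample_matches_exhaustive_permutation(self):
        # {1,2} vs {3,4}: enumerate all C(4,2) group assignments of the
        # ranks; two-sided p = fraction with |rank-sum deviation| >= observed
        feat = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        values = feat.to_numpy()
        ranks = pd.Series(values).rank().to_numpy()
        observed = ranks[:2].sum()
        expected_sum = ranks.sum() / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(4), 2):
            s = ranks[list(combo)].sum()
            total += 1
            if abs(s - expected_sum) >= abs(observed - expected_sum) - 1e-12:
                count += 1
        p_oracle = count / total
        out = compare_feature(feat, ["a", "b"], ["c", "d"])
        assert out.p == pytest.approx(p_oracle)

    def test_envelope_brackets_random_medians(self):
        rng = np.random.default_rng(0)
        feat = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
        sets = [rng.choice(feat.index, 20, replace=False) for _ in range(100)]
        out = compare_feature(feat, feat.index[:20], feat.index[20:40], sets)
        lo, hi = out.envelope
        medians = [feat.loc[s].median() for s in sets]
        assert lo <= np.median(medians) <= hi

    def test_empty_set_rejected(self):
        feat = pd.Series({"a": 1.0})
        with pytest.raises(ValueError):
            compare_feature(feat, [], ["a"])


class TestTFCounts:
    def test_matches_bruteforce_scan(self):
        universe = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        targets = {f"tf{j}": set(rng.choice(universe, 4, replace=False)) for j in range(5)}
        counts = count_tf_per_gene(targets, universe)
        for g in universe:
            assert counts[g] == sum(g in t for t in targets.values())

    def test_untargeted_gene_zero_and_outside_warned(self):
        counts_args = ({"tf1": {"a", "zz"}}, ["a", "b"])
        with pytest.warns(UserWarning, match="outside the universe"):
            counts = count_tf_per_gene(*counts_args)
        assert counts["b"] == 0 and counts["a"] == 1


class TestOverrepresentation:
    def test_annotation_equal_universe_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = set_overrepresentation(universe[:10], {"all": universe}, universe)
        assert out.loc["all", "p"] == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        # universe 20, query 10, annotation 10, overlap 10:
        # p = C(10,10) C(10,0) / C(20,10)
        universe = [f"g{i}" for i in range(20)]
        query = universe[:10]
        out = set_overrepresentation(query, {"s": query}, universe)
        p_oracle = math.comb(10, 10) * math.comb(10, 0) / math.comb(20, 10)
        assert out.loc["s", "p"] == pytest.approx(p_oracle, rel=1e-12)

    def test_overlap_at_expectation_not_small(self):
        # expectation: |query| * K / N; hypergeometric upper tail at its
        # own mean is >= 0.5 (enumeration over the support)
        universe = [f"g{i}" for i in range(20)]
        query = universe[:10]
        ann = universe[5:15]  # K=10, expected overlap 5, observed 5
        out = set_overrepresentation(query, {"s": ann}, universe)
        # enumeration oracle
        N, K, n, k = 20, 10, 10, 5
        tail = sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(k, min(K, n) + 1)
        )
        assert out.loc["s", "overlap"] == 5
        assert out.loc["s", "p"] == pytest.approx(tail, rel=1e-10)
        assert out.loc["s", "p"] >= 0.5

    def test_bh_across_batch(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {f"s{j}": universe[j : j + 10] for j in range(5)}
        out = set_overrepresentation(universe[:10], sets, universe)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumeration over tables with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFamilyEnrichment:
    def test_proportional_hits_not_significant(self):
        fams = {f"tf{i}": ("A" if i < 10 else "B") for i in range(20)}
        hits = [f"tf{i}" for i in (0, 1, 10, 11)]  # 2 of 10 in each family
        out = family_enrichment(hits, fams)
        assert (out["p"] > 0.9).all()

    def test_matches_enumeration_oracle(self):
        # family A: 3 hits 1 non-hit; others: 1 hit 3 non-hits
        fams = {f"a{i}": "A" for i in range(4)} | {f"b{i}": "B" for i in range(4)}
        hits = ["a0", "a1", "a2", "b0"]
        out = family_enrichment(hits, fams)
        assert out.loc["A", "p"] == pytest.approx(_fisher_oracle(3, 1, 1, 3), rel=1e-9)

    def test_planted_family_excess_flagged(self):
        # one family with 3x odds of membership in the hit list is flagged
        # at p < 0.05 in >= 90% of replicates
        rng = np.random.default_rng(0)
        fams = {f"tf{i}": f"F{i % 8}" for i in range(400)}
        flagged = 0
        n_rep = 20
        for _ in range(n_rep):
            p_hit = np.array([0.45 if fams[f"tf{i}"] == "F0" else 0.15 for i in range(400)])
            hits = [f"tf{i}" for i in range(400) if rng.random() < p_hit[i]]
            out = family_enrichment(hits, fams)
            flagged += out.loc["F0", "p"] < 0.05
        assert flagged >= 0.9 * n_rep

    def test_unlabeled_tf_rejected(self):
        with pytest.raises(ValueError, match="family label"):
            family_enrichment(["mystery"], {"tf1": "A"})


class TestPresenceEnrichment:
    def test_query_equal_universe_degenerate(self):
        universe = [f"g{i}" for i in range(10)]
        out = presence_enrichment(universe, universe[:5], universe, [universe[:5]])
        assert out.p == 1.0
        assert out.prop_query == out.prop_universe

    def test_chi2_statistic_matches_hand_formula(self):
        # fixed 2x2; uncorrected chi-square = sum (O-E)^2 / E
        universe = [f"g{i}" for i in range(100)]
        query = universe[:40]
        marked = universe[20:60]  # 20 marked in query, 20 in the rest
        out = presence_enrichment(query, marked, universe, [universe[:40]], yates=False)
        table = np.array([[20.0, 20.0], [20.0, 40.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = ((table - expected) ** 2 / expected).sum()
        assert out.statistic == pytest.approx(chi2_hand)

    def test_small_expected_falls_back_to_fisher(self):
        universe = [f"g{i}" for i in range(30)]
        query = universe[:3]
        marked = universe[:1]
        out = presence_enrichment(query, marked, universe, [universe[:3]])
        assert out.test == "fisher"

    def test_null_random_queries_covered_by_ci(self):
        # no planted association: the universe proportion falls inside the
        # random-set 95% interval in about 95% of replicates
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(500)]
        marked = set(rng.choice(universe, 150, replace=False))
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            random_sets = [rng.choice(universe, 60, replace=False) for _ in range(200)]
            out = presence_enrichment(universe[:60], marked, universe, random_sets)
            covered += out.ci_low <= out.prop_universe <= out.ci_high
        assert 0.85 * n_rep <= covered


class TestShannonEntropy:
    def test_worked_values(self):
        assert shannon_entropy([1.0] * 8) == pytest.approx(3.0)
        assert shannon_entropy([0, 0, 5.0, 0]) == pytest.approx(0.0)
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(1.0)

    def test_all_zero_filtered_to_nan(self):
        with pytest.warns(UserWarning, match="no expression"):
            assert np.isnan(shannon_entropy([0.0, 0.0]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1e4), min_size=2, max_size=12).filter(lambda x: sum(x) > 0))
    def test_bounds_and_permutation_invariance(self, vec):
        H = shannon_entropy(vec)
        assert -1e-9 <= H <= np.log2(len(vec)) + 1e-9
        assert shannon_entropy(vec[::-1]) == pytest.approx(H)

    def test_table_version_matches_scalar(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.uniform(size=(6, 5)),
                             columns=[f"g{i}" for i in range(5)])
        H = tissue_specificity_entropy(table)
        for g in table.columns:
            assert H[g] == pytest.approx(shannon_entropy(table[g]))


class TestMatchedSizeSubset:
    def test_window_membership(self):
        lengths = pd.Series({"in": 1250.0, "out": 1000.0, "edge_lo": 1100.0, "edge_hi": 1400.0})
        out = matched_size_subset({"s": ["in", "out", "edge_lo", "edge_hi"]}, lengths)
        assert out["s"] == ["edge_hi", "edge_lo", "in"]

    def test_subset_of_original_and_empty_warns(self):
        lengths = pd.Series({"a": 500.0})
        with pytest.warns(UserWarning, match="empty"):
            out = matched_size_subset({"s": ["a"]}, lengths)
        assert out["s"] == []


@pytest.fixture(scope="module")
def frag_run(single_timepoint):
    counts, truth = single_timepoint
    tpm = compute_tpm(counts)
    report = filter_genes({tpm.timepoint: tpm}, tpm.timepoint)
    table, _ = variability_table(tpm, genes=report.retained)
    lens = counts.gene_lengths
    eligible = table.index[(lens.loc[table.index] >= 1500) & (lens.loc[table.index] <= 2500)]
    hvgs = [g for g in eligible if table.loc[g, "p_adj"] < 0.01][:10]
    nulls = [g for g in eligible if table.loc[g, "p_adj"] > 0.5][:10]
    res = fragmentation_control(counts, hvgs + nulls, seed=0)
    return counts, hvgs + nulls, res


class TestFragmentation:
    def test_partition_lengths_conserved_and_in_range(self):
        rng = np.random.default_rng(0)
        for length in (600, 1800, 5000):
            frags = fragment_gene(length, rng)
            assert sum(frags) == length
            assert all(f >= 250 for f in frags)

    def test_1800bp_gene_six_or_seven_fragments(self):
        counts = {len(fragment_gene(1800, np.random.default_rng(s))) for s in range(100)}
        assert counts <= {6, 7}

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fragment_gene(400, np.random.default_rng(0))

    def test_multinomial_split_conserves_counts(self, frag_run):
        counts, genes, res = frag_run
        # recompute the split with the same seed and check per-individual sums
        rng = np.random.default_rng(0)
        for g in genes:
            frags = fragment_gene(int(counts.gene_lengths.loc[g]), rng)
            probs = np.array(frags, dtype=float) / sum(frags)
            for c in counts.values.loc[g]:
                split = rng.multinomial(int(c), probs)
                assert split.sum() == int(c)

    def test_fragment_parent_concordance(self, frag_run):
        _, _, res = frag_run
        assert res.concordance >= 0.9

    def test_report_covers_all_fragments(self, frag_run):
        counts, genes, res = frag_run
        assert set(res.table["parent"]) == set(genes)
        assert (res.table.groupby("parent")["length_bp"].sum().sort_index()
                == counts.gene_lengths.loc[sorted(genes)].astype(int)).all()
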