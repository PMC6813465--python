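"""Deviation flags, Pearson accuracy, UPGMA/UniFrac, and group comparison."""

import itertools

import numpy as np
import pytest

from afmock import (
    CompositionProfile,
    build_taxon_tree,
    compare_groups,
    pearson_accuracy,
    percentage_deviation,
    weighted_unifrac,
)
from conftest import random_dna


def taxon_profile(ab):
    return CompositionProfile("taxon", ab)


class TestPercentageDeviation:
    def test_identical_profiles_zero_deviation(self):
        prof = taxon_profile({"a": 0.6, "b": 0.4})
        out = percentage_deviation(prof, prof)
        assert all(e.deviation == 0.0 and e.flag is None for e in out.values())

    def test_doubling_is_plus_100(self):
        out = percentage_deviation(
            taxon_profile({"a": 0.030, "b": 0.970}),
            taxon_profile({"a": 0.015, "b": 0.985}),
        )
        assert out["a"].deviation == pytest.approx(100.0)

    def test_expected_but_missing_is_nd(self):
        out = percentage_deviation(
            taxon_profile({"b": 1.0}),
            taxon_profile({"a": 0.049, "b": 0.951}),
        )
        assert out["a"].flag == "ND" and out["a"].deviation is None

    def test_unexpected_detection_is_d(self):
        out = percentage_deviation(
            taxon_profile({"a": 0.01, "b": 0.99}),
            taxon_profile({"b": 1.0}),
        )
        assert out["a"].flag == "D"


class TestPearson:
    def test_identical_profiles_give_one(self):
        prof = taxon_profile({"a": 0.5, "b": 0.3, "c": 0.2})
        assert pearson_accuracy(prof, prof) == pytest.approx(1.0)

    def test_textbook_formula_oracle(self):
        theor = {"a": 0.5, "b": 0.3, "c": 0.15, "d": 0.05}
        obs = {"a": 0.4, "b": 0.35, "c": 0.2, "d": 0.05}
        got = pearson_accuracy(taxon_profile(obs), taxon_profile(theor))
        x = np.array([theor[k] for k in "abcd"])
        y = np.array([obs[k] for k in "abcd"])
        n = 4
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * \
            np.sqrt(n * (y**2).sum() - y.sum() ** 2)
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_union_with_zero_fill(self):
        got = pearson_accuracy(
            taxon_profile({"a": 0.7, "b": 0.3}),
            taxon_profile({"a": 0.5, "c": 0.5}),
        )
        x = np.array([0.5, 0.0, 0.5])  # theor over union a, b, c
        y = np.array([0.7, 0.3, 0.0])
        expected = np.corrcoef(x, y)[0, 1]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_three_taxa_undefined(self):
        prof = taxon_profile({"a": 0.5, "b": 0.5})
        assert pearson_accuracy(prof, prof) is None

    def test_zero_variance_undefined(self):
        flat = taxon_profile({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3})
        other = taxon_profile({"a": 0.5, "b": 0.3, "c": 0.2})
        assert pearson_accuracy(flat, other) is None


def seq_at_distance(base, k, positions):
    out = list(base)
    for p in positions[:k]:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def measured_distance(a, b):
    """Alignment distance exactly as the tree builder defines it;
    pairwise_identity itself is validated against an exhaustive DP oracle
    in the taxonomy tests."""
    from afmock import pairwise_identity

    return 1.0 - pairwise_identity(a, b) / 100.0


@pytest.fixture(scope="module")
def three_taxon_tree():
    # three taxa with d(A,B) clearly smallest so the merge order is fixed
    rng = np.random.default_rng(9)
    a = random_dna(rng, 100)
    positions = list(rng.permutation(100))
    b = seq_at_distance(a, 10, positions[:10])
    c = seq_at_distance(a, 40, positions[10:50])
    reps = {"A": a, "B": b, "C": c}
    return build_taxon_tree(reps), reps


class TestUPGMA:
    def test_two_taxa_heights(self):
        rng = np.random.default_rng(10)
        a = random_dna(rng, 100)
        b = seq_at_distance(a, 20, list(rng.permutation(100)))
        d = measured_distance(a, b)
        tree = build_taxon_tree({"A": a, "B": b})
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].length == pytest.approx(d / 2)
        assert tips["B"].length == pytest.approx(d / 2)

    def test_three_taxa_merge_order_and_heights(self, three_taxon_tree):
        tree, reps = three_taxon_tree
        # hand UPGMA on the measured distance matrix: A and B merge first
        # at height d_ab/2, then join C at ((d_ac + d_bc)/2)/2
        d_ab = measured_distance(reps["A"], reps["B"])
        d_ac = measured_distance(reps["A"], reps["C"])
        d_bc = measured_distance(reps["B"], reps["C"])
        assert d_ab < min(d_ac, d_bc)
        root_height = (d_ac + d_bc) / 4
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].length == pytest.approx(d_ab / 2)
        assert tips["B"].length == pytest.approx(d_ab / 2)
        assert tips["C"].length == pytest.approx(root_height)
        ab = tips["A"].parent
        assert {t.name for t in ab.tips()} == {"A", "B"}
        assert ab.length == pytest.approx(root_height - d_ab / 2)

    def test_ultrametric(self, three_taxon_tree):
        tree, _ = three_taxon_tree
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert len({round(d, 9) for d in depths.values()}) == 1

    def test_identical_sequences_zero_height_star(self):
        seq = "ACGT" * 25
        tree = build_taxon_tree({"A": seq, "B": seq, "C": seq})
        for tip in tree.tips():
            assert tip.accumulate_to_ancestor(tree) == pytest.approx(0.0)

    def test_duplicate_or_single_taxa_rejected(self):
        with pytest.raises(ValueError):
            build_taxon_tree({"A": "ACGT"})


def unifrac_oracle(prof_a, prof_b, tree):
    """Brute-force branch enumeration: per-branch tip-set mass sums."""
    total = 0.0
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} or {node.name}
        mass_a = sum(prof_a.abundances.get(t, 0.0) for t in tips)
        mass_b = sum(prof_b.abundances.get(t, 0.0) for t in tips)
        total += (node.length or 0.0) * abs(mass_a - mass_b)
    return total


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self, three_taxon_tree):
        tree, _ = three_taxon_tree
        prof = taxon_profile({"A": 0.2, "B": 0.5, "C": 0.3})
        assert weighted_unifrac(prof, prof, tree) == pytest.approx(0.0)

    def test_two_leaf_closed_form(self):
        rng = np.random.default_rng(11)
        a = random_dna(rng, 100)
        b = seq_at_distance(a, 30, list(rng.permutation(100)))
        tree = build_taxon_tree({"A": a, "B": b})
        h = {t.name: t.length for t in tree.tips()}["A"]
        d = weighted_unifrac(taxon_profile({"A": 1.0}), taxon_profile({"B": 1.0}), tree)
        assert d == pytest.approx(2 * h)

    def test_matches_brute_force_on_random_4_taxon_instances(self):
        rng = np.random.default_rng(12)
        base = random_dna(rng, 120)
        positions = list(rng.permutation(120))
        reps = {
            "A": base,
            "B": seq_at_distance(base, 12, positions[:12]),
            "C": seq_at_distance(base, 30, positions[12:42]),
            "D": seq_at_distance(base, 45, positions[42:87]),
        }
        tree = build_taxon_tree(reps)
        for _ in range(20):
            w1, w2 = rng.random(4), rng.random(4)
            p1 = taxon_profile(dict(zip("ABCD", w1 / w1.sum())))
            p2 = taxon_profile(dict(zip("ABCD", w2 / w2.sum())))
            assert weighted_unifrac(p1, p2, tree) == pytest.approx(
                unifrac_oracle(p1, p2, tree), abs=1e-12)

    def test_agrees_with_skbio(self, three_taxon_tree):
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        tree, _ = three_taxon_tree
        p1 = taxon_profile({"A": 0.2, "B": 0.5, "C": 0.3})
        p2 = taxon_profile({"A": 0.6, "B": 0.1, "C": 0.3})
        ours = weighted_unifrac(p1, p2, tree)
        # skbio takes integer counts and normalizes them internally
        theirs = skbio_wu(
            [int(round(p1.abundances[t] * 10)) for t in "ABC"],
            [int(round(p2.abundances[t] * 10)) for t in "ABC"],
            taxa=list("ABC"), tree=tree, normalized=False, validate=True,
        )
        assert ours == pytest.approx(float(theirs), abs=1e-9)

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(13)
        base = random_dna(rng, 100)
        positions = list(rng.permutation(100))
        reps = {"A": base,
                "B": seq_at_distance(base, 14, positions[:14]),
                "C": seq_at_distance(base, 36, positions[14:50])}
        tree = build_taxon_tree(reps)
        for _ in range(20):
            profs = []
            for _ in range(3):
                w = rng.random(3)
                profs.append(taxon_profile(dict(zip("ABC", w / w.sum()))))
            p, q, r = profs
            d_pq = weighted_unifrac(p, q, tree)
            assert d_pq == pytest.approx(weighted_unifrac(q, p, tree), abs=1e-12)
            assert weighted_unifrac(p, p, tree) == pytest.approx(0.0)
            assert d_pq <= weighted_unifrac(p, r, tree) + \
                weighted_unifrac(r, q, tree) + 1e-12

    def test_missing_taxon_errors(self, three_taxon_tree):
        tree, _ = three_taxon_tree
        with pytest.raises(ValueError, match="missing"):
            weighted_unifrac(taxon_profile({"Z": 1.0}),
                             taxon_profile({"A": 1.0}), tree)


class TestCompareGroups:
    def test_identical_groups_share_letter(self):
        out = compare_groups({"m1": [1.0, 1.0, 1.0], "m2": [1.0, 1.0, 1.0]})
        assert out.f_statistic == 0.0 and out.p_value == 1.0
        assert out.letters["m1"] == out.letters["m2"]

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(14)
        jitter = lambda v: [v + 1e-6 * float(x) for x in rng.standard_normal(4)]
        out = compare_groups({"low": jitter(0.0), "high": jitter(1.0)})
        assert set(out.letters["low"]).isdisjoint(out.letters["high"])
        assert out.p_value < 0.05

    def test_textbook_anova_sums_of_squares(self):
        groups = {"g1": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  "g2": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  "g3": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
        out = compare_groups(groups)
        # manual one-way ANOVA
        flat = [v for vs in groups.values() for v in vs]
        grand = np.mean(flat)
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum((x - np.mean(v)) ** 2 for v in groups.values() for x in v)
        f_manual = (ss_between / 2) / (ss_within / 15)
        assert out.f_statistic == pytest.approx(f_manual, abs=1e-9)

    def test_degenerate_group_sizes_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [2.0, 3.0]})
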