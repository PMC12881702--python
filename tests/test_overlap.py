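import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from defrac import (ValidationError, fraction_asv_sets, shared_fraction,
                    venn_partition, weighted_contribution)

from conftest import make_record, make_table


class TestVennPartition:
    def test_three_set_enumeration(self):
        regions = venn_partition({"S": {"a", "b"}, "L": {"b", "c"}, "W": {"b", "d"}})
        assert regions["S_only"] == {"a"}
        assert regions["L_only"] == {"c"}
        assert regions["W_only"] == {"d"}
        assert regions["S∩L∩W"] == {"b"}
        assert regions["S∩L"] == set() and regions["S∩W"] == set()
        assert regions["L∩W"] == set()

    def test_identical_sets(self):
        regions = venn_partition({"A": {"x", "y"}, "B": {"x", "y"}})
        assert regions["A∩B"] == {"x", "y"}
        assert regions["A_only"] == set() and regions["B_only"] == set()

    def test_disjoint_sets(self):
        regions = venn_partition({"A": {"x"}, "B": {"y"}, "C": {"z"}})
        assert regions["A_only"] == {"x"}
        assert all(not regions[r] for r in regions if "∩" in r)

    def test_arity_limit(self):
        with pytest.raises(ValidationError, match="2 or 3"):
            venn_partition({"A": set(), "B": set(), "C": set(), "D": set()})

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_partition_is_exhaustive_and_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"a{i}" for i in range(15)]
        sets = {lab: set(rng.choice(universe, rng.integers(0, 15), replace=False))
                for lab in "XYZ"}
        regions = venn_partition(sets)
        union = set().union(*sets.values())
        covered = [a for members in regions.values() for a in members]
        assert set(covered) == union
        assert len(covered) == len(union)  # disjoint


def brute_force_weight(region_members, reads):
    """Independent per-ASV loop oracle for the weighted contribution."""
    total = sum(reads.values())
    acc = 0.0
    for asv in region_members:
        acc += reads[asv]
    return len(region_members) * acc / total


class TestWeightedContribution:
    def test_hand_evaluated_weights(self):
        part = {"s1": frozenset({"a"}), "s2": frozenset({"b", "c"})}
        reads = {"a": 50, "b": 25, "c": 25}
        w = weighted_contribution(part, reads)
        assert w.table.loc["s1", "weight_raw"] == pytest.approx(0.5)
        assert w.table.loc["s2", "weight_raw"] == pytest.approx(1.0)
        assert w.table.loc["s1", "weight_normalized"] == pytest.approx(1 / 3)
        assert w.table.loc["s2", "weight_normalized"] == pytest.approx(2 / 3)

    def test_single_region_raw_weight_is_n(self):
        part = {"all": frozenset({"a", "b", "c"})}
        w = weighted_contribution(part, {"a": 1, "b": 1, "c": 1})
        assert w.table.loc["all", "weight_raw"] == pytest.approx(3.0)
        assert w.table.loc["all", "weight_normalized"] == pytest.approx(1.0)

    def test_zero_read_region(self):
        part = {"r0": frozenset({"a"}), "r1": frozenset({"b"})}
        w = weighted_contribution(part, {"a": 0, "b": 10})
        assert w.table.loc["r0", "weight_raw"] == 0.0

    def test_zero_total_reads_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            weighted_contribution({"r": frozenset({"a"})}, {"a": 0})

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        asvs = [f"a{i}" for i in range(n)]
        reads = {a: float(rng.integers(0, 1000)) for a in asvs}
        if sum(reads.values()) == 0:
            reads[asvs[0]] = 1.0
        labels = rng.integers(0, 3, size=n)
        part = {f"r{k}": frozenset(a for a, l in zip(asvs, labels) if l == k)
                for k in range(3)}
        w = weighted_contribution(part, reads)
        for k in range(3):
            assert w.table.loc[f"r{k}", "weight_raw"] == pytest.approx(
                brute_force_weight(part[f"r{k}"], reads))
        norm = w.table["weight_normalized"]
        assert norm.sum() == pytest.approx(1.0, abs=1e-9)

    def test_normalized_weights_scale_invariant(self):
        part = {"r0": frozenset({"a"}), "r1": frozenset({"b", "c"})}
        reads = {"a": 3.0, "b": 5.0, "c": 2.0}
        w1 = weighted_contribution(part, reads)
        w2 = weighted_contribution(part, {k: 17 * v for k, v in reads.items()})
        np.testing.assert_allclose(w1.table["weight_normalized"],
                                   w2.table["weight_normalized"])


class TestSharedFraction:
    def test_everything_shared(self):
        part = {"A_only": frozenset(), "B_only": frozenset(),
                "A∩B": frozenset({"a", "b"})}
        w = weighted_contribution(part, {"a": 10, "b": 20})
        assert shared_fraction(w, ["A∩B"]) == (1.0, 1.0)

    def test_rare_unique_asvs(self):
        # 3 of 10 ASVs are unique but carry only 3 of 1000 reads
        unique = {f"u{i}" for i in range(3)}
        shared = {f"s{i}" for i in range(7)}
        reads = {a: 1.0 for a in unique} | {a: 997.0 / 7 for a in shared}
        w = weighted_contribution(
            {"S_only": frozenset(unique), "S∩W": frozenset(shared)}, reads)
        count_prop, read_prop = shared_fraction(w, ["S_only"])
        assert count_prop == pytest.approx(0.3)
        assert read_prop == pytest.approx(0.003)

    def test_empty_region(self):
        part = {"A_only": frozenset({"a"}), "A∩B": frozenset()}
        w = weighted_contribution(part, {"a": 5})
        assert shared_fraction(w, ["A∩B"]) == (0.0, 0.0)

    def test_unknown_label_rejected(self):
        part = {"A_only": frozenset({"a"})}
        w = weighted_contribution(part, {"a": 5})
        with pytest.raises(ValidationError, match="unknown"):
            shared_fraction(w, ["nope"])


class TestFractionAsvSets:
    def test_presence_across_series(self):
        table = make_table([[1, 0, 2], [0, 0, 3], [0, 5, 0]],
                           sample_ids=["s1", "s2", "l1"])
        meta = {"s1": make_record("s1", week=1, fraction="S"),
                "s2": make_record("s2", week=2, fraction="S"),
                "l1": make_record("l1", week=1, fraction="L")}
        sets = fraction_asv_sets(table, meta, ["S", "L"])
        assert sets["S"] == {"asv1", "asv3"}
        assert sets["L"] == {"asv2"}

    def test_by_context_grouping(self):
        table = make_table([[1, 0], [0, 2]], sample_ids=["s1", "l1"])
        meta = {"s1": make_record("s1", week=1, fraction="S"),
                "l1": make_record("l1", week=1, fraction="L")}
        grouped = fraction_asv_sets(table, meta, ["S", "L"], by_context=True)
        assert grouped[(1, 5.0)]["S"] == {"asv1"}
        assert grouped[(1, 5.0)]["L"] == {"asv2"}
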