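"""Promiscuity summary statistics and stratified variants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import profiles_from_counts
from promispace.errors import MalformedInputError
from promispace.io import TargetProfile
from promispace.stats import (
    MWBinSpec,
    high_promiscuity_fraction,
    read_summary_json,
    summarize,
    summarize_by_family,
    summarize_by_mw,
    write_summary_json,
)


class TestSummarize:
    def test_worked_example(self, toy_profiles):
        s = summarize(toy_profiles)  # counts 1,1,2,6
        assert s.rate == pytest.approx(4.0)
        assert s.p_at_least_2 == pytest.approx(0.5)
        assert s.p_more_than_5 == pytest.approx(0.25)
        assert s.distribution == {1: 2, 2: 1, 6: 1}

    def test_rate_over_multi_target_only(self):
        s = summarize(profiles_from_counts({"a": 2, "b": 3, "c": 5}))
        assert s.rate == pytest.approx(10 / 3)

    def test_rate_undefined_without_multi_target_compounds(self):
        s = summarize(profiles_from_counts({"a": 1, "b": 1}))
        assert s.rate is None
        assert s.p_at_least_2 == 0.0

    def test_inactive_compounds_enter_denominator_and_distribution(self):
        s = summarize(profiles_from_counts({"a": 11, "b": 3}), n_inactive=2)
        assert s.n_compounds_total == 4
        assert s.distribution[0] == 2
        assert s.p_at_least_2 == pytest.approx(0.5)

    def test_removing_single_target_compound_keeps_rate(self):
        counts = {"a": 1, "b": 2, "c": 6}
        with_single = summarize(profiles_from_counts(counts))
        without = summarize(profiles_from_counts({"b": 2, "c": 6}))
        assert with_single.rate == without.rate
        assert with_single.p_at_least_2 != without.p_at_least_2

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=30), min_size=1, max_size=40))
    def test_invariants(self, counts):
        profiles = profiles_from_counts({f"c{i}": t for i, t in enumerate(counts)})
        s = summarize(profiles)
        assert s.p_more_than_5 <= s.p_at_least_2 <= 1
        assert sum(s.distribution.values()) == s.n_compounds_total
        assert sum(t * n for t, n in s.distribution.items()) == sum(counts)
        if s.n_multi_target:
            assert s.rate >= 2


class TestByFamily:
    @pytest.fixture
    def families(self):
        fam = {f"G{i}": "GPCR-A" for i in range(5)}
        fam.update({f"K{i}": "kinase" for i in range(5)})
        return fam

    def test_restriction_semantics(self, families):
        profiles = [TargetProfile("c1", frozenset(["G0", "G1", "K0", "K1", "K2"]))]
        g = summarize_by_family(profiles, families, "GPCR-A")
        k = summarize_by_family(profiles, families, "kinase")
        assert g.rate == pytest.approx(2.0)
        assert k.rate == pytest.approx(3.0)

    def test_single_target_within_family_excluded_from_rate(self, families):
        profiles = [
            TargetProfile("c1", frozenset(["G0", "K0", "K1", "K2", "K3"])),
            TargetProfile("c2", frozenset(["G0", "G1"])),
        ]
        g = summarize_by_family(profiles, families, "GPCR-A")
        assert g.n_multi_target == 1  # only c2 is multi-target within GPCR-A
        assert g.rate == pytest.approx(2.0)

    def test_unknown_family_is_an_error(self, families):
        profiles = [TargetProfile("c1", frozenset(["G0", "G1"]))]
        with pytest.raises(MalformedInputError):
            summarize_by_family(profiles, families, "protease")

    def test_family_multi_target_never_exceeds_global(self, families):
        profiles = [
            TargetProfile("c1", frozenset(["G0", "G1", "K0"])),
            TargetProfile("c2", frozenset(["K0", "K1"])),
            TargetProfile("c3", frozenset(["G0"])),
        ]
        total = summarize(profiles).n_multi_target
        per_family = [
            summarize_by_family(profiles, families, fam).n_multi_target
            for fam in ("GPCR-A", "kinase")
        ]
        assert all(n <= total for n in per_family)


class TestByMolecularWeight:
    def test_benzene_falls_in_smallest_bin(self):
        profiles = [TargetProfile("bz", frozenset(["T1", "T2"]))]
        rows = summarize_by_mw(profiles, {"bz": "c1ccccc1"})
        by_label = dict(rows)
        assert by_label["(0,200]"] is not None
        assert by_label["(0,200]"].n_compounds_total == 1

    def test_exact_edge_goes_to_lower_bin(self):
        spec = MWBinSpec()
        assert spec.assign(300.0) == "(200,300]"
        assert spec.assign(300.0001) == "(300,400]"

    def test_beyond_last_edge_goes_to_open_bin(self):
        assert MWBinSpec().assign(1234.5) == "(700,inf)"

    def test_every_compound_lands_in_exactly_one_bin(self):
        structures = {"a": "c1ccccc1", "b": "C" * 30, "c": "CCO"}
        profiles = [TargetProfile(c, frozenset(["T1"])) for c in structures]
        rows = summarize_by_mw(profiles, structures)
        assert sum(s.n_compounds_total for _, s in rows if s is not None) == 3

    def test_edges_must_increase(self):
        with pytest.raises(MalformedInputError):
            MWBinSpec(edges=(0, 300, 200))


class TestHighPromiscuityFraction:
    def test_binary_matrix_example(self):
        profiles = profiles_from_counts({"c": 11, "d": 3})
        assert high_promiscuity_fraction(profiles, 10, n_inactive=2) == pytest.approx(0.25)

    def test_threshold_above_max_gives_zero(self):
        profiles = profiles_from_counts({"a": 3, "b": 4})
        assert high_promiscuity_fraction(profiles, 10) == 0.0


def test_summary_json_round_trip(tmp_path, toy_profiles):
    s = summarize(toy_profiles)
    path = tmp_path / "summary.json"
    write_summary_json(s, path)
    assert read_summary_json(path) == s
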