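"""Sequence canonicalization, cross-platform matching, replicate collapsing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirconcord.matching import (
    canonicalize_sequence,
    collapse_replicates,
    match_across_platforms,
    present_intersections,
    sequences_match,
)
from mirconcord.types import ProbeAnnotation, ValidationError

seq_strategy = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("uaGcuu", "TAGCTT"),
            ("ACGT", "ACGT"),
            ("uggagugugacaaugguguuug", "TGGAGTGTGACAATGGTGTTTG"),
        ],
    )
    def test_rna_to_dna_uppercase(self, raw, expected):
        assert canonicalize_sequence(raw) == expected

    @pytest.mark.parametrize("bad", ["", "ACGX", "AC GT", "ACGN"])
    def test_illegal_input_rejected(self, bad):
        with pytest.raises(ValidationError):
            canonicalize_sequence(bad)


class TestSequencesMatch:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGTACGT", "TTACGTACGTTT", True),  # containment
            ("ACGT", "ACGT", True),  # equality
            ("ACGTT", "ACGAA", False),
            ("AAAA", "TTTT", False),
        ],
    )
    def test_containment_rule(self, a, b, expected):
        assert sequences_match(a, b) is expected

    def test_requires_canonical_input(self):
        with pytest.raises(ValidationError):
            sequences_match("acgu", "ACGT")

    @settings(deadline=None, derandomize=True)
    @given(a=seq_strategy, b=seq_strategy)
    def test_symmetric(self, a, b):
        assert sequences_match(a, b) == sequences_match(b, a)

    @settings(deadline=None, derandomize=True)
    @given(a=seq_strategy)
    def test_reflexive(self, a):
        assert sequences_match(a, a)


def _probe(pid, name, seq, platform):
    return ProbeAnnotation(pid, name, seq, platform_id=platform)


class TestMatchAcrossPlatforms:
    def test_name_merge_with_sequence_verification(self):
        # three shared names; only two have compatible sequences
        pa = {
            "P1": [
                _probe("a1", "miR-1", "ACGTACGTACGT", "P1"),
                _probe("a2", "miR-2", "TTTTCCCCGGGG", "P1"),
                _probe("a3", "miR-3", "GGGGAAAATTTT", "P1"),
            ],
            "P2": [
                _probe("b1", "miR-1", "AAACGTACGTACGTAA", "P2"),  # contains a1
                _probe("b2", "miR-2", "TTTTCCCCGGGG", "P2"),  # equal
                _probe("b3", "miR-3", "CCCCCCCCCCCC", "P2"),  # conflict
            ],
        }
        ms = match_across_platforms(pa)
        assert sorted(ms.entries) == ["miR-1", "miR-2"]
        assert ms.entries["miR-1"] == {"P1": ["a1"], "P2": ["b1"]}

    def test_sequence_authoritative_over_names(self):
        pa = {
            "P1": [_probe("a1", "mmu-miR-1", "ACGTACGTACGTACGTACGTAC", "P1")],
            "P2": [_probe("b1", "mmu-miR-1-3p", "ACGTACGTACGTACGTACGTAC", "P2")],
        }
        ms = match_across_platforms(pa)
        assert len(ms.entries) == 1
        (key,) = ms.entries
        assert set(ms.entries[key]) == {"P1", "P2"}

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 22)) for _ in range(10)]
        pa = {
            "P1": [_probe(f"a{i}", f"m{i}", s, "P1") for i, s in enumerate(seqs)],
            "P2": [_probe(f"b{i}", f"m{i}", s, "P2") for i, s in enumerate(seqs)],
        }
        pa_rev = {p: list(reversed(v)) for p, v in reversed(list(pa.items()))}
        assert match_across_platforms(pa).entries == match_across_platforms(pa_rev).entries

    def test_empty_platform_rejected(self):
        pa = {"P1": [_probe("a1", "m", "ACGT", "P1")], "P2": []}
        with pytest.raises(ValidationError):
            match_across_platforms(pa)

    def test_generator_overlap_matches_truth(self):
        # 4 synthetic platforms built from a known 60-miRNA shared core
        from mirconcord.simulate import generate_truth, simulate_platform, PlatformModel

        truth = generate_truth(n_mirna=60, seed=11)
        annotations = {}
        for k, (lo, hi) in enumerate([(22, 22), (22, 28), (28, 34), (34, 40)]):
            pid = f"plat{k}"
            model = PlatformModel(
                platform_id=pid, probe_length_range=(lo, hi), content_fraction=1.0
            )
            ann, _ = simulate_platform(truth, model, seed=100 + k)
            annotations[pid] = ann
        ms = match_across_platforms(annotations)
        assert len(ms.keys_spanning_all()) == 60

    def test_ambiguous_containment_dropped(self):
        # one P1 probe matched by two distinct miRNAs' probes on P2,
        # which themselves are incompatible -> unresolvable, all dropped
        core = "ACGTACGTACGTACGTACGTAC"
        pa = {
            "P1": [_probe("a1", "miR-x", core, "P1")],
            "P2": [
                _probe("b1", "miR-x", "AA" + core + "AA", "P2"),
                _probe("b2", "miR-y", core + "GGGGGGGG", "P2"),
            ],
            "P3": [_probe("c1", "miR-y", core + "GGGGGGGG", "P3")],
        }
        ms = match_across_platforms(pa)
        assert "miR-x" not in ms.entries and "miR-y" not in ms.entries
        assert set(ms.dropped_ambiguous) == {"miR-x", "miR-y"}


class TestCollapseReplicates:
    def _setup(self):
        values = pd.DataFrame(
            {
                "A1.Cy3": [2.0, 4.0, 100.0, 7.0],
                "A2.Cy3": [1.0, 1.0, 1.0, np.nan],
            },
            index=pd.Index(["p1", "p2", "p3", "q1"], name="probe_id"),
        )
        ann = [
            _probe("p1", "miR-a", "ACGTACGTAC", "P"),
            _probe("p2", "miR-a", "ACGTACGTAC", "P"),
            _probe("p3", "miR-a", "ACGTACGTAC", "P"),
            _probe("q1", "miR-b", "TTTTGGGGCC", "P"),
        ]
        detection = pd.DataFrame(True, index=values.index, columns=values.columns)
        return values, ann, detection

    def test_median_of_technical_replicates(self):
        values, ann, det = self._setup()
        out = collapse_replicates(values, ann, det, platform_id="P")
        assert out.values.loc["miR-a", "A1.Cy3"] == 4.0  # median of {2,4,100}
        assert out.values.loc["miR-b", "A1.Cy3"] == 7.0  # single replicate

    def test_any_absent_flag_propagates(self):
        values, ann, det = self._setup()
        det.loc["p2", "A1.Cy3"] = False  # one of three replicates absent
        out = collapse_replicates(values, ann, det)
        assert bool(out.absent.loc["miR-a", "A1.Cy3"])
        assert not bool(out.absent.loc["miR-a", "A2.Cy3"])

    def test_all_nan_contributors(self):
        values, ann, det = self._setup()
        out = collapse_replicates(values, ann, det)
        assert np.isnan(out.values.loc["miR-b", "A2.Cy3"])
        assert bool(out.absent.loc["miR-b", "A2.Cy3"])

    def test_majority_consensus(self):
        values, ann, det = self._setup()
        det.loc["p2", "A1.Cy3"] = False  # 2/3 pass -> present under majority
        out = collapse_replicates(values, ann, det, consensus="majority")
        assert not bool(out.absent.loc["miR-a", "A1.Cy3"])

    def test_commutes_with_column_permutation(self):
        values, ann, det = self._setup()
        out1 = collapse_replicates(values, ann, det)
        perm = ["A2.Cy3", "A1.Cy3"]
        out2 = collapse_replicates(values[perm], ann, det[perm])
        pd.testing.assert_frame_equal(out1.values[perm], out2.values)


class TestPresentIntersections:
    def test_nested_sets(self):
        counts = present_intersections({"P1": {"a", "b", "c"}, "P2": {"b", "c"}, "P3": {"c"}})
        assert counts[frozenset({"P1", "P2", "P3"})] == 1
        assert counts[frozenset({"P1", "P2"})] == 1  # b only
        assert counts[frozenset({"P1"})] == 1  # a only
        assert counts[frozenset({"P2"})] == 0

    def test_identical_sets_concentrate_in_full_cell(self):
        s = set("abcdef")
        counts = present_intersections({p: s for p in "WXYZ"})
        for subset, c in counts.items():
            assert c == (6 if len(subset) == 4 else 0)

    def test_counts_equal_bruteforce_enumeration(self):
        rng = np.random.default_rng(3)
        universe = [f"m{i}" for i in range(40)]
        sets = {
            p: {m for m in universe if rng.random() < 0.6} for p in ["P1", "P2", "P3", "P4"]
        }
        counts = present_intersections(sets)
        platforms = sorted(sets)
        for r in range(1, 5):
            for subset in itertools.combinations(platforms, r):
                expected = sum(
                    1
                    for m in universe
                    if all(m in sets[p] for p in subset)
                    and not any(m in sets[p] for p in platforms if p not in subset)
                )
                assert counts[frozenset(subset)] == expected

    def test_venn_cells_sum_to_set_size(self):
        rng = np.random.default_rng(9)
        sets = {p: {f"m{i}" for i in range(30) if rng.random() < 0.5} for p in "ABC"}
        counts = present_intersections(sets)
        for p in sets:
            total = sum(c for subset, c in counts.items() if p in subset)
            assert total == len(sets[p])

    def test_qpcr_filter_restricts_universe(self):
        sets = {"P1": {"a", "b"}, "P2": {"a", "b"}}
        counts = present_intersections(sets, qpcr_detected={"a"})
        assert counts[frozenset({"P1", "P2"})] == 1
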