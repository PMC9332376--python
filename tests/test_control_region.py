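"""Control region: span, tandem repeats, stem-loops, oracle equivalence."""

import random

import pytest

from mitocompare import (
    control_region_span,
    find_stem_loops,
    find_tandem_repeats,
)
from mitocompare.control_region import StemLoop, verify_repeat, verify_stem_loop
from mitocompare.model import MitoAnnotation, reverse_complement
from mitocompare.simulate import CRSpec, SimSpec, simulate


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_repeat_positions(s, min_period, min_copies):
    """Exhaustive (start, period) scan for tandem arrays; returns the set
    of maximal (start, period, span) triples."""
    s = s.upper()
    n = len(s)
    hits = set()
    for p in range(min_period, n // 2 + 1):
        for start in range(n):
            span = p
            while start + span < n and s[start + span] == s[start + span - p]:
                span += 1
            if span / p >= min_copies:
                # maximal: not extendable to the left
                if start >= 1 and s[start - 1] == s[start - 1 + p]:
                    continue
                hits.add((start + 1, p, span))
    return hits


def oracle_stem_loops(s, min_stem, loop_range):
    """Exhaustive O(n^3) enumeration of perfect inverted repeats with the
    loop length constraint; keeps only maximal ones (arms not extendable
    outward, nor inward within the loop range)."""
    s = s.upper()
    n = len(s)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    all_hits = set()
    for i in range(n):  # 0-based start of 5' arm
        for k in range(min_stem, n):
            if i + k > n:
                break
            for loop in range(loop_range[0], loop_range[1] + 1):
                j = i + k + loop  # start of 3' arm
                if j + k > n:
                    continue
                five = s[i : i + k]
                three = s[j : j + k]
                if reverse_complement(five) == three:
                    all_hits.add((i, k, loop))
    maximal = set()
    for (i, k, loop) in all_hits:
        # outward extension: (i-1, k+1, loop) also a perfect hairpin
        if (i - 1, k + 1, loop) in all_hits:
            continue
        # inward extension: (i, k+1, loop-2) within range
        if (i, k + 1, loop - 2) in all_hits and loop - 2 >= loop_range[0]:
            continue
        maximal.add((i + 1, k, loop))
    return maximal


def hairpin_key(h: StemLoop):
    return (h.five_arm[0], h.stem_len, h.loop_len)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestSpan:
    def test_fixture_span(self, ibericum):
        assert control_region_span(ibericum) == (15375, 15715, 341)

    def test_planted_length(self):
        truth = simulate(SimSpec(seed=1, cr=CRSpec(length=500)))
        assert control_region_span(truth.annotation) == (1, 500, 500)

    def test_inference_from_gap_matches_annotation(self, default_truth):
        ann = default_truth.annotation
        annotated = control_region_span(ann)
        stripped = MitoAnnotation(
            genome_length=ann.genome_length,
            features=[f for f in ann.features if f.kind != "CR"],
            sequence=ann.sequence,
        )
        inferred = control_region_span(stripped)
        assert inferred == annotated


class TestTandemRepeats:
    def test_taactaact_spacer_repeat(self):
        [rep] = find_tandem_repeats("TAACTAACT", min_period=4, min_copies=2.0)
        assert (rep.period, rep.consensus, rep.copies) == (4, "TAAC", 2.25)
        assert rep.start == 1

    def test_planted_13bp_five_copies_recovered(self):
        truth = simulate(
            SimSpec(seed=2, cr=CRSpec(length=400, repeats=((13, 5),)))
        )
        s, e, _ = control_region_span(truth.annotation)
        region = truth.annotation.slice(s, e)
        found = find_tandem_repeats(region)
        [planted] = truth.planted_repeats
        assert planted in found
        assert verify_repeat(region, planted)

    def test_planted_33bp_repeat_recovered(self):
        # the long-period case seen in T. melanocephalum control regions
        truth = simulate(
            SimSpec(seed=3, cr=CRSpec(length=420, repeats=((33, 3),)))
        )
        s, e, _ = control_region_span(truth.annotation)
        region = truth.annotation.slice(s, e)
        found = find_tandem_repeats(region)
        [planted] = truth.planted_repeats
        assert planted in found

    def test_case_invariance(self):
        upper = find_tandem_repeats("TAACTAACT", 4, 2.0)
        lower = find_tandem_repeats("taactaact", 4, 2.0)
        assert upper == lower

    def test_reported_repeats_verify_literally(self, default_truth):
        ann = default_truth.annotation
        s, e, _ = control_region_span(ann)
        region = ann.slice(s, e)
        for rep in find_tandem_repeats(region, min_period=4, min_copies=2.0):
            assert verify_repeat(region, rep)

    def test_matches_exhaustive_scan_on_random_strings(self):
        rng = random.Random(13)
        for _ in range(8):
            s = "".join(rng.choice("AATTG") for _ in range(120))
            found = {
                (r.start, r.period, r.span)
                for r in find_tandem_repeats(s, min_period=5, min_copies=2.0)
            }
            oracle = oracle_repeat_positions(s, 5, 2.0)
            # every find is a true maximal array; every oracle array is
            # covered by a reported one (reports merge harmonics)
            assert found <= oracle
            for (start, period, span) in oracle:
                assert any(
                    fs <= start and fs + fspan >= start + span
                    for (fs, _, fspan) in found
                ), (start, period, span)

    def test_no_repeats_in_gc_balanced_random_string(self):
        rng = random.Random(99)
        s = "".join(rng.choice("ACGT") for _ in range(341))
        assert find_tandem_repeats(s, min_period=8, min_copies=2.0) == []
        assert oracle_repeat_positions(s, 8, 2.0) == set()


class TestStemLoops:
    def test_constructed_hairpin(self):
        [h] = find_stem_loops("GGGGGAAACCCCC", min_stem=5, loop_range=(3, 10))
        assert (h.stem_len, h.loop_len) == (5, 3)
        assert h.five_arm == (1, 5) and h.three_arm == (9, 13)

    def test_at_extension_of_gc_hairpin_detected(self):
        # the A/T bases flanking the loop also pair, so the maximal stem
        # is 6 with a 4-nt loop
        hits = find_stem_loops("GGGGGAAATTTCCCCC", min_stem=5, loop_range=(3, 10))
        top = hits[0]
        assert (top.stem_len, top.loop_len) == (6, 4)

    def test_planted_stem_loop_recovered_span_in_window(self, default_truth):
        ann = default_truth.annotation
        s, e, _ = control_region_span(ann)
        region = ann.slice(s, e)
        found = find_stem_loops(region)
        planted = default_truth.planted_stem_loop
        assert planted in found
        assert 27 <= planted.span <= 30
        assert verify_stem_loop(region, planted)

    def test_reported_arms_are_reverse_complements(self, default_truth):
        ann = default_truth.annotation
        s, e, _ = control_region_span(ann)
        region = ann.slice(s, e)
        for h in find_stem_loops(region):
            assert verify_stem_loop(region, h)

    def test_case_invariance(self):
        u = find_stem_loops("GGGGGAAACCCCC", 5, (3, 10))
        l = find_stem_loops("gggggaaaccccc", 5, (3, 10))
        assert u == l

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(21)
        for n in (60, 120):
            s = "".join(rng.choice("AATTGC") for _ in range(n))
            found = {hairpin_key(h) for h in find_stem_loops(s, 4, (3, 8))}
            oracle = {
                (i, k, loop) for (i, k, loop) in oracle_stem_loops(s, 4, (3, 8))
            }
            assert found == oracle
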