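"""Gene-order signatures, cluster calls, breakpoint distance, events."""

import random

import pytest

from mitocompare import (
    ancestral_signature,
    breakpoint_distance,
    call_clusters,
    extract_signature,
    infer_events,
)
from mitocompare.gene_order import ANCESTRAL_ORDER, GeneOrderSignature
from mitocompare.model import GeneFeature, MitoAnnotation
from mitocompare.simulate import SimSpec, perturb, resolve_gene_order, simulate


def brute_force_adjacencies(order):
    """Independent adjacency enumeration: walk the circle both ways and
    canonicalise each neighbour pair by taking the lexicographic minimum
    of its two traversal readings."""
    flip = {"H": "L", "L": "H"}
    out = set()
    n = len(order)
    for i in range(n):
        x, y = order[i], order[(i + 1) % n]
        fwd = (x, y)
        rev = ((y[0], flip[y[1]]), (x[0], flip[x[1]]))
        out.add(min(fwd, rev))
    return out


def brute_force_distance(a, b):
    return len(brute_force_adjacencies(a.order) - brute_force_adjacencies(b.order))


def random_signature(rng, genes):
    order = [(g, rng.choice("HL")) for g in genes]
    rng.shuffle(order)
    return GeneOrderSignature(tuple(order))


class TestSignature:
    def test_fixture_order_starts_cr_miq_nad2_wyc(self, ibericum):
        sig = extract_signature(ibericum)
        assert sig.tokens[:9] == (
            "CR", "M", "I", "Q", "nad2", "W", "Y", "C", "cox1"
        )
        assert sig.missing == ()

    def test_rotation_invariant_equality(self):
        a = GeneOrderSignature((("x", "H"), ("y", "L"), ("z", "H")))
        b = GeneOrderSignature((("z", "H"), ("x", "H"), ("y", "L")))
        assert a == b
        c = GeneOrderSignature((("x", "H"), ("z", "H"), ("y", "L")))
        assert a != c

    def test_ancestral_round_trips_through_synthetic_annotation(self):
        truth = simulate(SimSpec(seed=2, gene_order="ancestral"))
        sig = extract_signature(truth.annotation)
        assert sig == ancestral_signature()

    def test_extraction_invariant_to_origin_rotation(self):
        truth = simulate(SimSpec(seed=3))
        ann = truth.annotation
        sig0 = extract_signature(ann)
        rng = random.Random(3)
        for _ in range(5):
            # rotate the sequence origin into a spacer between features
            feats = sorted(ann.features, key=lambda f: f.start)
            gaps = [
                (f.end + 1, g.start - 1)
                for f, g in zip(feats, feats[1:])
                if g.start - f.end - 1 > 0
            ]
            lo, hi = rng.choice(gaps)
            shift = rng.randint(lo, hi)  # new origin (1-based) - 1
            rotated = MitoAnnotation(
                genome_length=ann.genome_length,
                features=[
                    GeneFeature(
                        f.name, f.kind, f.strand,
                        (f.start - shift - 1) % ann.genome_length + 1,
                        (f.end - shift - 1) % ann.genome_length + 1,
                    )
                    for f in ann.features
                ],
            )
            assert extract_signature(rotated) == sig0


class TestClusterCalls:
    def test_fixture_is_miq_wyc(self, ibericum):
        call = call_clusters(extract_signature(ibericum))
        assert (call.iqm_label, call.wcy_label) == ("MIQ", "WYC")

    def test_ancestral_is_iqm_wcy(self):
        call = call_clusters(ancestral_signature())
        assert (call.iqm_label, call.wcy_label) == ("IQM", "WCY")
        assert call.breakpoint_distance_to_ancestral == 0

    @pytest.mark.parametrize(
        "arrangement,iqm,wcy",
        [
            ("ancestral", "IQM", "WCY"),
            ("MIQ+WCY", "MIQ", "WCY"),
            ("MIQ+WYC", "MIQ", "WYC"),
            ("QMI+WCY", "QMI", "WCY"),
            ("IMQ+WCY", "IMQ", "WCY"),
        ],
    )
    def test_named_arrangements_round_trip(self, arrangement, iqm, wcy):
        truth = simulate(SimSpec(seed=4, gene_order=arrangement))
        call = call_clusters(extract_signature(truth.annotation))
        assert (call.iqm_label, call.wcy_label) == (iqm, wcy)
        assert (truth.iqm_label, truth.wcy_label) == (iqm, wcy)

    def test_translocated_q_reported(self):
        # D. lamellosus-like: Q moved between rrnS and the control region
        truth = perturb(simulate(SimSpec(seed=5)), {"type": "q_translocation"})
        call = call_clusters(extract_signature(truth.annotation))
        assert call.iqm_label == "MI"
        [dev] = [d for d in call.deviations if d["gene"] == "Q"]
        assert dev["type"] == "translocation"
        assert set(dev["neighbours"]) == {"rrnS", "CR"}


class TestBreakpointDistance:
    def test_identical_signatures_zero(self, ibericum):
        sig = extract_signature(ibericum)
        assert breakpoint_distance(sig, sig) == 0

    def test_single_swap_on_toy_circle_matches_oracle(self):
        a = GeneOrderSignature(tuple((g, "H") for g in "abcde"))
        b = GeneOrderSignature(
            (("a", "H"), ("c", "H"), ("b", "H"), ("d", "H"), ("e", "H"))
        )
        assert breakpoint_distance(a, b) == brute_force_distance(a, b)
        assert breakpoint_distance(a, b) > 0

    def test_ancestral_vs_fixture_matches_oracle(self, ibericum):
        sig = extract_signature(ibericum)
        anc = ancestral_signature()
        assert breakpoint_distance(sig, anc) == brute_force_distance(sig, anc)

    def test_pseudometric_on_random_signatures(self):
        rng = random.Random(42)
        genes = list("abcdefg")
        sigs = [random_signature(rng, genes) for _ in range(12)]
        for s in sigs:
            assert breakpoint_distance(s, s) == 0
        for x in sigs[:6]:
            for y in sigs[6:]:
                assert breakpoint_distance(x, y) == breakpoint_distance(y, x)
        for x, y, z in zip(sigs[:4], sigs[4:8], sigs[8:]):
            assert breakpoint_distance(x, z) <= (
                breakpoint_distance(x, y) + breakpoint_distance(y, z)
            )

    def test_zero_iff_rotation_equal(self):
        rng = random.Random(7)
        genes = list("abcdef")
        for _ in range(20):
            x, y = random_signature(rng, genes), random_signature(rng, genes)
            assert (breakpoint_distance(x, y) == 0) == (x == y)

    def test_disjoint_alphabets_rejected(self):
        a = GeneOrderSignature((("x", "H"), ("y", "H")))
        b = GeneOrderSignature((("u", "H"), ("v", "H")))
        with pytest.raises(ValueError):
            breakpoint_distance(a, b)


class TestInferEvents:
    def test_wcy_to_wyc_is_a_cy_shift_with_alternative(self):
        anc = ancestral_signature()
        var = GeneOrderSignature(resolve_gene_order("WYC"))
        [event] = infer_events(anc, var)
        assert event["gene"] == "C"  # lexicographic tie-break
        assert "Y" in event["alternatives"]
        assert event["type"] in ("local-shift", "translocation")

    def test_iqm_to_miq_is_a_single_m_event(self):
        anc = ancestral_signature()
        var = GeneOrderSignature(resolve_gene_order("MIQ"))
        [event] = infer_events(anc, var)
        assert event["gene"] == "M"

    def test_identity_gives_no_events(self):
        anc = ancestral_signature()
        assert infer_events(anc, anc) == []

    def test_planted_random_translocations_recovered(self):
        rng = random.Random(11)
        anc = ancestral_signature()
        trnas = [g for g, _ in ANCESTRAL_ORDER if len(g) <= 2 and g != "CR"]
        recovered = 0
        trials = 30
        for _ in range(trials):
            gene = rng.choice(trnas)
            others = [g for g, _ in ANCESTRAL_ORDER if g != gene]
            after = rng.choice(others)
            order = [e for e in ANCESTRAL_ORDER if e[0] != gene]
            idx = [g for g, _ in order].index(after)
            order.insert(idx + 1, (gene, dict(ANCESTRAL_ORDER)[gene]))
            moved = GeneOrderSignature(tuple(order))
            events = infer_events(anc, moved)
            if moved == anc:
                recovered += events == []
                continue
            assert len(events) == 1
            cands = {events[0]["gene"], *events[0].get("alternatives", ())}
            recovered += gene in cands
        assert recovered == trials
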