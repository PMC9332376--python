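"""Synthetic circular mitogenomes with fully known (planted) structure.

The generator emulates an ant-like mitogenome: 13 protein-coding genes,
22 tRNAs, 2 rRNAs and one control region on a ~15.7 kb circle, with an
A+T fraction of 0.848, codon usage drawn from the *Tapinoma ibericum*
profile, small intergenic spacers, the two junction overlaps observed in
that genome (-3 at I/Q, -7 at atp8/atp6 through the conserved ATGATAA
motif), and a control region that can carry planted tandem repeats and a
planted perfect stem-loop.

Every realized property is returned as a :class:`SyntheticTruth`, so each
analysis stage can be tested round-trip without downloading anything.
Generation is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .composition import count_codons, extract_cds
from .control_region import StemLoop, TandemRepeat, verify_repeat, verify_stem_loop
from .datasets import tapinoma_ibericum_codon_counts
from .gene_order import ANCESTRAL_ORDER, Element, GeneOrderSignature
from .model import (
    GeneFeature,
    GeneticCode,
    INVERTEBRATE_MITO,
    MitoAnnotation,
    kind_of,
    reverse_complement,
    translate,
)

__all__ = ["CRSpec", "SimSpec", "SyntheticTruth", "simulate", "perturb",
           "resolve_gene_order"]


# Gene lengths modelled on the T. ibericum annotation (bp).
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "nad2": 984, "cox1": 1530, "cox2": 690, "atp8": 162, "atp6": 669,
    "cox3": 783, "nad3": 351, "nad5": 1668, "nad4": 1341, "nad4l": 288,
    "nad6": 546, "cob": 1122, "nad1": 948,
    "M": 68, "I": 66, "Q": 69, "W": 74, "Y": 69, "C": 67, "L1": 66,
    "K": 73, "D": 69, "G": 68, "A": 73, "R": 76, "N": 69, "S1": 63,
    "E": 71, "F": 72, "H": 69, "T": 71, "P": 72, "S2": 67, "L2": 72,
    "V": 72, "rrnL": 1345, "rrnS": 791,
}

# Spacer (positive) and overlap (negative) lengths planted by default,
# keyed by (upstream, downstream) on the H-strand circle; junctions not
# listed get a small random spacer.
DEFAULT_JUNCTIONS: dict[tuple[str, str], int] = {
    ("Q", "nad2"): 104,
    ("I", "Q"): -3,
    ("atp8", "atp6"): -7,
    ("nad4", "nad4l"): 5,
}

ATP_JUNCTION_MOTIF = "ATGATAA"


@dataclass(frozen=True)
class CRSpec:
    """Planted control-region structure.

    ``repeats`` is a list of (period, copies) tandem arrays; ``stem_loop``
    an optional (stem_len, loop_len) perfect hairpin placed in the last
    part of the region, as observed in *Tapinoma* control regions.
    """

    length: int = 341
    repeats: tuple[tuple[int, int], ...] = ()
    stem_loop: Optional[tuple[int, int]] = (12, 5)
    at_fraction: float = 0.99  # control regions are nearly pure A+T


@dataclass(frozen=True)
class SimSpec:
    seed: int = 0
    gene_order: Union[str, tuple[Element, ...]] = "MIQ+WYC"
    at_fraction: float = 0.848  # genome-wide target
    rrna_at: float = 0.885  # rRNAs sit near 88-89% A+T
    codon_profile: Optional[dict[str, float]] = None  # default: study profile
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    junction_overrides: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_JUNCTIONS)
    )
    default_spacer_max: int = 10  # unlisted junctions: uniform 0..max
    cr: CRSpec = CRSpec()
    stop_codons: dict[str, str] = field(default_factory=dict)  # per-gene stop
    code: GeneticCode = INVERTEBRATE_MITO
    name: str = "synthetic"


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for round-trip testing."""

    spec: SimSpec
    annotation: MitoAnnotation
    gene_order: tuple[Element, ...]
    iqm_label: str
    wcy_label: str
    ign: list[tuple[str, str, int]]  # (upstream, downstream, ign)
    cr_span: tuple[int, int, int]
    planted_repeats: list[TandemRepeat]  # coordinates relative to the CR
    planted_stem_loop: Optional[StemLoop]  # idem
    codon_counts: dict[str, int]


# ---------------------------------------------------------------------------
# gene-order arrangements
# ---------------------------------------------------------------------------

_STRAND_OF = {g: s for g, s in ANCESTRAL_ORDER}

_NAMED_IQM = {"IQM": ("I", "Q", "M"), "MIQ": ("M", "I", "Q"),
              "QMI": ("Q", "M", "I"), "IMQ": ("I", "M", "Q")}
_NAMED_WCY = {"WCY": ("W", "C", "Y"), "WYC": ("W", "Y", "C")}


def resolve_gene_order(spec: Union[str, Sequence[Element]]) -> tuple[Element, ...]:
    """Resolve an arrangement name ('ancestral', 'MIQ+WYC', ...) or an
    explicit element list into a concrete signed order."""
    if not isinstance(spec, str):
        return tuple(spec)
    name = spec.strip()
    if name.lower() == "ancestral":
        return ANCESTRAL_ORDER
    iqm, wcy = "IQM", "WCY"
    for part in name.replace("-", "+").split("+"):
        p = part.strip().upper()
        if p in _NAMED_IQM:
            iqm = p
        elif p in _NAMED_WCY:
            wcy = p
        elif p:
            raise ValueError(f"unknown arrangement component {part!r}")
    order: list[Element] = []
    i = 0
    anc = list(ANCESTRAL_ORDER)
    while i < len(anc):
        g, s = anc[i]
        if g == "I":  # start of the IQM block
            order.extend((x, _STRAND_OF[x]) for x in _NAMED_IQM[iqm])
            i += 3
        elif g == "W":  # start of the WCY block
            order.extend((x, _STRAND_OF[x]) for x in _NAMED_WCY[wcy])
            i += 3
        else:
            order.append((g, s))
            i += 1
    return tuple(order)


def _cluster_labels(order: Sequence[Element]) -> tuple[str, str]:
    tokens = [g for g, _ in order]
    n = len(tokens)

    def arc(a: str, b: str) -> list[str]:
        i, j = tokens.index(a), tokens.index(b)
        out, k = [], (i + 1) % n
        while k != j:
            out.append(tokens[k])
            k = (k + 1) % n
        return out

    iqm = "".join(g for g in arc("CR", "nad2") if g in {"I", "Q", "M"})
    wcy = "".join(g for g in arc("nad2", "cox1") if g in {"W", "C", "Y"})
    return iqm, wcy


# ---------------------------------------------------------------------------
# sequence synthesis helpers
# ---------------------------------------------------------------------------

def _default_codon_profile() -> dict[str, float]:
    counts = tapinoma_ibericum_codon_counts()
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


def _filler(rng: np.random.Generator, n: int, at: float) -> str:
    """Non-coding filler: A/T with probability ``at``, else G/C."""
    bases = np.where(
        rng.random(n) < at,
        rng.choice(np.array(["A", "T"]), size=n),
        rng.choice(np.array(["G", "C"]), size=n),
    )
    return "".join(bases)


def _sample_codons(
    rng: np.random.Generator,
    n: int,
    profile: dict[str, float],
    stops: frozenset[str],
) -> list[str]:
    codons = [c for c in sorted(profile) if c not in stops]
    probs = np.array([profile[c] for c in codons], dtype=float)
    probs /= probs.sum()
    idx = rng.choice(len(codons), size=n, p=probs)
    return [codons[i] for i in idx]


def _make_cds(
    rng: np.random.Generator,
    gene: str,
    length: int,
    profile: dict[str, float],
    code: GeneticCode,
    stop: str,
    start: str = "ATG",
    pin_prefix: bool = False,
    pin_suffix: bool = False,
) -> str:
    """A CDS of exactly ``length`` bp: start codon, stop-free body, stop.

    ``stop`` may be incomplete (TA or T), in which case the body is
    extended so the total length still matches.  ``pin_prefix`` forces
    the CDS to open with the conserved ATGATAA junction window (a gene
    whose start codon sits inside an overlap, like atp6 or nad4);
    ``pin_suffix`` forces it to close with that window (the upstream
    partner, like atp8, whose TAA stop is the window's tail).  The
    window starts mid-codon on the suffix side, so the two bases before
    it are pinned to make the straddling codon ATA, never a premature
    stop.
    """
    body_bp = length - 3 - len(stop)
    if body_bp < 0 or body_bp % 3:
        raise ValueError(
            f"{gene}: length {length} incompatible with start+stop ({stop!r})"
        )
    body = _sample_codons(rng, body_bp // 3, profile, code.stop_codons)
    seq = start + "".join(body) + stop
    if pin_suffix:
        seq = seq[: length - 9] + "AT" + ATP_JUNCTION_MOTIF
    if pin_prefix:
        seq = ATP_JUNCTION_MOTIF + seq[len(ATP_JUNCTION_MOTIF):]
    return seq


def _profile_at(profile: dict[str, float]) -> float:
    return sum(
        p * sum(1 for b in codon if b in "AT") / 3
        for codon, p in profile.items()
    ) / sum(profile.values())


def _build_control_region(
    rng: np.random.Generator, cr: CRSpec
) -> tuple[str, list[TandemRepeat], Optional[StemLoop]]:
    at = cr.at_fraction
    s = list(_filler(rng, cr.length, at))
    planted_reps: list[TandemRepeat] = []
    cursor = 10  # leave unstructured flanks
    for period, copies in cr.repeats:
        span = period * copies
        if cursor + span + 2 > cr.length:
            raise ValueError("planted repeats do not fit inside the CR")
        motif = _primitive_motif(rng, period, at)
        block = (motif * copies)[:span]
        s[cursor : cursor + span] = block
        # break tandem extension on both flanks
        if cursor >= 1 and s[cursor - 1] == s[cursor - 1 + period]:
            s[cursor - 1] = _other_base(s[cursor - 1])
        end = cursor + span
        if end < cr.length and s[end] == s[end - period]:
            s[end] = _other_base(s[end])
        planted_reps.append(
            TandemRepeat(
                start=cursor + 1, period=period, copies=float(copies),
                consensus=motif,
            )
        )
        cursor = end + max(period, 10)
    hairpin = None
    if cr.stem_loop is not None:
        stem, loop = cr.stem_loop
        span = 2 * stem + loop
        # place in the last part of the region, as in Tapinoma CRs
        a = cr.length - span - 12
        if a <= cursor:
            raise ValueError("planted stem-loop does not fit inside the CR")
        arm = _filler(rng, stem, at)
        loop_seq = list(_filler(rng, loop, at))
        loop_seq[0] = "A"
        loop_seq[-1] = "A"  # A/A cannot pair: blocks inward extension
        block = arm + "".join(loop_seq) + reverse_complement(arm)
        s[a : a + span] = block
        # block outward extension
        if a >= 1:
            s[a - 1] = _non_complement(rng, s[a + span]) if a + span < cr.length else "A"
        if a + span < cr.length:
            s[a + span] = _non_complement(rng, s[a - 1])
        hairpin = StemLoop(
            stem_len=stem, loop_len=loop,
            five_arm=(a + 1, a + stem),
            three_arm=(a + stem + loop + 1, a + span),
        )
    return "".join(s), planted_reps, hairpin


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _other_base(b: str) -> str:
    return "T" if b == "A" else "A"


def _non_complement(rng: np.random.Generator, b: str) -> str:
    choices = [x for x in "AT" if x != _COMP.get(b)]
    return choices[int(rng.integers(len(choices)))]


def _primitive_motif(rng: np.random.Generator, period: int, at: float) -> str:
    """AT-biased motif whose tandem concatenation has no shorter period."""
    for _ in range(100):
        motif = _filler(rng, period, at)
        run = motif * 3
        if all(
            any(run[i] != run[i + d] for i in range(len(run) - d))
            for d in range(1, period)
        ):
            return motif
    raise RuntimeError("could not draw a primitive motif")


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate(spec: SimSpec) -> SyntheticTruth:
    """Realize a :class:`SimSpec` into a sequence-bearing annotation.

    The genome is assembled feature by feature along the requested gene
    order starting with the control region at position 1.  Overlapping
    junctions reuse the bases already written by the upstream gene; the
    engineered atp8/atp6 motif guarantees both reading frames stay valid.
    The result is self-verified (CDS translate without internal stops,
    planted repeats and hairpins re-checked literally) before return.
    """
    rng = np.random.default_rng(spec.seed)
    order = resolve_gene_order(spec.gene_order)
    tokens = [g for g, _ in order]
    if "CR" not in tokens:
        raise ValueError("gene order must include the control region (CR)")
    # rotate so CR comes first: the CR then occupies positions 1..len
    i = tokens.index("CR")
    order = order[i:] + order[:i]

    profile = spec.codon_profile or _default_codon_profile()

    # first pass: draw every junction length, lay out coordinates, and
    # solve for the tRNA/spacer filler A+T that makes the genome-wide
    # composition hit ``at_fraction`` in expectation (the coding, rRNA
    # and control-region classes have their own compositions, as real
    # mitogenomes do)
    igns: list[int] = []
    prev = "CR"
    for gene, _ in order[1:]:
        if (prev, gene) in spec.junction_overrides:
            igns.append(spec.junction_overrides[(prev, gene)])
        elif prev == "CR":
            # the control region is annotated as every base between its
            # flanking genes, so it abuts them unless told otherwise
            igns.append(0)
        else:
            igns.append(int(rng.integers(0, spec.default_spacer_max + 1)))
        prev = gene
    genome_length = spec.cr.length + sum(
        spec.gene_lengths[g] + ign for (g, _), ign in zip(order[1:], igns)
    )
    pcg_bp = sum(spec.gene_lengths[g] for g, _ in order[1:] if kind_of(g) == "PCG")
    rrn_bp = sum(spec.gene_lengths[g] for g, _ in order[1:] if kind_of(g) == "rRNA")
    filler_bp = genome_length - pcg_bp - rrn_bp - spec.cr.length
    target_at_bp = spec.at_fraction * genome_length
    fixed_at_bp = (
        _profile_at(profile) * pcg_bp
        + spec.rrna_at * rrn_bp
        + spec.cr.at_fraction * spec.cr.length
    )
    filler_at = (
        float(np.clip((target_at_bp - fixed_at_bp) / filler_bp, 0.02, 0.98))
        if filler_bp > 0
        else spec.at_fraction
    )

    cr_seq, planted_reps, hairpin = _build_control_region(rng, spec.cr)

    genome: list[Optional[str]] = []

    def write(pos0: int, seq: str, gene: str, engineered_overlap: bool) -> None:
        """Write H-strand bases at 0-based pos0, reusing existing bases in
        overlap regions."""
        need = pos0 + len(seq) - len(genome)
        if need > 0:
            genome.extend([None] * need)
        for k, b in enumerate(seq):
            cur = genome[pos0 + k]
            if cur is None:
                genome[pos0 + k] = b
            elif cur != b and not engineered_overlap:
                raise ValueError(f"{gene}: inconsistent overlap at {pos0 + k + 1}")

    features: list[GeneFeature] = []
    ign_truth: list[tuple[str, str, int]] = []
    # control region first
    write(0, cr_seq, "CR", False)
    features.append(
        GeneFeature(name="CR", kind="CR", strand="H", start=1, end=spec.cr.length)
    )
    prev_gene = "CR"
    prev_end = spec.cr.length  # 1-based end of previous feature

    start_codon_cycle = ["ATG", "ATT", "ATA", "ATG", "ATC", "ATG"]
    n_pcg = 0

    for (gene, strand), ign in zip(order[1:], igns):
        kind = kind_of(gene)
        length = spec.gene_lengths[gene]
        start = prev_end + ign + 1
        if start < 1:
            raise ValueError(f"{gene}: overlap exceeds upstream gene")
        if kind == "PCG":
            stop = spec.stop_codons.get(gene, "TAA")
            start_codon = start_codon_cycle[n_pcg % len(start_codon_cycle)]
            n_pcg += 1
            coding = _make_cds(
                rng, gene, length, profile, spec.code, stop, start_codon,
                # nad4 opens with the conserved window in these ants even
                # though the ancestral overlap is gone
                pin_prefix=gene in ("atp6", "nad4"),
                pin_suffix=(gene == "atp8")
                or (gene == "nad4l" and ign == -7),
            )
            feat = GeneFeature(
                name=gene, kind=kind, strand=strand,
                start=start, end=start + length - 1,
                start_codon=coding[:3],
                stop_codon=stop,
            )
        else:
            coding = _filler(rng, length, spec.rrna_at if kind == "rRNA" else filler_at)
            feat = GeneFeature(
                name=gene, kind=kind, strand=strand,
                start=start, end=start + length - 1,
            )
        h_strand = coding if strand == "H" else reverse_complement(coding)
        engineered = ign < 0 and gene in ("atp6", "nad4l")
        write(start - 1, h_strand, gene, engineered or kind != "PCG")
        ign_truth.append((prev_gene, gene, ign))
        prev_gene, prev_end = gene, feat.end
        features.append(feat)

    # wrap junction back to the CR: abutting by construction
    ign_truth.append((prev_gene, "CR", 0))
    assert prev_end == genome_length
    spacer_fill = iter(_filler(rng, genome_length, filler_at))
    sequence = "".join(
        b if b is not None else next(spacer_fill) for b in genome[:genome_length]
    )

    ann = MitoAnnotation(
        genome_length=genome_length,
        features=features,
        circular=True,
        sequence=sequence,
        name=spec.name,
    )
    _self_verify(ann, spec, planted_reps, hairpin)
    iqm, wcy = _cluster_labels(order)
    return SyntheticTruth(
        spec=spec,
        annotation=ann,
        gene_order=order,
        iqm_label=iqm,
        wcy_label=wcy,
        ign=ign_truth,
        cr_span=(1, spec.cr.length, spec.cr.length),
        planted_repeats=planted_reps,
        planted_stem_loop=hairpin,
        codon_counts=dict(count_codons(extract_cds(ann), code=spec.code).counts),
    )


def _self_verify(
    ann: MitoAnnotation,
    spec: SimSpec,
    reps: list[TandemRepeat],
    hairpin: Optional[StemLoop],
) -> None:
    for cds in extract_cds(ann):
        expected_stop = spec.stop_codons.get(cds.gene, "TAA")
        body = cds.seq[: len(cds.seq) - (len(cds.seq) % 3)]
        aa = translate(body, spec.code).protein
        if "*" in aa[:-1]:
            raise AssertionError(f"{cds.gene}: internal stop codon in synthesis")
        if expected_stop in ("TAA", "TAG") and not aa.endswith("*"):
            raise AssertionError(f"{cds.gene}: missing stop codon")
    cr = ann.slice(1, spec.cr.length)
    for r in reps:
        if not verify_repeat(cr, r):
            raise AssertionError("planted tandem repeat does not verify")
    if hairpin is not None and not verify_stem_loop(cr, hairpin):
        raise AssertionError("planted stem-loop does not verify")


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def perturb(truth: SyntheticTruth, event: dict) -> SyntheticTruth:
    """Apply one named rearrangement to a synthetic genome and resimulate.

    Supported events: ``{"type": "identity"}``; ``{"type": "cy_shift"}``
    (swap C and Y, the *Tapinoma* synapomorphy); ``{"type":
    "q_translocation"}`` (move Q between rrnS and the CR, as in
    *D. lamellosus*); ``{"type": "translocate", "gene": g, "after": x}``.
    """
    order = list(truth.gene_order)
    tokens = [g for g, _ in order]
    etype = event.get("type")
    if etype == "identity":
        new_order = order
    elif etype == "cy_shift":
        ic, iy = tokens.index("C"), tokens.index("Y")
        order[ic], order[iy] = order[iy], order[ic]
        new_order = order
    elif etype == "q_translocation":
        q = order.pop(tokens.index("Q"))
        tokens = [g for g, _ in order]
        order.insert(tokens.index("rrnS") + 1, q)
        new_order = order
    elif etype == "translocate":
        gene, after = event["gene"], event["after"]
        if gene not in tokens or after not in tokens:
            raise ValueError(f"event references missing gene: {event}")
        el = order.pop(tokens.index(gene))
        tokens = [g for g, _ in order]
        order.insert(tokens.index(after) + 1, el)
        new_order = order
    else:
        raise ValueError(f"unknown event type {etype!r}")
    if len({g for g, _ in new_order}) != len(new_order):
        raise ValueError("event would duplicate a gene")
    # moved genes may break planted junction constraints; keep only the
    # overrides whose adjacency survives
    adj = {(a, b) for (a, _), (b, _) in zip(new_order, new_order[1:] + new_order[:1])}
    overrides = {
        j: v for j, v in truth.spec.junction_overrides.items() if j in adj
    }
    new_spec = replace(
        truth.spec, gene_order=tuple(new_order), junction_overrides=overrides
    )
    return simulate(new_spec)
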