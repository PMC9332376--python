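"""Circular gene-order signatures and rearrangement calls.

A mitogenome's gene order is modelled as a circular signed permutation of
the 37 genes plus the control region (CR).  Two orders are equal when one
is a rotation of the other; reflections are *not* identified, because the
strand annotation fixes the reading direction.

Rearrangements in ants concentrate in two tRNA clusters flanking nad2:
the Ile-Gln-Met (IQM) cluster between the control region and nad2, and
the Trp-Cys-Tyr (WCY) cluster between nad2 and cox1.  The observed
letter orders of these clusters (MIQ, QMI, WYC, ...) are widely used as
phylogenetic characters; cluster labels here ignore strand, which is
carried separately in the signature.

Distances between orders are measured as the breakpoint distance: the
number of signed adjacencies (neighbour pairs on the circle) of one order
that are absent from the other.  It is zero iff the orders are equal up
to rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import MitoAnnotation

__all__ = [
    "GeneOrderSignature",
    "ArrangementCall",
    "ANCESTRAL_ORDER",
    "ancestral_signature",
    "extract_signature",
    "call_clusters",
    "breakpoint_distance",
    "infer_events",
]

Element = tuple[str, str]  # (gene token, strand 'H'/'L')

#: Ancestral pancrustacean-insect gene order, read H-strandwise from the
#: control region.  Minority-strand genes follow the standard insect
#: arrangement.
ANCESTRAL_ORDER: tuple[Element, ...] = (
    ("CR", "H"),
    ("I", "H"), ("Q", "L"), ("M", "H"),
    ("nad2", "H"),
    ("W", "H"), ("C", "L"), ("Y", "L"),
    ("cox1", "H"), ("L1", "H"), ("cox2", "H"),
    ("K", "H"), ("D", "H"),
    ("atp8", "H"), ("atp6", "H"), ("cox3", "H"),
    ("G", "H"), ("nad3", "H"),
    ("A", "H"), ("R", "H"), ("N", "H"), ("S1", "H"), ("E", "H"),
    ("F", "L"), ("nad5", "L"), ("H", "L"),
    ("nad4", "L"), ("nad4l", "L"),
    ("T", "H"), ("P", "L"),
    ("nad6", "H"), ("cob", "H"), ("S2", "H"),
    ("nad1", "L"), ("L2", "L"), ("rrnL", "L"), ("V", "L"), ("rrnS", "L"),
)


@dataclass(frozen=True)
class GeneOrderSignature:
    """Circular signed gene order, conventionally rotated to start at CR."""

    order: tuple[Element, ...]
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tokens = [g for g, _ in self.order]
        if len(tokens) != len(set(tokens)):
            raise ValueError("duplicate gene token in signature")
        object.__setattr__(self, "order", _rotate_to_anchor(self.order))

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.order)

    def restrict(self, alphabet: Iterable[str]) -> "GeneOrderSignature":
        keep = set(alphabet)
        return GeneOrderSignature(
            tuple(e for e in self.order if e[0] in keep)
        )

    def adjacencies(self) -> frozenset:
        return _adjacencies(self.order)

    def rotation_equal(self, other: "GeneOrderSignature") -> bool:
        return _rotation_equal(self.order, other.order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrderSignature):
            return NotImplemented
        return self.rotation_equal(other)

    def __hash__(self) -> int:
        return hash(frozenset(self.order))


def _rotate_to_anchor(order: Sequence[Element]) -> tuple[Element, ...]:
    order = tuple(order)
    if not order:
        return order
    tokens = [g for g, _ in order]
    if "CR" in tokens:
        i = tokens.index("CR")
    else:
        i = min(range(len(order)), key=lambda k: order[k:] + order[:k])
    return order[i:] + order[:i]


def _rotation_equal(a: Sequence[Element], b: Sequence[Element]) -> bool:
    a, b = tuple(a), tuple(b)
    if len(a) != len(b):
        return False
    if not a:
        return True
    return any(b[i:] + b[:i] == a for i in range(len(b)))


def _adjacencies(order: Sequence[Element]) -> frozenset:
    """Signed adjacencies of a circular order, direction-independent.

    The adjacency of consecutive elements (x, sx)(y, sy) equals the
    adjacency (y, -sy)(x, -sx) seen when traversing the circle the other
    way; each pair is stored in a canonical one of the two forms.
    """
    flip = {"H": "L", "L": "H"}
    adj = set()
    n = len(order)
    for i in range(n):
        x, y = order[i], order[(i + 1) % n]
        fwd = (x, y)
        rev = ((y[0], flip[y[1]]), (x[0], flip[x[1]]))
        adj.add(min(fwd, rev))
    return frozenset(adj)


def ancestral_signature() -> GeneOrderSignature:
    return GeneOrderSignature(ANCESTRAL_ORDER)


def extract_signature(ann: MitoAnnotation) -> GeneOrderSignature:
    """Signed circular gene order of an annotation, CR first.

    Features are ordered by start position on the H strand; genes from
    the canonical 38-token alphabet that are absent are reported in
    ``missing``.
    """
    feats = sorted(ann.features, key=lambda f: (f.start, f.end))
    order = tuple((f.name, f.strand if f.kind != "CR" else "H") for f in feats)
    from .model import ALL_GENE_NAMES

    missing = tuple(g for g in ALL_GENE_NAMES if g not in {f.name for f in feats})
    return GeneOrderSignature(order, missing=missing)


@dataclass(frozen=True)
class ArrangementCall:
    iqm_label: str
    wcy_label: str
    deviations: tuple[dict, ...] = ()
    breakpoint_distance_to_ancestral: int = 0
    warnings: tuple[str, ...] = ()


def _arc(sig: GeneOrderSignature, a: str, b: str) -> list[Element]:
    """Elements strictly between tokens a and b walking forward on the circle."""
    tokens = sig.tokens
    if a not in tokens or b not in tokens:
        raise ValueError(f"anchors {a!r}/{b!r} not both present")
    i, j = tokens.index(a), tokens.index(b)
    n = len(tokens)
    out = []
    k = (i + 1) % n
    while k != j:
        out.append(sig.order[k])
        k = (k + 1) % n
    return out


def call_clusters(sig: GeneOrderSignature) -> ArrangementCall:
    """Name the IQM- and WCY-region arrangements of a signature.

    The IQM label is the observed order of {I, Q, M} between CR and nad2;
    the WCY label the order of {W, C, Y} between nad2 and cox1.  Cluster
    genes found outside their expected region are reported as
    translocations with their observed neighbours.
    """
    warnings: list[str] = []
    deviations: list[dict] = []

    def region_label(a: str, b: str, letters: set[str]) -> str:
        try:
            arc = _arc(sig, a, b)
        except ValueError as e:
            warnings.append(str(e))
            return ""
        label = "".join(g for g, _ in arc if g in letters)
        missing = letters - set(g for g, _ in arc)
        tokens = sig.tokens
        for g in sorted(missing):
            if g not in tokens:
                warnings.append(f"{g} absent from genome")
                continue
            i = tokens.index(g)
            n = len(tokens)
            deviations.append(
                {
                    "type": "translocation",
                    "gene": g,
                    "expected_region": f"{a}..{b}",
                    "neighbours": (tokens[i - 1], tokens[(i + 1) % n]),
                }
            )
        return label

    iqm = region_label("CR", "nad2", {"I", "Q", "M"})
    wcy = region_label("nad2", "cox1", {"W", "C", "Y"})
    dist = breakpoint_distance(sig, ancestral_signature())
    return ArrangementCall(
        iqm_label=iqm,
        wcy_label=wcy,
        deviations=tuple(deviations),
        breakpoint_distance_to_ancestral=dist,
        warnings=tuple(warnings),
    )


def breakpoint_distance(a: GeneOrderSignature, b: GeneOrderSignature) -> int:
    """Number of adjacencies of ``a`` (restricted to the shared gene set)
    absent from ``b``; symmetric on equal alphabets, 0 iff rotation-equal."""
    shared = set(a.tokens) & set(b.tokens)
    if not shared:
        raise ValueError("signatures share no genes")
    ra, rb = a.restrict(shared), b.restrict(shared)
    return len(ra.adjacencies() - rb.adjacencies())


def infer_events(a: GeneOrderSignature, b: GeneOrderSignature) -> list[dict]:
    """Greedy single-gene explanation of the difference between two orders.

    Any gene whose removal from both orders makes them rotation-equal is
    a candidate single-gene event; the lexicographically smallest is
    reported, the others noted as equivalent alternatives.  Differences
    not explainable by one gene are returned as an ``unresolved`` record
    carrying the adjacency differences.
    """
    shared = sorted(set(a.tokens) & set(b.tokens))
    ra, rb = a.restrict(shared), b.restrict(shared)
    if ra.rotation_equal(rb):
        return []

    candidates = []
    for g in shared:
        rest = [x for x in shared if x != g]
        if ra.restrict(rest).rotation_equal(rb.restrict(rest)):
            candidates.append(g)
    if candidates:
        gene = candidates[0]
        ta, tb = ra.tokens, rb.tokens

        def neighbours(tokens: tuple[str, ...], g: str) -> tuple[str, str]:
            i = tokens.index(g)
            return (tokens[i - 1], tokens[(i + 1) % len(tokens)])

        sa = dict(ra.order)[gene]
        sb = dict(rb.order)[gene]
        na, nb = neighbours(ta, gene), neighbours(tb, gene)
        if sa != sb and na == nb:
            etype = "inversion"
        elif set(na) & set(nb):
            etype = "local-shift"
        else:
            etype = "translocation"
        return [
            {
                "type": etype,
                "gene": gene,
                "from_neighbours": na,
                "to_neighbours": nb,
                "strand_change": sa != sb,
                "alternatives": tuple(candidates[1:]),
            }
        ]
    return [
        {
            "type": "unresolved",
            "adjacency_differences": sorted(
                map(repr, ra.adjacencies() ^ rb.adjacencies())
            ),
        }
    ]
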