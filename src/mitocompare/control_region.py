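"""Control-region characterisation: span, tandem repeats, stem-loops.

The control region (A+T-rich region) is the major non-coding stretch of
the mitogenome, downstream of the small rRNA.  Its diagnostic features in
ants are internal tandem repeats (periods of roughly 11-33 bp have been
reported across Dolichoderinae) and a short hairpin of ~27-30 bp total
span whose two arms pair with a *perfect* match.

Both finders are exhaustive scans -- control regions are a few hundred
bp, so quadratic/cubic enumeration is instantaneous and easy to verify
against brute force.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .composition import at_content
from .model import MitoAnnotation, feature_length, reverse_complement

__all__ = [
    "TandemRepeat",
    "StemLoop",
    "control_region_span",
    "find_tandem_repeats",
    "find_stem_loops",
    "control_region_report",
]


@dataclass(frozen=True)
class TandemRepeat:
    """A tandem array: ``copies`` repeats of ``consensus`` starting at
    1-based ``start`` within the searched region.  The final copy may be
    fractional (arrays often end mid-motif)."""

    start: int
    period: int
    copies: float
    consensus: str

    @property
    def span(self) -> int:
        return round(self.period * self.copies)


@dataclass(frozen=True)
class StemLoop:
    """A perfect hairpin: ``five_arm`` and ``three_arm`` are 1-based
    inclusive intervals whose sequences are exact reverse complements."""

    stem_len: int
    loop_len: int
    five_arm: tuple[int, int]
    three_arm: tuple[int, int]

    @property
    def span(self) -> int:
        return 2 * self.stem_len + self.loop_len


def control_region_span(ann: MitoAnnotation) -> tuple[int, int, int]:
    """(start, end, length) of the control region.

    Uses the annotated CR feature when present; otherwise the largest
    inter-feature gap on the circle (the usual location, flanked by the
    small rRNA) is taken as the candidate.
    """
    cr = next((f for f in ann.features if f.kind == "CR"), None)
    if cr is not None:
        return cr.start, cr.end, feature_length(cr, ann.genome_length)
    feats = sorted(ann.features, key=lambda f: (f.start, f.end))
    if not feats:
        raise ValueError("no features to infer a control region from")
    best: Optional[tuple[int, int, int]] = None
    n = len(feats)
    for i, f in enumerate(feats):
        g = feats[(i + 1) % n]
        gap = g.start - f.end - 1
        if i + 1 == n:
            gap = g.start + ann.genome_length - f.end - 1
        if gap > 0:
            start = f.end + 1
            end = f.end + gap
            if start > ann.genome_length:
                start -= ann.genome_length
            if end > ann.genome_length:
                end -= ann.genome_length
            if best is None or gap > best[2]:
                best = (start, end, gap)
    if best is None:
        raise ValueError("no unannotated stretch found")
    return best


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def find_tandem_repeats(
    region: str, min_period: int = 8, min_copies: float = 2.0
) -> list[TandemRepeat]:
    """Maximal tandem repeats of ``region`` with period >= ``min_period``
    and at least ``min_copies`` copies.

    A candidate at (start, period) is the maximal run of positions i with
    region[i] == region[i - period].  Runs that are sub-intervals of a
    longer-span run are dropped; runs covering the same interval at a
    multiple of a shorter period are reported once, at the shortest
    (primitive) period.  Results are sorted by span (desc) then position.
    """
    s = region.upper()
    n = len(s)
    candidates: list[TandemRepeat] = []
    for p in range(min_period, n // 2 + 1):
        i = 0
        while i + p < n:
            if s[i] != s[i + p]:
                i += 1
                continue
            j = i
            while j + p < n and s[j] == s[j + p]:
                j += 1
            span = (j + p) - i  # run of matches plus one period
            copies = span / p
            if copies >= min_copies:
                candidates.append(
                    TandemRepeat(
                        start=i + 1,
                        period=p,
                        copies=round(copies, 4),
                        consensus=s[i : i + p],
                    )
                )
            i = j + 1
    # drop nested/equivalent reports: keep the shortest period for each
    # maximal spanned interval
    candidates.sort(key=lambda r: (-r.span, r.start, r.period))
    kept: list[TandemRepeat] = []
    for r in candidates:
        r_lo, r_hi = r.start, r.start + r.span - 1
        nested = False
        for k in kept:
            k_lo, k_hi = k.start, k.start + k.span - 1
            if r_lo >= k_lo and r_hi <= k_hi and r.period % k.period == 0:
                nested = True
                break
            if r_lo >= k_lo and r_hi <= k_hi and k.period % r.period == 0:
                nested = True
                break
            if r_lo >= k_lo and r_hi <= k_hi and r.period == k.period:
                nested = True
                break
        if not nested:
            kept.append(r)
    kept.sort(key=lambda r: (-r.span, r.start, r.period))
    return kept


def verify_repeat(region: str, rep: TandemRepeat) -> bool:
    """Independent check that a reported repeat is literally present."""
    s = region.upper()
    seg = s[rep.start - 1 : rep.start - 1 + rep.span]
    motif = rep.consensus.upper()
    full = motif * (len(seg) // len(motif) + 1)
    return len(seg) >= 2 * rep.period and seg == full[: len(seg)]


# ---------------------------------------------------------------------------
# stem-loops
# ---------------------------------------------------------------------------

def find_stem_loops(
    region: str,
    min_stem: int = 8,
    loop_range: tuple[int, int] = (3, 15),
) -> list[StemLoop]:
    """All maximal perfect inverted repeats (hairpins) of ``region``.

    For every putative loop interval with length inside ``loop_range``
    the two arms are extended outward while they remain exact reverse
    complements.  Hairpins whose arms are contained in another reported
    hairpin's arms are dropped as non-maximal.  Results are ranked by
    stem length (desc), then loop length (asc), then position.
    """
    s = region.upper()
    n = len(s)
    lo, hi = loop_range
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    found: list[StemLoop] = []
    for loop_len in range(lo, hi + 1):
        for loop_start in range(1, n - loop_len):  # 0-based loop start
            i = loop_start - 1  # last 5' arm position
            j = loop_start + loop_len  # first 3' arm position
            k = 0
            while i - k >= 0 and j + k < n and comp.get(s[i - k]) == s[j + k]:
                k += 1
            if k < min_stem:
                continue
            found.append(
                StemLoop(
                    stem_len=k,
                    loop_len=loop_len,
                    five_arm=(i - k + 2, i + 1),
                    three_arm=(j + 1, j + k),
                )
            )
    # drop hairpins nested inside a larger one
    def contains(a: StemLoop, b: StemLoop) -> bool:
        return (
            a is not b
            and a.five_arm[0] <= b.five_arm[0]
            and a.five_arm[1] >= b.five_arm[1]
            and a.three_arm[0] <= b.three_arm[0]
            and a.three_arm[1] >= b.three_arm[1]
            and a.stem_len >= b.stem_len
        )

    maximal = [
        h for h in found if not any(contains(other, h) for other in found)
    ]
    # dedupe identical reports reached from different loop enumerations
    maximal = sorted(set(maximal), key=lambda h: (-h.stem_len, h.loop_len, h.five_arm))
    return maximal


def verify_stem_loop(region: str, h: StemLoop) -> bool:
    """Independent re-check that the two arms are exact reverse complements."""
    s = region.upper()
    five = s[h.five_arm[0] - 1 : h.five_arm[1]]
    three = s[h.three_arm[0] - 1 : h.three_arm[1]]
    gap = h.three_arm[0] - h.five_arm[1] - 1
    return (
        len(five) == len(three) == h.stem_len
        and gap == h.loop_len
        and reverse_complement(five) == three
    )


def control_region_report(
    ann: MitoAnnotation,
    min_period: int = 8,
    min_copies: float = 2.0,
    min_stem: int = 8,
    loop_range: tuple[int, int] = (3, 15),
) -> dict:
    start, end, length = control_region_span(ann)
    report: dict = {"start": start, "end": end, "length": length}
    if ann.sequence is not None:
        region = ann.slice(start, end)
        report["at_fraction"] = at_content(region)
        report["tandem_repeats"] = [
            vars(r) | {"span": r.span}
            for r in find_tandem_repeats(region, min_period, min_copies)
        ]
        report["stem_loops"] = [
            vars(h) | {"span": h.span}
            for h in find_stem_loops(region, min_stem, loop_range)
        ]
    return report
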