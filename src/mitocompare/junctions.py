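"""Intergenic spacers and gene overlaps on the circular genome.

For adjacent features the intergenic nucleotide count is

    IGN = start(downstream) - end(upstream) - 1

with negative values meaning the genes overlap.  The junction between the
last and first feature through the sequence origin is always included, so
the conservation law

    sum(feature lengths) + sum(signed IGN) == genome length

holds for every fully annotated circular genome (assuming no base is
covered by more than two features).

When the input carries a *stated* IGN column (published tables do), every
junction where the stated and the recomputed value disagree is collected
into a discrepancy list rather than silently adopted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import GeneFeature, MitoAnnotation, feature_length

__all__ = [
    "JunctionRecord",
    "SpacerSummary",
    "compute_ign",
    "summarize_spacers",
    "junction_sequence",
    "ign_discrepancies",
    "audit_nad4_junction",
    "classify_spacer",
]


@dataclass(frozen=True)
class JunctionRecord:
    upstream: str
    downstream: str
    ign: int
    stated_ign: Optional[int] = None
    junction_seq: Optional[str] = None

    @property
    def is_overlap(self) -> bool:
        return self.ign < 0

    @property
    def is_spacer(self) -> bool:
        return self.ign > 0

    @property
    def label(self) -> str:
        return f"{self.upstream}/{self.downstream}"


@dataclass(frozen=True)
class SpacerSummary:
    n_spacers: int
    n_overlaps: int
    largest: Optional[tuple[str, int]]
    total_spacer_bp: int
    total_overlap_bp: int


def compute_ign(ann: MitoAnnotation, with_sequences: bool = False) -> list[JunctionRecord]:
    """One junction record per adjacent feature pair, wrap junction included.

    Features are taken in start order; the stated IGN attached to a
    feature (table convention: printed on the upstream gene's row) is
    carried onto its downstream junction for auditing.
    """
    feats = sorted(ann.features, key=lambda f: (f.start, f.end))
    if len(feats) < 2:
        return []
    for a, b in zip(feats, feats[1:]):
        if (a.start, a.end) == (b.start, b.end):
            raise ValueError(
                f"features {a.name} and {b.name} have identical coordinates"
            )
    records = []
    n = len(feats)
    for i, f in enumerate(feats):
        g = feats[(i + 1) % n]
        if i + 1 < n:
            ign = g.start - f.end - 1
        else:
            if not ann.circular:
                break
            # wrap junction through the origin
            ign = g.start + ann.genome_length - f.end - 1
        seq = None
        if with_sequences and ann.sequence is not None and ign != 0:
            seq = junction_sequence(ann, f, g, ign)
        records.append(
            JunctionRecord(
                upstream=f.name,
                downstream=g.name,
                ign=ign,
                stated_ign=f.stated_ign,
                junction_seq=seq,
            )
        )
    return records


def junction_sequence(
    ann: MitoAnnotation,
    upstream: GeneFeature | str,
    downstream: GeneFeature | str,
    ign: Optional[int] = None,
) -> str:
    """H-strand sequence of a junction: spacer bases, or the shared bases
    of an overlap.  Empty string for abutting genes."""
    if isinstance(upstream, str):
        upstream = ann.get(upstream)
    if isinstance(downstream, str):
        downstream = ann.get(downstream)
    if upstream is None or downstream is None:
        raise ValueError("junction genes not found in annotation")
    if ann.sequence is None:
        raise ValueError("annotation carries no sequence")
    if ign is None:
        ign = downstream.start - upstream.end - 1
        if ign <= -ann.genome_length // 2:  # wrap junction
            ign += ann.genome_length
    if ign > 0:
        start = upstream.end + 1
        end = upstream.end + ign
        if start > ann.genome_length:
            start -= ann.genome_length
            end -= ann.genome_length
        elif end > ann.genome_length:
            end -= ann.genome_length
        return ann.slice(start, end)
    if ign < 0:
        return ann.slice(downstream.start, upstream.end)
    return ""


def summarize_spacers(junctions: list[JunctionRecord]) -> SpacerSummary:
    spacers = [j for j in junctions if j.is_spacer]
    overlaps = [j for j in junctions if j.is_overlap]
    largest = None
    if spacers:
        top = max(spacers, key=lambda j: j.ign)
        largest = (top.label, top.ign)
    return SpacerSummary(
        n_spacers=len(spacers),
        n_overlaps=len(overlaps),
        largest=largest,
        total_spacer_bp=sum(j.ign for j in spacers),
        total_overlap_bp=sum(-j.ign for j in overlaps),
    )


def ign_discrepancies(junctions: list[JunctionRecord]) -> list[JunctionRecord]:
    """Junctions whose stated IGN disagrees with the recomputed value."""
    return [
        j
        for j in junctions
        if j.stated_ign is not None and j.stated_ign != j.ign
    ]


def classify_spacer(seq: str) -> dict:
    """Simple composition call for an intergenic spacer.

    * ``TA run`` when >= 80% of the spacer is consecutive TA-dinucleotide
      repeats (the repeat count is reported);
    * ``G run`` when >= 80% of its bases are G;
    * ``A+T-rich`` when the A+T fraction is >= 0.8;
    * ``mixed`` otherwise.
    """
    s = seq.upper()
    if not s:
        return {"classification": "empty", "ta_repeats": 0, "at_fraction": None}
    # longest run of TA repeats anywhere in the spacer
    best = 0
    for i in range(len(s)):
        k = 0
        while s[i + 2 * k : i + 2 * k + 2] == "TA":
            k += 1
        best = max(best, k)
    at = (s.count("A") + s.count("T")) / len(s)
    if 2 * best / len(s) >= 0.8:
        cls = "TA run"
    elif s.count("G") / len(s) >= 0.8:
        cls = "G run"
    elif at >= 0.8:
        cls = "A+T-rich"
    else:
        cls = "mixed"
    return {"classification": cls, "ta_repeats": best, "at_fraction": at}


def audit_nad4_junction(ann: MitoAnnotation) -> dict:
    """Audit the nad4l/nad4 junction.

    In the ancestral insect arrangement the two genes overlap by 7 bp and
    are expressed from one bicistronic transcript; in Dolichoderinae ants
    the overlap is replaced by a short intergenic spacer.  Reports whether
    an overlap is present, the spacer length/sequence when not, a
    composition call for the spacer, and the stop codon of the
    upstream-in-transcription gene when available.
    """
    nad4, nad4l = ann.get("nad4"), ann.get("nad4l")
    if nad4 is None or nad4l is None:
        return {"warning": "nad4/nad4l not both present", "overlap_present": None}
    first, second = (nad4, nad4l) if nad4.start <= nad4l.start else (nad4l, nad4)
    ign = second.start - first.end - 1
    report: dict = {
        "overlap_present": ign < 0,
        "ign": ign,
        "igs_len": max(ign, 0),
        "igs_seq": None,
        "stop_codon_used": nad4l.stop_codon,
    }
    if ann.sequence is not None and ign != 0:
        seq = junction_sequence(ann, first, second, ign)
        report["igs_seq"] = seq
        if ign > 0:
            report.update(classify_spacer(seq))
    return report
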