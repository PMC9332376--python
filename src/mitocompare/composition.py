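"""Base composition, codon usage and RSCU.

Relative synonymous codon usage (RSCU) of a codon c is

    RSCU(c) = n_c / (N_f / k_f)

where N_f is the total count over c's synonymous family and k_f the family
size.  Families are defined by the genetic code in use; under the
invertebrate mitochondrial code (NCBI table 5) serine is one eight-codon
family (UCN + AGN), tryptophan is {UGA, UGG}, and the two stop codons
{UAA, UAG} form their own family.  Stop codons are counted in the usage
table: with 13 protein-coding genes all ending in UAA one expects
n(UAA)=13 and RSCU(UAA)=2, as published mitogenome tables show.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    GeneFeature,
    GeneticCode,
    INVERTEBRATE_MITO,
    MitoAnnotation,
    _norm_codon,
    translate,
)

__all__ = [
    "at_content",
    "base_counts",
    "extract_cds",
    "count_codons",
    "CodonUsageTable",
    "CodonClassification",
    "classify_codons",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention of printed tables."""
    import decimal

    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def base_counts(seq: str) -> Counter:
    return Counter(seq.upper())


def at_content(seq: str) -> float:
    """Fraction (A+T)/(A+C+G+T+N) of a DNA string.

    N is counted in the denominator; callers wanting the N tally can use
    :func:`base_counts`.
    """
    if not seq:
        raise ValueError("empty sequence")
    c = base_counts(seq)
    denom = sum(c[b] for b in "ACGTN")
    if denom == 0:
        raise ValueError("sequence contains no ACGTN bases")
    return (c["A"] + c["T"]) / denom


@dataclass
class ExtractedCDS:
    gene: str
    seq: str  # coding strand, start codon first
    complete: bool  # False when length % 3 != 0 (incomplete stop)


def extract_cds(ann: MitoAnnotation) -> list[ExtractedCDS]:
    """Coding-strand CDS sequences of every protein-coding gene.

    L-strand genes are reverse-complemented.  A CDS whose length is not a
    multiple of three keeps its trailing remainder and is flagged
    incomplete.
    """
    out = []
    for f in ann.features:
        if f.kind != "PCG":
            continue
        s = ann.feature_sequence(f)
        out.append(ExtractedCDS(gene=f.name, seq=s, complete=len(s) % 3 == 0))
    return out


@dataclass
class CodonUsageTable:
    """Per-codon counts with derived percent and RSCU columns."""

    counts: dict[str, int]
    code: GeneticCode = INVERTEBRATE_MITO
    zero_families: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        clean = {_norm_codon(c): int(n) for c, n in self.counts.items()}
        if any(n < 0 for n in clean.values()):
            raise ValueError("negative codon count")
        # fill out all 64 codons
        for c in self.code.codon_map:
            clean.setdefault(c, 0)
        self.counts = clean

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percent(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c: 0.0 for c in self.counts}
        return {c: 100.0 * n / total for c, n in self.counts.items()}

    def rscu(self) -> dict[str, float]:
        """RSCU per codon; empty families yield 0 and are flagged."""
        out: dict[str, float] = {}
        self.zero_families = []
        for aa, family in self.code.families().items():
            family_total = sum(self.counts[c] for c in family)
            if family_total == 0:
                self.zero_families.append(aa)
                for c in family:
                    out[c] = 0.0
                continue
            expected = family_total / len(family)
            for c in family:
                out[c] = self.counts[c] / expected
        return out

    def as_rows(self) -> list[dict]:
        """Report rows in fixed codon order (U<C<A<G by position, RNA form)."""
        order = "UCAG"
        percent = self.percent()
        rscu = self.rscu()
        rows = []
        for b1 in order:
            for b2 in order:
                for b3 in order:
                    rna = b1 + b2 + b3
                    dna = _norm_codon(rna)
                    rows.append(
                        {
                            "codon": rna,
                            "amino_acid": self.code.amino_acid(dna),
                            "n": self.counts[dna],
                            "percent": round_half_up(percent[dna]),
                            "rscu": round_half_up(rscu[dna]),
                        }
                    )
        return rows


def count_codons(
    cds_list: Iterable[ExtractedCDS | str],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> CodonUsageTable:
    """Tally complete in-frame codons over a collection of CDS.

    Start codons and complete stop codons are included; a trailing 1-2 nt
    incomplete stop is excluded (no defensible amino-acid assignment).
    """
    counts: Counter = Counter()
    for item in cds_list:
        seq = item.seq if isinstance(item, ExtractedCDS) else item
        s = _norm_codon(seq)
        if len(s) < 3:
            raise ValueError("CDS shorter than one codon")
        for i in range(0, len(s) - len(s) % 3, 3):
            counts[s[i : i + 3]] += 1
    return CodonUsageTable(counts=dict(counts), code=code)


@dataclass(frozen=True)
class CodonClassification:
    gene: str
    start_codon: str
    stop_codon: str  # TAA/TAG, or TA/T when incomplete
    complete: bool
    start_is_canonical: bool


def classify_codons(
    ann: MitoAnnotation, code: GeneticCode = INVERTEBRATE_MITO
) -> list[CodonClassification]:
    """Start/stop codon classification of every PCG.

    Requires the genome sequence.  A CDS whose length is a multiple of
    three and whose last codon is in the stop set is complete; otherwise
    the trailing TA/T remainder is reported as an incomplete stop
    (completed to UAA by polyadenylation of the transcript).  A start
    codon outside the configured start set is flagged, not rejected.
    """
    if ann.sequence is None:
        raise ValueError("sequence required for codon classification")
    out = []
    for cds in extract_cds(ann):
        s = _norm_codon(cds.seq)
        start = s[:3]
        if len(s) % 3 == 0:
            last = s[-3:]
            stop, complete = (last, True) if last in code.stop_codons else (last, False)
        else:
            stop, complete = s[-(len(s) % 3) :], False
        out.append(
            CodonClassification(
                gene=cds.gene,
                start_codon=start,
                stop_codon=stop,
                complete=complete,
                start_is_canonical=start in code.start_codons,
            )
        )
    return out


def composition_report(ann: MitoAnnotation,
                       code: GeneticCode = INVERTEBRATE_MITO) -> dict:
    """Whole-genome and codon-usage summary used by the CLI."""
    report: dict = {}
    if ann.sequence is not None:
        c = base_counts(ann.sequence)
        report["genome_at_percent"] = round_half_up(100 * at_content(ann.sequence))
        report["n_bases"] = c.get("N", 0)
        table = count_codons(extract_cds(ann), code=code)
        report["total_codons"] = table.total
        report["codon_usage"] = table.as_rows()
        report["codon_classifications"] = [
            vars(x) | {} for x in classify_codons(ann, code)
        ]
    else:
        # coordinate-only mode: fall back to annotated codon columns
        report["codon_classifications"] = [
            {
                "gene": f.name,
                "start_codon": f.start_codon,
                "stop_codon": f.stop_codon,
                "complete": f.stop_codon in ("TAA", "TAG") if f.stop_codon else None,
            }
            for f in ann.features
            if f.kind == "PCG"
        ]
    return report
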