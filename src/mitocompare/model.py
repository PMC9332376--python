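"""Core domain types for annotated circular mitochondrial genomes.

Coordinates are 1-based and inclusive on both ends, the GenBank convention.
A feature whose ``end`` is smaller than its ``start`` wraps across the
sequence origin of the circular molecule.

Strands are named ``H`` (heavy/majority, the strand the sequence is written
on) and ``L`` (light/minority), as is customary for animal mitogenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "PCG_NAMES",
    "TRNA_NAMES",
    "RRNA_NAMES",
    "GENE_KINDS",
    "GeneFeature",
    "MitoAnnotation",
    "GeneticCode",
    "Translation",
    "INVERTEBRATE_MITO",
    "load_vocabulary",
    "canonical_gene_name",
    "feature_length",
    "translate",
    "reverse_complement",
]

# The 13 mitochondrial protein-coding genes in canonical lower-case form.
PCG_NAMES = (
    "nad2", "cox1", "cox2", "atp8", "atp6", "cox3", "nad3",
    "nad5", "nad4", "nad4l", "nad6", "cob", "nad1",
)

# 22 tRNAs by one-letter amino-acid code; the Leu and Ser isoacceptors are
# disambiguated by number.  L1 carries anticodon UAA, L2 UAG, S1 UCU and
# S2 UGA -- the anticodon is authoritative when both a name and an
# anticodon are available.
TRNA_NAMES = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I", "K",
    "L1", "L2", "M", "F", "P", "S1", "S2", "T", "W", "Y", "V",
)

RRNA_NAMES = ("rrnL", "rrnS")

#: control-region token
CR = "CR"

ALL_GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES + (CR,)

GENE_KINDS = ("PCG", "tRNA", "rRNA", "CR")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a circular mitogenome.

    ``stated_ign`` holds an intergenic-nucleotide value *claimed* by the
    input (e.g. the IGN column of a published feature table).  It is kept
    for cross-checking only and never used as ground truth.
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    stated_ign: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates must be >= 1")

    @property
    def wraps(self) -> bool:
        """True when the feature crosses the sequence origin."""
        return self.end < self.start

    def length(self, genome_length: int) -> int:
        return feature_length(self, genome_length)


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circle of ``genome_length`` bp."""
    if f.start > genome_length or f.end > genome_length:
        raise ValueError(
            f"{f.name}: coordinates {f.start}-{f.end} exceed genome "
            f"length {genome_length}"
        )
    if f.wraps:
        return genome_length - f.start + 1 + f.end
    return f.end - f.start + 1


@dataclass
class MitoAnnotation:
    """A circular mitogenome: length, ordered features, optional sequence."""

    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    sequence: Optional[str] = None
    name: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != genome_length "
                f"{self.genome_length}"
            )
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise ValueError(f"duplicate gene token {f.name!r}")
            seen.add(f.name)
        self.features.sort(key=lambda f: (f.start, f.end))

    def get(self, name: str) -> Optional[GeneFeature]:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def __contains__(self, name: str) -> bool:
        return self.get(name) is not None

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice of the genome sequence, wrap-aware."""
        if self.sequence is None:
            raise ValueError("annotation carries no sequence")
        if end >= start:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def feature_sequence(self, f: GeneFeature) -> str:
        """Coding-strand sequence of a feature (revcomp for L-strand)."""
        s = self.slice(f.start, f.end)
        return reverse_complement(s) if f.strand == "L" else s

    def copy(self) -> "MitoAnnotation":
        return MitoAnnotation(
            genome_length=self.genome_length,
            features=[replace(f) for f in self.features],
            circular=self.circular,
            sequence=self.sequence,
            name=self.name,
            warnings=list(self.warnings),
        )


class Translation(NamedTuple):
    """Result of conceptual translation of a CDS.

    ``protein`` has one letter per complete codon ('*' for stops, 'X' for
    ambiguous codons); ``remainder`` is the 1-2 nt left over when the CDS
    length is not a multiple of three (an incomplete terminal codon).
    """

    protein: str
    remainder: str


@dataclass(frozen=True)
class GeneticCode:
    """A mitochondrial genetic code keyed by NCBI translation-table id.

    The default (table 5, invertebrate mitochondrial) decodes TGA as Trp,
    AGA/AGG as Ser and ATA as Met.  The start-codon set defaults to the
    ATN codons observed as mitochondrial initiators in insects.
    """

    table_id: int = 5
    start_codons: frozenset[str] = frozenset({"ATG", "ATA", "ATT", "ATC"})
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG"})

    @property
    def codon_map(self) -> dict[str, str]:
        return _codon_map(self.table_id, self.stop_codons)

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid for a DNA codon; '*' for stop, 'X' unknown."""
        return self.codon_map.get(_norm_codon(codon), "X")

    def family(self, codon: str) -> tuple[str, ...]:
        """All codons synonymous with ``codon`` (its own family), sorted."""
        aa = self.amino_acid(codon)
        return tuple(sorted(c for c, a in self.codon_map.items() if a == aa))

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families keyed by amino-acid letter ('*' = stops)."""
        fams: dict[str, list[str]] = {}
        for c, a in self.codon_map.items():
            fams.setdefault(a, []).append(c)
        return {a: tuple(sorted(cs)) for a, cs in fams.items()}


def _norm_codon(codon: str) -> str:
    """Upper-case DNA form of a codon given in DNA or RNA alphabet."""
    return codon.upper().replace("U", "T")


_CODON_MAP_CACHE: dict[tuple[int, frozenset[str]], dict[str, str]] = {}


def _codon_map(table_id: int, stops: frozenset[str]) -> dict[str, str]:
    key = (table_id, stops)
    if key not in _CODON_MAP_CACHE:
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(ncbi.forward_table)
        for s in ncbi.stop_codons:
            mapping[s] = "*"
        _CODON_MAP_CACHE[key] = mapping
    return _CODON_MAP_CACHE[key]


#: module-level default code (NCBI table 5)
INVERTEBRATE_MITO = GeneticCode(table_id=5)


def translate(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> Translation:
    """Translate a coding-strand DNA string codon by codon.

    Codons containing N (or any non-ACGT symbol after normalisation)
    yield 'X'.  A trailing 1-2 nt remainder is returned separately; it is
    what an incomplete stop codon looks like at the DNA level.
    """
    s = _norm_codon(cds)
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbols in CDS: {sorted(bad)}")
    if len(s) < 3:
        raise ValueError("CDS shorter than one codon")
    n_codons = len(s) // 3
    aa = "".join(
        code.codon_map.get(s[3 * i : 3 * i + 3], "X") for i in range(n_codons)
    )
    return Translation(protein=aa, remainder=s[3 * n_codons :])


# ---------------------------------------------------------------------------
# Controlled vocabulary
# ---------------------------------------------------------------------------

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "lys": "K", "leu": "L", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# anticodon -> numbered isoacceptor for the two twofold tRNAs
_LEU_SER_BY_ANTICODON = {
    ("L", "TAA"): "L1",
    ("L", "TAG"): "L2",
    ("S", "TCT"): "S1",
    ("S", "TGA"): "S2",
}


def _base_aliases() -> dict[str, str]:
    aliases: dict[str, str] = {}

    def add(alias: str, token: str) -> None:
        aliases[alias.lower()] = token

    for g in ALL_GENE_NAMES:
        add(g, g)
    # protein-coding synonyms
    for i in (1, 2, 3):
        add(f"co{i}", f"cox{i}")
        add(f"coi" if i == 1 else ("coii" if i == 2 else "coiii"), f"cox{i}")
        add(f"cytochrome c oxidase subunit {i}", f"cox{i}")
        add(f"cytochrome oxidase subunit {i}", f"cox{i}")
    for i in (1, 2, 3, 4, 5, 6):
        add(f"nd{i}", f"nad{i}")
        add(f"nadh{i}", f"nad{i}")
        add(f"nadh dehydrogenase subunit {i}", f"nad{i}")
    add("nd4l", "nad4l")
    add("nadh dehydrogenase subunit 4l", "nad4l")
    add("cytb", "cob")
    add("cytochrome b", "cob")
    add("cob/cytb", "cob")
    for i in (6, 8):
        add(f"atpase{i}", f"atp{i}")
        add(f"atpase {i}", f"atp{i}")
        add(f"atp synthase f0 subunit {i}", f"atp{i}")
    # rRNAs
    for alias in ("rrnl", "16s", "16s rrna", "16s ribosomal rna", "l-rrna",
                  "lrrna", "large subunit ribosomal rna", "rrn16"):
        add(alias, "rrnL")
    for alias in ("rrns", "12s", "12s rrna", "12s ribosomal rna", "s-rrna",
                  "srrna", "small subunit ribosomal rna", "rrn12"):
        add(alias, "rrnS")
    # control region
    for alias in ("cr", "control region", "d-loop", "d loop", "dloop",
                  "a+t-rich region", "at-rich region", "putative control region"):
        add(alias, "CR")
    # tRNAs: trnM / tRNA-Met / tRNA Met forms; numbered isoacceptors
    for three, one in _AA3_TO_1.items():
        if one in ("L", "S"):
            for num in ("1", "2"):
                add(f"trn{one.lower()}{num}", f"{one}{num}")
                add(f"trna-{three}{num}", f"{one}{num}")
                add(f"trna-{three} {num}", f"{one}{num}")
        else:
            add(f"trn{one.lower()}", one)
            add(f"trna-{three}", one)
            add(f"trna {three}", one)
            add(one, one)
    # bare tRNA-Leu / tRNA-Ser map to the aa letter; anticodon resolves 1/2
    add("trna-leu", "L")
    add("trna-ser", "S")
    add("trnl", "L")
    add("trns", "S")
    return aliases


_ALIASES = _base_aliases()


def load_vocabulary() -> dict[str, str]:
    """Mapping of lower-cased gene-name aliases to canonical tokens.

    Canonical tokens map to themselves (the mapping is idempotent).
    """
    return dict(_ALIASES)


def canonical_gene_name(
    name: str, anticodon: Optional[str] = None
) -> tuple[str, bool]:
    """Resolve ``name`` (optionally with an anticodon) to a canonical token.

    Returns ``(token, known)``.  Unknown names pass through stripped but
    otherwise unchanged, flagged with ``known=False``.  For the Leu and
    Ser isoacceptors the anticodon decides the 1/2 label whenever it is
    given (L1=UAA, L2=UAG, S1=UCU, S2=UGA).
    """
    raw = name.strip()
    # strip a leading parenthesised letter label, e.g. "(Q) tRNA-Gln"
    if raw.startswith("(") and ")" in raw:
        raw = raw.split(")", 1)[1].strip()
    key = raw.strip("* ").lower()
    token = _ALIASES.get(key)
    if token is None:
        return raw, False
    if token in ("L", "S") or (anticodon and token in ("L1", "L2", "S1", "S2")):
        if anticodon:
            resolved = _LEU_SER_BY_ANTICODON.get(
                (token[0], _norm_codon(anticodon))
            )
            if resolved:
                return resolved, True
        if token in ("L", "S"):
            # ambiguous isoacceptor without anticodon
            return token, False
    return token, True


def kind_of(token: str) -> str:
    """Feature kind implied by a canonical gene token."""
    if token in PCG_NAMES:
        return "PCG"
    if token in TRNA_NAMES:
        return "tRNA"
    if token in RRNA_NAMES:
        return "rRNA"
    if token == CR:
        return "CR"
    raise KeyError(f"not a canonical gene token: {token!r}")


def total_annotated_bp(ann: MitoAnnotation) -> int:
    return sum(feature_length(f, ann.genome_length) for f in ann.features)
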