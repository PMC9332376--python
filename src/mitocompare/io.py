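"""Read and write annotated mitogenomes.

Supported dialects:

* GenBank flat files (via Biopython), the deposit format for mitogenomes;
* a plain feature TSV mirroring published annotation tables
  (``Gene  Anticodon  Strand  Nucleotide Number  Start Codon  Stop Codon  IGN``);
* FASTA for raw sequence.

The feature-TSV reader is deliberately liberal about typography: en-dashes
and hyphens in coordinate ranges, Unicode minus signs, and thousands
separators are all accepted, because published tables use all of them.
An ``IGN`` column is stored per feature as ``stated_ign`` — a claim to be
audited, never trusted as ground truth.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import (
    CR,
    GeneFeature,
    MitoAnnotation,
    PCG_NAMES,
    canonical_gene_name,
    kind_of,
)

__all__ = [
    "read_annotation",
    "read_feature_tsv",
    "write_feature_tsv",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "write_report",
]

PathLike = Union[str, Path]

_DASHES = "–—−"  # en dash, em dash, minus sign


def _norm_number(text: str) -> str:
    out = text.strip().replace(",", "")
    for d in _DASHES:
        out = out.replace(d, "-")
    return out


def _parse_int(text: str) -> int:
    return int(_norm_number(text))


def _parse_range(text: str) -> tuple[int, int]:
    """Parse '135–203' / '135-203' / '10,191–10,261' into (start, end)."""
    s = _norm_number(text)
    parts = [p for p in s.split("-") if p]
    if len(parts) != 2:
        raise ValueError(f"unparseable coordinate range {text!r}")
    return int(parts[0]), int(parts[1])


def _guess_kind(token: str, raw_name: str) -> str:
    try:
        return kind_of(token)
    except KeyError:
        low = raw_name.lower()
        if "trn" in low or "trna" in low:
            return "tRNA"
        if "rrn" in low or "ribosomal" in low or "rrna" in low:
            return "rRNA"
        if "control" in low or "d-loop" in low:
            return "CR"
        return "PCG"


# ---------------------------------------------------------------------------
# feature TSV
# ---------------------------------------------------------------------------

_HEADER_ALIASES = {
    "gene": "gene",
    "anticodon": "anticodon",
    "strand": "strand",
    "nucleotide_number": "range",
    "range": "range",
    "position": "range",
    "start": "start",
    "end": "end",
    "start_codon": "start_codon",
    "stop_codon": "stop_codon",
    "ign": "ign",
}


def read_feature_tsv(path: PathLike) -> MitoAnnotation:
    """Parse a feature table TSV into a :class:`MitoAnnotation`.

    Leading ``#`` comment lines may carry ``genome_length``, ``circular``
    and ``name`` as ``# key: value`` pairs; otherwise the genome length is
    inferred from the largest end coordinate.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: Optional[list[str]] = None
    rows: list[dict[str, str]] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            body = line.lstrip("# ").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip().lower()] = v.strip()
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = [
                _HEADER_ALIASES.get(c.strip().lower().replace(" ", "_"),
                                    c.strip().lower().replace(" ", "_"))
                for c in cells
            ]
            continue
        cells += [""] * (len(header) - len(cells))
        rows.append(dict(zip(header, cells)))
    if header is None:
        raise ValueError(f"{path}: no header row found")

    warnings: list[str] = []
    features: list[GeneFeature] = []
    for row in rows:
        raw_name = row.get("gene", "").strip()
        if not raw_name:
            continue
        anticodon = row.get("anticodon", "").strip() or None
        token, known = canonical_gene_name(raw_name, anticodon)
        if not known:
            warnings.append(f"unknown gene name {raw_name!r} kept as-is")
        if any(f.name == token for f in features):
            raise ValueError(f"{path}: duplicate gene token {token!r}")
        if row.get("range", "").strip():
            start, end = _parse_range(row["range"])
        else:
            start = _parse_int(row["start"])
            end = _parse_int(row["end"])
        strand = (row.get("strand", "").strip() or "H").upper()
        ign_text = row.get("ign", "").strip()
        stated_ign = _parse_int(ign_text) if ign_text else None
        features.append(
            GeneFeature(
                name=token,
                kind=_guess_kind(token, raw_name),
                strand=strand,
                start=start,
                end=end,
                anticodon=anticodon,
                start_codon=row.get("start_codon", "").strip() or None,
                stop_codon=row.get("stop_codon", "").strip() or None,
                stated_ign=stated_ign,
            )
        )

    if "genome_length" in meta:
        genome_length = int(meta["genome_length"])
    else:
        genome_length = max(max(f.start, f.end) for f in features)
        warnings.append(
            "genome_length not declared; inferred from largest coordinate"
        )
    circular = meta.get("circular", "true").lower() in ("true", "yes", "1")
    return MitoAnnotation(
        genome_length=genome_length,
        features=features,
        circular=circular,
        name=meta.get("name", path.stem),
        warnings=warnings,
    )


def write_feature_tsv(ann: MitoAnnotation, path: PathLike) -> None:
    path = Path(path)
    lines = [
        f"# genome_length: {ann.genome_length}",
        f"# circular: {str(ann.circular).lower()}",
        f"# name: {ann.name}",
        "Gene\tAnticodon\tStrand\tNucleotide Number\tStart Codon\tStop Codon\tIGN",
    ]
    for f in ann.features:
        lines.append(
            "\t".join(
                [
                    f.name,
                    f.anticodon or "",
                    f.strand,
                    f"{f.start}-{f.end}",
                    f.start_codon or "",
                    f.stop_codon or "",
                    "" if f.stated_ign is None else str(f.stated_ign),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_KIND_TO_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature"}


def read_genbank(path: PathLike) -> MitoAnnotation:
    """Read the first record of a GenBank flat file.

    Wrapping ``join()`` locations across the origin are accepted and
    flagged with a warning.  Control regions are recognised either as
    ``D-loop`` features or as ``misc_feature`` with a control-region note.
    """
    record = SeqIO.read(str(path), "genbank")
    genome_length = len(record.seq)
    try:
        sequence: Optional[str] = str(record.seq).upper()
    except Exception:  # undefined sequence (no ORIGIN block)
        sequence = None
    circular = record.annotations.get("topology", "linear") == "circular"

    warnings: list[str] = []
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        quals = feat.qualifiers
        note = " ".join(quals.get("note", []))
        if feat.type == "misc_feature" and "control region" not in note.lower():
            warnings.append(f"misc_feature without control-region note skipped")
            continue
        if feat.type in ("misc_feature", "D-loop"):
            raw_name = "control region"
        else:
            raw_name = (
                quals.get("gene", [None])[0]
                or quals.get("product", [None])[0]
                or note
                or feat.type
            )
        extras = dict(
            kv.split("=", 1) for kv in note.split(";") if "=" in kv
        )
        anticodon = quals.get("anticodon", [None])[0] or extras.get("anticodon")
        token, known = canonical_gene_name(raw_name, anticodon)
        if not known:
            warnings.append(f"unknown gene name {raw_name!r} kept as-is")
        if token in seen:
            raise ValueError(f"duplicate gene token {token!r} in {path}")
        seen.add(token)

        loc = feat.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            if len(parts) == 2 and int(parts[-1].end) == genome_length and int(parts[0].start) == 0:
                start = int(parts[-1].start) + 1
                end = int(parts[0].end)
                warnings.append(f"{token}: join() across origin interpreted as wrap")
            else:
                raise ValueError(f"{token}: unsupported compound location {loc}")
        else:
            start = int(loc.start) + 1
            end = int(loc.end)
        if end > genome_length:
            raise ValueError(
                f"{token}: end {end} outside declared length {genome_length}"
            )
        features.append(
            GeneFeature(
                name=token,
                kind=_guess_kind(token, raw_name),
                strand="L" if loc.strand == -1 else "H",
                start=start,
                end=end,
                anticodon=anticodon,
                start_codon=extras.get("start_codon"),
                stop_codon=extras.get("stop_codon"),
            )
        )
    return MitoAnnotation(
        genome_length=genome_length,
        features=features,
        circular=circular,
        sequence=sequence,
        name=record.id if record.id != "<unknown id>" else Path(path).stem,
        warnings=warnings,
    )


def write_genbank(ann: MitoAnnotation, path: PathLike) -> None:
    """Write an annotation (sequence N-filled when absent) as GenBank."""
    seq = ann.sequence or ("N" * ann.genome_length)
    record = SeqRecord(
        Seq(seq),
        id=ann.name or "mitogenome",
        name=(ann.name or "mitogenome")[:16],
        description="mitochondrial genome, complete sequence",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if ann.circular else "linear",
        },
    )
    for f in ann.features:
        strand = -1 if f.strand == "L" else 1
        if f.wraps:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, ann.genome_length, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals: dict[str, list[str]] = {}
        notes = []
        if f.kind == "CR":
            notes.append("control region")
        else:
            gene = f.name if f.kind != "tRNA" else f"trn{f.name}"
            quals["gene"] = [gene]
        if f.anticodon:
            notes.append(f"anticodon={f.anticodon}")
        if f.start_codon:
            notes.append(f"start_codon={f.start_codon}")
        if f.stop_codon:
            notes.append(f"stop_codon={f.stop_codon}")
        if notes:
            quals["note"] = [";".join(notes)]
        if f.kind == "PCG":
            quals["transl_table"] = ["5"]
        record.features.append(
            SeqFeature(loc, type=_GB_KIND_TO_TYPE[f.kind], qualifiers=quals)
        )
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> tuple[str, str]:
    record = SeqIO.read(str(path), "fasta")
    return record.id, str(record.seq).upper()


def write_fasta(name: str, seq: str, path: PathLike, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def read_annotation(path: PathLike, dialect: Optional[str] = None,
                    fasta: Optional[PathLike] = None) -> MitoAnnotation:
    """Dispatch on dialect (or file suffix) and optionally attach a FASTA."""
    path = Path(path)
    if dialect is None:
        dialect = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank", ".gbff") else "tsv"
    ann = read_genbank(path) if dialect == "genbank" else read_feature_tsv(path)
    if fasta is not None:
        _, seq = read_fasta(fasta)
        if len(seq) != ann.genome_length:
            raise ValueError(
                f"FASTA length {len(seq)} != annotated genome length "
                f"{ann.genome_length}"
            )
        ann.sequence = seq
    return ann


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.2f}"
    if value is None:
        return ""
    return str(value)


def write_report(results: dict, path: PathLike) -> None:
    """Write analysis results as deterministic TSV/JSON files.

    ``results`` maps a report name to either a list of dicts (written as a
    TSV with a fixed column order taken from the first row) or a plain
    dict (written as JSON).  Floats are printed with two decimals,
    matching the precision of published mitogenome tables.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in sorted(results):
        value = results[name]
        if isinstance(value, list):
            target = outdir / f"{name}.tsv"
            buf = _io.StringIO()
            if value:
                cols = list(value[0].keys())
                buf.write("\t".join(cols) + "\n")
                for row in value:
                    buf.write("\t".join(_fmt(row.get(c)) for c in cols) + "\n")
            target.write_text(buf.getvalue(), encoding="utf-8")
        else:
            target = outdir / f"{name}.json"
            target.write_text(
                json.dumps(value, indent=2, sort_keys=True, default=_fmt) + "\n",
                encoding="utf-8",
            )
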