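"""Bundled reference data.

The package ships the published annotation table and protein-coding-gene
codon counts of the *Tapinoma ibericum* mitogenome (GenBank ON746721) as
plain TSV files.  These are coordinate/count tables only — the deposited
nucleotide sequence is not redistributed and must be fetched from GenBank
if sequence-level analyses of the real genome are wanted.
"""

from __future__ import annotations

from importlib import resources

from .io import read_feature_tsv
from .model import MitoAnnotation, _norm_codon

__all__ = ["tapinoma_ibericum_annotation", "tapinoma_ibericum_codon_counts"]


def _data_path(name: str):
    return resources.files("mitocompare.data").joinpath(name)


def tapinoma_ibericum_annotation() -> MitoAnnotation:
    """Published annotation of accession ON746721 (15,715 bp, 38 features).

    The bundled IGN column is the *printed* one and is stored per feature
    as ``stated_ign``; junction analysis recomputes IGN from coordinates
    and reports any disagreement.
    """
    with resources.as_file(_data_path("ON746721_features.tsv")) as p:
        return read_feature_tsv(p)


def tapinoma_ibericum_codon_counts(dna: bool = True) -> dict[str, int]:
    """Published per-codon counts over the 13 PCGs (3695 codons).

    Keys are DNA codons by default (``dna=False`` keeps the printed RNA
    form).
    """
    counts: dict[str, int] = {}
    text = _data_path("ON746721_codon_counts.tsv").read_text(encoding="utf-8")
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("codon"):
            continue
        codon, _aa, n = line.split("\t")
        key = _norm_codon(codon) if dna else codon.strip().upper()
        counts[key] = int(n)
    return counts
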