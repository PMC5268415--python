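"""Gene annotation: GTF gene records, biotype vocabulary, TSS/TTS logic."""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List

from hmcscan.intervals import GenomicInterval

__all__ = [
    "GeneModel",
    "BIOTYPES",
    "MOLECULE_TYPES",
    "normalize_biotype",
    "read_gtf_genes",
    "write_gtf_genes",
    "read_gene_sets",
]

# Controlled biotype vocabulary (GENCODE-style labels collapsed onto it).
BIOTYPES = (
    "protein_coding",
    "lincRNA",
    "processed_transcript",
    "pseudogene",
    "short_ncRNA",
    "other",
)

# IPA-style molecule-type vocabulary used for group averages.
MOLECULE_TYPES = (
    "enzyme",
    "kinase",
    "transcription_regulator",
    "transporter",
    "ion_channel",
    "gpcr",
    "microRNA",
    "other",
)

_SHORT_NCRNA = {
    "miRNA", "snRNA", "snoRNA", "rRNA", "tRNA", "misc_RNA", "scRNA",
    "sRNA", "scaRNA", "Mt_tRNA", "Mt_rRNA",
}


def normalize_biotype(raw: str) -> str:
    """Map a raw GTF biotype label onto the controlled vocabulary."""
    if raw in BIOTYPES:  # already controlled labels pass through
        return raw
    if raw.endswith("pseudogene"):
        return "pseudogene"
    if raw in _SHORT_NCRNA:
        return "short_ncRNA"
    return "other"


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: full span (TSS to TTS including introns)."""

    gene_id: str
    name: str
    span: GenomicInterval
    biotype: str = "other"
    molecule_type: str = "other"

    def __post_init__(self) -> None:
        if self.span.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def length(self) -> int:
        return self.span.length

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.span.start if self.span.strand == "+" else self.span.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination site (0-based position of the last base)."""
        return self.span.end - 1 if self.span.strand == "+" else self.span.start


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf_genes(path: str | Path) -> List[GeneModel]:
    """Read ``gene`` feature rows from a GENCODE-dialect GTF.

    GTF coordinates are 1-based closed; they are converted to the package's
    0-based half-open convention (``start-1``, ``end``). Biotype comes from
    ``gene_type`` (or ``gene_biotype``) and is collapsed onto the controlled
    vocabulary; an optional ``molecule_type`` attribute is honoured.
    """
    path = Path(path)
    genes: List[GeneModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            chrom, start1, end1, strand = fields[0], fields[3], fields[4], fields[6]
            attrs = _parse_attributes(fields[8])
            if "gene_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            raw_biotype = attrs.get("gene_type", attrs.get("gene_biotype", "other"))
            span = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            genes.append(
                GeneModel(
                    gene_id=attrs["gene_id"],
                    name=attrs.get("gene_name", ""),
                    span=span,
                    biotype=normalize_biotype(raw_biotype),
                    molecule_type=attrs.get("molecule_type", "other"),
                )
            )
    return genes


def write_gtf_genes(genes: Iterable[GeneModel], path: str | Path,
                    source: str = "hmcscan") -> None:
    """Write gene records as GTF (1-based closed coordinates on output)."""
    with Path(path).open("w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; gene_type "{g.biotype}"; '
                f'gene_name "{g.name}"; molecule_type "{g.molecule_type}";'
            )
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.span.start + 1}\t{g.span.end}\t"
                f".\t{g.span.strand}\t.\t{attrs}\n"
            )


def read_gene_sets(path: str | Path) -> Dict[str, List[str]]:
    """Read a two-column ``gene_id<TAB>set_name`` file into name -> id lists."""
    sets: Dict[str, List[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene_id set_name'")
            sets.setdefault(fields[1], []).append(fields[0])
    return sets
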