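"""Reference genome and gene annotation handling.

Coordinates are 1-based inclusive throughout (GFF3 convention); any
half-open arithmetic is confined inside individual functions.
"""

from __future__ import annotations

import math
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """A single scaffold: id plus an uppercase A/C/G/T/N string."""

    scaffold_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """A protein-coding gene interval, 1-based inclusive."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    aliases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into GenomeSequence records.

    Sequences are uppercased; characters outside A/C/G/T/N and duplicate
    scaffold ids are rejected.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_NT
        if bad:
            raise ValueError(
                f"scaffold {rec.id}: invalid character(s) {sorted(bad)} in sequence"
            )
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(scaffolds: Iterable[GenomeSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.sequence), id=s.scaffold_id, description="")
        for s in scaffolds
    ]
    SeqIO.write(recs, str(path), "fasta")


def _parse_attributes(attr_col: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in attr_col.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            continue
        key, val = item.split("=", 1)
        attrs[key] = urllib.parse.unquote(val)
    return attrs


# attribute keys searched, in order, for the primary gene id
_ID_KEYS = ("locus_tag", "ID", "Name", "gene")
_ALIAS_KEYS = ("old_locus_tag", "Alias", "gene_synonym")


def read_gff(
    path: str | Path,
    feature_type: str = "gene",
    genome: list[GenomeSequence] | None = None,
) -> list[GeneAnnotation]:
    """Read gene annotations from a GFF3 file.

    Only rows whose type column equals *feature_type* are kept. The primary
    gene id comes from locus_tag/ID/Name (first found); old_locus_tag and
    Alias values are stored as aliases. Rows are returned sorted by
    (scaffold, start). If *genome* is given, scaffold ids and coordinate
    bounds are validated against it.
    """
    lengths = {s.scaffold_id: s.length for s in genome} if genome else None
    genes: list[GeneAnnotation] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            scaffold, _source, ftype, start_s, end_s, _score, strand, _frame, attr_col = cols
            if ftype != feature_type:
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            attrs = _parse_attributes(attr_col)
            gene_id = next((attrs[k] for k in _ID_KEYS if k in attrs), None)
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: no usable gene identifier in attributes")
            if gene_id in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen_ids.add(gene_id)
            aliases = []
            for k in _ALIAS_KEYS:
                if k in attrs:
                    aliases.extend(a for a in attrs[k].split(",") if a)
            if lengths is not None:
                if scaffold not in lengths:
                    raise ValueError(
                        f"{path}:{lineno}: scaffold {scaffold!r} not in genome"
                    )
                if end > lengths[scaffold]:
                    raise ValueError(
                        f"{path}:{lineno}: gene {gene_id} end {end} beyond "
                        f"scaffold length {lengths[scaffold]}"
                    )
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    scaffold_id=scaffold,
                    start=start,
                    end=end,
                    strand=strand,
                    product=attrs.get("product", ""),
                    aliases=aliases,
                )
            )
    genes.sort(key=lambda g: (g.scaffold_id, g.start))
    return genes


def write_gff(genes: Iterable[GeneAnnotation], path: str | Path,
              feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold_id, g.start)):
            attrs = [f"ID={g.gene_id}", f"locus_tag={g.gene_id}"]
            if g.aliases:
                attrs.append("old_locus_tag=" + ",".join(g.aliases))
            if g.product:
                attrs.append("product=" + urllib.parse.quote(g.product, safe=" "))
            fh.write(
                "\t".join(
                    [
                        g.scaffold_id,
                        "magscreen",
                        feature_type,
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def central_region(
    gene: GeneAnnotation, lo_frac: float = 0.1, hi_frac: float = 0.9
) -> tuple[int, int]:
    """Interior interval of a gene in which insertions count as disruptive.

    Returns the 1-based inclusive interval
    [start + floor(lo*L), start + ceil(hi*L) - 1] clamped to the gene body;
    always nonempty.
    """
    if not (0 <= lo_frac < hi_frac <= 1):
        raise ValueError(f"invalid fractions ({lo_frac}, {hi_frac})")
    L = gene.length
    lo = gene.start + math.floor(lo_frac * L)
    hi = gene.start + math.ceil(hi_frac * L) - 1
    lo = max(gene.start, min(lo, gene.end))
    hi = max(gene.start, min(hi, gene.end))
    if hi < lo:  # degenerate tiny gene: fall back to single base
        hi = lo
    return lo, hi
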