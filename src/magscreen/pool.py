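"""TnSeq read parsing, junction mapping, pool construction, and library QC.

The pool is represented as a pandas DataFrame with one row per unique
barcode and columns::

    barcode scaffold pos strand n_reads gene_id central multimapped

``pos`` is the 1-based coordinate of the first genomic base of the
junction on the forward strand; ``strand`` is the strand of the junction
match. ``gene_id`` is None for intergenic or ambiguous insertions;
``central`` is True only when the insertion falls in the central region of
exactly one gene.
"""

from __future__ import annotations

import gzip
import json
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.Seq import reverse_complement

from magscreen.genome_io import GeneAnnotation, GenomeSequence, central_region

POOL_COLUMNS = [
    "barcode",
    "scaffold",
    "pos",
    "strand",
    "n_reads",
    "gene_id",
    "central",
    "multimapped",
]

# rejection reasons returned by parse_tnseq_read
FLANK5_MISSING = "flank5_missing"
FLANK3_MISSING = "flank3_missing"
BARCODE_N = "barcode_N"
JUNCTION_SHORT = "junction_short"


@dataclass(frozen=True)
class TnSeqReadModel:
    """Layout of a TnSeq read: flank5 + barcode + flank3 + junction."""

    flank5: str = "GATGTCCACGAGGTCTCT"
    flank3: str = "CGTACGCTGCAGGTCGAC"
    barcode_len: int = 20
    min_junction_len: int = 15

    def __post_init__(self) -> None:
        if self.barcode_len < 1:
            raise ValueError("barcode_len must be >= 1")
        if self.min_junction_len < 1:
            raise ValueError("min_junction_len must be >= 1")


def parse_tnseq_read(
    read: str, model: TnSeqReadModel
) -> tuple[str, str] | tuple[None, str]:
    """Extract (barcode, junction) from a TnSeq read.

    Returns ``(barcode, junction)`` on success, ``(None, reason)`` on
    rejection with reason one of flank5_missing / flank3_missing /
    barcode_N / junction_short.
    """
    read = read.upper()
    if not read.startswith(model.flank5):
        return None, FLANK5_MISSING
    b0 = len(model.flank5)
    barcode = read[b0 : b0 + model.barcode_len]
    if len(barcode) < model.barcode_len:
        return None, FLANK3_MISSING
    j0 = b0 + model.barcode_len
    if not read[j0:].startswith(model.flank3):
        return None, FLANK3_MISSING
    if "N" in barcode:
        return None, BARCODE_N
    junction = read[j0 + len(model.flank3) :]
    if len(junction) < model.min_junction_len:
        return None, JUNCTION_SHORT
    return barcode, junction


def _find_all(haystack: str, needle: str, limit: int) -> list[int]:
    """0-based start positions of *needle* in *haystack* (overlapping),
    stopping after *limit* matches."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1 and len(out) < limit:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def map_junction(
    junction: str, genome: list[GenomeSequence]
) -> tuple[str, int, str] | str:
    """Exact-match a junction (and its reverse complement) over all scaffolds.

    Returns ``(scaffold_id, position, strand)`` for a unique hit, else the
    string ``"unmapped"`` or ``"multimapped"``. Position is the 1-based
    first genomic base of the junction on the forward strand.
    """
    if not junction:
        raise ValueError("empty junction")
    junction = junction.upper()
    rc = reverse_complement(junction)
    hits: list[tuple[str, int, str]] = []
    for scaf in genome:
        for i in _find_all(scaf.sequence, junction, limit=2):
            hits.append((scaf.scaffold_id, i + 1, "+"))
        if rc != junction:
            # palindromic junctions match both strands at the same start;
            # count them once, as forward hits
            for i in _find_all(scaf.sequence, rc, limit=2):
                hits.append((scaf.scaffold_id, i + 1, "-"))
        if len(hits) > 1:
            return "multimapped"
    if not hits:
        return "unmapped"
    return hits[0]


def _read_fastq_seqs(path: str | Path) -> Iterator[str]:
    """Yield sequences from a (optionally gzipped) FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()  # +
            fh.readline()  # quals
            yield seq


def assign_gene(
    scaffold: str,
    pos: int,
    genes: list[GeneAnnotation],
    lo_frac: float = 0.1,
    hi_frac: float = 0.9,
) -> tuple[str | None, bool]:
    """Map an insertion position to (gene_id, central).

    Central assignment requires the position to lie in the central region
    of exactly one gene; positions central in >1 overlapping gene are
    ambiguous and get no gene. Non-central genic positions are assigned
    when the position lies within exactly one gene body.
    """
    central_hits = []
    body_hits = []
    for g in genes:
        if g.scaffold_id != scaffold:
            continue
        if g.start <= pos <= g.end:
            body_hits.append(g)
            lo, hi = central_region(g, lo_frac, hi_frac)
            if lo <= pos <= hi:
                central_hits.append(g)
    if len(central_hits) == 1:
        return central_hits[0].gene_id, True
    if len(central_hits) > 1:
        return None, False  # ambiguous overlap
    if len(body_hits) == 1:
        return body_hits[0].gene_id, False
    return None, False


def build_pool(
    reads: Iterable[str] | str | Path,
    model: TnSeqReadModel,
    genome: list[GenomeSequence],
    genes: list[GeneAnnotation],
    minority_fraction: float = 0.25,
    central_fracs: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Build a barcode pool from TnSeq reads.

    *reads* is a FASTQ path or an iterable of read sequences. Per barcode
    the modal mapped locus is kept with n_reads = reads supporting it; a
    barcode is flagged multimapped when its minority (non-modal plus
    genome-multimapped) read fraction exceeds *minority_fraction*, when
    the mode is tied, or when it has only genome-multimapped reads.
    """
    if isinstance(reads, (str, Path)):
        reads = _read_fastq_seqs(reads)

    junction_cache: dict[str, tuple[str, int, str] | str] = {}
    votes: dict[str, Counter] = defaultdict(Counter)
    multi_reads: Counter = Counter()
    n_usable = 0
    for read in reads:
        barcode, junction = parse_tnseq_read(read, model)
        if barcode is None:
            continue
        n_usable += 1
        loc = junction_cache.get(junction)
        if loc is None:
            loc = map_junction(junction, genome)
            junction_cache[junction] = loc
        if loc == "unmapped":
            continue
        if loc == "multimapped":
            multi_reads[barcode] += 1
        else:
            votes[barcode][loc] += 1
    if n_usable == 0:
        raise ValueError("no usable TnSeq reads")

    rows = []
    for barcode in sorted(set(votes) | set(multi_reads)):
        counter = votes.get(barcode)
        if not counter:
            continue  # only genome-multimapped evidence: no locus to report
        ranked = counter.most_common()
        (modal_locus, modal_n) = ranked[0]
        tie = len(ranked) > 1 and ranked[1][1] == modal_n
        total = sum(counter.values()) + multi_reads.get(barcode, 0)
        minority = total - modal_n
        multimapped = tie or (minority / total > minority_fraction)
        scaffold, pos, strand = modal_locus
        gene_id, central = assign_gene(scaffold, pos, genes, *central_fracs)
        rows.append(
            {
                "barcode": barcode,
                "scaffold": scaffold,
                "pos": pos,
                "strand": strand,
                "n_reads": modal_n,
                "gene_id": gene_id,
                "central": central and not multimapped,
                "multimapped": multimapped,
            }
        )
    if not rows:
        raise ValueError("no mappable barcodes in read stream")
    return pd.DataFrame(rows, columns=POOL_COLUMNS)


@dataclass(frozen=True)
class PoolQC:
    n_unique_barcodes: int
    n_hit_proteins: int
    hits_per_protein_mean: float
    hits_per_protein_median: float
    reads_per_hit_protein_mean: float
    reads_per_hit_protein_median: float
    read_bias: float  # mean - median reads per hit protein
    fraction_genic: float
    fraction_central: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def pool_qc(pool: pd.DataFrame, genes: list[GeneAnnotation]) -> PoolQC:
    """Library statistics over "hit proteins": genes carrying at least one
    central, uniquely-mapped barcode."""
    if pool.empty:
        raise ValueError("empty pool")
    usable = pool[pool["central"] & ~pool["multimapped"]]
    hits = usable.groupby("gene_id", dropna=True)
    strain_counts = hits.size()
    read_totals = hits["n_reads"].sum()
    if strain_counts.empty:
        raise ValueError("no hit proteins in pool")
    reads_mean = float(read_totals.mean())
    reads_median = float(read_totals.median())
    return PoolQC(
        n_unique_barcodes=int(len(pool)),
        n_hit_proteins=int(len(strain_counts)),
        hits_per_protein_mean=float(strain_counts.mean()),
        hits_per_protein_median=float(strain_counts.median()),
        reads_per_hit_protein_mean=reads_mean,
        reads_per_hit_protein_median=reads_median,
        read_bias=reads_mean - reads_median,
        fraction_genic=float(pool["gene_id"].notna().mean()),
        fraction_central=float(pool["central"].mean()),
    )


def write_pool_tsv(pool: pd.DataFrame, path: str | Path) -> None:
    out = pool.rename(
        columns={"n_reads": "nReads", "gene_id": "geneId"}
    ).copy()
    out["geneId"] = out["geneId"].fillna("-")
    out["central"] = out["central"].map({True: "1", False: "0"})
    out["multimapped"] = out["multimapped"].map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False)


def read_pool_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "geneId": str})
    df = df.rename(columns={"nReads": "n_reads", "geneId": "gene_id"})
    df["gene_id"] = df["gene_id"].replace("-", None)
    df["central"] = df["central"].astype(int).astype(bool)
    df["multimapped"] = df["multimapped"].astype(int).astype(bool)
    if df["barcode"].duplicated().any():
        dups = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValueError(f"duplicate barcode in pool TSV: {dups}")
    return df[POOL_COLUMNS]


def insertion_density_track(
    pool: pd.DataFrame, genome: list[GenomeSequence], bin_size: int = 1000
) -> pd.DataFrame:
    """Simple linear insertion-density track: insertions per bin."""
    frames = []
    for scaf in genome:
        sub = pool[pool["scaffold"] == scaf.scaffold_id]
        n_bins = (scaf.length + bin_size - 1) // bin_size
        counts = [0] * n_bins
        for pos in sub["pos"]:
            counts[(pos - 1) // bin_size] += 1
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaf.scaffold_id,
                    "bin_start": [i * bin_size + 1 for i in range(n_bins)],
                    "n_insertions": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
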