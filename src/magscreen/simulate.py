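"""Forward simulator for a barcoded transposon selection screen.

Generates a random genome with non-overlapping genes, plants an essential
gene set and per-gene column-retention effects, builds an insertion pool,
and simulates growth plus column partitioning into magnetic and
nonmagnetic fractions with multinomial read sampling. Column retention is
per-cell Binomial with a gene-level probability, so the expected
normalized magnetic score of an effect gene has the closed form
log2(p_gene / p_wildtype) (up to the population-average retention of the
denominator). Everything is deterministic under (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from magscreen import barseq, genome_io, pool as pool_mod
from magscreen.barseq import BarSeqReadModel, CountMatrix, Sample, SampleSheet
from magscreen.genome_io import GeneAnnotation, GenomeSequence, central_region
from magscreen.pool import TnSeqReadModel

NT = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int
    genome_len: int = 200_000
    n_genes: int = 200
    gene_len_median: float = 900.0
    gene_len_sigma: float = 0.25
    essential_fraction: float = 0.10
    # gene index -> column retention probability for its central mutants
    retention_effects: dict[int, float] = field(default_factory=dict)
    p_wt: float = 0.9
    n_insertions: int = 10_000
    # gene index -> growth fitness multiplier for its central mutants
    growth_fitness: dict[int, float] = field(default_factory=dict)
    read_depth: int = 300_000
    cell_depth: int = 1_000_000
    replicates: int = 3
    conditions: tuple[str, ...] = ("standard",)
    barcode_len: int = 20
    junction_len: int = 20
    tnseq_reads_per_strain: float = 3.0
    error_rate: float = 0.0
    central_fracs: tuple[float, float] = (0.1, 0.9)
    scaffold_id: str = "scaffold_1"

    def __post_init__(self) -> None:
        if not 0 < self.p_wt <= 1:
            raise ValueError("p_wt must be in (0, 1]")
        for i, p in self.retention_effects.items():
            if not 0 < p <= 1:
                raise ValueError(f"retention for gene index {i} out of (0,1]: {p}")
        if not 0 <= self.essential_fraction <= 1:
            raise ValueError("essential_fraction must be in [0,1]")
        if self.n_insertions <= 0:
            raise ValueError("n_insertions must be > 0")


@dataclass
class SimTruth:
    """Planted ground truth: essential genes and per-gene retention."""

    essential_gene_ids: list[str]
    effect_map: dict[str, float]  # gene_id -> retention p_g
    growth_fitness: dict[str, float]  # gene_id -> multiplier
    p_wt: float

    def expected_mcs(self, gene_id: str) -> float:
        return log2(self.effect_map.get(gene_id, self.p_wt) / self.p_wt)

    def expected_sign(self, gene_id: str) -> str:
        e = self.expected_mcs(gene_id)
        return "-" if e < 0 else ("+" if e > 0 else "0")

    def to_frame(self, gene_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "essential": [g in set(self.essential_gene_ids) for g in gene_ids],
                "retention": [self.effect_map.get(g, self.p_wt) for g in gene_ids],
                "growth_fitness": [self.growth_fitness.get(g, 1.0) for g in gene_ids],
                "expected_mcs": [self.expected_mcs(g) for g in gene_ids],
                "expected_sign": [self.expected_sign(g) for g in gene_ids],
            }
        )


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per pipeline stage
    return np.random.default_rng([stage, config.seed])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=n)])


def simulate_genome(
    config: SimConfig,
) -> tuple[list[GenomeSequence], list[GeneAnnotation], SimTruth]:
    """Random genome with non-overlapping genes on both strands, plus the
    planted essential/effect assignments."""
    rng = _rng(config, 1)
    lengths = np.round(
        rng.lognormal(np.log(config.gene_len_median), config.gene_len_sigma,
                      size=config.n_genes)
    ).astype(int)
    lengths = np.maximum(lengths, 60)
    slack = config.genome_len - int(lengths.sum())
    if slack < config.n_genes + 1:
        raise ValueError(
            f"cannot place {config.n_genes} genes totalling {lengths.sum()} nt "
            f"in a {config.genome_len} nt genome"
        )
    gaps = rng.multinomial(slack - (config.n_genes + 1),
                           np.full(config.n_genes + 1, 1 / (config.n_genes + 1))) + 1
    genes: list[GeneAnnotation] = []
    cursor = 0
    for i in range(config.n_genes):
        start = cursor + int(gaps[i]) + 1  # 1-based
        end = start + int(lengths[i]) - 1
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i:04d}",
                scaffold_id=config.scaffold_id,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                product=f"simulated protein {i}",
                aliases=[f"sim_{i:04d}"],
            )
        )
        cursor = end
    sequence = _random_seq(rng, config.genome_len)
    genome = [GenomeSequence(config.scaffold_id, sequence)]

    effect_idx = set(config.retention_effects) | set(config.growth_fitness)
    bad = [i for i in effect_idx if not 0 <= i < config.n_genes]
    if bad:
        raise ValueError(f"retention_effects indices out of range: {bad}")
    n_essential = int(np.floor(config.essential_fraction * config.n_genes))
    candidates = np.array(sorted(set(range(config.n_genes)) - effect_idx))
    if n_essential > len(candidates):
        raise ValueError("not enough non-effect genes to plant essentials")
    essential_idx = rng.choice(candidates, size=n_essential, replace=False)
    truth = SimTruth(
        essential_gene_ids=sorted(genes[i].gene_id for i in essential_idx),
        effect_map={genes[i].gene_id: p for i, p in config.retention_effects.items()},
        growth_fitness={genes[i].gene_id: w for i, w in config.growth_fitness.items()},
        p_wt=config.p_wt,
    )
    return genome, genes, truth


def _gene_lookup_arrays(genes: list[GeneAnnotation], fracs: tuple[float, float]):
    """Interval arrays for vectorized gene assignment (genes must be
    non-overlapping and sorted, as the simulator guarantees)."""
    starts = np.array([g.start for g in genes])
    ends = np.array([g.end for g in genes])
    regions = [central_region(g, *fracs) for g in genes]
    c_lo = np.array([r[0] for r in regions])
    c_hi = np.array([r[1] for r in regions])
    return starts, ends, c_lo, c_hi


def _assign_vectorized(pos: np.ndarray, genes, starts, ends, c_lo, c_hi):
    """(gene index or -1, central flag) for each position."""
    idx = np.searchsorted(starts, pos, side="right") - 1
    idx_c = np.clip(idx, 0, len(genes) - 1)
    in_body = (idx >= 0) & (pos <= ends[idx_c])
    in_central = in_body & (pos >= c_lo[idx_c]) & (pos <= c_hi[idx_c])
    gene_idx = np.where(in_body, idx_c, -1)
    return gene_idx, in_central


def _kmer_is_unique(seq: str, kmer: str, counts: dict[str, int]) -> bool:
    rc = reverse_complement(kmer)
    if rc == kmer:
        return False  # palindromic junction is strand-ambiguous
    return counts.get(kmer, 0) == 1 and counts.get(rc, 0) == 0


def simulate_pool(
    genome: list[GenomeSequence],
    genes: list[GeneAnnotation],
    truth: SimTruth,
    config: SimConfig,
) -> pd.DataFrame:
    """Insertion pool: uniform positions, lethal filtering of essential
    central hits, unique random barcodes, unique-junction guarantee.

    Insertions whose junction would run off the scaffold or would not map
    back uniquely are resampled; insertions in an essential gene's central
    region are discarded (the mutant is dead), not resampled.
    """
    rng = _rng(config, 2)
    seq = genome[0].sequence
    L = len(seq)
    max_pos = L - config.junction_len + 1
    if max_pos < 1:
        raise ValueError("junction_len exceeds genome length")

    starts, ends, c_lo, c_hi = _gene_lookup_arrays(genes, config.central_fracs)
    essential = set(truth.essential_gene_ids)

    # 20-mer occurrence counts over the forward strand, for uniqueness checks
    k = config.junction_len
    counts: dict[str, int] = {}
    for i in range(L - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1

    positions: list[int] = []
    need = config.n_insertions
    while need > 0:
        draw = rng.integers(1, max_pos + 1, size=need)
        ok = np.fromiter(
            (_kmer_is_unique(seq, seq[p - 1 : p - 1 + k], counts) for p in draw),
            dtype=bool,
            count=len(draw),
        )
        positions.extend(int(p) for p in draw[ok])
        need = config.n_insertions - len(positions)
    pos = np.array(positions)
    strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")

    gene_idx, central = _assign_vectorized(pos, genes, starts, ends, c_lo, c_hi)
    gene_ids = np.array([g.gene_id for g in genes] + [None], dtype=object)
    assigned = gene_ids[gene_idx]  # -1 wraps to the trailing None

    lethal = central & np.fromiter(
        (g in essential for g in assigned), dtype=bool, count=len(assigned)
    )
    keep = ~lethal
    pos, strand, assigned, central = pos[keep], strand[keep], assigned[keep], central[keep]

    barcodes: list[str] = []
    seen: set[str] = set()
    for _ in range(len(pos)):
        while True:
            b = _random_seq(rng, config.barcode_len)
            if b not in seen:
                break
        seen.add(b)
        barcodes.append(b)

    n_reads = 1 + rng.poisson(max(config.tnseq_reads_per_strain - 1, 0), size=len(pos))
    df = pd.DataFrame(
        {
            "barcode": barcodes,
            "scaffold": config.scaffold_id,
            "pos": pos,
            "strand": strand,
            "n_reads": n_reads,
            "gene_id": assigned,
            "central": central,
            "multimapped": False,
        }
    )
    return df[pool_mod.POOL_COLUMNS]


def make_sample_sheet(config: SimConfig, index_len: int = 8) -> SampleSheet:
    """Deterministic sheet: one sample per condition x fraction x replicate."""
    samples = []
    i = 0
    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            for fraction in barseq.FRACTIONS:
                digits = []
                n = i
                for _ in range(index_len):
                    digits.append("ACGT"[n % 4])
                    n //= 4
                samples.append(
                    Sample(
                        sample_id=f"{cond}_{fraction}_r{rep}",
                        condition=cond,
                        fraction=fraction,
                        replicate=rep,
                        index_seq="".join(digits),
                    )
                )
                i += 1
    return SampleSheet(samples)


def simulate_selection(
    pool: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
) -> tuple[CountMatrix, SampleSheet, dict[tuple[str, int], pd.DataFrame]]:
    """Simulate growth, column partitioning, and read sampling.

    Per replicate: precolumn cell counts are multinomial over initial
    abundance times growth fitness; each cell is retained on the column
    with its gene's probability (Binomial per strain); nonmagnetic cells
    are the complement. Reads are multinomial draws from the cell (or
    initial, for t0) proportions at the configured depth. Returns the
    count matrix, the sample sheet, and per-(condition, replicate) latent
    cell-count tables.
    """
    rng = _rng(config, 3)
    sheet = make_sample_sheet(config)
    n = len(pool)
    is_central = (pool["central"] & ~pool["multimapped"]).to_numpy()
    gene = pool["gene_id"].to_numpy(dtype=object)
    retention = np.full(n, truth.p_wt)
    growth = np.ones(n)
    for i in range(n):
        if is_central[i] and gene[i] is not None:
            retention[i] = truth.effect_map.get(gene[i], truth.p_wt)
            growth[i] = truth.growth_fitness.get(gene[i], 1.0)

    init = rng.exponential(1.0, size=n)
    init_p = init / init.sum()

    columns: dict[str, np.ndarray] = {}
    latents: dict[tuple[str, int], pd.DataFrame] = {}
    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            t0_reads = rng.multinomial(config.read_depth, init_p)
            grown = init * growth
            pre_cells = rng.multinomial(config.cell_depth, grown / grown.sum())
            mag_cells = rng.binomial(pre_cells, retention)
            nonmag_cells = pre_cells - mag_cells
            pre_reads = rng.multinomial(config.read_depth, pre_cells / pre_cells.sum())
            mag_reads = rng.multinomial(config.read_depth, mag_cells / mag_cells.sum())
            nm_total = nonmag_cells.sum()
            if nm_total > 0:
                nm_reads = rng.multinomial(config.read_depth, nonmag_cells / nm_total)
            else:
                nm_reads = np.zeros(n, dtype=np.int64)
            columns[f"{cond}_t0_r{rep}"] = t0_reads
            columns[f"{cond}_precolumn_r{rep}"] = pre_reads
            columns[f"{cond}_magnetic_r{rep}"] = mag_reads
            columns[f"{cond}_nonmagnetic_r{rep}"] = nm_reads
            latents[(cond, rep)] = pd.DataFrame(
                {
                    "barcode": pool["barcode"].to_numpy(),
                    "precolumn_cells": pre_cells,
                    "magnetic_cells": mag_cells,
                    "nonmagnetic_cells": nonmag_cells,
                }
            )
    counts = pd.DataFrame(
        {s.sample_id: columns[s.sample_id] for s in sheet.samples},
        index=pd.Index(pool["barcode"], name="barcode"),
    )
    return CountMatrix(counts=counts), sheet, latents


def _mutate(read: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return read
    arr = np.array(list(read))
    hit = rng.random(len(arr)) < error_rate
    if hit.any():
        arr[hit] = NT[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


def emit_tnseq_fastq(
    pool: pd.DataFrame,
    genome: list[GenomeSequence],
    model: TnSeqReadModel,
    path: str | Path,
    config: SimConfig,
) -> int:
    """Write TnSeq reads (flank5+barcode+flank3+junction), n_reads copies
    per strain; junction is the genomic sequence at the insertion locus on
    the recorded strand. Returns the number of reads written."""
    rng = _rng(config, 4)
    seq = {g.scaffold_id: g.sequence for g in genome}
    n_written = 0
    with open(path, "w") as fh:
        for row in pool.itertuples():
            s = seq[row.scaffold]
            junction = s[row.pos - 1 : row.pos - 1 + config.junction_len]
            if row.strand == "-":
                junction = reverse_complement(junction)
            read = model.flank5 + row.barcode + model.flank3 + junction
            for i in range(row.n_reads):
                out = _mutate(read, config.error_rate, rng)
                fh.write(f"@tn_{row.barcode}_{i}\n{out}\n+\n{'I' * len(out)}\n")
                n_written += 1
    return n_written


def emit_barseq_fastq(
    matrix: CountMatrix,
    sheet: SampleSheet,
    model: BarSeqReadModel,
    path: str | Path,
    config: SimConfig | None = None,
) -> int:
    """Write one multiplexed BarSeq FASTQ (index+flank+barcode), count
    copies per (barcode, sample). Returns the number of reads written."""
    by_id = {s.sample_id: s for s in sheet.samples}
    rng = _rng(config, 5) if config is not None else None
    error_rate = config.error_rate if config is not None else 0.0
    n_written = 0
    with open(path, "w") as fh:
        for sample_id in matrix.counts.columns:
            index = by_id[sample_id].index_seq
            col = matrix.counts[sample_id]
            for barcode, count in col[col > 0].items():
                read = index + model.flank5 + barcode
                for i in range(int(count)):
                    out = _mutate(read, error_rate, rng) if rng is not None else read
                    fh.write(
                        f"@bs_{sample_id}_{barcode}_{i}\n{out}\n+\n{'I' * len(out)}\n"
                    )
                    n_written += 1
    return n_written


def run_screen(config: SimConfig, out_dir: str | Path, write_fastq: bool = False) -> dict:
    """End-to-end simulation writing all artifacts to *out_dir*.

    Writes genome FASTA, genes GFF3, pool TSV, truth TSV, sample sheet
    TSV, counts TSV, and optionally TnSeq/BarSeq FASTQ. Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate_genome(config)
    pool_df = simulate_pool(genome, genes, truth, config)
    matrix, sheet, _ = simulate_selection(pool_df, truth, config)

    paths = {
        "genome": out / "genome.fasta",
        "genes": out / "genes.gff3",
        "pool": out / "pool.tsv",
        "truth": out / "truth.tsv",
        "sample_sheet": out / "samples.tsv",
        "counts": out / "counts.tsv",
    }
    genome_io.write_fasta(genome, paths["genome"])
    genome_io.write_gff(genes, paths["genes"])
    pool_mod.write_pool_tsv(pool_df, paths["pool"])
    truth.to_frame([g.gene_id for g in genes]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    barseq.write_sample_sheet(sheet, paths["sample_sheet"])
    barseq.write_counts_tsv(matrix, paths["counts"])
    if write_fastq:
        paths["tnseq_fastq"] = out / "tnseq.fastq"
        paths["barseq_fastq"] = out / "barseq.fastq"
        emit_tnseq_fastq(pool_df, genome, TnSeqReadModel(), paths["tnseq_fastq"], config)
        emit_barseq_fastq(matrix, sheet, BarSeqReadModel(), paths["barseq_fastq"], config)
    return {k: str(v) for k, v in paths.items()}
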